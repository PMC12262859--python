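"""Fragmentomics features: S2L ratio, size histogram, periodicity, motifs, FSD.

Conventions
-----------
* S2L = count(80-160 bp) / count(161-200 bp), inclusive bounds.
* End motifs (EDM): the first 6 reference bases inside each fragment end,
  read 5'->3' into the fragment, i.e. ``ref[start:start+6]`` upstream and
  the reverse complement of ``ref[end-6:end]`` downstream.
* Breakpoint motifs (BPM): 6-mers spanning each break, 3 bases outside +
  3 inside: ``ref[start-3:start+3]`` upstream and the reverse complement of
  ``ref[end-3:end+3]`` downstream.
* FSD: per-chromosome-arm fractions of fragment lengths in 5-bp bins
  65-69, 70-74, ..., 395-399 (67 bins, inclusive bounds), normalized
  within each arm.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .genome import GenomeModel, InvalidSpecError

logger = logging.getLogger(__name__)

S2L_SHORT_RANGE = (80, 160)
S2L_LONG_RANGE = (161, 200)
FSD_RANGE = (65, 399)
FSD_STEP = 5

_ALL_MOTIFS = ["".join(m) for m in itertools.product("ACGT", repeat=6)]
_POW4 = 4 ** np.arange(5, -1, -1)


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is undefined for the given input."""


@dataclass(frozen=True)
class S2LRatio:
    short_count: int
    long_count: int

    @property
    def ratio(self) -> float:
        return self.short_count / self.long_count


def compute_s2l(
    lengths: Iterable[int] | pd.DataFrame,
    short_range: tuple[int, int] = S2L_SHORT_RANGE,
    long_range: tuple[int, int] = S2L_LONG_RANGE,
) -> S2LRatio:
    """Short-to-long ratio of fragment counts (inclusive bounds)."""
    if isinstance(lengths, pd.DataFrame):
        lengths = lengths["length"]
    arr = np.asarray(lengths)
    short = int(((arr >= short_range[0]) & (arr <= short_range[1])).sum())
    long = int(((arr >= long_range[0]) & (arr <= long_range[1])).sum())
    if long == 0:
        raise UndefinedStatisticError(
            f"no fragments in the long range {long_range[0]}-{long_range[1]} bp"
        )
    return S2LRatio(short, long)


def size_histogram(lengths: Iterable[int] | pd.DataFrame) -> pd.Series:
    """Integer-length counts as a Series indexed by length (ascending)."""
    if isinstance(lengths, pd.DataFrame):
        lengths = lengths["length"]
    arr = np.asarray(lengths, dtype=np.int64)
    if arr.size == 0:
        raise UndefinedStatisticError("size_histogram: empty input")
    counts = np.bincount(arr)
    idx = np.arange(counts.size)
    nz = counts > 0
    lo, hi = idx[nz][0], idx[nz][-1]
    return pd.Series(counts[lo : hi + 1], index=idx[lo : hi + 1], name="count")


def histogram_mode(hist: pd.Series) -> int:
    """Argmax of the histogram; ties broken toward the smallest length."""
    return int(hist.index[np.argmax(hist.to_numpy())])


def size_fractions(hist: pd.Series) -> pd.Series:
    return hist / hist.sum()


def estimate_periodicity(
    hist: pd.Series,
    search_range: tuple[int, int] = (90, 160),
    smooth_window: int = 3,
    rel_prominence: float = 0.15,
) -> float:
    """Mean spacing of local maxima of the smoothed histogram in ``search_range``.

    The histogram is smoothed with a centered moving average (window 3 bp by
    default); local maxima whose prominence is at least ``rel_prominence``
    of their own height count as peaks.  At least two peaks are required.
    """
    lo, hi = search_range
    full = hist.reindex(np.arange(hist.index.min(), hist.index.max() + 1), fill_value=0)
    smoothed = (
        full.rolling(smooth_window, center=True, min_periods=1).mean().to_numpy()
    )
    idx = full.index.to_numpy()
    sel = (idx >= lo) & (idx <= hi)
    y = smoothed[sel]
    x = idx[sel]
    if y.size < 3:
        raise UndefinedStatisticError("periodicity: search range too narrow")
    peaks, props = find_peaks(y, prominence=0)
    keep = props["prominences"] >= rel_prominence * y[peaks]
    positions = x[peaks[keep]]
    if positions.size < 2:
        raise UndefinedStatisticError(
            "periodicity: fewer than two local maxima in the search range"
        )
    return float(np.mean(np.diff(positions)))


@dataclass
class MotifSpectrum:
    """Normalized frequency vector over the 4,096 6-mers (BPM or EDM)."""

    flavor: str  # "BPM" or "EDM"
    frequencies: pd.Series  # index = all 4096 motifs
    n_counted: int = 0
    n_skipped: int = 0

    def to_tsv(self, path) -> None:
        self.frequencies.rename_axis("motif").rename("frequency").to_csv(path, sep="\t")


def _motif_indices(codes: np.ndarray, positions: np.ndarray, revcomp: bool) -> np.ndarray:
    """Base-4 indices of 6-mers at ``positions``; -1 where the window holds an N."""
    win = codes[positions[:, None] + np.arange(6)]
    if revcomp:
        win = 3 - win[:, ::-1]
    valid = (win >= 0).all(axis=1) & (win <= 3).all(axis=1)
    idx = np.where(valid, (win.clip(0, 3) * _POW4).sum(axis=1), -1)
    return idx


def compute_motif_spectrum(
    frags: pd.DataFrame, genome: GenomeModel, flavor: str
) -> MotifSpectrum:
    """Count 6-mers at both fragment ends against the reference.

    Each fragment contributes one upstream and one downstream motif, both
    oriented 5'->3' into the fragment (the downstream motif is the reverse
    complement of the reference window).  Windows running off the
    chromosome and windows containing N are skipped and logged.
    """
    flavor = flavor.upper()
    if flavor == "EDM":
        up_off, down_off = 0, -6  # ref[start:start+6], ref[end-6:end]
    elif flavor == "BPM":
        up_off, down_off = -3, -3  # ref[start-3:start+3], ref[end-3:end+3]
    else:
        raise InvalidSpecError(f"unknown motif flavor {flavor!r}")

    counts = np.zeros(4096, dtype=np.int64)
    n_counted = 0
    n_skipped = 0
    for chrom, sub in frags.groupby("chrom", observed=True, sort=True):
        codes = genome.codes(str(chrom)).astype(np.int16)
        L = codes.size
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if (starts < 0).any() or (ends > L).any():
            raise InvalidSpecError(f"fragment outside chromosome {chrom}")
        up_pos = starts + up_off
        down_pos = ends + down_off
        for pos, rc in ((up_pos, False), (down_pos, True)):
            ok = (pos >= 0) & (pos + 6 <= L)
            n_skipped += int((~ok).sum())
            idx = _motif_indices(codes, pos[ok], rc)
            n_skipped += int((idx < 0).sum())
            idx = idx[idx >= 0]
            counts += np.bincount(idx, minlength=4096)
            n_counted += idx.size
    total = counts.sum()
    freqs = counts / total if total > 0 else counts.astype(float)
    if n_skipped:
        logger.info("compute_motif_spectrum(%s): skipped %d ends", flavor, n_skipped)
    return MotifSpectrum(flavor, pd.Series(freqs, index=_ALL_MOTIFS), n_counted, n_skipped)


def fsd_bins(
    size_range: tuple[int, int] = FSD_RANGE, step: int = FSD_STEP
) -> list[tuple[int, int]]:
    """Inclusive (lo, hi) length bins: 65-69, ..., 395-399 by default."""
    lo, hi = size_range
    if (hi - lo + 1) % step != 0:
        raise InvalidSpecError(
            f"FSD range {lo}-{hi} is not tiled by bins of width {step}"
        )
    return [(s, s + step - 1) for s in range(lo, hi + 1, step)]


def fsd_feature_index(
    arms: Sequence[str], bins: Sequence[tuple[int, int]] | None = None
) -> list[str]:
    """Marker names '<arm>:<lo>-<hi>' in arm-major order."""
    bins = fsd_bins() if bins is None else list(bins)
    return [f"{arm}:{lo}-{hi}" for arm in arms for lo, hi in bins]


def compute_fsd(
    frags: pd.DataFrame,
    arm_table: Sequence,
    bins: Sequence[tuple[int, int]] | None = None,
) -> pd.Series:
    """Per-arm fragment-size-distribution fractions.

    Fragments are assigned to arms by start position; lengths outside the
    bin range are excluded; fractions are normalized within each arm.  Arms
    with no in-range fragment yield zero rows (logged).  The result is a
    Series over ``fsd_feature_index`` of the arm table's arms.
    """
    bins = fsd_bins() if bins is None else list(bins)
    widths = {hi - lo + 1 for lo, hi in bins}
    if len(widths) != 1:
        raise InvalidSpecError("FSD bins must share one width")
    step = widths.pop()
    lo_all = bins[0][0]
    hi_all = bins[-1][1]

    arm_names = [a.name for a in arm_table]
    arm_of = {}
    by_chrom: dict[str, list] = {}
    for ai, a in enumerate(arm_table):
        by_chrom.setdefault(a.chrom, []).append((a.start, a.end, ai))
    n_arms = len(arm_names)
    n_bins = len(bins)
    counts = np.zeros((n_arms, n_bins), dtype=np.int64)

    for chrom, sub in frags.groupby("chrom", observed=True, sort=True):
        arms = sorted(by_chrom.get(str(chrom), []))
        if not arms:
            raise InvalidSpecError(f"fragment on chromosome {chrom!r} with no arm")
        arm_starts = np.array([a[0] for a in arms])
        arm_ends = np.array([a[1] for a in arms])
        arm_idx = np.array([a[2] for a in arms])
        starts = sub["start"].to_numpy()
        pos = np.searchsorted(arm_starts, starts, side="right") - 1
        ok = (pos >= 0) & (starts < arm_ends[np.clip(pos, 0, len(arms) - 1)])
        if not ok.all():
            raise InvalidSpecError(
                f"{int((~ok).sum())} fragments on {chrom} fall outside every arm"
            )
        lengths = sub["length"].to_numpy() if "length" in sub else (
            sub["end"].to_numpy() - starts
        )
        in_range = (lengths >= lo_all) & (lengths <= hi_all)
        bi = (lengths[in_range] - lo_all) // step
        flat = arm_idx[pos[in_range]] * n_bins + bi
        counts += np.bincount(flat, minlength=n_arms * n_bins).reshape(n_arms, n_bins)

    totals = counts.sum(axis=1, keepdims=True)
    empty = totals[:, 0] == 0
    if empty.any():
        logger.info(
            "compute_fsd: %d arms with no in-range fragments (zero rows)",
            int(empty.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        fracs = np.where(totals > 0, counts / np.maximum(totals, 1), 0.0)
    return pd.Series(fracs.ravel(), index=fsd_feature_index(arm_names, bins), name="fraction")
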