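"""ctDNA isolation: blacklist construction, classifier-call merging, filters.

The isolation logic mirrors the xenograft dissection workflow: human-genome
regions recurrently hit by host ("human-prone") reads across control samples
and classification methods are blacklisted; reads called human by either
classifier are merged; alignments are kept when MAPQ >= 30 and they do not
overlap the blacklist; fragments are inferred from mate pairs and kept when
50 <= length <= 1000 bp.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeModel, InvalidSpecError

logger = logging.getLogger(__name__)

DEFAULT_MIN_MAPQ = 30
DEFAULT_LENGTH_RANGE = (50, 1000)


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Merge overlapping or touching (start, end) intervals; returns sorted array."""
    if len(intervals) == 0:
        return np.empty((0, 2), dtype=np.int64)
    ivals = np.asarray(intervals, dtype=np.int64)
    order = np.lexsort((ivals[:, 1], ivals[:, 0]))
    ivals = ivals[order]
    merged = [list(ivals[0])]
    for s, e in ivals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


@dataclass
class Blacklist:
    """Merged genomic intervals with per-interval supporting (sample, method) pairs."""

    intervals: dict[str, np.ndarray] = field(default_factory=dict)  # chrom -> (n, 2)
    provenance: dict[str, list[set[tuple[str, str]]]] = field(default_factory=dict)

    def overlaps(self, chrom: np.ndarray, start: np.ndarray, end: np.ndarray) -> np.ndarray:
        """Vectorized any-overlap test for (chrom, start, end) intervals."""
        start = np.asarray(start)
        end = np.asarray(end)
        hit = np.zeros(start.shape[0], dtype=bool)
        chrom = np.asarray(chrom)
        for c, ivals in self.intervals.items():
            if len(ivals) == 0:
                continue
            sel = chrom == c
            if not sel.any():
                continue
            # interval i overlaps [s, e) iff starts[i] < e and ends[i] > s;
            # with sorted disjoint intervals the candidate is the first one
            # whose end exceeds s.
            idx = np.searchsorted(ivals[:, 1], start[sel], side="right")
            cand = np.minimum(idx, len(ivals) - 1)
            hit_sel = (idx < len(ivals)) & (ivals[cand, 0] < end[sel])
            hit[sel] = hit_sel
        return hit

    @property
    def total_bp(self) -> int:
        return int(sum((iv[:, 1] - iv[:, 0]).sum() for iv in self.intervals.values()))

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.intervals):
                for (s, e), prov in zip(self.intervals[chrom], self.provenance[chrom]):
                    name = ";".join(sorted(f"{smp}|{m}" for smp, m in prov)) or "."
                    fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")


def build_blacklist(
    control_regions: Mapping[tuple[str, str], pd.DataFrame],
    known_chroms: Iterable[str] | None = None,
) -> Blacklist:
    """Compile blacklisted regions from control human-prone alignments.

    ``control_regions`` maps (sample, method) to a table of intervals
    (columns chrom/start/end); overlapping alignments of one (sample,
    method) are first merged into regions.  A genomic position is
    blacklisted iff it is covered by regions of at least two distinct
    samples or at least two distinct methods; adjacent blacklisted
    positions are merged into intervals.
    """
    if not control_regions:
        raise InvalidSpecError("at least one (sample, method) region set is required")
    known = set(known_chroms) if known_chroms is not None else None

    # merged region list per (sample, method), grouped by chromosome
    per_key: dict[str, dict[tuple[str, str], np.ndarray]] = {}
    for key, df in control_regions.items():
        if len(df) == 0:
            continue
        for chrom, sub in df.groupby("chrom", observed=True, sort=True):
            chrom = str(chrom)
            if known is not None and chrom not in known:
                raise InvalidSpecError(f"unknown chromosome {chrom!r} in control regions")
            ivals = merge_intervals(sub[["start", "end"]].to_numpy())
            per_key.setdefault(chrom, {})[key] = ivals

    out = Blacklist()
    for chrom, keyed in sorted(per_key.items()):
        bounds = np.unique(np.concatenate([iv.ravel() for iv in keyed.values()]))
        if bounds.size < 2:
            continue
        seg_start = bounds[:-1]
        seg_end = bounds[1:]
        mid = seg_start  # segments are elementary: covered iff start is covered
        cover = {}  # key -> bool per segment
        for key, ivals in keyed.items():
            idx = np.searchsorted(ivals[:, 1], mid, side="right")
            cand = np.minimum(idx, len(ivals) - 1)
            cover[key] = (idx < len(ivals)) & (ivals[cand, 0] <= mid)
        samples_per_seg = np.zeros(mid.size, dtype=np.int32)
        methods_per_seg = np.zeros(mid.size, dtype=np.int32)
        for smp in {k[0] for k in keyed}:
            any_cov = np.zeros(mid.size, dtype=bool)
            for key, cov in cover.items():
                if key[0] == smp:
                    any_cov |= cov
            samples_per_seg += any_cov
        for meth in {k[1] for k in keyed}:
            any_cov = np.zeros(mid.size, dtype=bool)
            for key, cov in cover.items():
                if key[1] == meth:
                    any_cov |= cov
            methods_per_seg += any_cov
        keep = (samples_per_seg >= 2) | (methods_per_seg >= 2)
        if not keep.any():
            continue
        merged = merge_intervals(np.column_stack([seg_start[keep], seg_end[keep]]))
        prov = []
        for s, e in merged:
            supp = set()
            for key, ivals in keyed.items():
                idx = np.searchsorted(ivals[:, 1], s, side="right")
                if idx < len(ivals) and ivals[idx, 0] < e:
                    supp.add(key)
            prov.append(supp)
        out.intervals[chrom] = merged
        out.provenance[chrom] = prov
    return out


def merge_human_calls(verdicts: pd.DataFrame) -> np.ndarray:
    """Union of read_ids called human by any method (duplicates collapsed).

    Raises on conflicting duplicate verdicts for one (read, method).
    """
    dup = verdicts.duplicated(subset=["read_id", "method"], keep=False)
    if dup.any():
        sub = verdicts[dup]
        n_conflict = sub.groupby(["read_id", "method"], observed=True)["call"].nunique()
        if (n_conflict > 1).any():
            rid, meth = n_conflict[n_conflict > 1].index[0]
            raise InvalidSpecError(
                f"conflicting verdicts for read {rid!r} by method {meth!r}"
            )
    human = verdicts.loc[np.asarray(verdicts["call"]) == "human", "read_id"]
    return np.unique(human.to_numpy())


def filter_alignments(
    reads: pd.DataFrame,
    blacklist: Blacklist | None = None,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> pd.DataFrame:
    """Keep reads with MAPQ >= min_mapq and no blacklist overlap (any overlap)."""
    keep = reads["mapq"].to_numpy() >= min_mapq
    if blacklist is not None and blacklist.intervals:
        keep &= ~blacklist.overlaps(
            reads["chrom"].to_numpy(), reads["start"].to_numpy(), reads["end"].to_numpy()
        )
    return reads.loc[keep].reset_index(drop=True)


def infer_fragments(
    reads: pd.DataFrame,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
) -> pd.DataFrame:
    """Infer fragments as the outer span of each mate pair.

    Pairs with mates on different chromosomes and orphan reads are skipped
    (counts logged and recorded in ``df.attrs``).  Fragments with length
    outside ``length_range`` (inclusive) are dropped.
    """
    lo, hi = length_range
    grp = reads.groupby("read_id", observed=True, sort=True)
    agg = grp.agg(
        chrom=("chrom", "first"),
        n_chrom=("chrom", "nunique"),
        start=("start", "min"),
        end=("end", "max"),
        mapq=("mapq", "min"),
        n=("chrom", "size"),
    )
    orphans = int((agg["n"] != 2).sum())
    discordant = int(((agg["n"] == 2) & (agg["n_chrom"] > 1)).sum())
    if orphans:
        logger.info("infer_fragments: skipped %d orphan read groups", orphans)
    if discordant:
        logger.info("infer_fragments: skipped %d discordant pairs", discordant)
    ok = (agg["n"] == 2) & (agg["n_chrom"] == 1)
    frags = agg.loc[ok, ["chrom", "start", "end", "mapq"]].reset_index()
    frags["length"] = frags["end"] - frags["start"]
    length_dropped = int(((frags["length"] < lo) | (frags["length"] > hi)).sum())
    frags = frags[(frags["length"] >= lo) & (frags["length"] <= hi)].reset_index(drop=True)
    frags.attrs["n_orphans"] = orphans
    frags.attrs["n_discordant"] = discordant
    frags.attrs["n_length_dropped"] = length_dropped
    return frags


def fragments_to_read_pairs(frags: pd.DataFrame, read_len: int = 75) -> pd.DataFrame:
    """Expand fragment intervals into convergent mate-pair alignments."""
    r1 = frags[["read_id", "chrom", "start", "end", "mapq"]].copy()
    r1["mate"] = 1
    r1["end"] = np.minimum(r1["start"] + read_len, frags["end"])
    r2 = frags[["read_id", "chrom", "start", "end", "mapq"]].copy()
    r2["mate"] = 2
    r2["start"] = np.maximum(r2["end"] - read_len, frags["start"])
    return pd.concat([r1, r2], ignore_index=True)


def pool_replicates(
    samples: Mapping[str, pd.DataFrame], groups: Mapping[str, str]
) -> dict[str, pd.DataFrame]:
    """Multiset union of fragment tables within each group.

    ``groups`` maps sample name to group key; every sample must be mapped.
    """
    pooled: dict[str, list[pd.DataFrame]] = {}
    for name, df in samples.items():
        if name not in groups:
            raise InvalidSpecError(f"sample {name!r} has no group key")
        df = df.copy()
        df["sample"] = name
        pooled.setdefault(groups[name], []).append(df)
    return {
        key: pd.concat(frames, ignore_index=True) for key, frames in sorted(pooled.items())
    }


def downsample(frags: pd.DataFrame, target_count: int, seed: int) -> pd.DataFrame:
    """Uniform sample without replacement of min(target, available) fragments."""
    if target_count < 1:
        raise InvalidSpecError("target_count must be >= 1")
    n = len(frags)
    if target_count >= n:
        if target_count > n:
            warnings.warn(
                f"downsample target {target_count} exceeds available {n}; returning all",
                stacklevel=2,
            )
        return frags.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=target_count, replace=False)
    return frags.iloc[np.sort(idx)].reset_index(drop=True)
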