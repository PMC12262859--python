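"""Binned copy-number features: 1-Mb fragment counts and log2 coverage ratios.

This reproduces only the bin-level log2-ratio feature matrix used for
clustering/PCA of copy-number patterns; segmentation and tumor-fraction
modeling are intentionally out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .genome import GenomeModel, InvalidSpecError

DEFAULT_BIN_SIZE = 1_000_000
DEFAULT_PSEUDOCOUNT = 0.5


class DegenerateInputError(ValueError):
    """Raised when a matrix carries no usable variation."""


@dataclass
class BinGrid:
    """Fixed-width genome tiling with an exclusion mask.

    ``bins`` has columns chrom/start/end plus a boolean ``masked`` column
    for bins overlapping excluded regions (gap/excludable analogue).
    """

    bins: pd.DataFrame
    bin_size: int

    @classmethod
    def from_genome(
        cls,
        genome: GenomeModel,
        bin_size: int = DEFAULT_BIN_SIZE,
        exclude: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    ) -> "BinGrid":
        if bin_size < 1:
            raise InvalidSpecError("bin_size must be positive")
        exclude = dict(exclude or {})
        for chrom, ivals in genome.excluded_regions.items():
            exclude.setdefault(chrom, [])
            exclude[chrom] = list(exclude[chrom]) + list(ivals)
        rows = []
        for chrom, length in genome.lengths.items():
            for s in range(0, length, bin_size):
                e = min(s + bin_size, length)
                masked = any(xs < e and xe > s for xs, xe in exclude.get(chrom, ()))
                rows.append((chrom, s, e, masked))
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end", "masked"]), bin_size)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def unmasked_index(self) -> pd.Index:
        b = self.bins
        return pd.Index(
            [f"{c}:{s}-{e}" for c, s, e, m in b.itertuples(index=False) if not m]
        )

    def bin_labels(self) -> pd.Index:
        return pd.Index(
            [f"{c}:{s}-{e}" for c, s, e in self.bins[["chrom", "start", "end"]].itertuples(index=False)]
        )


def bin_counts(frags: pd.DataFrame, grid: BinGrid) -> pd.Series:
    """Per-bin fragment counts; a fragment belongs to the bin holding its midpoint.

    Midpoints exactly on a bin boundary go to the higher bin (half-open
    convention).  Masked bins report counts too (flagged in the grid).
    """
    counts = np.zeros(grid.n_bins, dtype=np.int64)
    b = grid.bins
    for chrom, sub in frags.groupby("chrom", observed=True, sort=True):
        rows = b.index[b["chrom"] == str(chrom)].to_numpy()
        if rows.size == 0:
            raise InvalidSpecError(f"fragments on {chrom!r} absent from the bin grid")
        starts = b.loc[rows, "start"].to_numpy()
        ends = b.loc[rows, "end"].to_numpy()
        mid = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
        bi = np.searchsorted(starts, mid, side="right") - 1
        ok = (bi >= 0) & (mid < ends[np.clip(bi, 0, rows.size - 1)])
        counts += np.bincount(rows[bi[ok]], minlength=grid.n_bins)
    return pd.Series(counts, index=grid.bin_labels(), name="count")


def log2_ratio_matrix(
    sample_counts: Mapping[str, pd.Series],
    grid: BinGrid,
    reference_counts: Mapping[str, pd.Series] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Samples x unmasked-bins matrix of log2 coverage ratios.

    Every count vector is first depth-normalized to an equal total (one
    million) over unmasked bins, so vectors of any depth are comparable and
    the pseudocount only guards zero bins.  The expected per-bin coverage
    is the mean of the normalized reference samples (pooled controls) when
    given, otherwise each sample's own median unmasked-bin count.  Values
    are ``log2((sample + pc) / (expected + pc))``.
    """
    unmasked = ~grid.bins["masked"].to_numpy()
    labels = grid.bin_labels()[unmasked]

    def normalized(counts: pd.Series) -> np.ndarray:
        v = counts.to_numpy(dtype=float)[unmasked]
        total = v.sum()
        if total <= 0:
            raise InvalidSpecError("sample with zero total count over unmasked bins")
        return v * (1e6 / total)  # counts per million over unmasked bins

    norm = {name: normalized(c) for name, c in sample_counts.items()}
    expected = None
    if reference_counts:
        ref = np.vstack([normalized(c) for c in reference_counts.values()])
        expected = ref.mean(axis=0)
    rows = {}
    for name, v in norm.items():
        exp = expected if expected is not None else np.full_like(v, np.median(v))
        rows[name] = np.log2((v + pseudocount) / (exp + pseudocount))
    return pd.DataFrame.from_dict(rows, orient="index", columns=labels)


def cna_pca(matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Column-centered PCA: component scores and variance-explained percentages.

    The percentages sum to 100 over all computed components.
    """
    if len(matrix) < 2:
        raise DegenerateInputError("PCA needs at least 2 samples")
    X = matrix.to_numpy(dtype=float)
    if np.allclose(X.var(axis=0), 0):
        raise DegenerateInputError("constant matrix: no variance to decompose")
    n_comp = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X - X.mean(axis=0))
    var_pct = 100.0 * pca.explained_variance_ratio_
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=matrix.index, columns=cols), var_pct
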