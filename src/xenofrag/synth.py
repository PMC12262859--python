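"""Synthetic two-species cfDNA cohorts.

Generates the full statistical structure the downstream analysis assumes:
random references for host (mouse-like) and graft (human-like) genomes,
fragment populations with nucleosome-like size structure, per-sample ctDNA
fractions, group-specific fragment-size effects, CNA-weighted placement of
graft fragments, and imperfect per-read species-classifier verdicts.

The size model is a discrete distribution over integer lengths: a skewed
unimodal kernel around the mode (slow decay below, fast decay above, as in
plasma cfDNA), multiplied below the mode by a cosine comb of the stated
period (the nucleosome-protection "ladder"), plus a dinucleosome bump near
twice the mode, a small uniform floor, and a multiplicative boost of the
sub-mononucleosomal tail for tumor-like profiles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import (
    Arm,
    GenomeModel,
    InvalidSpecError,
    ReferenceSpec,
    generate_reference,
)

__all__ = [
    "SizeProfile",
    "FSDEffect",
    "ClassifierModel",
    "CNASegment",
    "CohortDesign",
    "Cohort",
    "SampleData",
    "HOST_CFDNA_PROFILE",
    "CTDNA_PROFILE",
    "sample_fragment_lengths",
    "generate_cohort",
    "default_host_spec",
    "default_graft_spec",
]

CALLS = ("human", "mouse", "both", "neither")


@dataclass(frozen=True)
class SizeProfile:
    """Parametric fragment-length distribution for one cfDNA population.

    Parameters
    ----------
    mode : int
        Modal fragment length in bp (167 for host plasma cfDNA, ~143 for
        tumor-derived ctDNA).
    period : float
        Spacing in bp of the sub-modal oscillation (~10 bp for cfDNA).
    comb_depth : float
        Depth in [0, 1] of the cosine comb below the mode; 0 disables it.
    short_boost : float
        Multiplier (>= 0) applied to the sub-mononucleosomal tail, i.e.
        lengths below ``mode - period``; >1 enriches short fragments.
    dinucleosome_weight : float
        Probability mass of the bump near 2x the mode.
    support : (int, int)
        Inclusive length bounds; nothing is generated outside.
    tail_left, tail_right : float
        Exponential decay scales (bp) of the kernel below/above the mode.
    floor_weight : float
        Probability mass spread uniformly over the support.
    """

    mode: int = 167
    period: float = 10.0
    comb_depth: float = 0.55
    short_boost: float = 1.0
    dinucleosome_weight: float = 0.04
    support: tuple[int, int] = (50, 420)
    tail_left: float = 18.0
    tail_right: float = 7.0
    dinucleosome_sd: float = 25.0
    floor_weight: float = 0.02

    def __post_init__(self) -> None:
        lo, hi = self.support
        if lo >= hi:
            raise InvalidSpecError("empty size-profile support")
        if not (lo <= self.mode <= hi):
            raise InvalidSpecError("profile mode outside support")
        if self.period <= 0:
            raise InvalidSpecError("period must be positive")
        for name in ("comb_depth", "short_boost", "dinucleosome_weight", "floor_weight"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be non-negative")
        if self.comb_depth > 1:
            raise InvalidSpecError("comb_depth must be <= 1")

    def pmf(self, effects: Sequence[tuple[tuple[int, int], float]] = ()) -> tuple[np.ndarray, np.ndarray]:
        """Return (lengths, probabilities) of the discrete length distribution.

        ``effects`` is a list of ((lo, hi), multiplier) range enrichments
        applied multiplicatively before the final renormalization.
        """
        lo, hi = self.support
        lengths = np.arange(lo, hi + 1)
        below = lengths <= self.mode
        kernel = np.where(
            below,
            np.exp(-(self.mode - lengths) / self.tail_left),
            np.exp(-(lengths - self.mode) / self.tail_right),
        )
        phase = 2.0 * np.pi * (self.mode - lengths) / self.period
        comb = np.where(below, 1.0 - self.comb_depth * (1.0 - np.cos(phase)) / 2.0, 1.0)
        w = kernel * comb
        # smooth sub-mononucleosomal enrichment: full boost well below the
        # mode, fading out ~2 periods beneath it so the mode itself stays put
        ramp_center = self.mode - 2.0 * self.period
        ramp = 1.0 / (1.0 + np.exp(np.clip((lengths - ramp_center) / (self.period / 2.0), -50, 50)))
        w *= 1.0 + (self.short_boost - 1.0) * ramp
        w /= w.sum()
        core = 1.0 - self.dinucleosome_weight - self.floor_weight
        if core < 0:
            raise InvalidSpecError("dinucleosome_weight + floor_weight exceeds 1")
        p = core * w
        if self.dinucleosome_weight > 0:
            bump = np.exp(-0.5 * ((lengths - 2 * self.mode) / self.dinucleosome_sd) ** 2)
            s = bump.sum()
            if s > 0:
                p = p + self.dinucleosome_weight * bump / s
        p = p + self.floor_weight / lengths.size
        for (rlo, rhi), mult in effects:
            if rlo < lo or rhi > hi:
                raise InvalidSpecError(
                    f"effect range {rlo}-{rhi} outside profile support {lo}-{hi}"
                )
            p[(lengths >= rlo) & (lengths <= rhi)] *= mult
        return lengths, p / p.sum()


#: Default host (mouse plasma) cfDNA profile: 167 bp mode, ~10 bp ladder.
HOST_CFDNA_PROFILE = SizeProfile()

#: Default tumor-derived ctDNA profile: ~143 bp mode, shorter periodicity,
#: enriched sub-mononucleosomal tail.
CTDNA_PROFILE = SizeProfile(
    mode=143,
    period=7.0,
    comb_depth=0.6,
    short_boost=1.8,
    dinucleosome_weight=0.02,
    tail_left=20.0,
    tail_right=9.0,
)


def sample_fragment_lengths(
    profile: SizeProfile,
    n: int,
    seed: int | np.random.Generator,
    effects: Sequence[tuple[tuple[int, int], float]] = (),
) -> np.ndarray:
    """Draw ``n`` integer fragment lengths from a :class:`SizeProfile`."""
    if n < 1:
        raise InvalidSpecError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths, p = profile.pmf(effects)
    cdf = np.cumsum(p)
    cdf[-1] = 1.0
    return lengths[np.searchsorted(cdf, rng.random(n), side="right")]


@dataclass(frozen=True)
class FSDEffect:
    """Group-specific enrichment of a fragment-length range.

    ``target`` selects the population ("host_cfdna" or "ctdna"), ``factor``
    the grouping variable ("cell_line" or "site"), ``level`` the group that
    carries the effect, and ``multiplier`` the enrichment of ``size_range``.
    """

    target: str
    factor: str
    level: str
    size_range: tuple[int, int]
    multiplier: float

    def __post_init__(self) -> None:
        if self.target not in ("host_cfdna", "ctdna"):
            raise InvalidSpecError(f"unknown effect target {self.target!r}")
        if self.factor not in ("cell_line", "site"):
            raise InvalidSpecError(f"unknown effect factor {self.factor!r}")
        if self.multiplier < 0:
            raise InvalidSpecError("effect multiplier must be non-negative")


@dataclass(frozen=True)
class ClassifierModel:
    """Per-read species classifier with independent mislabeling.

    ``sensitivity`` is P(call = human | graft read); ``false_human_rate`` is
    P(call = human | host read).  Non-human calls are split among
    mouse/both/neither with fixed proportions.
    """

    name: str
    sensitivity: float = 0.98
    false_human_rate: float = 0.01
    both_share: float = 0.10  # share of non-human calls labeled "both"
    neither_share: float = 0.05

    def __post_init__(self) -> None:
        for name in ("sensitivity", "false_human_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidSpecError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class CNASegment:
    """Copy-number segment in fractional chromosome coordinates.

    ``chrom_index`` indexes the graft genome's chromosomes; the segment
    covers [start_frac, end_frac) of that chromosome and multiplies the
    placement weight of overlapping bins by ``multiplier`` (2.0 = gain,
    0.5 = loss).
    """

    chrom_index: int
    start_frac: float
    end_frac: float
    multiplier: float


@dataclass(frozen=True)
class CohortDesign:
    """Study design: 2 cell lines x 2 sites x 3 replicates + 3 controls."""

    cell_lines: tuple[str, str] = ("A549", "M97H")
    sites: tuple[str, str] = ("pancreas", "rectum")
    replicates_per_group: int = 3
    controls: int = 3
    ctdna_fraction_range: tuple[float, float] = (0.0021, 0.1896)
    fragments_per_sample: int = 400_000
    host_profile: SizeProfile = HOST_CFDNA_PROFILE
    ctdna_profile: SizeProfile = CTDNA_PROFILE
    fsd_effects: tuple[FSDEffect, ...] = (
        FSDEffect("host_cfdna", "cell_line", "A549", (150, 174), 1.25),
        FSDEffect("host_cfdna", "cell_line", "M97H", (220, 309), 2.0),
        FSDEffect("ctdna", "site", "pancreas", (120, 129), 2.0),
        FSDEffect("ctdna", "site", "rectum", (185, 214), 1.8),
    )
    cna_segments: Mapping[str, tuple[CNASegment, ...]] = field(
        default_factory=lambda: {
            "A549": (CNASegment(0, 0.0, 0.4, 2.0), CNASegment(1, 0.5, 0.8, 0.5)),
            "M97H": (CNASegment(0, 0.6, 1.0, 0.5), CNASegment(1, 0.0, 0.3, 2.0)),
        }
    )
    classifiers: tuple[ClassifierModel, ...] = (
        ClassifierModel("A", sensitivity=0.98, false_human_rate=0.012),
        ClassifierModel("B", sensitivity=0.95, false_human_rate=0.008),
    )
    low_mapq_rate: float = 0.03
    cna_bin_size: int = 1_000_000
    homology_span: int = 30_000  # per-chromosome host/graft homology analogue

    def __post_init__(self) -> None:
        lo, hi = self.ctdna_fraction_range
        if not (0.0 < lo <= hi < 1.0):
            raise InvalidSpecError("ctdna_fraction_range must lie within (0, 1)")
        if self.replicates_per_group < 1:
            raise InvalidSpecError("replicates_per_group must be >= 1")
        if self.controls < 0:
            raise InvalidSpecError("controls must be >= 0")
        for eff in self.fsd_effects:
            prof = self.host_profile if eff.target == "host_cfdna" else self.ctdna_profile
            lo_s, hi_s = prof.support
            rlo, rhi = eff.size_range
            if rlo < lo_s or rhi > hi_s:
                raise InvalidSpecError(
                    f"effect range {rlo}-{rhi} outside {eff.target} support {lo_s}-{hi_s}"
                )

    def noiseless(self) -> "CohortDesign":
        """Copy of the design with perfect classifiers and no low-MAPQ reads."""
        clean = tuple(
            replace(c, sensitivity=1.0, false_human_rate=0.0) for c in self.classifiers
        )
        return replace(self, classifiers=clean, low_mapq_rate=0.0)

    @property
    def cdx_sample_names(self) -> list[str]:
        return [
            f"{cl}-{site}-{r}"
            for cl in self.cell_lines
            for site in self.sites
            for r in range(1, self.replicates_per_group + 1)
        ]

    @property
    def control_sample_names(self) -> list[str]:
        return [f"ctrl-{r}" for r in range(1, self.controls + 1)]


def default_host_spec(chrom_length: int = 3_000_000, n_chroms: int = 3) -> ReferenceSpec:
    """Small mouse-like host reference (acrocentric, q arms only)."""
    return ReferenceSpec(
        "mouse", {f"mchr{i}": chrom_length for i in range(1, n_chroms + 1)}, p_fraction=0.0
    )


def default_graft_spec(chrom_length: int = 3_000_000, n_chroms: int = 2) -> ReferenceSpec:
    """Small human-like graft reference (p/q arms, centromere at 40%)."""
    return ReferenceSpec(
        "human", {f"hchr{i}": chrom_length for i in range(1, n_chroms + 1)}, p_fraction=0.4
    )


@dataclass
class SampleData:
    """One sample's generated reads and classifier verdicts.

    ``frags`` holds true fragments with coordinates on their species' own
    genome.  ``verdicts`` holds one row per (read, method).  ``human_prone``
    holds the human-genome alignments of host reads that at least one
    classifier mislabeled as human (placed in homology regions).
    """

    name: str
    frags: pd.DataFrame  # read_id, species, chrom, start, end, length, mapq
    verdicts: pd.DataFrame  # read_id, method, call
    human_prone: pd.DataFrame  # read_id, chrom, start, end, mapq


@dataclass
class Cohort:
    design: CohortDesign
    host_genome: GenomeModel
    graft_genome: GenomeModel
    homology_regions: list[tuple[str, int, int]]
    samples: dict[str, SampleData]
    sheet: pd.DataFrame  # sample, kind, cell_line, site, ctdna_fraction

    @property
    def cdx_sheet(self) -> pd.DataFrame:
        return self.sheet[self.sheet["kind"] == "cdx"].reset_index(drop=True)


def _placement_weights(
    genome: GenomeModel, bin_size: int, segments: Sequence[CNASegment] = ()
) -> tuple[pd.DataFrame, np.ndarray]:
    """Tile the genome into bins and compute per-bin placement weights."""
    rows = []
    for ci, (chrom, length) in enumerate(genome.lengths.items()):
        starts = np.arange(0, length, bin_size)
        for s in starts:
            rows.append((ci, chrom, int(s), int(min(s + bin_size, length))))
    bins = pd.DataFrame(rows, columns=["ci", "chrom", "start", "end"])
    mult = np.ones(len(bins))
    for seg in segments:
        chrom_names = genome.chrom_names
        if not (0 <= seg.chrom_index < len(chrom_names)):
            continue  # segment beyond this genome's chromosomes: inert
        chrom = chrom_names[seg.chrom_index]
        length = genome.lengths[chrom]
        lo = seg.start_frac * length
        hi = seg.end_frac * length
        sel = (bins["chrom"] == chrom) & (bins["start"] < hi) & (bins["end"] > lo)
        mult[sel.to_numpy()] *= seg.multiplier
    weights = (bins["end"] - bins["start"]).to_numpy(float) * mult
    return bins, weights / weights.sum()


def _place_fragments(
    rng: np.random.Generator,
    genome: GenomeModel,
    lengths: np.ndarray,
    bins: pd.DataFrame,
    weights: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Place fragments: pick a bin by weight, then a uniform start inside it."""
    n = lengths.size
    cdf = np.cumsum(weights)
    cdf[-1] = 1.0
    bi = np.searchsorted(cdf, rng.random(n), side="right")
    b_start = bins["start"].to_numpy()[bi]
    b_end = bins["end"].to_numpy()[bi]
    starts = b_start + np.floor(rng.random(n) * (b_end - b_start)).astype(np.int64)
    # clamp so fragments stay on-chromosome
    chrom_idx = bins["ci"].to_numpy()[bi]
    chrom_lengths = np.array(list(genome.lengths.values()))[chrom_idx]
    starts = np.minimum(starts, chrom_lengths - lengths)
    starts = np.maximum(starts, 0)
    return chrom_idx.astype(np.int64), starts


def _classifier_calls(
    rng: np.random.Generator, clf: ClassifierModel, is_graft: np.ndarray
) -> np.ndarray:
    """Return per-read call codes (index into CALLS) for one classifier."""
    n = is_graft.size
    p_human = np.where(is_graft, clf.sensitivity, clf.false_human_rate)
    u = rng.random(n)
    calls = np.full(n, 1, dtype=np.int8)  # default "mouse"
    calls[u < p_human] = 0  # "human"
    # split the non-human remainder into mouse/both/neither
    rem = calls != 0
    v = rng.random(n)
    calls[rem & (v < clf.both_share)] = 2
    calls[rem & (v >= clf.both_share) & (v < clf.both_share + clf.neither_share)] = 3
    return calls


def _effects_for(
    design: CohortDesign, target: str, cell_line: str | None, site: str | None
) -> list[tuple[tuple[int, int], float]]:
    out = []
    for eff in design.fsd_effects:
        if eff.target != target:
            continue
        level = cell_line if eff.factor == "cell_line" else site
        if level == eff.level:
            out.append((eff.size_range, eff.multiplier))
    return out


def generate_cohort(
    design: CohortDesign,
    host_genome: GenomeModel,
    graft_genome: GenomeModel,
    seed: int,
) -> Cohort:
    """Generate all samples of the xenograft study design.

    Controls contain host fragments only.  Each CDX sample is a host/graft
    mixture at a ctDNA fraction drawn log-uniformly from the design range,
    with graft placement weighted by the cell line's CNA segments, FSD
    effects applied per group, and per-read classifier verdicts drawn with
    the configured error rates.  Host reads mislabeled as human receive a
    human-genome alignment inside fixed homology regions, which is what the
    control-derived blacklist is built from.
    """
    ss = np.random.SeedSequence(seed)
    names = design.control_sample_names + design.cdx_sample_names
    children = ss.spawn(len(names))

    # Homology regions: one fixed window per graft chromosome.
    homology: list[tuple[str, int, int]] = []
    for chrom, length in graft_genome.lengths.items():
        span = min(design.homology_span, max(length // 10, 1))
        start = int(0.45 * length)
        homology.append((chrom, start, min(start + span, length)))
    hom_lengths = np.array([e - s for _, s, e in homology], dtype=float)
    hom_p = hom_lengths / hom_lengths.sum()

    host_bins, host_w = _placement_weights(host_genome, design.cna_bin_size)
    graft_grids = {
        cl: _placement_weights(
            graft_genome, design.cna_bin_size, design.cna_segments.get(cl, ())
        )
        for cl in design.cell_lines
    }

    lo_f, hi_f = design.ctdna_fraction_range
    samples: dict[str, SampleData] = {}
    sheet_rows = []
    host_chroms = np.array(host_genome.chrom_names)
    graft_chroms = np.array(graft_genome.chrom_names)

    for name, child in zip(names, children):
        rng = np.random.default_rng(child)
        is_control = name.startswith("ctrl-")
        if is_control:
            cell_line = site = None
            frac = 0.0
            n_graft = 0
        else:
            cell_line, site, _rep = name.rsplit("-", 2)
            frac = float(np.exp(rng.uniform(np.log(lo_f), np.log(hi_f))))
            n_graft = int(rng.binomial(design.fragments_per_sample, frac))
        n_host = design.fragments_per_sample - n_graft

        host_eff = _effects_for(design, "host_cfdna", cell_line, site)
        host_len = sample_fragment_lengths(design.host_profile, n_host, rng, host_eff)
        h_ci, h_start = _place_fragments(rng, host_genome, host_len, host_bins, host_w)

        if n_graft > 0:
            graft_eff = _effects_for(design, "ctdna", cell_line, site)
            graft_len = sample_fragment_lengths(design.ctdna_profile, n_graft, rng, graft_eff)
            gbins, gw = graft_grids[cell_line]
            g_ci, g_start = _place_fragments(rng, graft_genome, graft_len, gbins, gw)
        else:
            graft_len = np.empty(0, dtype=np.int64)
            g_ci = g_start = np.empty(0, dtype=np.int64)

        n = n_host + n_graft
        read_id = np.arange(n, dtype=np.int64)
        species = np.concatenate(
            [np.zeros(n_host, dtype=np.int8), np.ones(n_graft, dtype=np.int8)]
        )
        chrom = np.concatenate([host_chroms[h_ci], graft_chroms[g_ci]])
        start = np.concatenate([h_start, g_start])
        length = np.concatenate([host_len, graft_len]).astype(np.int64)
        mapq = np.full(n, 60, dtype=np.int16)
        if design.low_mapq_rate > 0:
            low = rng.random(n) < design.low_mapq_rate
            mapq[low] = rng.integers(0, 30, size=int(low.sum()))

        frags = pd.DataFrame(
            {
                "read_id": read_id,
                "species": pd.Categorical.from_codes(species, ["host", "graft"]),
                "chrom": chrom,
                "start": start,
                "end": start + length,
                "length": length,
                "mapq": mapq,
            }
        )

        is_graft = species == 1
        verdict_frames = []
        any_human_host = np.zeros(n, dtype=bool)
        for clf in design.classifiers:
            calls = _classifier_calls(rng, clf, is_graft)
            verdict_frames.append(
                pd.DataFrame(
                    {
                        "read_id": read_id,
                        "method": clf.name,
                        "call": pd.Categorical.from_codes(calls, list(CALLS)),
                    }
                )
            )
            any_human_host |= (calls == 0) & ~is_graft
        verdicts = pd.concat(verdict_frames, ignore_index=True)

        # Human-genome alignments of host reads mislabeled as human.
        hp_idx = np.flatnonzero(any_human_host)
        if hp_idx.size:
            ri = np.searchsorted(np.cumsum(hom_p), rng.random(hp_idx.size), side="right")
            hp_len = length[hp_idx]
            hp_chrom = np.array([homology[i][0] for i in ri])
            reg_start = np.array([homology[i][1] for i in ri])
            reg_end = np.array([homology[i][2] for i in ri])
            span = np.maximum(reg_end - reg_start - hp_len, 1)
            hp_start = reg_start + np.floor(rng.random(hp_idx.size) * span).astype(np.int64)
            human_prone = pd.DataFrame(
                {
                    "read_id": read_id[hp_idx],
                    "chrom": hp_chrom,
                    "start": hp_start,
                    "end": hp_start + hp_len,
                    "mapq": mapq[hp_idx],
                }
            )
        else:
            human_prone = pd.DataFrame(
                columns=["read_id", "chrom", "start", "end", "mapq"]
            ).astype({"read_id": np.int64, "start": np.int64, "end": np.int64, "mapq": np.int16})

        samples[name] = SampleData(name, frags, verdicts, human_prone)
        sheet_rows.append(
            (name, "control" if is_control else "cdx", cell_line, site, frac)
        )

    sheet = pd.DataFrame(
        sheet_rows, columns=["sample", "kind", "cell_line", "site", "ctdna_fraction"]
    )
    return Cohort(design, host_genome, graft_genome, homology, samples, sheet)
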