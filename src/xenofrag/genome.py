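"""Synthetic reference genomes with chromosome-arm bookkeeping.

A :class:`GenomeModel` holds per-chromosome sequence plus an arm table in
0-based half-open coordinates.  Two naming conventions matter downstream:

* mouse-like genomes are acrocentric, so every chromosome contributes a
  single q arm (19 autosomes + X + Y = 21 arms);
* human-like genomes contribute p and q arms, with the short arms of the
  acrocentric chromosomes (13p, 14p, 15p, 21p, 22p) plus chrY and chrXp
  excluded from the default feature set (40 arms).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class InvalidSpecError(ValueError):
    """Raised when a genome or generator specification is inconsistent."""


_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase
_CODE[ord("N")] = 4
_CODE[ord("n")] = 4

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0, C=1, G=2, T=3, N=4).

    Raises :class:`InvalidSpecError` on characters outside A/C/G/T/N.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    if (codes == 255).any():
        bad = chr(raw[codes == 255][0])
        raise InvalidSpecError(f"sequence contains invalid character {bad!r}")
    return codes


@dataclass(frozen=True)
class Arm:
    chrom: str
    arm: str  # "p" or "q"
    start: int
    end: int

    @property
    def name(self) -> str:
        return f"{self.chrom}{self.arm}"


@dataclass
class GenomeModel:
    """A reference genome: ordered chromosomes, arm table, excluded regions."""

    species_tag: str
    chromosomes: dict[str, str]  # name -> sequence, insertion-ordered
    arm_table: list[Arm]
    excluded_regions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    _codes: dict[str, np.ndarray] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        lengths = self.lengths
        seen: dict[str, list[tuple[int, int]]] = {}
        for a in self.arm_table:
            if a.chrom not in lengths:
                raise InvalidSpecError(f"arm on unknown chromosome {a.chrom!r}")
            if a.arm not in ("p", "q"):
                raise InvalidSpecError(f"arm label must be p or q, got {a.arm!r}")
            if not (0 <= a.start < a.end <= lengths[a.chrom]):
                raise InvalidSpecError(f"arm {a.name} outside chromosome bounds")
            seen.setdefault(a.chrom, []).append((a.start, a.end))
        for chrom, ivals in seen.items():
            ivals.sort()
            for (s1, e1), (s2, _e2) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise InvalidSpecError(f"overlapping arms on {chrom}")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chromosomes)

    @property
    def arm_names(self) -> list[str]:
        return [a.name for a in self.arm_table]

    @property
    def arms_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(a.chrom, a.arm, a.start, a.end) for a in self.arm_table],
            columns=["chrom", "arm", "start", "end"],
        )

    def codes(self, chrom: str) -> np.ndarray:
        """uint8-encoded sequence of one chromosome (cached)."""
        if chrom not in self._codes:
            self._codes[chrom] = encode_sequence(self.chromosomes[chrom])
        return self._codes[chrom]

    def to_fasta(self, path, line_width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chromosomes.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")


@dataclass(frozen=True)
class ReferenceSpec:
    """Recipe for a random reference: lengths, arm split, base composition.

    ``p_fraction`` gives the fraction of each chromosome assigned to the p
    arm; 0 means acrocentric (single q arm spanning the chromosome).
    """

    species_tag: str
    chromosome_lengths: Mapping[str, int]
    p_fraction: float | Mapping[str, float] = 0.0
    base_probs: Sequence[float] = (0.295, 0.205, 0.205, 0.295)  # ~41% GC

    def p_fraction_of(self, chrom: str) -> float:
        if isinstance(self.p_fraction, Mapping):
            return float(self.p_fraction.get(chrom, 0.0))
        return float(self.p_fraction)


def generate_reference(spec: ReferenceSpec, seed: int, fasta_path=None) -> GenomeModel:
    """Generate a reproducible random reference from a :class:`ReferenceSpec`.

    The same (spec, seed) always yields byte-identical sequences.
    """
    if not spec.chromosome_lengths:
        raise InvalidSpecError("reference spec has no chromosomes")
    probs = np.asarray(spec.base_probs, dtype=float)
    if probs.shape != (4,) or (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
        raise InvalidSpecError("base_probs must be 4 non-negative values summing to 1")
    rng = np.random.default_rng(seed)
    chromosomes: dict[str, str] = {}
    arms: list[Arm] = []
    for name, length in spec.chromosome_lengths.items():
        length = int(length)
        if length < 2000:
            raise InvalidSpecError(f"chromosome {name!r} length {length} < 2000 bp")
        draws = rng.choice(4, size=length, p=probs).astype(np.uint8)
        chromosomes[name] = _BASES[draws].tobytes().decode("ascii")
        pf = spec.p_fraction_of(name)
        if not (0.0 <= pf < 1.0):
            raise InvalidSpecError(f"p_fraction for {name!r} must be in [0, 1)")
        split = int(round(pf * length))
        if split > 0:
            arms.append(Arm(name, "p", 0, split))
        arms.append(Arm(name, "q", split, length))
    genome = GenomeModel(spec.species_tag, chromosomes, arms)
    if fasta_path is not None:
        genome.to_fasta(fasta_path)
    return genome


def mouse_like_spec(chrom_length: int = 100_000, n_autosomes: int = 19) -> ReferenceSpec:
    """Mouse-convention spec: acrocentric autosomes plus X and Y (q arms only)."""
    names = [f"chr{i}" for i in range(1, n_autosomes + 1)] + ["chrX", "chrY"]
    return ReferenceSpec("mouse", {n: chrom_length for n in names}, p_fraction=0.0)


# Human arm convention used for FSD feature indexing: p+q for chr1-22 and
# chrX, minus the acrocentric short arms (13p/14p/15p/21p/22p), chrY, and
# chrXp -- 40 arms in total.
_HUMAN_EXCLUDED_ARMS = {"chr13p", "chr14p", "chr15p", "chr21p", "chr22p", "chrXp"}


def human_arm_names() -> list[str]:
    arms = []
    for c in [f"chr{i}" for i in range(1, 23)] + ["chrX"]:
        for a in ("p", "q"):
            if f"{c}{a}" not in _HUMAN_EXCLUDED_ARMS:
                arms.append(f"{c}{a}")
    return arms


def mouse_arm_names(n_autosomes: int = 19) -> list[str]:
    return [f"chr{i}q" for i in range(1, n_autosomes + 1)] + ["chrXq", "chrYq"]
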