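"""Plain-text interchange: BED6 fragments, arm tables, FASTA references."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .genome import Arm, GenomeModel

BED_COLUMNS = ["chrom", "start", "end", "read_id", "mapq", "strand"]


def write_fragments_bed(frags: pd.DataFrame, path) -> None:
    """Write fragments as BED6 (name = read_id, score = MAPQ, strand = +)."""
    out = pd.DataFrame(
        {
            "chrom": frags["chrom"],
            "start": frags["start"],
            "end": frags["end"],
            "read_id": frags["read_id"],
            "mapq": frags.get("mapq", 60),
            "strand": "+",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_fragments_bed(path) -> pd.DataFrame:
    frags = pd.read_csv(path, sep="\t", names=BED_COLUMNS)
    frags["length"] = frags["end"] - frags["start"]
    return frags


def write_arms_tsv(arm_table: Sequence[Arm], path) -> None:
    pd.DataFrame(
        [(a.chrom, a.arm, a.start, a.end) for a in arm_table],
        columns=["chrom", "arm", "start", "end"],
    ).to_csv(path, sep="\t", index=False)


def read_arms_tsv(path) -> list[Arm]:
    df = pd.read_csv(path, sep="\t")
    return [Arm(r.chrom, r.arm, int(r.start), int(r.end)) for r in df.itertuples()]


def read_genome_fasta(path, arms_path=None, species_tag: str = "genome") -> GenomeModel:
    """Load a FASTA reference (and optional arm table) into a GenomeModel.

    Without an arm table every chromosome becomes a single q arm.
    """
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    chromosomes = {name: str(fa[name][:]) for name in fa.keys()}
    if arms_path is not None:
        arms = read_arms_tsv(arms_path)
    else:
        arms = [Arm(name, "q", 0, len(seq)) for name, seq in chromosomes.items()]
    return GenomeModel(species_tag, chromosomes, arms)
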