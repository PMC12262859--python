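"""End-to-end orchestration: simulate -> separate -> features -> cna -> stats.

`run_study` reproduces the synthetic xenograft study in one call: it
generates the cohort, builds the control-derived blacklist, isolates the
host-cfDNA and ctDNA streams per sample, computes FSD/EDM/BPM/S2L feature
matrices, the informative-marker table for the four factor-by-stream
comparisons, the FSD permutation tests, and the CNA log2-ratio matrix with
its PCA.  All stage contracts are file-based (BED/TSV/JSON) so individual
stages can be re-run or replaced with real-data inputs.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genome import GenomeModel, InvalidSpecError, generate_reference
from .synth import (
    Cohort,
    CohortDesign,
    SampleData,
    default_graft_spec,
    default_host_spec,
    generate_cohort,
)
from .separate import (
    Blacklist,
    build_blacklist,
    filter_alignments,
    fragments_to_read_pairs,
    infer_fragments,
    merge_human_calls,
)
from . import features as feat
from .cna import BinGrid, bin_counts, cna_pca, log2_ratio_matrix
from .stats import count_informative, permutation_test, two_group_test
from .io import write_arms_tsv, write_fragments_bed

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, dict[str, Any]] = {
    "run": {"seed": 7, "outdir": "xenofrag-run"},
    "genome": {
        "host_chroms": 3,
        "host_chrom_length": 3_000_000,
        "graft_chroms": 2,
        "graft_chrom_length": 3_000_000,
        "graft_p_fraction": 0.4,
    },
    "cohort": {
        "fragments_per_sample": 400_000,
        "replicates_per_group": 3,
        "controls": 3,
        "ctdna_fraction_range": [0.0021, 0.1896],
        "zero_noise": False,
    },
    "filters": {"min_mapq": 30, "min_len": 50, "max_len": 1000},
    "features": {
        "fsd_min": 65,
        "fsd_max": 399,
        "fsd_step": 5,
        "s2l_short": [80, 160],
        "s2l_long": [161, 200],
        "motifs": True,
        "read_len": 75,
    },
    "stats": {"n_perm": 1000, "auc_informative": 0.9, "auc_permutation": 0.8},
    "cna": {"bin_size": 1_000_000, "pseudocount": 0.5},
}


class ConfigError(ValueError):
    """Raised for malformed or contradictory run configurations."""


def validate_config(config: Mapping[str, Any] | None) -> dict[str, Any]:
    """Fill defaults, reject unknown keys, and check cross-field consistency."""
    merged = copy.deepcopy(DEFAULT_CONFIG)
    config = config or {}
    for section, values in config.items():
        if section not in merged:
            raise ConfigError(f"unknown config section {section!r}")
        if values is None:
            continue
        if not isinstance(values, Mapping):
            raise ConfigError(f"config section {section!r} must be a mapping")
        for key, val in values.items():
            if key not in merged[section]:
                raise ConfigError(f"unknown config key {section}.{key}")
            merged[section][key] = val

    f = merged["filters"]
    if f["min_len"] >= f["max_len"]:
        raise ConfigError(
            f"filters.min_len ({f['min_len']}) must be below filters.max_len ({f['max_len']})"
        )
    ft = merged["features"]
    if (ft["fsd_max"] - ft["fsd_min"] + 1) % ft["fsd_step"] != 0:
        raise ConfigError(
            f"features.fsd_min..fsd_max ({ft['fsd_min']}-{ft['fsd_max']}) is not "
            f"tiled by bins of width {ft['fsd_step']}"
        )
    support = CohortDesign().host_profile.support
    for name in ("s2l_short", "s2l_long"):
        lo, hi = ft[name]
        if lo >= hi:
            raise ConfigError(f"features.{name} bounds are inverted")
        if lo < support[0] or hi > support[1]:
            raise ConfigError(
                f"features.{name} ({lo}-{hi}) lies outside the fragment-size "
                f"support ({support[0]}-{support[1]})"
            )
    s = merged["stats"]
    for key in ("auc_informative", "auc_permutation"):
        if not (0.5 < s[key] <= 1.0):
            raise ConfigError(f"stats.{key} must be in (0.5, 1]")
    if merged["stats"]["n_perm"] < 1:
        raise ConfigError("stats.n_perm must be >= 1")
    return merged


def load_config(path) -> dict[str, Any]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return validate_config(raw)


@dataclass
class StreamExtraction:
    """Isolated fragment tables for one sample, with per-stage counts."""

    ctdna: pd.DataFrame
    host: pd.DataFrame
    counts: dict[str, int]


def isolate_sample(
    sample: SampleData,
    blacklist: Blacklist,
    min_mapq: int = 30,
    length_range: tuple[int, int] = (50, 1000),
    read_len: int = 75,
) -> StreamExtraction:
    """Split one sample into a ctDNA stream and a host-cfDNA stream.

    ctDNA: reads called human by either classifier, taken at their
    human-genome alignments, MAPQ- and blacklist-filtered (any overlap of
    the fragment span removes it), fragments inferred from mate pairs, then
    length-filtered.  Host cfDNA: reads not called human, on the host
    genome, MAPQ- and length-filtered (the blacklist is a human-genome
    construct and does not apply).
    """
    human_ids = merge_human_calls(sample.verdicts)
    frags = sample.frags
    is_graft = np.asarray(frags["species"]) == "graft"
    called_human = frags["read_id"].isin(human_ids).to_numpy()

    graft_aln = frags.loc[is_graft & called_human, ["read_id", "chrom", "start", "end", "mapq"]]
    contam = sample.human_prone[["read_id", "chrom", "start", "end", "mapq"]]
    # offset contaminant ids so the two id spaces cannot collide in pairing
    contam = contam.assign(read_id=contam["read_id"] + len(frags))
    human_aln = pd.concat([graft_aln, contam], ignore_index=True)

    ct_filtered = filter_alignments(human_aln, blacklist, min_mapq)
    ct_pairs = fragments_to_read_pairs(ct_filtered, read_len)
    ctdna = infer_fragments(ct_pairs, length_range)

    host_aln = frags.loc[~is_graft & ~called_human, ["read_id", "chrom", "start", "end", "mapq"]]
    h_filtered = filter_alignments(host_aln, None, min_mapq)
    h_pairs = fragments_to_read_pairs(h_filtered, read_len)
    host = infer_fragments(h_pairs, length_range)

    # fragments lost to MAPQ/blacklist read filtering = candidates minus
    # everything still visible after pairing (kept or length-dropped)
    counts = {
        "n_reads": int(len(frags)),
        "n_true_graft": int(is_graft.sum()),
        "ctdna_candidates": int(len(human_aln)),
        "ctdna_read_filtered": int(
            len(human_aln) - len(ctdna) - ctdna.attrs["n_length_dropped"]
        ),
        "ctdna_length_dropped": int(ctdna.attrs["n_length_dropped"]),
        "ctdna_kept": int(len(ctdna)),
        "host_candidates": int(len(host_aln)),
        "host_read_filtered": int(
            len(host_aln) - len(host) - host.attrs["n_length_dropped"]
        ),
        "host_length_dropped": int(host.attrs["n_length_dropped"]),
        "host_kept": int(len(host)),
    }
    for stream in ("ctdna", "host"):  # filter-chain conservation
        assert counts[f"{stream}_candidates"] == (
            counts[f"{stream}_kept"]
            + counts[f"{stream}_read_filtered"]
            + counts[f"{stream}_length_dropped"]
        )
    return StreamExtraction(ctdna, host, counts)


def control_blacklist(cohort: Cohort) -> Blacklist:
    """Blacklist from control samples' human-prone alignments, per method."""
    regions: dict[tuple[str, str], pd.DataFrame] = {}
    methods = [c.name for c in cohort.design.classifiers]
    for name in cohort.design.control_sample_names:
        sd = cohort.samples[name]
        if len(sd.human_prone) == 0:
            continue
        human_by = {
            m: set(
                sd.verdicts.loc[
                    (sd.verdicts["method"] == m)
                    & (np.asarray(sd.verdicts["call"]) == "human"),
                    "read_id",
                ]
            )
            for m in methods
        }
        for m in methods:
            sub = sd.human_prone[sd.human_prone["read_id"].isin(human_by[m])]
            if len(sub):
                regions[(name, m)] = sub[["chrom", "start", "end"]]
    if not regions:
        return Blacklist()
    return build_blacklist(regions, known_chroms=cohort.graft_genome.chrom_names)


@dataclass
class StudyResult:
    config: dict[str, Any]
    cohort: Cohort
    blacklist: Blacklist
    extractions: dict[str, StreamExtraction]
    feature_matrices: dict[str, pd.DataFrame]  # e.g. "fsd_ctdna" -> samples x markers
    s2l_table: pd.DataFrame
    informative_table: pd.DataFrame
    permutation_table: pd.DataFrame
    cna_matrix: pd.DataFrame
    cna_pca_scores: pd.DataFrame
    cna_variance_pct: np.ndarray
    manifest: dict[str, Any]


def _design_from_config(cfg: dict[str, Any]) -> CohortDesign:
    c = cfg["cohort"]
    design = CohortDesign(
        replicates_per_group=int(c["replicates_per_group"]),
        controls=int(c["controls"]),
        ctdna_fraction_range=tuple(c["ctdna_fraction_range"]),
        fragments_per_sample=int(c["fragments_per_sample"]),
        cna_bin_size=int(cfg["cna"]["bin_size"]),
    )
    if c["zero_noise"]:
        design = design.noiseless()
    return design


def run_study(config: Mapping[str, Any] | None = None, outdir=None) -> StudyResult:
    """Run the full synthetic study; optionally write all result tables."""
    cfg = validate_config(config)
    seed = int(cfg["run"]["seed"])
    g = cfg["genome"]
    host_genome = generate_reference(
        default_host_spec(int(g["host_chrom_length"]), int(g["host_chroms"])), seed + 1
    )
    graft_spec = default_graft_spec(int(g["graft_chrom_length"]), int(g["graft_chroms"]))
    graft_spec = dataclasses.replace(graft_spec, p_fraction=float(g["graft_p_fraction"]))
    graft_genome = generate_reference(graft_spec, seed + 2)

    design = _design_from_config(cfg)
    cohort = generate_cohort(design, host_genome, graft_genome, seed)
    blacklist = control_blacklist(cohort)

    fl = cfg["filters"]
    ft = cfg["features"]
    length_range = (int(fl["min_len"]), int(fl["max_len"]))
    extractions = {
        name: isolate_sample(
            sd, blacklist, int(fl["min_mapq"]), length_range, int(ft["read_len"])
        )
        for name, sd in cohort.samples.items()
    }

    bins = feat.fsd_bins((int(ft["fsd_min"]), int(ft["fsd_max"])), int(ft["fsd_step"]))
    cdx = cohort.cdx_sheet
    cdx_names = cdx["sample"].tolist()

    feature_matrices: dict[str, pd.DataFrame] = {}
    streams = {"host": (host_genome, "host"), "ctdna": (graft_genome, "ctdna")}
    for stream, (genome, attr) in streams.items():
        fsd_rows = {}
        edm_rows = {}
        bpm_rows = {}
        for name in cdx_names:
            frags = getattr(extractions[name], attr)
            fsd_rows[name] = feat.compute_fsd(frags, genome.arm_table, bins)
            if ft["motifs"]:
                edm_rows[name] = feat.compute_motif_spectrum(frags, genome, "EDM").frequencies
                bpm_rows[name] = feat.compute_motif_spectrum(frags, genome, "BPM").frequencies
        feature_matrices[f"fsd_{stream}"] = pd.DataFrame.from_dict(fsd_rows, orient="index")
        if ft["motifs"]:
            feature_matrices[f"edm_{stream}"] = pd.DataFrame.from_dict(edm_rows, orient="index")
            feature_matrices[f"bpm_{stream}"] = pd.DataFrame.from_dict(bpm_rows, orient="index")

    # S2L per sample per stream (controls included for the host stream)
    s2l_rows = []
    for name, ext in extractions.items():
        kind = cohort.sheet.loc[cohort.sheet["sample"] == name, "kind"].iloc[0]
        try:
            host_s2l = feat.compute_s2l(ext.host, tuple(ft["s2l_short"]), tuple(ft["s2l_long"]))
            s2l_rows.append((name, kind, "host", host_s2l.ratio))
        except feat.UndefinedStatisticError:
            pass
        if len(ext.ctdna):
            try:
                ct = feat.compute_s2l(ext.ctdna, tuple(ft["s2l_short"]), tuple(ft["s2l_long"]))
                s2l_rows.append((name, kind, "ctdna", ct.ratio))
            except feat.UndefinedStatisticError:
                pass
    s2l_table = pd.DataFrame(s2l_rows, columns=["sample", "kind", "stream", "s2l"])

    # informative-marker table (AUC > reporting threshold) and FSD permutations
    st = cfg["stats"]
    info_rows = []
    perm_rows = []
    factors = {"cell_line": cdx["cell_line"].to_numpy(), "site": cdx["site"].to_numpy()}
    for stream in streams:
        fkeys = [f"fsd_{stream}"] + (
            [f"edm_{stream}", f"bpm_{stream}"] if ft["motifs"] else []
        )
        for key in fkeys:
            matrix = feature_matrices[key].loc[cdx_names]
            for factor, labels in factors.items():
                n_inf, _ = count_informative(matrix, labels, float(st["auc_informative"]))
                info_rows.append((stream, key.split("_")[0], factor, n_inf, matrix.shape[1]))
        perm_seed = seed + 1000
        for factor, labels in factors.items():
            res = permutation_test(
                feature_matrices[f"fsd_{stream}"].loc[cdx_names],
                labels,
                n_perm=int(st["n_perm"]),
                threshold=float(st["auc_permutation"]),
                seed=perm_seed,
            )
            perm_seed += 1
            perm_rows.append(
                (stream, factor, res.observed_informative, res.p_value, res.null_q95)
            )
    informative_table = pd.DataFrame(
        info_rows, columns=["stream", "feature", "factor", "n_informative", "n_markers"]
    )
    permutation_table = pd.DataFrame(
        perm_rows, columns=["stream", "factor", "observed", "p_value", "null_q95"]
    )

    # CNA matrix and PCA on the ctDNA stream
    grid = BinGrid.from_genome(graft_genome, int(cfg["cna"]["bin_size"]))
    counts = {name: bin_counts(extractions[name].ctdna, grid) for name in cdx_names}
    cna_matrix = log2_ratio_matrix(counts, grid, pseudocount=float(cfg["cna"]["pseudocount"]))
    scores, var_pct = cna_pca(cna_matrix)

    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "blacklist_bp": blacklist.total_bp,
        "samples": {name: ext.counts for name, ext in extractions.items()},
    }

    result = StudyResult(
        cfg, cohort, blacklist, extractions, feature_matrices, s2l_table,
        informative_table, permutation_table, cna_matrix, scores, var_pct, manifest,
    )
    if outdir is not None:
        write_study(result, outdir)
    return result


def write_cohort(cohort: Cohort, outdir) -> None:
    outdir = Path(outdir)
    (outdir / "genomes").mkdir(parents=True, exist_ok=True)
    (outdir / "samples").mkdir(exist_ok=True)
    cohort.host_genome.to_fasta(outdir / "genomes" / "host.fa")
    cohort.graft_genome.to_fasta(outdir / "genomes" / "graft.fa")
    write_arms_tsv(cohort.host_genome.arm_table, outdir / "genomes" / "host_arms.tsv")
    write_arms_tsv(cohort.graft_genome.arm_table, outdir / "genomes" / "graft_arms.tsv")
    cohort.sheet.to_csv(outdir / "samples" / "sheet.tsv", sep="\t", index=False)
    for name, sd in cohort.samples.items():
        frags = sd.frags.copy()
        write_fragments_bed(frags, outdir / "samples" / f"{name}.bed")
        frags[["read_id", "species"]].to_csv(
            outdir / "samples" / f"{name}.truth.tsv", sep="\t", index=False
        )
        sd.verdicts.to_csv(outdir / "samples" / f"{name}.verdicts.tsv", sep="\t", index=False)


def write_study(result: StudyResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_cohort(result.cohort, outdir)
    with open(outdir / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(result.config, fh, sort_keys=True)
    result.blacklist.to_bed(outdir / "blacklist.bed")
    iso = outdir / "isolated"
    iso.mkdir(exist_ok=True)
    for name, ext in result.extractions.items():
        write_fragments_bed(ext.ctdna, iso / f"{name}.ctdna.bed")
        write_fragments_bed(ext.host, iso / f"{name}.host.bed")
    fdir = outdir / "features"
    fdir.mkdir(exist_ok=True)
    for key, matrix in result.feature_matrices.items():
        matrix.rename_axis("sample").to_csv(fdir / f"{key}.tsv", sep="\t")
    result.s2l_table.to_csv(fdir / "s2l.tsv", sep="\t", index=False)
    sdir = outdir / "stats"
    sdir.mkdir(exist_ok=True)
    result.informative_table.to_csv(sdir / "informative_counts.tsv", sep="\t", index=False)
    result.permutation_table.to_csv(sdir / "permutation_fsd.tsv", sep="\t", index=False)
    cdir = outdir / "cna"
    cdir.mkdir(exist_ok=True)
    result.cna_matrix.rename_axis("sample").to_csv(cdir / "matrix.tsv", sep="\t")
    result.cna_pca_scores.rename_axis("sample").to_csv(cdir / "pca_scores.tsv", sep="\t")
    pd.Series(
        result.cna_variance_pct,
        index=[f"PC{i + 1}" for i in range(len(result.cna_variance_pct))],
        name="variance_pct",
    ).rename_axis("component").to_csv(cdir / "pca_variance.tsv", sep="\t")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
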