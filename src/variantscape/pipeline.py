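"""End-to-end orchestration: simulate -> ms-quant -> profiles -> cluster ->
direction -> tf-enrich, with plain-file handoff between stages.

Every stage reads its inputs from the previous stage's files and writes its
own outputs, so any stage can be re-run in isolation from cached upstream
outputs and reproduce the full-run results bit for bit. The consolidated
``report.json`` records every tunable (full provenance) plus per-stage record
counts and the headline tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anchors_profiles import AnchorSet, ProfileMatrix, filter_distal, stack_profiles
from .clustering import (asymmetry_report, classify_and_orient, kmeans_profiles,
                         mirror_pair)
from .directionality import pairwise_cluster_comparisons, polii_skew, strand_bias
from .genomic_io import read_bed, read_bedgraph, read_genes, rpkm_normalize, write_bed
from .ms_quant import (build_families, h2a_variant_fractions, h3_variant_fractions,
                       log2_enrichment, ptm_relative_abundance)
from .synthetic_data import (GenomeFixtureConfig, generate_genome_fixture,
                             generate_nucleosome_pool, generate_peptide_table,
                             heterotypic, homotypic, write_fixture)
from .tf_enrichment import enrichment_table

VARIANT_TRACKS = ("H3.1", "H3.3", "H2A.Z", "macroH2A")


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline; all values land in the report."""

    seed: int = 0
    # synthetic genome
    anchors_per_group: int = 60
    n_genes: int = 60
    noise: str = "poisson"
    erna_bias: float = 0.3
    # synthetic MS
    n_nucleosomes: int = 10_000
    ms_noise_cv: float = 0.1
    # profiles
    window: int = 2000
    bin_width: int = 100
    rpkm_scale: float = 1.0
    min_dist: int = 2000
    # clustering
    k: int = 16
    kmeans_seed: int = 0
    metric: str = "abs_pearson"
    mirror_min_corr: float = 0.8
    asym_threshold: float = 0.2
    track_priority: tuple[str, ...] = ("H3.3", "H2A.Z")
    # directionality
    n_boot: int = 1000
    # tf enrichment
    flank: int = 500
    version: str = field(default=__version__)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "track_priority" in raw:
            raw["track_priority"] = tuple(raw["track_priority"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["track_priority"] = list(d["track_priority"])
        return d


def default_ms_design() -> dict[str, tuple[dict, dict[str, float]]]:
    """Sample -> (composition mixture, planted PTM profile). The input sample
    models bulk chromatin; each FLAG purification models the pool structure
    the stoichiometry arm is meant to resolve (heterotypic variant pools; an
    H3.1 pool carrying a 1:3 H3.3:canonical copy ratio)."""
    bulk = {homotypic("H2A"): 0.80, heterotypic("H2A.Z"): 0.08,
            heterotypic("macroH2A"): 0.04, heterotypic("H3.3"): 0.08}
    return {
        "input": (bulk,
                  {"H3K27me3": 0.06, "H3K4me2": 0.01, "H3K36me3": 0.04,
                   "H4K16ac": 0.20}),
        "FLAG-H2A.Z": ({heterotypic("H2A.Z"): 1.0},
                       {"H3K4me2": 0.20, "H3K36me3": 0.15, "H3K27me3": 0.02,
                        "H4K16ac": 0.40}),
        "FLAG-macroH2A": ({heterotypic("macroH2A"): 1.0},
                          {"H3K27me3": 0.18, "H3K36me3": 0.01, "H4K16ac": 0.10}),
        "FLAG-H3.3": ({heterotypic("H3.3"): 1.0},
                      {"H3K4me2": 0.115, "H3K36me3": 0.07, "H3K27me3": 0.03,
                       "H4K16ac": 0.50}),
        "FLAG-H3.1": ({homotypic("H3.1"): 0.5, heterotypic("H3.3"): 0.5},
                      {"H3K27me3": 0.05, "H3K36me3": 0.04, "H4K16ac": 0.20}),
    }


# ---------------------------------------------------------------- stages

def stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict:
    fixture_cfg = GenomeFixtureConfig(
        anchors_per_group=cfg.anchors_per_group, n_genes=cfg.n_genes,
        noise=cfg.noise, bin_width=cfg.bin_width, window=cfg.window,
        seed=cfg.seed)
    fixture = generate_genome_fixture(fixture_cfg)
    paths = write_fixture(fixture, outdir / "fixture")

    tables = []
    for i, (sample, (mixture, ptms)) in enumerate(sorted(default_ms_design()
                                                         .items())):
        pool = generate_nucleosome_pool(mixture, cfg.n_nucleosomes,
                                        seed=cfg.seed * 1000 + i)
        tables.append(generate_peptide_table(
            pool, ptms, noise_cv=cfg.ms_noise_cv, seed=cfg.seed * 1000 + 100 + i,
            sample_id=sample))
    peptides = pd.concat(tables, ignore_index=True)
    pep_path = outdir / "peptides.csv"
    peptides.to_csv(pep_path, index=False)
    paths["peptides"] = str(pep_path)
    paths = {k: str(Path(v).relative_to(outdir)) for k, v in paths.items()}
    return {"paths": paths, "n_anchors": len(fixture.anchors),
            "n_genes": len(fixture.genes), "n_peptide_records": len(peptides)}


def stage_ms_quant(peptides_csv, input_sample: str, outdir: Path) -> dict:
    table = pd.read_csv(peptides_csv, keep_default_na=False)
    table["mods"] = table["mods"].astype(str)
    families = build_families(table)
    abundances = ptm_relative_abundance(families)
    abundances.to_csv(outdir / "ptm_abundance.csv", index=False)

    input_tab = abundances[abundances["sample"] == input_sample]
    if input_tab.empty:
        raise ValueError(f"input sample {input_sample!r} not in peptide table")
    enrich = []
    for sample in sorted(abundances["sample"].unique()):
        if sample == input_sample:
            continue
        ip_tab = abundances[abundances["sample"] == sample]
        enrich.append(log2_enrichment(ip_tab, input_tab))
    enrichment = pd.concat(enrich, ignore_index=True)
    enrichment.to_csv(outdir / "ptm_log2_enrichment.csv", index=False)

    h2a = h2a_variant_fractions(families)
    h3 = h3_variant_fractions(families)
    rows = []
    for res in list(h2a.values()) + list(h3.values()):
        for variant, frac in res.fractions.items():
            rows.append((res.sample_id, res.family, variant, frac))
    fractions = pd.DataFrame(rows, columns=["sample", "family", "variant",
                                            "fraction"])
    fractions.to_csv(outdir / "variant_fractions.csv", index=False)
    return {"n_families": len(families), "n_marks": len(abundances),
            "variant_fractions": fractions.to_dict("records")}


def _load_tracks(fixture_dir: Path, cfg: PipelineConfig,
                 names=VARIANT_TRACKS + ("PolII",)) -> dict:
    tracks = {}
    for name in names:
        path = fixture_dir / f"{name.replace('.', '')}.bedgraph"
        tracks[name] = rpkm_normalize(read_bedgraph(path, cfg.bin_width),
                                      scale=cfg.rpkm_scale)
    return tracks


def stage_profiles(fixture_dir: Path, cfg: PipelineConfig, outdir: Path) -> dict:
    dhs = read_bed(fixture_dir / "anchors.bed")
    genes = read_genes(fixture_dir / "genes.tsv")
    anchors = filter_distal(dhs, genes, cfg.min_dist)
    tracks = _load_tracks(fixture_dir, cfg)
    matrix = stack_profiles(tracks, anchors, cfg.window, cfg.bin_width)
    np.savez(outdir / "profiles.npz",
             **{f"track_{t}": matrix.data[t] for t in matrix.track_names})
    write_bed(matrix.anchors, outdir / "profile_anchors.bed")
    return {"n_input_dhs": len(dhs), "n_distal": len(anchors),
            "n_profiled": len(matrix.anchors), "tracks": list(matrix.track_names)}


def _load_matrix(outdir: Path, cfg: PipelineConfig,
                 tracks=VARIANT_TRACKS) -> ProfileMatrix:
    npz = np.load(outdir / "profiles.npz")
    anchors = read_bed(outdir / "profile_anchors.bed")
    data = {t: npz[f"track_{t}"] for t in tracks}
    return ProfileMatrix(data, anchors, cfg.window, cfg.bin_width, list(tracks))


def stage_cluster(profiles_dir: Path, cfg: PipelineConfig, outdir: Path) -> dict:
    matrix = _load_matrix(profiles_dir, cfg)
    result = kmeans_profiles(matrix, K=cfg.k, seed=cfg.kmeans_seed,
                             metric=cfg.metric)
    result = mirror_pair(result, cfg.mirror_min_corr)
    report = asymmetry_report(result, matrix, cfg.track_priority,
                              cfg.asym_threshold)
    result = classify_and_orient(result, report, cfg.track_priority)

    finals = result.final_labels()
    sides = {1: "right", -1: "left", 0: "none"}
    out_anchors = []
    for a, g, f, o in zip(matrix.anchors, result.labels, finals,
                          result.orientation):
        out_anchors.append(dataclasses.replace(
            a, name=f"{a.name}|group={g}|cluster={f}|orient={sides[o]}",
            score=float(f)))
    write_bed(out_anchors, outdir / "clusters.bed")
    pd.DataFrame([(g, *c) for g, c in sorted(result.centroids.items())]
                 ).to_csv(outdir / "centroids.csv", index=False, header=False)
    pairs = pd.DataFrame(result.mirror_pairs,
                         columns=["group_a", "group_b", "mirror_corr"])
    pairs.to_csv(outdir / "mirror_pairs.csv", index=False)
    np.savez(outdir / "cluster_labels.npz", labels=result.labels, finals=finals,
             orientation=result.orientation)
    return {"K": cfg.k, "n_mirror_pairs": len(result.mirror_pairs),
            "n_final_clusters": result.n_final_clusters,
            "mirror_pairs": result.mirror_pairs,
            "asymmetry_calls": report.calls}


def stage_direction(profiles_dir: Path, cluster_dir: Path, fixture_dir: Path,
                    cfg: PipelineConfig, outdir: Path) -> dict:
    from .clustering import ClusterResult

    matrix = _load_matrix(profiles_dir, cfg, tracks=VARIANT_TRACKS + ("PolII",))
    lab = np.load(cluster_dir / "cluster_labels.npz")
    merged = {}
    for g, f in zip(lab["labels"], lab["finals"]):
        merged.setdefault(int(f), set()).add(int(g))
    oriented = ClusterResult(
        labels=lab["labels"], centroids={}, K=cfg.k, seed=cfg.kmeans_seed,
        metric=cfg.metric, track_names=list(VARIANT_TRACKS),
        n_bins=matrix.n_bins, orientation=lab["orientation"],
        merged_clusters={f: tuple(sorted(gs)) for f, gs in merged.items()})

    report = polii_skew(matrix, oriented)
    report.cluster_skew.to_csv(outdir / "polii_skew.csv", index=False)

    # plus/minus must be normalized identically: share one library size
    plus = read_bedgraph(fixture_dir / "erna_plus.bedgraph", cfg.bin_width)
    minus = read_bedgraph(fixture_dir / "erna_minus.bedgraph", cfg.bin_width)
    library = plus.total() + minus.total()
    plus.library_size = minus.library_size = library
    plus = rpkm_normalize(plus, scale=cfg.rpkm_scale)
    minus = rpkm_normalize(minus, scale=cfg.rpkm_scale)
    anchors = AnchorSet(matrix.anchors)
    B, bias_table = strand_bias(plus, minus, anchors, oriented, cfg.window,
                                n_boot=cfg.n_boot, seed=cfg.seed)
    bias_table.to_csv(outdir / "strand_bias.csv", index=False)

    totals = np.array([
        plus.window_sum(a.chrom, a.center - cfg.window, a.center + cfg.window)
        + minus.window_sum(a.chrom, a.center - cfg.window, a.center + cfg.window)
        for a in matrix.anchors])
    comparisons = pairwise_cluster_comparisons(totals, oriented.final_labels())
    comparisons.to_csv(outdir / "erna_comparisons.csv", index=False)
    return {"concordance": report.concordance,
            "cluster_skew": report.cluster_skew.to_dict("records"),
            "strand_bias": bias_table.to_dict("records"),
            "top_comparisons": comparisons.head(5).to_dict("records")}


def stage_tf_enrich(cluster_dir: Path, fixture_dir: Path, cfg: PipelineConfig,
                    outdir: Path) -> dict:
    anchors = AnchorSet(read_bed(cluster_dir / "clusters.bed"))
    finals = np.load(cluster_dir / "cluster_labels.npz")["finals"]
    tf_peaks = {p.stem[3:]: read_bed(p)
                for p in sorted(Path(fixture_dir).glob("tf_*.bed"))}
    table = enrichment_table(anchors, finals, tf_peaks, cfg.flank)
    table.to_csv(outdir / "tf_enrichment.csv", index=False)
    sig = table[table["p"] < 0.05]
    return {"n_tests": len(table), "n_raw_significant": len(sig),
            "top": table.nsmallest(5, "p").to_dict("records")}


def run_all(cfg: PipelineConfig, outdir) -> dict:
    """Run every stage through its file interface; returns the report dict
    (also written to ``report.json``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {"config": cfg.to_dict(), "stages": {}}
    try:
        report["stages"]["simulate"] = stage_simulate(cfg, outdir)
        fixture_dir = outdir / "fixture"
        report["stages"]["ms_quant"] = stage_ms_quant(
            outdir / "peptides.csv", "input", outdir)
        report["stages"]["profiles"] = stage_profiles(fixture_dir, cfg, outdir)
        report["stages"]["cluster"] = stage_cluster(outdir, cfg, outdir)
        report["stages"]["direction"] = stage_direction(outdir, outdir,
                                                        fixture_dir, cfg, outdir)
        report["stages"]["tf_enrich"] = stage_tf_enrich(outdir, fixture_dir,
                                                        cfg, outdir)
    except Exception as exc:
        stage = list(report["stages"])[-1] if report["stages"] else "simulate"
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {exc}") from exc
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
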