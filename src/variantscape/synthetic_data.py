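"""Synthetic inputs with known ground truth for both pipeline arms.

The MS arm is fed by nucleosome pools: each nucleosome carries two H3-family
slots and two H2A-family slots, so a *heterotypic* pool (every nucleosome one
variant copy + one canonical copy) has exactly 50% canonical copies — the
analytic signature the stoichiometry quantifier must recover. Peptide tables
are generated by a forward model of bottom-up MS: reference-peptide intensity
proportional to total family copies, variant-specific intensity proportional
to that variant's copies, modified forms splitting a peptide family according
to a planted PTM profile, multiplicative log-normal noise with a chosen CV,
and optional per-peptide response factors (to expose the bias the ratio
method inherits when ionization efficiency differs between peptides).

The genomics arm is fed by a single synthetic chromosome carrying genes (with
expression-scaled promoter signal) and intergenic anchors drawn from planted
*archetypes*: per-track Gaussian occupancy bumps whose signed offsets encode
symmetric vs asymmetric (oriented) element classes, PolII bumps offset with
the same sign, stranded eRNA with a planted bias toward the offset direction,
and TF peak sets enriched at chosen archetypes with configured odds. Bin
counts are Poisson unless noise is disabled. Everything is deterministic
given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genomic_io import GeneModel, GenomicInterval, SignalTrack
from .ms_quant import (PEPTIDE_COLUMNS, PTM_PEPTIDES, PTM_SITES,
                       REFERENCE_PEPTIDES, canonical_mods, parse_mark)

__all__ = [
    "NucleosomeComposition", "NucleosomePool", "heterotypic", "homotypic",
    "generate_nucleosome_pool", "generate_peptide_table",
    "TrackBump", "Archetype", "GenomeFixtureConfig", "GenomeFixture",
    "default_archetypes", "generate_genome_fixture", "write_fixture",
]

VARIANT_TRACKS = ("H3.1", "H3.3", "H2A.Z", "macroH2A")

H3_VARIANTS = ("H3.1", "H3.2", "H3.3")
H2A_VARIANTS = ("H2A", "H2A.Z", "macroH2A")


# --------------------------------------------------------------------------
# nucleosome pools and the MS forward model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NucleosomeComposition:
    """Slot occupancy of one nucleosome: two H3-family and two H2A-family
    copies, plus the FLAG tag (which purification it would co-purify with)."""

    h3_slots: tuple[str, str] = ("H3.1", "H3.1")
    h2a_slots: tuple[str, str] = ("H2A", "H2A")
    tag: str | None = None

    def __post_init__(self) -> None:
        if len(self.h3_slots) != 2 or any(v not in H3_VARIANTS
                                          for v in self.h3_slots):
            raise ValueError(f"invalid H3 slots {self.h3_slots}")
        if len(self.h2a_slots) != 2 or any(v not in H2A_VARIANTS
                                           for v in self.h2a_slots):
            raise ValueError(f"invalid H2A slots {self.h2a_slots}")


def heterotypic(variant: str) -> NucleosomeComposition:
    """One copy of ``variant`` paired with one canonical copy in its family."""
    if variant in ("H2A.Z", "macroH2A"):
        return NucleosomeComposition(h2a_slots=(variant, "H2A"), tag=variant)
    if variant == "H3.3":
        return NucleosomeComposition(h3_slots=("H3.3", "H3.1"), tag=variant)
    raise ValueError(f"no heterotypic form for {variant!r}")


def homotypic(variant: str) -> NucleosomeComposition:
    """Both family slots carrying ``variant`` (canonical names allowed)."""
    if variant in H2A_VARIANTS:
        return NucleosomeComposition(h2a_slots=(variant, variant), tag=variant)
    if variant in H3_VARIANTS:
        return NucleosomeComposition(h3_slots=(variant, variant), tag=variant)
    raise ValueError(f"unknown variant {variant!r}")


@dataclass
class NucleosomePool:
    """A purified mononucleosome population with per-nucleosome composition."""

    nucleosomes: list[NucleosomeComposition]
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.nucleosomes)

    def copy_counts(self) -> dict[str, int]:
        """Histone copy counts across the pool (two slots per family per
        nucleosome; H4 has two invariant copies)."""
        counts = {v: 0 for v in H3_VARIANTS + H2A_VARIANTS}
        for nuc in self.nucleosomes:
            for v in nuc.h3_slots:
                counts[v] += 1
            for v in nuc.h2a_slots:
                counts[v] += 1
        counts["H4"] = 2 * len(self.nucleosomes)
        return counts

    def copy_fractions(self, family: str) -> dict[str, float]:
        counts = self.copy_counts()
        members = H2A_VARIANTS if family == "H2A" else H3_VARIANTS
        total = sum(counts[v] for v in members)
        return {v: counts[v] / total for v in members}


def generate_nucleosome_pool(mixture_spec: dict[NucleosomeComposition, float],
                             n: int, seed: int = 0) -> NucleosomePool:
    """Sample ``n`` nucleosomes from a mixture of composition patterns.

    ``mixture_spec`` maps composition -> proportion; proportions must sum to 1
    (within 1e-9). Sampling is multinomial, so empirical proportions converge
    to the requested mixture as n grows; output is deterministic given the
    seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    comps = list(mixture_spec)
    probs = np.array([mixture_spec[c] for c in comps], float)
    if (probs < 0).any():
        raise ValueError("mixture proportions must be non-negative")
    if not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
        raise ValueError(f"mixture proportions sum to {probs.sum()}, expected 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, probs)
    nucs: list[NucleosomeComposition] = []
    for comp, k in zip(comps, counts):
        nucs.extend([comp] * int(k))
    return NucleosomePool(nucs, seed=seed)


def _quantified_peptides(counts: dict[str, int]) -> list[tuple[str, tuple[int, int],
                                                               str, float]]:
    """(histone, span, sequence, base intensity) for every peptide the
    quantification scheme measures, with base intensity = copies carrying it."""
    h2a_total = sum(counts[v] for v in H2A_VARIANTS)
    h3_total = sum(counts[v] for v in H3_VARIANTS)
    peptides = []
    for name in ("H2Ac_1", "H2Ac_2", "H2Ac_3", "H2Ac_4"):
        hist, s, e, seq = REFERENCE_PEPTIDES[name]
        peptides.append((hist, (s, e), seq, float(h2a_total)))
    for name, copies in (("H2A_canonical", counts["H2A"]),
                         ("H2A.Z", counts["H2A.Z"]),
                         ("macroH2A", counts["macroH2A"])):
        hist, s, e, seq = REFERENCE_PEPTIDES[name]
        peptides.append((hist, (s, e), seq, float(copies)))
    h3_can = counts["H3.1"] + counts["H3.2"]
    for name, copies in (("H3_canonical_27_40", h3_can),
                         ("H3.3_27_40", counts["H3.3"])):
        hist, s, e, seq = REFERENCE_PEPTIDES[name]
        peptides.append((hist, (s, e), seq, float(copies)))
    for span, seq in PTM_PEPTIDES["H3"].items():
        peptides.append(("H3", span, seq, float(h3_total)))
    for span, seq in PTM_PEPTIDES["H4"].items():
        peptides.append(("H4", span, seq, float(counts["H4"])))
    return peptides


def generate_peptide_table(pool: NucleosomePool,
                           ptm_profile: dict[str, float] | None = None,
                           noise_cv: float = 0.0,
                           response_factors: dict[str, float] | None = None,
                           seed: int = 0,
                           sample_id: str = "sample") -> pd.DataFrame:
    """Forward-model a peptide intensity table from a nucleosome pool.

    ``ptm_profile`` maps a mark (e.g. ``"H3K27me3"``) or an exact combination
    (``"H4K5acK8ac"``) to the fraction of its peptide family carried by that
    form; the remainder stays unmodified. ``noise_cv`` applies i.i.d.
    multiplicative log-normal noise with unit mean and the given CV.
    ``response_factors`` maps peptide backbone sequences to positive
    ionization-efficiency multipliers (default 1 everywhere). Deterministic
    given the seed; byte-identical tables for equal calls.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    ptm_profile = ptm_profile or {}
    counts = pool.copy_counts()
    peptides = _quantified_peptides(counts)

    known_seqs = {seq for _, _, seq, _ in peptides}
    rf = dict.fromkeys(known_seqs, 1.0)
    for key, factor in (response_factors or {}).items():
        if key not in known_seqs:
            raise ValueError(f"unknown peptide {key!r} in response_factors")
        if factor <= 0:
            raise ValueError(f"response factor for {key!r} must be positive")
        rf[key] = float(factor)

    # marks grouped by the (histone, span) family they sit on
    by_family: dict[tuple[str, tuple[int, int]], list[tuple[str, float]]] = {}
    for mark, frac in ptm_profile.items():
        if not (0 <= frac <= 1):
            raise ValueError(f"PTM fraction for {mark!r} out of [0, 1]")
        histone, tokens = parse_mark(mark)
        spans = {PTM_SITES.get(histone, {}).get(pos) for _, pos, _ in tokens}
        if len(spans) != 1 or None in spans:
            raise ValueError(f"mark {mark!r} does not map to one peptide span")
        mods = canonical_mods("".join(f"{aa}{pos}{mod}" for aa, pos, mod in tokens))
        by_family.setdefault((histone, spans.pop()), []).append((mods, frac))

    rows = []
    for histone, span, seq, base in peptides:
        marks = by_family.get((histone, span), [])
        planted = sum(f for _, f in marks)
        if planted > 1 + 1e-12:
            raise ValueError(f"PTM fractions on {histone} {span} exceed 1")
        forms = [("", base * (1 - planted))] + [(m, base * f) for m, f in marks]
        for mods, inten in forms:
            rows.append((sample_id, histone, span[0], span[1], seq, mods,
                         inten * rf[seq]))
    table = pd.DataFrame(rows, columns=PEPTIDE_COLUMNS)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log(1 + noise_cv ** 2))
        table["intensity"] *= rng.lognormal(-sigma ** 2 / 2, sigma, len(table))
    return table


# --------------------------------------------------------------------------
# genome fixture
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrackBump:
    """One Gaussian occupancy bump: peak height ``amplitude`` (expected counts
    per bin at the summit), signed ``offset`` from the anchor center, sigma =
    ``width``/2. ``flank`` > 0 plants a symmetric pair at offset +- flank."""

    amplitude: float
    offset: int = 0
    width: int = 600
    flank: int = 0


@dataclass(frozen=True)
class Archetype:
    """A planted anchor class: per-track occupancy bumps, a PolII bump whose
    offset shares the sign of the variant offsets, an eRNA level, and a signed
    eRNA strand bias toward the offset direction. ``orientation`` is the truth
    label: +1 (right-skewed), -1 (left), 0 (symmetric)."""

    name: str
    bumps: dict[str, TrackBump]
    polii: TrackBump
    erna_amplitude: float
    erna_bias: float = 0.0
    orientation: int = 0

    def __post_init__(self) -> None:
        offsets = [b.offset for b in self.bumps.values()]
        if self.orientation == 0:
            if any(offsets) or self.polii.offset or self.erna_bias:
                raise ValueError(f"symmetric archetype {self.name!r} must have "
                                 "zero offsets and bias")
        else:
            if not any(offsets):
                raise ValueError(f"asymmetric archetype {self.name!r} needs a "
                                 "nonzero offset")
            if any(np.sign(o) not in (0, self.orientation) for o in offsets):
                raise ValueError(f"offsets of {self.name!r} disagree with its "
                                 "orientation")
            if np.sign(self.polii.offset) != self.orientation:
                raise ValueError(f"PolII offset of {self.name!r} must share the "
                                 "variant offset sign")

    def mirrored(self) -> "Archetype":
        bumps = {t: replace(b, offset=-b.offset) for t, b in self.bumps.items()}
        return replace(self, name=self.name[:-2] + "_L" if self.name.endswith("_R")
                       else self.name + "_L",
                       bumps=bumps, polii=replace(self.polii,
                                                  offset=-self.polii.offset),
                       orientation=-self.orientation)


def default_archetypes(erna_bias: float = 0.3) -> list[Archetype]:
    """The 16 planted groups: 4 symmetric classes + 6 mirror pairs, emulating
    the observed spectrum of element classes (a repressive macroH2A class, an
    H3.1 class, an open-site H2A.Z flanking class, a centered H2A.Z+H3.3
    class, and oriented classes skewed in single or combined variants)."""
    P = TrackBump  # noqa: N806 - terse local alias
    sym = [
        Archetype("macroH2A_dom", {"macroH2A": P(45, width=1400)},
                  polii=P(6), erna_amplitude=6),
        Archetype("H3.1_dom", {"H3.1": P(60)}, polii=P(14), erna_amplitude=14),
        Archetype("H2A.Z_flanking", {"H2A.Z": P(45, flank=400, width=300)},
                  polii=P(16), erna_amplitude=16),
        Archetype("H2A.Z_H3.3_centered", {"H2A.Z": P(55), "H3.3": P(55)},
                  polii=P(30), erna_amplitude=40),
    ]
    asym_bases = [
        Archetype("H3.3_skew_R", {"H3.3": P(60, 400)},
                  polii=P(25, 250), erna_amplitude=50, erna_bias=erna_bias,
                  orientation=1),
        Archetype("H2A.Z_skew_R", {"H2A.Z": P(60, 400)},
                  polii=P(22, 250), erna_amplitude=35, erna_bias=erna_bias,
                  orientation=1),
        Archetype("H3.3_H2A.Z_skew_R", {"H3.3": P(55, 300), "H2A.Z": P(55, 550)},
                  polii=P(30, 300), erna_amplitude=60, erna_bias=erna_bias,
                  orientation=1),
        Archetype("H3.1_skew_R", {"H3.1": P(55, 400), "macroH2A": P(14, 400)},
                  polii=P(15, 250), erna_amplitude=20, erna_bias=erna_bias,
                  orientation=1),
        Archetype("macroH2A_skew_R", {"macroH2A": P(55, 400), "H3.1": P(30, 0)},
                  polii=P(10, 250), erna_amplitude=10, erna_bias=erna_bias,
                  orientation=1),
        Archetype("H3.3_H2A.Z_tight_R", {"H3.3": P(50, 700, width=300),
                                         "H2A.Z": P(50, 150, width=300)},
                  polii=P(28, 350), erna_amplitude=45, erna_bias=erna_bias,
                  orientation=1),
    ]
    out = list(sym)
    for base in asym_bases:
        out.append(base)
        out.append(base.mirrored())
    return out


@dataclass
class GenomeFixtureConfig:
    chrom: str = "chrSim"
    bin_width: int = 100
    window: int = 2000            # profile half-width the layout must respect
    n_genes: int = 60
    anchors_per_group: int = 60
    archetypes: list[Archetype] = field(default_factory=default_archetypes)
    background: float = 0.2       # expected counts per bin off-anchor
    noise: str = "poisson"        # "poisson" | "none"
    anchor_width: int = 300
    anchor_spacing: int = 6000
    min_gene_dist: int = 2000
    tf_specs: dict[str, tuple[tuple[str, ...], float]] = field(
        default_factory=lambda: {
            "CTCF": (("H2A.Z_flanking", "H3.1_skew_R", "H3.1_skew_L"), 9.0),
            "ZZZ3": (("macroH2A_dom", "H3.1_dom"), 9.0),
            "EP300": (("H2A.Z_H3.3_centered", "H3.3_skew_R", "H3.3_skew_L",
                       "H3.3_H2A.Z_skew_R", "H3.3_H2A.Z_skew_L"), 4.0),
        })  # TF -> (target archetype names, enrichment odds)
    tf_peak_width: int = 200
    polii_concordant: bool = True  # flip to plant anti-oriented PolII
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise not in ("poisson", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.anchor_spacing < 2 * self.window + self.anchor_width:
            raise ValueError("anchor spacing too small for the profile window")


@dataclass
class GenomeFixture:
    config: GenomeFixtureConfig
    genes: list[GeneModel]
    expression: dict[str, float]
    anchors: list[GenomicInterval]       # name = archetype, score = group id
    truth: pd.DataFrame                  # anchor, group, archetype, orientation
    tracks: dict[str, SignalTrack]       # variant + PolII count tracks
    erna_plus: SignalTrack
    erna_minus: SignalTrack
    tf_peaks: dict[str, list[GenomicInterval]]


def _add_bump(arr: np.ndarray, bin_width: int, center_bp: float,
              amplitude: float, sigma_bp: float) -> None:
    if amplitude <= 0:
        return
    half = int(4 * sigma_bp // bin_width) + 1
    cbin = int(center_bp // bin_width)
    lo, hi = max(cbin - half, 0), min(cbin + half + 1, len(arr))
    x = (np.arange(lo, hi) + 0.5) * bin_width
    arr[lo:hi] += amplitude * np.exp(-((x - center_bp) ** 2) / (2 * sigma_bp ** 2))


def _add_track_bump(arr, bin_width, center_bp, bump: TrackBump) -> None:
    sigma = bump.width / 2
    if bump.flank:
        _add_bump(arr, bin_width, center_bp + bump.offset - bump.flank,
                  bump.amplitude, sigma)
        _add_bump(arr, bin_width, center_bp + bump.offset + bump.flank,
                  bump.amplitude, sigma)
    else:
        _add_bump(arr, bin_width, center_bp + bump.offset, bump.amplitude, sigma)


def generate_genome_fixture(config: GenomeFixtureConfig) -> GenomeFixture:
    """Build the synthetic chromosome: genes, distal anchors with planted
    archetype labels, variant/PolII/eRNA tracks, and TF peak sets."""
    rng = np.random.default_rng(config.seed)
    b = config.bin_width
    cfg = config

    # gene layout: left portion of the chromosome
    genes: list[GeneModel] = []
    expression: dict[str, float] = {}
    pos = 10 * b
    for i in range(cfg.n_genes):
        length = int(rng.integers(2000, 10001)) // b * b
        strand = "+" if rng.random() < 0.5 else "-"
        name = f"gene{i:04d}"
        genes.append(GeneModel(GenomicInterval(cfg.chrom, pos, pos + length,
                                               name, strand=strand),
                               "lncRNA" if rng.random() < 0.15 else "mRNA"))
        expression[name] = float(rng.lognormal(2.0, 1.0))
        pos += length + int(rng.integers(3000, 8001)) // b * b
    gene_region_end = pos

    # anchor layout: to the right, clear of all genes; group order shuffled
    groups = []
    for gid, arch in enumerate(cfg.archetypes, start=1):
        groups.extend([(gid, arch)] * cfg.anchors_per_group)
    order = rng.permutation(len(groups))
    groups = [groups[i] for i in order]

    anchors: list[GenomicInterval] = []
    truth_rows = []
    pos = gene_region_end + cfg.min_gene_dist + 4 * cfg.window
    tss_tts = [p for g in genes for p in (g.tss, g.tts)]
    for idx, (gid, arch) in enumerate(groups):
        placed = False
        for _ in range(50):  # bounded retries against the distal rule
            center = pos // b * b
            start = center - cfg.anchor_width // 2
            ok = all(abs(center - p) > cfg.min_gene_dist for p in tss_tts) and \
                start > gene_region_end
            if ok:
                placed = True
                break
            pos += cfg.anchor_spacing
        if not placed:
            raise RuntimeError("could not place anchor satisfying the distal rule")
        anchors.append(GenomicInterval(cfg.chrom, start,
                                       start + cfg.anchor_width, arch.name,
                                       float(gid)))
        truth_rows.append((idx, gid, arch.name, arch.orientation,
                           arch.erna_bias * arch.orientation))
        pos += cfg.anchor_spacing
    truth = pd.DataFrame(truth_rows, columns=["anchor", "group", "archetype",
                                              "orientation", "signed_bias"])
    chrom_length = (pos + 4 * cfg.window) // b * b
    nbins = chrom_length // b

    track_names = list(VARIANT_TRACKS) + ["PolII"]
    expected = {t: np.full(nbins, cfg.background, float) for t in track_names}
    e_plus = np.full(nbins, cfg.background / 2, float)
    e_minus = np.full(nbins, cfg.background / 2, float)

    # promoter signal scaled by expression (H2A.Z and PolII at the TSS)
    emax = max(expression.values())
    for g in genes:
        scale = expression[g.interval.name] / emax
        _add_bump(expected["H2A.Z"], b, g.tss, 40 * scale, 200)
        _add_bump(expected["PolII"], b, g.tss, 30 * scale, 250)
        _add_bump(expected["H3.3"], b, (g.interval.start + g.interval.end) / 2,
                  8 * scale, (g.interval.end - g.interval.start) / 4)

    for anchor, (_, arch) in zip(anchors, groups):
        c = anchor.center
        for tname, bump in arch.bumps.items():
            _add_track_bump(expected[tname], b, c, bump)
        polii = arch.polii
        if not cfg.polii_concordant:
            polii = replace(polii, offset=-polii.offset)
        _add_track_bump(expected["PolII"], b, c, polii)
        s = arch.orientation
        amp = arch.erna_amplitude
        _add_bump(e_plus, b, c, amp * (1 + s * arch.erna_bias) / 2, 300)
        _add_bump(e_minus, b, c, amp * (1 - s * arch.erna_bias) / 2, 300)

    def sample(arr: np.ndarray) -> np.ndarray:
        return rng.poisson(arr).astype(float) if cfg.noise == "poisson" else arr

    tracks = {t: SignalTrack({cfg.chrom: sample(expected[t])}, b)
              for t in track_names}
    erna_plus = SignalTrack({cfg.chrom: sample(e_plus)}, b, strand="+")
    erna_minus = SignalTrack({cfg.chrom: sample(e_minus)}, b, strand="-")

    tf_peaks: dict[str, list[GenomicInterval]] = {}
    for tf, (targets, odds) in cfg.tf_specs.items():
        p_hit = odds / (odds + 1)
        p_bg = 1 / (odds + 1)
        peaks = []
        for anchor, (_, arch) in zip(anchors, groups):
            p = p_hit if arch.name in targets else p_bg
            if rng.random() < p:
                jitter = int(rng.integers(-100, 101))
                mid = anchor.center + jitter
                peaks.append(GenomicInterval(cfg.chrom,
                                             mid - cfg.tf_peak_width // 2,
                                             mid + cfg.tf_peak_width // 2, tf))
        tf_peaks[tf] = peaks

    return GenomeFixture(cfg, genes, expression, anchors, truth, tracks,
                         erna_plus, erna_minus, tf_peaks)


def expected_strand_bias(arch: Archetype, config: GenomeFixtureConfig,
                         window: int | None = None) -> float:
    """Closed-form expected anchor-window strand bias for an archetype under
    the generator's model: the planted signal bias diluted by the unbiased
    background transcription inside the window,

        E[B] = s * bias * S / (S + bg_total),

    with S the expected eRNA signal counts in the window and bg_total the
    expected background counts (both strands)."""
    b = config.bin_width
    W = window or config.window
    x = np.arange(-W, W, b) + b / 2  # bin midpoints relative to the center
    sigma = 300.0  # the generator's eRNA bump width
    S = arch.erna_amplitude * np.exp(-x ** 2 / (2 * sigma ** 2)).sum()
    bg_total = config.background * len(x)
    return float(arch.orientation * arch.erna_bias * S / (S + bg_total))


def write_fixture(fixture: GenomeFixture, outdir) -> dict[str, str]:
    """Write every fixture component as plain text; returns name -> path."""
    from pathlib import Path

    from .genomic_io import write_bed, write_bedgraph, write_genes

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def record(key, path):
        paths[key] = str(path)
        return path

    write_genes(fixture.genes, record("genes", outdir / "genes.tsv"))
    write_bed(fixture.anchors, record("anchors", outdir / "anchors.bed"))
    for name, track in fixture.tracks.items():
        safe = name.replace(".", "")
        write_bedgraph(track, record(name, outdir / f"{safe}.bedgraph"))
    write_bedgraph(fixture.erna_plus,
                   record("eRNA_plus", outdir / "erna_plus.bedgraph"))
    write_bedgraph(fixture.erna_minus,
                   record("eRNA_minus", outdir / "erna_minus.bedgraph"))
    for tf, peaks in fixture.tf_peaks.items():
        write_bed(peaks, record(f"tf_{tf}", outdir / f"tf_{tf}.bed"))
    with open(record("expression", outdir / "expression.tsv"), "w") as fh:
        for name, val in fixture.expression.items():
            fh.write(f"{name}\t{val:.6g}\n")
    fixture.truth.to_csv(record("truth", outdir / "truth.csv"), index=False)
    return paths
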