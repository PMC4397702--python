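# Methods

## The MS arm: peptide-ratio quantification

**Model.** Bottom-up histone MS measures one intensity per (sample, peptide
backbone, modification form). We assume (i) intensity proportional to the
molar amount of the peptide's parent histone copies in the pool, (ii) a
peptide-specific but form-independent ionization response, and (iii)
multiplicative measurement error. Under these assumptions, ratios of peptides
within one sample cancel loadings, and ratios of forms within one backbone
family cancel the response factor — which is why both statistics below are
ratio-based.

*PTM relative abundance* of a mark is the summed intensity of all forms
carrying it divided by the summed intensity of every form (modified and
unmodified) of its backbone family. Single marks aggregate co-modified forms;
combinations match the exact form. Marks on the 27–40 H3 peptide aggregate
the canonical and H3.3 backbones (they differ at residue 31, but the mark is
not variant-specific and one number per sample is wanted).
Propionylation is assumed complete and ignored as a constant label.

*Variant stoichiometry.* Each H2A-family variant-specific peptide is ratioed
against each of four reference peptides shared across the family, the four
ratios are combined by arithmetic mean (kept per-reference for QC; the mean
is the natural unbiased combiner when the references are exchangeable; a
median can be swapped in), and the three variant summaries are renormalized
to fractions summing to 1 — the renormalization removes the common loading
scale. The references are treated as family-shared rather than
canonical-specific; a separate canonical-specific peptide (`KGNYAER`) exists
precisely because the references are not discriminating. For H3 the 27–40
canonical/H3.3 peptide pair is compared directly:
f(H3.3) = I₃.₃/(I₍₃.₁/₃.₂₎ + I₃.₃), with family totals summing all modified
forms. H3.1 and H3.2 share every quantified peptide and are merged
throughout.

*Enrichment.* log2((a_IP + p)/(a_input + p)) with pseudocount p = 10⁻⁴ by
default (recorded in output); marks absent in both arms map to exactly 0.

**Known bias.** The pipeline applies no correction for peptide-specific
ionization response: a variant peptide ionizing 2× better reads as a ~2×
inflated ratio. The forward model exposes `response_factors` so this bias can
be demonstrated (the test suite does); the quantification itself leaves it
uncorrected, since no response calibration is part of the procedure.

## The genomics arm

**Anchors.** Open-chromatin intervals are kept as analysis anchors when their
midpoint lies strictly more than 2,000 bp (configurable) from every annotated
TSS and TTS and their interval overlaps no gene body — mRNA or lncRNA, any-bp
overlap, the stricter reading. This distal universe is also the population N
for every enrichment test downstream.

**Profiles.** Signal is binned coverage (100 bp bins), RPKM-normalized
(value = count × 10⁹ / (bin width × library size) × global constant; the
constant is display-only — every downstream statistic is scale-invariant,
which the suite asserts). Profile rows cover ±2,000 bp around the anchor
midpoint; centers off the bin grid are resolved by linear weighting of the
two straddling bins, the exact mean under the piecewise-constant signal
model. Gene-level meta-profiles (TSS ±2 kb, TTS ±500 bp) are averaged within
five equal-size expression quantiles, minus-strand rows reversed so bins run
5′→3′.

**Clustering.** Rows are the concatenation of the four variant profiles.
K-means uses d(x, y) = 1 − |r(x, y)| (Pearson r of the concatenated vectors;
plain 1 − r available), member-mean centroids, k-means++-style seeding from
the same metric, convergence on labels, and re-seeds empty clusters from the
worst-fit point. Zero-variance rows (correlation undefined) go to the
Euclidean-nearest centroid and are flagged. K defaults to 16: the observed
structure is 4 symmetric classes plus 6 mirror pairs, and mirror-merging
16 groups with 6 pairs yields the 10 final clusters. Rows are not
standardized before clustering; the correlation metric already ignores
per-row offset and scale, and cross-track amplitude ratios are informative.

**Mirror pairing.** The mirror score between two centroids is the Pearson
correlation between one concatenated centroid and the other after reversing
the bin order within each track block — the same footing as the clustering
metric, so tracks without signal carry no weight (a per-track average of
correlations would let background-only tracks dilute true pairs toward
zero). Greedy matching on descending score with a 0.8 floor, ties to lower
group ids, each group in at most one pair; pairs merge into one final
cluster.

**Asymmetry and orientation.** A profile's asymmetry is
A = (R − L)/(R + L + ε), sums strictly left/right of the window center
(center bin excluded when the bin count is odd; ε = 10⁻¹²; A ≡ 0 for empty
windows). A is antisymmetric under bin reversal and bounded by 1. A cluster
is called asymmetric when |A| ≥ 0.2 on the first priority track (H3.3, then
H2A.Z) that carries signal in its centroid; "carries signal" means the
centroid peak exceeds 3× its median bin — a scale-invariant enrichment test;
a raw nonzero-sum test would be satisfied by background noise on every
track. The threshold 0.2, the priority order, and ε are design choices
exposed in configuration; the suite includes sensitivity checks (mirror
partners score equal-magnitude, opposite-sign A). Within a mirror pair the
member with the larger priority-track A is "right" (+1), its partner "left"
(−1); unpaired asymmetric clusters orient by the sign of A; symmetric
clusters orient "none".

**Directionality.** PolII rows of left-oriented anchors are bin-reversed
before scoring, so positive A means "skewed toward the variant orientation";
concordance is the fraction of asymmetric-cluster anchors with aligned A > 0.
Strand bias is B = (P − M)/(P + M + ε) over the anchor window (plus/minus
normalized with a shared library so depth cannot masquerade as bias), sign-
flipped for left-oriented anchors; cluster means carry a seeded 1,000-resample
percentile bootstrap CI. Between-cluster eRNA totals (P + M per anchor) are
compared with a one-sided Mann–Whitney U — a rank test, chosen because eRNA
totals are heavy-tailed; exact null distribution when min(n) ≤ 20 without
ties, normal approximation with continuity correction otherwise; identical
constant samples return p = 0.5 with a tie warning.

**TF enrichment.** An anchor overlaps a TF iff any peak intersects
[center − 500, center + 500) (half-open; flank configurable). With K_pop of
the N distal anchors overlapping and k of a cluster's n, p is the upper
hypergeometric tail P(X ≥ k); BH q-values are reported alongside raw p for
multiplicity across all (TF, cluster) rows.

## The synthetic-data generator

**What it emulates.** Nucleosome pools are mixtures of composition patterns
(two H3-family and two H2A-family slots each), sampled multinomially — a
fully heterotypic pool is exactly 50% canonical per construction, the
analytic signature the quantifier must invert. Peptide intensities follow
the forward model above: reference peptides ∝ total family copies,
variant-specific peptides ∝ variant copies, planted PTM fractions splitting
families into forms, i.i.d. log-normal noise with unit mean and the given CV
per record, optional response factors. Noise-free tables invert exactly
(error < 10⁻⁹ in the suite).

The synthetic chromosome lays out genes (2–10 kb, expression drawn
log-normally, H2A.Z/PolII promoter bumps scaled by expression) and, well
clear of them, intergenic anchors drawn from 16 planted archetypes: 4
symmetric classes (a broad macroH2A domain, an H3.1 class, an
H2A.Z-flanking open site, a centered H2A.Z+H3.3 class) and 6 asymmetric base
classes, each emitted in both orientations (offsets negated) to form mirror
pairs. Signal is a Gaussian bump per track (σ = width/2, default 300 bp) on
a uniform background (0.2 expected counts/bin), Poisson-sampled (or exact
expectations with `noise="none"`). PolII bumps share the offset sign
(magnitude ~250–350 bp; a flag plants anti-oriented PolII for negative
controls). eRNA is a centered bump split between strands as (1 ± s·bias)/2
with s the orientation sign and bias 0.3 by default; the *observable*
anchor-window bias is the planted bias diluted by the unbiased background,
and `expected_strand_bias` returns that closed form so tests compare against
the model's own expectation rather than the raw parameter. TF peaks hit
target-archetype anchors with probability odds/(odds+1) versus 1/(odds+1)
elsewhere. Archetype amplitudes and offsets were chosen so that distinct
classes are mutually distinguishable under the correlation metric (shapes,
not just amplitudes, differ between any two classes) while true mirror
partners are exact reversals — the property the study's cluster figure
displays. Everything is deterministic given the seed.

**Default problem sizes.** 60 anchors per group (960 anchors), 60 genes,
~6.5 Mb chromosome, 100 bp bins, 10,000 nucleosomes per MS sample, CV 0.1 —
sizes at which the full pipeline runs in about a second while keeping Poisson
and log-normal noise at realistic levels relative to the planted amplitudes
(peak ~50–60 counts/bin against background 0.2, matching deeply sequenced
ChIP-seq at strong sites).

**What passing does not show.** The generator plants unimodal (or cleanly
flanking) bumps with a single archetype per anchor, independent Poisson bins,
no mappability/GC structure, no replicate-level batch effects, no
co-elution/interference in MS, and response factors default to 1. Recovery on
these fixtures demonstrates that the estimators invert their own forward
models and that the statistics are calibrated — not that real chromatin
decomposes into 16 classes, nor that real ionization bias is negligible.

## Numerical choices and degenerate inputs

- Fractions are validated to sum to 1 within 10⁻⁹; negative intensities,
  overlapping bedGraph records, double normalization, zero reference totals,
  and inconsistent hypergeometric counts are rejected with messages.
- Missing marks are reported as missing, never as zero; a missing variant
  peptide is an error unless explicitly allowed, in which case the variant is
  treated as absent.
- A 50/50 variant fraction estimated from two independent CV-0.1 records has
  a standard error of ≈0.035; recovery claims in the suite are therefore
  stated over the ensemble of recovered quantities across 100 seeded
  replicates rather than per worst-case quantity.
- K-means ties, greedy-matching ties, and paired-orientation ties all break
  toward lower group ids; seeds are recorded in every output.

## Limitations

Anchor windows are fixed-width and centered on interval midpoints (no summit
refinement); the mirror merge assumes at most one partner per group; the
asymmetry statistic summarizes a profile to one number and cannot separate
shoulder-vs-summit geometry; exact Mann–Whitney is disabled in the presence
of ties; and the per-anchor orientation is inherited from the cluster, not
estimated per anchor.
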