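# variantscape

Histone variants (H3.3, H2A.Z, macroH2A) are deposited at regulatory regions
and carry information about how those regions are used. `variantscape`
implements, as a tested analysis pipeline over synthetic data with known
ground truth, the two arms of a ChIP-MS + ChIP-seq study of
variant-containing mononucleosomes:

1. **ChIP-MS quantification.** From peptide-level intensity tables:
   PTM relative abundance (intensity of a modified form divided by the summed
   intensity of all forms sharing its backbone), log2 IP/input enrichment,
   and histone-variant stoichiometry. Variant stoichiometry normalizes each
   variant-specific peptide (canonical H2A `KGNYAER`, H2A.Z 1–19, macroH2A
   4–14) to four H2A reference peptides (`GKQGGKAR`, `AKAKTR`, `AGLQFPVGR`,
   `HLQLAIR`), averages the four ratios, and renormalizes to fractions; the
   H3 family compares the canonical 27–40 peptide `KSAPATGGVKKPHR` directly
   to the H3.3 form `KSAPSTGGVKKPHR` (one residue apart; H3.1 and H3.2 are
   indistinguishable and merged). The signature result: a purification in
   which every nucleosome is *heterotypic* (one variant copy + one canonical
   copy per family slot pair) quantifies to exactly 50% canonical.

2. **ChIP-seq architecture of distal regulatory regions.** Promoter-distal
   anchors (>2 kb from every TSS/TTS, outside mRNA and lncRNA bodies) are
   profiled in ±2 kb / 100 bp bins over four variant tracks, clustered with
   K-means under the correlation distance d(x, y) = 1 − |r(x, y)| (K = 16),
   and groups whose centroids are bin-reversals of each other are paired as
   *mirror clusters* — the same element class in opposite genomic
   orientations — and merged (16 groups → 10 clusters). Each profile gets an
   asymmetry score A = (R − L)/(R + L + ε) ∈ [−1, 1]; asymmetric clusters
   receive left/right orientations, which are then tested for concordance
   with PolII skew, for strand bias B = (P − M)/(P + M + ε) in stranded
   eRNA signal, for between-cluster eRNA differences (one-sided
   Mann–Whitney U), and for TF peak-set enrichment (upper-tail
   hypergeometric P with BH q-values).

A synthetic-data module generates every input with planted truth: nucleosome
pools with configurable heterotypic/homotypic composition and PTM profiles
(log-normal intensity noise, per-peptide response factors), and a synthetic
chromosome with 16 planted anchor archetypes (Gaussian occupancy bumps,
Poisson counts), expression-scaled promoter signal, concordantly skewed
PolII, biased bidirectional eRNA, and TF peaks with configured odds.

## Worked example

```sh
python analysis/01_simulate.py
python analysis/02_ms_quant.py
python analysis/03_profiles_and_clusters.py
python analysis/04_directionality.py
python analysis/05_tf_enrichment.py
```

The drivers write their tables under `results/` and print, e.g.:

```
  FLAG-H2A.Z      H2A-family: H2A=0.449, H2A.Z=0.551, macroH2A=0.000
  FLAG-H3.1       H3-family: H3=0.781, H3.3=0.219
...
960 distal anchors -> K=16 groups, 6 mirror pairs -> 10 final clusters
ARI vs planted groups: 1.000; orientation agreement: 1.000
...
PolII concordance with variant orientation: 1.000
strongest eRNA difference: cluster 2 < cluster 9, one-sided p = 3.46e-41
...
  CTCF   cluster  1: k/n = 100/120, fold = 3.54, p = 1.84e-51, q = 5.52e-50
```

Reading these: the simulated FLAG-H2A.Z pool is fully heterotypic, so
canonical H2A ≈ 0.5 of family copies (0.449 here under measurement noise
with CV 0.1); the FLAG-H3.1 pool was built with a 1:3 H3.3:canonical copy
ratio (0.25, measured 0.219). The 16 planted anchor groups are recovered
exactly at this seed, the 6 planted mirror pairs merge to 10 clusters, every
asymmetric anchor's orientation matches the planted offset sign, PolII skew
agrees with orientation at every asymmetric anchor, the weak-eRNA repressive
macroH2A-class cluster is significantly below the active classes, and the
planted TF targets top the enrichment table.

The same steps run as one command with full provenance in `report.json`:

```sh
variantscape run --outdir out/ --seed 0
```

Individual stages are exposed both as a CLI (`variantscape simulate |
ms-quant | profiles | cluster | direction | tf-enrich`) and as library
functions (`variantscape.pipeline.stage_*`); stages hand off through plain
files (CSV/BED/bedGraph/npz), so any stage can be re-run in isolation.

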