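#!/usr/bin/env python
"""Genomics arm, part 2: is PolII skewed the way the histone-variant
orientation points, and does stranded eRNA lean the same way?

Reports per-cluster PolII skew, overall concordance, per-cluster strand bias
with bootstrap CIs, and the between-cluster eRNA rank-sum comparisons
(e.g. the repressive macroH2A cluster vs the signal-poor cluster).
"""

from pathlib import Path

import pandas as pd

from variantscape.pipeline import PipelineConfig, stage_direction

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "pipeline"
RESULTS = ROOT / "results"


def main() -> None:
    cfg = PipelineConfig(seed=0)
    info = stage_direction(SCRATCH, SCRATCH, SCRATCH / "fixture", cfg, SCRATCH)

    for name, out in (("polii_skew", "04_polii_skew.csv"),
                      ("strand_bias", "04_strand_bias.csv"),
                      ("erna_comparisons", "04_erna_comparisons.csv")):
        pd.read_csv(SCRATCH / f"{name}.csv").to_csv(RESULTS / out, index=False)

    print(f"PolII concordance with variant orientation: "
          f"{info['concordance']:.3f}")
    skew = pd.read_csv(RESULTS / "04_polii_skew.csv")
    for r in skew.itertuples():
        print(f"  cluster {r.cluster:2d} ({r.call:10s}): "
              f"mean PolII A = {r.mean_polii_A:+.3f} (n={r.n})")
    comp = pd.read_csv(RESULTS / "04_erna_comparisons.csv")
    top = comp.iloc[0]
    print(f"strongest eRNA difference: cluster {int(top.cluster_low)} < "
          f"cluster {int(top.cluster_high)}, one-sided p = {top.pvalue:.2e}")


if __name__ == "__main__":
    main()
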