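#!/usr/bin/env python
"""Module-trait correlation, VIP gene filtering and UpSet classification.

Correlates module eigengenes with the phenotype panel (photochemical yield,
pigment and phycobilisome ratios, temperature, lipid metrics), filters
member genes of each significant module-trait pair by PLS VIP > 1, and
counts DE genes per exclusive condition set and module.
"""

import argparse
from pathlib import Path

from stresscape import pipeline as pl
from stresscape import io as sio


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/synthetic_study"))
    args = ap.parse_args()

    cfg = pl.PipelineConfig(seed=args.seed, stages=("integrate",))
    pl.run_all(cfg, args.outdir)

    corr = sio.read_table(args.outdir / "module_trait_corr.csv", sep=",")
    sig = corr[corr["significant"]]
    print(f"{len(sig)} of {len(corr)} module-trait pairs significant "
          f"(BH-adjusted p <= 1e-3):")
    for _, row in sig.iterrows():
        print(f"  module {row['module']} ~ {row['trait']}: r = {row['r']:+.2f}")
    vip = sio.read_table(args.outdir / "vip.tsv")
    if not vip.empty:
        n_vip = vip.loc[vip["vip_flag"], "gene_id"].nunique()
        print(f"VIP genes (VIP > 1 in >= 1 significant model): {n_vip}")
    upset = sio.read_table(args.outdir / "upset_counts.tsv")
    top = upset.groupby("set")["n_genes"].sum().sort_values(ascending=False).head(5)
    print("largest exclusive condition sets (ever-DE genes):")
    for s, n in top.items():
        print(f"  {s}: {n} genes")


if __name__ == "__main__":
    main()
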