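#!/usr/bin/env python
"""Differential expression across all stress and diel contrasts.

Each (condition, time) group is tested against its reference (the
acclimation's shared T0 for shift experiments, the 6 a.m. point for
light/dark cycles) with the NB Wald test; genes with BH-adjusted p <= 0.05
and |log2FC| >= 1 are called DE.  Reports the per-contrast up/down counts,
the analogue of the study's DE-landscape figure.
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

    cfg = pl.PipelineConfig(seed=args.seed, stages=("de",))
    pl.run_all(cfg, args.outdir)

    summary = sio.read_table(args.outdir / "de_summary.tsv")
    total = summary[["up", "down", "ns"]].sum(axis=1).iloc[0]
    summary["pct_de"] = (100 * (summary["up"] + summary["down"]) / total).round(1)
    print(summary.to_string(index=False))
    worst = summary.loc[summary["pct_de"].idxmax()]
    print(f"\nstrongest response: {worst['condition']} at {worst['time_h']} h "
          f"({worst['pct_de']}% of genes DE)")


if __name__ == "__main__":
    main()
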