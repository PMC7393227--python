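# stresscape

Integrative analysis of stress-response transcriptomics in the marine
picocyanobacterium *Synechococcus* sp. WH7803, rebuilt as a tested,
reproducible pipeline over fully synthetic data with planted ground truth.

The study design it emulates: cultures acclimated to low light (LL) or high
light (HL) are shifted to high light, UV, low (13 °C) or high (30 °C)
temperature and sampled over time courses (5 time points × 3 replicates per
shift), alongside modulated 12 h/12 h light/dark cycles at 21 and 27 °C
(8 time points × 4 replicates).  With one shared T0 reference set per
acclimation this yields 154 distinct transcriptome samples over 2,634 genes.

## What the pipeline computes

* **Differential expression** per (condition, time) contrast against the
  acclimation's T0 (shifts) or the 6 a.m. point (diel cycles):
  median-of-ratios size factors, per-gene NB dispersion α (variance
  μ + αμ²) by moments with trend shrinkage, a Wald test on
  log₂FC = log₂((m̄₁ + ½)/(m̄₀ + ½)) with a delta-method standard error,
  Benjamini–Hochberg adjustment, and the DE rule padj ≤ 0.05 ∧ |log₂FC| ≥ 1.
* **Signed weighted co-expression network**: aᵢⱼ = ((1 + rᵢⱼ)/2)^β with
  β = 12, scale-free-fit R², topological-overlap clustering into modules and
  submodules, and module eigengenes (PC1 of the standardized member
  expression).
* **Trait integration**: Pearson correlation of eigengenes with phenotypes
  (F_V/F_M, pigment and phycobilisome ratios, temperature, lipid metrics)
  with Student-t p-values thresholded at 10⁻³ after BH; PLS1 regression per
  significant module–trait pair with VIP scores
  (VIP_g = √(P·Σ_c w²_gc SS_c / Σ_c SS_c), mean VIP² = 1) flagging VIP > 1
  genes; exclusive intersection-set (UpSet) counts of DE genes per module.
* **Cyanorons**: maximal runs of ≥ 4 genomically adjacent genes in one
  module whose log₂FC passes |log₂FC| > 1 concordantly (all up or all down)
  at ≥ ⌈T/2⌉ of a stress's time points, verified against a brute-force
  window enumerator and exported as BED.
* **PAM-fluorometry physiology**: F_V/F_M = (F_M − F_0)/F_M, percent-of-
  initial normalisation, exponential decay fits y = a·e^(−kt), the PSII
  repair-rate proxy k(+lincomycin) − k(control), and phycobilisome emission
  ratios PE/PC (565–575 / 645–655 nm) and PC/TA (645–655 / 680 ± 5 nm).
* **Synthetic data generator** producing all of the above's inputs with
  planted modules, fold changes, adjacent runs and trait couplings, so every
  stage is testable offline against known truth.

## Worked example

The numbered scripts under `analysis/` run the stages in order on one
synthetic study (shared output directory, same master seed):

```
python analysis/01_simulate_dataset.py --seed 1
python analysis/02_differential_expression.py --seed 1
python analysis/03_coexpression_network.py --seed 1
python analysis/06_physiology.py --seed 1
```

prints, among other things:

```
design: 154 samples over 9 conditions
counts: 2634 genes x 154 samples, median library 777,908 reads
strongest response: HLLT at 16.0 h (60.6% of genes DE)
scale-free topology R^2 = 0.974 (slope -0.75) at beta = 12, signed mode
module sizes (0 = gray/unassigned):
  module 0: 787 genes
  module 1: 755 genes, 2 submodules
  module 2: 749 genes, 2 submodules
  module 3: 343 genes, 2 submodules
fitted decay coefficients: control 0.203/h, +lincomycin 0.470/h
PSII repair-rate proxy: 0.267/h (planted 0.3/h)
phycobilisome emission ratios: PE/PC = 2.00, PC/TA = 1.00
```

The 154 samples are the study's design arithmetic; the network's high
scale-free R² at β = 12 and the anti-correlated module pair (modules 1/2
mirror each other's trait correlations, see
`analysis/04_trait_integration.py`) reproduce the qualitative structure the
analysis assumes; the repair-rate proxy recovers the planted 0.3/h gap
between the decay coefficients of the control and translation-inhibited
cultures.

The same stages are available as a CLI
(`stresscape simulate|de|network|integrate|cyanorons|physiology|all
--seed N --outdir D`), and every stage re-reads prior outputs from the
output directory, so stages can be rerun individually.

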