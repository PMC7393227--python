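# Methods

This note documents the models and procedures implemented in `stresscape`,
the assumptions behind them, the parameters that matter, and what the
synthetic-data generator does and does not emulate.

## Experimental design model

The design is a list of conditions, each with an acclimation (LL, HL, LD21,
LD27), sampling times (hours) and a replicate count.  Shift conditions are
sampled at T0 plus four stress time points with three biological
replicates; the two light/dark cycles at eight clock times with four
replicates.  One T0 replicate set per acclimation is shared as the
reference of all that acclimation's shift conditions (a `share_t0` flag);
with sharing the design has 154 distinct samples, without it 169.  The
sharing convention reconciles the per-condition sampling table with the
dataset's stated total and is exposed as configuration rather than asserted
as fact.  Diel contrasts use the 6 a.m. sample as reference.

## Synthetic data generator

The generator is the package's test bed: it produces counts, traits,
annotation, kinetics and spectra with a queryable `PlantedTruth`.

**Counts.**  Gene g in sample j is NB-distributed (gamma–Poisson) with mean

    baseline_g · 2^lfc(g, condition_j, time_j) · exp(loading_g · factor_m(g), j) · s_j

and variance μ + αμ².  Baselines are log-normal (log-mean 5, log-sd 1,
i.e. a median of ~150 counts), dispersions log-uniform on [0.01, 0.5] —
the replicate-to-replicate variability range typical of bacterial
RNA-seq — and library factors s_j log-normal(0, 0.15) to exercise
normalization.  α = 0 degenerates to Poisson.

**Module structure.**  Three planted modules: modules 1 and 2 form a
mirrored pair driven by one latent program with opposite signs, module 3 is
independent, and the remainder is unassigned ("gray"; default fractions
0.30 / 0.30 / 0.15 with exact planted sizes).  The mirror structure is
deliberate and load-bearing: stress transcriptomes characteristically
contain large anti-correlated induced/repressed blocks, and — more
importantly — a transcriptome in which most genes swing coherently in one
direction makes library-size estimation unidentifiable.  Median-of-ratios
normalization assumes the median gene is invariant; with a balanced mirror
pair plus a gray fraction that assumption holds and the per-sample size
factor is estimable.  Without it we measured correlations up to ~0.6
between estimated log size factors and the planted module factors, which
caps the recoverability of absolute expression profiles regardless of the
clustering method.  This is a compositionality property of the data, not an
implementation artifact, and it applies equally to real sequencing data.

Latent programs follow an AR(1) (ρ = 0.7) over the ordered time points
within each condition so time courses are smooth like real stress kinetics,
are shared across replicates up to a small jitter (sd 0.1), are
orthogonalized across independent programs (smooth draws over ~45 distinct
condition–time points would otherwise correlate by chance and blur module
identity), standardized to unit variance, and centred to zero mean per
module.  Gene loadings are log-normal (median 0.5, log-sd 0.6, clipped to
[0.05, 2]): right-skewed membership — few hub genes, many peripheral ones —
is what gives the weighted network its approximately scale-free degree
distribution, as in real co-expression networks.

**Planted effects and runs.**  A fraction (default 10%) of genes per
condition receives a log₂ fold change ramping over the time course to ±2.
Planted cyanorons are contiguous runs of 4–8 genes forced into one module,
with boundary genes forced out of it so planted runs are maximal.
Annotation lays genes non-overlapping in index order (GFF3, 1-based
inclusive); adjacency is genome-index adjacency regardless of strand.

**Traits.**  Each trait is a linear combination of module programs plus
Gaussian noise (sd 0.3).  The default panel mirrors the study's phenotype
table (photochemical yield, β-carotene/chl a, PC/TA, PE/PC, temperature,
lipid chain length/unsaturation, cell-density change, zeaxanthin/chl a),
each coupled to one module with |loading| ≤ 1.

**Kinetics and spectra.**  The control arm of a repair experiment decays as
y₀e^(−k_decay·t), the lincomycin arm as y₀e^(−(k_decay+k_repair)·t): with
protein synthesis blocked, PSII damage is not repaired, so the coefficient
difference equals the repair rate.  Gaussian noise is added and values
truncated to [0, 1]; truncation is documented as such and clipped zeros are
kept (no censoring model).  Spectra are sums of Gaussians at 570, 650 and
680 nm (PE, PC, terminal acceptor) on a 545–750 nm grid; the default peak
widths (σ = 5, 5, 4 nm) keep the peaks separable so configured ratios
round-trip through the extractor.

**Seeding.**  All randomness flows from one integer through labelled
`SeedSequence` streams (`child_rng(seed, label)`); the same seed and config
reproduce every output bit-for-bit.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: batch effects beyond library size, within-sample
gene-length or GC bias, count outliers, overdispersion heterogeneity within
a gene across conditions, operon-level transcriptional coupling beyond
module co-membership, and trait nonlinearity.  Real-data module recovery
will also be degraded by the compositionality effect described above
whenever a large coherent expression shift is one-sided.

## Differential expression

A documented re-specification of the count-based DE workflow, aimed at
calibrated error control on NB data rather than output parity with any
published engine.

* Size factors: median over all-nonzero genes of count/geometric-mean; no
  post-hoc renormalization; genes failing the all-nonzero rule are excluded
  from factor estimation only.
* Dispersion: per-group method of moments α̂ = (s² − μ̄)/μ̄² on normalized
  counts, combined across replicate groups with df weights, floored at 0,
  then shrunk halfway toward a fitted trend α(μ) = a₀ + a₁/μ (least squares
  over genes with positive raw estimates), floored at 10⁻⁸.  The shrinkage
  stabilizes 4-df moment estimates enough for calibrated Wald tests at
  triplicate sample sizes.
* Wald test: log₂FC of shrunken group means with pseudocount 0.5; the
  variance of a group mean of normalized counts is (μ/s̄ + αμ²)/n (s̄ the
  group's mean size factor), propagated by the delta method; two-sided
  normal p.
* BH: padj₍ᵢ₎ = min over j ≥ i of min(1, m·p₍ⱼ₎/j), implemented directly
  and cross-checked against both a brute-force implementation and
  statsmodels in the tests.
* DE rule: padj ≤ 0.05 and |log₂FC| ≥ 1 (both configurable).

Measured on null simulations (2,634 genes, 3 vs 3): raw-p type-I fraction
≈ 0.056, false-call rate at the DE rule ≈ 0.3% of genes; power ≈ 1.0 for
|log₂FC| = 2 at mean 500, with false-discovery proportion well under 5%.
These numbers are recomputed by `scripts/acceptance.py`.

## Co-expression network

Expression input is log₂(normalized count + 1).  Signed adjacency
((1 + r)/2)^β with β = 12; the unsigned |r|^β variant is available.  The
source analysis describes the adjacency both as "signed" and as using
absolute-valued correlations — the two are inconsistent; signed is the
default here because the downstream interpretation (anti-correlated module
pairs kept separate) requires it, and the discrepancy is surfaced rather
than resolved silently.  Zero-variance genes are excluded with a warning.

Scale-free fit: connectivity kᵢ = Σⱼ≠ᵢ aᵢⱼ, 10 equal-width bins, R² of
log₁₀ frequency on log₁₀ mean-k over populated bins, sign-flipped negative
when the slope is positive.

Module detection is deterministic: average-linkage hierarchical clustering
(scipy) of topological-overlap dissimilarity (1 − TOM; plain 1 − a as an
alternative), a static cut at 0.9 of the maximal merge height, clusters
below 30 genes to gray, then two expression-informed refinements:
(i) modules whose eigengenes are closer than 0.25 in signed correlation
dissimilarity (1 − r) are merged — 0.25 is the field-standard
module-merge height; on TOM trees a *tree* cut at 0.25 of the height lies
below every within-module merge and assigns nothing, so the cut and the
merge heights are deliberately separate knobs here; (ii) members whose
correlation with their module eigengene (kME) is below 0.3 return to gray,
because a static cut attaches loosely connected genes that do not follow
the module profile.  The merge uses signed dissimilarity so mirrored
induced/repressed pairs never collapse.  Submodules re-cluster each
module's members at 0.7 of the subtree height (minimum 10 genes).

Eigengenes are the first right singular vector of the standardized member ×
sample matrix, scaled to unit variance and oriented so the mean member
correlation is non-negative.  The source text calls this quantity the
module "eigenvalue"; it is implemented as the standard eigengene (PC1).

Module-recovery acceptance uses a dedicated simulation
(`recovery_truth_config`): orthogonal blocks covering half the genome
(0.20 / 0.20 / 0.10, mirror pair + independent module), low NB noise, no
superimposed DE.  Half the transcriptome being stable keeps normalization
exactly identifiable, so the measurement isolates the clustering; under
these conditions the adjusted Rand index against planted labels exceeds
0.95 and eigengene–factor |r| exceeds 0.99 across seeds.

## Trait integration

Module–trait association is pairwise-complete Pearson r with the Student
t p-value (n − 2 df); pairs with fewer than 4 overlapping samples are
flagged untestable.  The significance threshold 10⁻³ is applied after BH
adjustment across the module × trait grid (the source states "adjusted
p-value" without naming the procedure; BH is used for consistency with the
DE stage, raw-p thresholding is a flag).

VIP uses single-trait PLS1 (scikit-learn's NIPALS PLS behind the module
surface) on standardized predictors with 2 components by default (the
source does not state the count; 2 captures a module's dominant profile
plus one contrast, and the identity mean(VIP²) = 1 holds for any count).
Whether the source regressed one trait at a time or a multi-trait response
is unstated; per-trait PLS1 is implemented and reported per trait.

UpSet sets use exclusive-intersection semantics (a gene's set is exactly
the set of conditions where it is DE at ≥ 1 time point), which makes the
sets a partition of the ever-DE genes — the partition property is asserted
in tests; an inclusive mode is not provided because counts would no longer
partition.  DE direction is ignored for membership and carried in output.

## Cyanorons

A call is a maximal run of ≥ `min_run` (default 4) genome-adjacent genes
sharing one non-gray module label, supported at ≥ ⌈T/2⌉ of a stress's T
time points, where a time point supports the run iff every member's log₂FC
exceeds `lfc` (default 1) or every member's is below −`lfc`.  Three
readings fixed deliberately: the source's "log₂FC > 1 or < 1" is read as
"> 1 or < −1" (the literal reading is vacuous); concordance is required
within each time point across all members (all up or all down), not per
gene independently; and only maximal runs are reported, since the runs of
one labelling partition the genome.  Strand is carried through but not
used.  Output BED intervals are 0-based half-open; annotation input is
GFF3 1-based inclusive; the 0-based genome index is the canonical
adjacency key.  A brute-force enumerator over all windows is part of the
package and the tests assert exact agreement; `cyanoron_null_rate`
contextualizes call counts against label-permuted genomes with independent
N(0, 0.5) fold changes (mean false calls ≈ 0 per 400-gene genome at the
default rule).  Predicted operons are generated and written alongside but
are not part of the call rule.

## Physiology

F_V/F_M = (F_M − F_0)/F_M with F_M > 0 and F_0 ≤ F_M enforced (signal
inversion raises).  Decay fits use y = a·e^(−kt) with the intercept free —
the source does not state whether the intercept was fixed or values
normalized; a free intercept is robust to measurement offset at T0, and
fits are seeded by log-linear regression with a coarse grid fallback when
non-positive values block the log.  The short-term repair proxy is
k(inhibited) − k(control) from exponential fits over the 6 h window; the
long-term protocol (15/30/60 min aliquots) uses linear slopes over the 1 h
window because three points under-determine a two-parameter exponential
under noise.  Spectrum ratios are window maxima: PE 565–575 nm, PC 645–655
nm, TA 680 ± 5 nm (the source gives a single wavelength for TA; a window
maximum is robust to ±nm grid offsets); a numerically vanished denominator
peak raises rather than returning an unstable ratio.

## Numerical and degenerate-input choices

Dispersion floor 10⁻⁸; pseudocount 0.5 before log₂; correlations clipped
to [−1, 1]; TOM denominators guarded and the matrix clipped to [0, 1];
dissimilarity symmetrized before linkage; module relabelling by decreasing
size with mergesort-stable ordering throughout, so every stage is a pure
function of its inputs.  Exponential fits try multiple seeds and keep the
lowest SSE; a constant series yields k = 0.

## Known limitations

The DE engine is a re-specification, not a parity clone: on the same real
dataset it would produce similar but not identical gene lists to the
published workflow.  The static-cut clustering is simpler than dynamic
tree cut and will split or merge differently on real dendrograms.  Module
recovery claims hold under the generator's conditions (see the generator
section for what those exclude).  The cyanoron null model assumes
independent fold changes across genes, which understates false-call rates
when residual spatial correlation exists along the genome.
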