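"""Synthetic experiment generator with planted ground truth.

Emulates the data a stress time-course transcriptome study of *Synechococcus*
sp. WH7803 produces: the sampling design (7 light/UV/temperature shift
conditions with 5 time points x 3 replicates, plus modulated light/dark
cycles at two temperatures with 8 time points x 4 replicates), gene-level
negative-binomial read counts with planted co-expression module structure and
condition/time-specific log2 fold changes, a genome-ordered gene annotation
with planted adjacent co-expressed runs ("cyanorons"), phenotypic traits
linearly coupled to the module latent factors, PSII fluorescence decay
kinetics with and without a translation inhibitor, and phycobilisome
fluorescence emission spectra.

Every generator is deterministic given its seed: all randomness flows from a
single integer through labelled :class:`numpy.random.SeedSequence` streams.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# seeding

_MAX_SEED = 2**31 - 1


def child_rng(master_seed: int, label: str) -> np.random.Generator:
    """Deterministic per-stage random generator derived from a master seed.

    The label is hashed with CRC32 (stable across runs and platforms) and
    combined with the master seed into a SeedSequence, so independently
    labelled streams never collide and the whole pipeline is reproducible
    from one integer.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed) & _MAX_SEED, zlib.crc32(label.encode())])
    )


# ---------------------------------------------------------------------------
# experiment design

#: Sampling design of the shift experiments: (acclimation, condition,
#: sampling times in hours, replicates).  Light/UV shifts are sampled over
#: 6 h, the low/high temperature shifts over 1-3 days.
SHIFT_CONDITIONS: tuple[tuple[str, str, tuple[float, ...], int], ...] = (
    ("LL", "LLHL", (0, 0.3, 1, 3, 6), 3),
    ("LL", "LLUV", (0, 0.3, 1, 3, 6), 3),
    ("LL", "LLLT", (0, 12, 24, 48, 72), 3),
    ("LL", "LLHT", (0, 12, 24, 48, 72), 3),
    ("HL", "HLUV", (0, 0.3, 1, 3, 6), 3),
    ("HL", "HLLT", (0, 4, 8, 16, 24), 3),
    ("HL", "HLHT", (0, 4, 8, 16, 24), 3),
)

#: Light/dark cycle design at 21 and 27 degC: virtual clock-time sampling
#: points (hours), four biological replicates, 6 a.m. as the reference.
LD_CONDITIONS: tuple[tuple[str, str, tuple[float, ...], int], ...] = (
    ("LD21", "LD21", (6, 9, 12, 15, 18, 20, 22, 2), 4),
    ("LD27", "LD27", (6, 9, 12, 15, 18, 20, 22, 2), 4),
)

LD_REFERENCE_TIME = 6.0  # 6 a.m.


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition: its acclimation, sampling times and
    replication, and which time point serves as the within-condition
    reference (T0 for shifts, 6 a.m. for diel cycles)."""

    acclimation: str
    condition: str
    times: tuple[float, ...]
    n_replicates: int
    reference_time: float = 0.0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError(f"replicate count must be >= 1, got {self.n_replicates}")
        if not self.times:
            raise ValueError(f"condition {self.condition} has no time points")


@dataclass(frozen=True)
class DesignConfig:
    conditions: tuple[ConditionSpec, ...]
    share_t0: bool = True

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("empty condition list")


def default_design_config(share_t0: bool = True) -> DesignConfig:
    """The study's full sampling design.

    With ``share_t0`` (the default) a single T0 replicate set per acclimation
    is reused as the reference of every shift condition under that
    acclimation, which yields the study's 154 distinct transcriptomes;
    without sharing each condition carries its own T0 set (169 samples).
    """
    conds = [
        ConditionSpec(acc, cond, times, reps, reference_time=0.0)
        for acc, cond, times, reps in SHIFT_CONDITIONS
    ]
    conds += [
        ConditionSpec(acc, cond, times, reps, reference_time=LD_REFERENCE_TIME)
        for acc, cond, times, reps in LD_CONDITIONS
    ]
    return DesignConfig(conditions=tuple(conds), share_t0=share_t0)


@dataclass
class ExperimentDesign:
    """Sample sheet: one row per distinct RNA sample.

    Columns: sample_id, acclimation, condition, time_h, replicate.  Shared
    reference samples (when T0 sharing is enabled) carry the condition label
    ``<acclimation>_T0``.
    """

    table: pd.DataFrame
    config: DesignConfig

    def __post_init__(self) -> None:
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_ids in design")
        trip = self.table[["condition", "time_h", "replicate"]]
        if trip.duplicated().any():
            raise ValueError("duplicate (condition, time, replicate) triples")

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def n_samples(self) -> int:
        return len(self.table)

    def condition_names(self, include_reference: bool = False) -> list[str]:
        names = [c.condition for c in self.config.conditions]
        if include_reference:
            names += sorted(
                set(self.table["condition"]) - set(names)
            )
        return names

    def spec_for(self, condition: str) -> ConditionSpec:
        for c in self.config.conditions:
            if c.condition == condition:
                return c
        raise KeyError(f"unknown condition: {condition}")

    def samples_of(self, condition: str, time_h: float) -> list[str]:
        t = self.table
        sel = t[(t["condition"] == condition) & (np.isclose(t["time_h"], time_h))]
        return sel["sample_id"].tolist()

    def reference_samples(self, condition: str) -> list[str]:
        """Reference group of a condition: the shared acclimation T0 set if
        T0 sharing is on, else the condition's own reference time point."""
        spec = self.spec_for(condition)
        if self.config.share_t0 and spec.reference_time == 0.0:
            shared = f"{spec.acclimation}_T0"
            if (self.table["condition"] == shared).any():
                return self.table.loc[
                    self.table["condition"] == shared, "sample_id"
                ].tolist()
        return self.samples_of(condition, spec.reference_time)

    def contrasts(self) -> list[tuple[str, float]]:
        """All (condition, time) pairs tested against their reference."""
        out = []
        for spec in self.config.conditions:
            for t in spec.times:
                if t == spec.reference_time:
                    continue
                out.append((spec.condition, float(t)))
        return out


def generate_design(config: DesignConfig | None = None) -> ExperimentDesign:
    """Expand a design configuration into the per-sample table.

    When T0 sharing is enabled, the time-0 samples of all shift conditions
    within one acclimation collapse into a single replicate set labelled
    ``<acclimation>_T0`` whose replicate count is the maximum requested by
    those conditions.
    """
    config = config or default_design_config()
    rows: list[dict] = []
    shared_t0_reps: dict[str, int] = {}
    if config.share_t0:
        for spec in config.conditions:
            if spec.reference_time == 0.0 and 0.0 in [float(t) for t in spec.times]:
                shared_t0_reps[spec.acclimation] = max(
                    shared_t0_reps.get(spec.acclimation, 0), spec.n_replicates
                )
        for acc, n_reps in shared_t0_reps.items():
            for r in range(1, n_reps + 1):
                rows.append(
                    dict(
                        sample_id=f"{acc}_T0_r{r}",
                        acclimation=acc,
                        condition=f"{acc}_T0",
                        time_h=0.0,
                        replicate=r,
                    )
                )
    for spec in config.conditions:
        for t in spec.times:
            t = float(t)
            if (
                config.share_t0
                and t == 0.0
                and spec.reference_time == 0.0
                and spec.acclimation in shared_t0_reps
            ):
                continue  # folded into the shared T0 set
            for r in range(1, spec.n_replicates + 1):
                tag = f"{t:g}".replace(".", "p")
                rows.append(
                    dict(
                        sample_id=f"{spec.condition}_t{tag}_r{r}",
                        acclimation=spec.acclimation,
                        condition=spec.condition,
                        time_h=t,
                        replicate=r,
                    )
                )
    return ExperimentDesign(table=pd.DataFrame(rows), config=config)


# ---------------------------------------------------------------------------
# planted truth

GRAY_LABEL = 0  # module id of unassigned genes


@dataclass
class GeneAnnotation:
    """Genome-ordered gene records plus operon membership.

    ``table`` columns: gene_id, start, end, strand, genome_index (0-based
    rank in genome order); coordinates are 1-based inclusive (GFF3
    convention).  ``operons`` is a list of gene_id runs, each genomically
    adjacent.
    """

    table: pd.DataFrame
    operons: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        t = self.table
        idx = t["genome_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(t))):
            raise ValueError("genome indices must be 0-based and consecutive")
        if not (t["start"].to_numpy()[1:] > t["start"].to_numpy()[:-1]).all():
            raise ValueError("genes must be sorted by start coordinate")
        if (t["start"] < 1).any() or (t["end"] < t["start"]).any():
            raise ValueError("coordinates must be 1-based with end >= start")

    @property
    def gene_ids(self) -> list[str]:
        return self.table["gene_id"].tolist()

    @property
    def n_genes(self) -> int:
        return len(self.table)


@dataclass
class PlantedTruth:
    """Generative ground truth behind a synthetic dataset.

    module_labels
        gene -> module id (0 = unassigned / gray).
    gene_loadings
        per-gene loading on its module's latent factor (0 for gray genes).
    latent_factors
        module x sample matrix (rows indexed by module id), zero mean per
        module across samples.
    de_truth
        (condition, time) -> per-gene planted log2 fold change (0 for nulls).
    trait_loadings
        trait x module coefficient matrix.
    cyanoron_truth
        planted adjacent runs as (start_index, end_index, module_id),
        inclusive genome indices.
    nb_dispersion, baseline_mean
        per-gene negative-binomial dispersion alpha >= 0 and baseline mean
        > 0.
    """

    module_labels: np.ndarray
    gene_loadings: np.ndarray
    latent_factors: pd.DataFrame
    de_truth: dict[tuple[str, float], np.ndarray]
    trait_loadings: pd.DataFrame
    cyanoron_truth: list[tuple[int, int, int]]
    nb_dispersion: np.ndarray
    baseline_mean: np.ndarray
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.baseline_mean)) or np.any(self.baseline_mean <= 0):
            raise ValueError("baseline_mean must be finite and positive")
        if np.any(self.nb_dispersion < 0):
            raise ValueError("negative dispersion")
        if not self.gene_ids:
            self.gene_ids = [f"SYN_{i:05d}" for i in range(len(self.module_labels))]

    @property
    def n_genes(self) -> int:
        return len(self.module_labels)

    @property
    def module_ids(self) -> list[int]:
        return [int(m) for m in self.latent_factors.index]

    def planted_lfc(self, gene: int, condition: str, time_h: float) -> float:
        key = (condition, float(time_h))
        if key not in self.de_truth:
            return 0.0
        return float(self.de_truth[key][gene])


@dataclass(frozen=True)
class TruthConfig:
    """Knobs of the generative model; the defaults are the study conditions.

    Three modules: modules 1 and 2 form a mirrored pair sharing one latent
    program with opposite signs (stress transcriptomes characteristically
    contain large anti-correlated induced/repressed module pairs), module 3
    is independent, and a quarter of the genome is unassigned (gray).  The
    mirrored pair plus the gray fraction keep the per-sample median gene
    approximately invariant, so median-of-ratios normalization remains
    identifiable -- as it is on real data, where most of the transcriptome
    is stable at any one time point.  Planted log2 fold changes ramp up
    over each condition's time course to magnitude ``effect_lfc`` for a
    fraction ``de_fraction`` of genes.  Latent factors follow an AR(1)
    (rho = 0.7) over time within each condition so that the time courses
    are smooth, as real stress kinetics are.
    """

    n_genes: int = 2634
    module_fractions: tuple[float, ...] = (0.30, 0.30, 0.15)
    mirror_pair: tuple[int, int] | None = (1, 2)
    mean_log_baseline: float = 5.0
    sd_log_baseline: float = 1.0
    dispersion_range: tuple[float, float] = (0.01, 0.5)
    # module loadings are right-skewed (few hub genes, many peripheral
    # members), which is what gives the weighted network its approximately
    # scale-free degree distribution
    loading_median: float = 0.5
    loading_sigma: float = 0.6
    loading_clip: tuple[float, float] = (0.05, 2.0)
    factor_rho: float = 0.7
    factor_scale: float = 1.0
    replicate_jitter: float = 0.1
    de_fraction: float = 0.1
    effect_lfc: float = 2.0
    n_cyanorons: int = 5
    cyanoron_length: tuple[int, int] = (4, 8)


def recovery_truth_config(n_genes: int = 400) -> "TruthConfig":
    """Conditions of the module-recovery simulation.

    Three orthogonal latent-factor blocks (a mirrored induced/repressed
    pair plus an independent module) covering half the transcriptome, the
    other half unassigned, with low observation noise and no superimposed
    differential-expression effects.  Half the genes being stable keeps the
    per-sample median gene null, so library-size normalization is exactly
    identifiable and recovery measures the clustering, not confounded
    normalization.
    """
    return TruthConfig(
        n_genes=n_genes,
        module_fractions=(0.2, 0.2, 0.1),
        n_cyanorons=3,
        de_fraction=0.0,
        dispersion_range=(0.01, 0.05),
        loading_median=1.0,
        loading_sigma=0.3,
    )


def make_planted_truth(
    design: ExperimentDesign,
    config: TruthConfig | None = None,
    seed: int = 0,
    traits: dict[str, dict[int, float]] | None = None,
) -> PlantedTruth:
    """Draw a complete ground truth consistent with a design.

    ``traits`` maps trait name -> {module id: loading}; by default a small
    panel emulating the study's phenotype table is generated, with each
    module driving a few traits with loading magnitude 1.
    """
    cfg = config or TruthConfig()
    rng = child_rng(seed, "truth")
    n = cfg.n_genes
    n_mod = len(cfg.module_fractions)

    # module membership: exact planted sizes scattered over the genome
    # (exact counts keep the mirrored pair balanced, so the per-sample
    # median gene stays null and normalization identifiable); cyanoron
    # runs are overwritten below
    labels = np.zeros(n, dtype=int)
    order = rng.permutation(n)
    start = 0
    for m, frac in enumerate(cfg.module_fractions, start=1):
        size = int(round(frac * n))
        labels[order[start : start + size]] = m
        start += size

    # planted cyanorons: contiguous runs forced into one module
    cyanorons: list[tuple[int, int, int]] = []
    occupied = np.zeros(n, dtype=bool)
    for _ in range(cfg.n_cyanorons):
        length = int(rng.integers(cfg.cyanoron_length[0], cfg.cyanoron_length[1] + 1))
        for _attempt in range(100):
            start = int(rng.integers(0, n - length))
            if not occupied[start : start + length].any():
                break
        else:
            continue
        module = int(rng.integers(1, n_mod + 1))
        labels[start : start + length] = module
        # planted runs are maximal: boundary genes must not share the label
        if start > 0 and labels[start - 1] == module:
            labels[start - 1] = GRAY_LABEL
        end = start + length - 1
        if end + 1 < n and labels[end + 1] == module:
            labels[end + 1] = GRAY_LABEL
        occupied[max(0, start - 1) : start + length + 1] = True
        cyanorons.append((start, end, module))

    loadings = np.clip(
        rng.lognormal(np.log(cfg.loading_median), cfg.loading_sigma, size=n),
        *cfg.loading_clip,
    )
    loadings[labels == 0] = 0.0

    # latent factors: AR(1) over ordered time points within each condition,
    # shared across replicates up to a small jitter; zero-centred per module
    samples = design.table
    pos_of = {sid: j for j, sid in enumerate(samples["sample_id"])}
    factors = np.zeros((n_mod, len(samples)))
    for m in range(n_mod):
        frng = child_rng(seed, f"factor_{m}")
        for cond, sub in samples.groupby("condition", sort=True):
            times = np.sort(sub["time_h"].unique())
            level = frng.normal()
            cond_values = {}
            for t in times:
                level = cfg.factor_rho * level + np.sqrt(1 - cfg.factor_rho**2) * frng.normal()
                cond_values[t] = level
            for _, row in sub.iterrows():
                j = pos_of[row["sample_id"]]
                factors[m, j] = cond_values[row["time_h"]] + cfg.replicate_jitter * frng.normal()
    factors -= factors.mean(axis=1, keepdims=True)
    # orthogonalize independent programs (distinct modules represent
    # distinct regulatory programs; chance correlation between smooth AR(1)
    # draws over few time points would blur module identity)
    mirror_target = cfg.mirror_pair[1] - 1 if cfg.mirror_pair else -1
    independent = [m for m in range(n_mod) if m != mirror_target]
    for pos, m in enumerate(independent):
        for prev in independent[:pos]:
            f_prev = factors[prev]
            factors[m] -= (factors[m] @ f_prev) / (f_prev @ f_prev) * f_prev
        sd = factors[m].std()
        if sd > 0:
            factors[m] /= sd
    if cfg.mirror_pair is not None and max(cfg.mirror_pair) <= n_mod:
        a, b = cfg.mirror_pair
        factors[b - 1] = -factors[a - 1]  # mirrored induced/repressed pair
    factors -= factors.mean(axis=1, keepdims=True)
    factors *= cfg.factor_scale
    latent = pd.DataFrame(
        factors, index=pd.Index(range(1, n_mod + 1), name="module"), columns=samples["sample_id"].tolist()
    )

    # planted DE: a fraction of genes per condition, effect ramping over time
    de_truth: dict[tuple[str, float], np.ndarray] = {}
    for cond, t in design.contrasts():
        de_truth[(cond, t)] = np.zeros(n)
    for spec in design.config.conditions:
        drng = child_rng(seed, f"de_{spec.condition}")
        n_de = int(round(cfg.de_fraction * n))
        de_genes = drng.choice(n, size=n_de, replace=False)
        signs = drng.choice([-1.0, 1.0], size=n_de)
        times = [t for t in spec.times if t != spec.reference_time]
        for k, t in enumerate(sorted(times)):
            ramp = (k + 1) / len(times)
            de_truth[(spec.condition, float(t))][de_genes] = signs * cfg.effect_lfc * ramp

    if traits is None:
        traits = _default_trait_loadings(n_mod)
    trait_loadings = pd.DataFrame(
        {name: [load.get(m, 0.0) for m in range(1, n_mod + 1)] for name, load in traits.items()},
        index=latent.index,
    ).T

    baseline = np.exp(rng.normal(cfg.mean_log_baseline, cfg.sd_log_baseline, size=n))
    lo, hi = cfg.dispersion_range
    dispersion = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))

    return PlantedTruth(
        module_labels=labels,
        gene_loadings=loadings,
        latent_factors=latent,
        de_truth=de_truth,
        trait_loadings=trait_loadings,
        cyanoron_truth=cyanorons,
        nb_dispersion=dispersion,
        baseline_mean=baseline,
    )


def _default_trait_loadings(n_modules: int) -> dict[str, dict[int, float]]:
    """A phenotype panel shaped like the study's trait table: photochemical
    yield, pigment and phycobilisome ratios, temperature and lipid metrics,
    each coupled (with sign) to one module."""
    panel = [
        ("fvfm_pct", 1, 1.0),
        ("beta_car_chla", 1, 1.0),
        ("pc_ta", 1, -1.0),
        ("temperature", 2, -1.0),
        ("pe_pc", 2, 1.0),
        ("sqdg_chain_length", 2, -0.8),
        ("chain_unsaturation", 2, 0.8),
        ("cell_density_change", 3, 1.0),
        ("zea_chla", 3, 0.6),
    ]
    out: dict[str, dict[int, float]] = {}
    for name, module, loading in panel:
        if module <= n_modules:
            out[name] = {module: loading}
        else:
            out[name] = {}
    return out


# ---------------------------------------------------------------------------
# counts

@dataclass
class CountMatrix:
    """Integer gene x sample read counts with the design attached."""

    counts: pd.DataFrame
    design: ExperimentDesign

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if list(self.counts.columns) != self.design.sample_ids:
            raise ValueError("count columns do not match design sample_ids")

    @property
    def gene_ids(self) -> list[str]:
        return self.counts.index.tolist()


def generate_counts(
    design: ExperimentDesign,
    truth: PlantedTruth,
    seed: int = 0,
    library_size_sd: float = 0.15,
) -> CountMatrix:
    """Negative-binomial counts under the planted truth.

    The expected count of gene g in sample j is

        baseline_g * 2**lfc(g, condition_j, time_j)
                   * exp(loading_g * factor_{module(g), j}) * s_j

    with library-size factor s_j ~ log-normal(0, ``library_size_sd``), and the
    count is drawn NB(mean, alpha_g) in the mean/dispersion parameterization
    (variance mu + alpha mu^2) via the gamma-Poisson mixture.  alpha = 0
    degenerates to Poisson.
    """
    if truth.latent_factors.shape[1] != design.n_samples:
        raise ValueError("truth latent factors do not match design size")
    rng = child_rng(seed, "counts")
    samples = design.table
    n_genes = truth.n_genes
    mean = np.tile(truth.baseline_mean[:, None], (1, design.n_samples))

    factors = truth.latent_factors.to_numpy()
    for g in range(n_genes):
        m = truth.module_labels[g]
        if m > 0:
            mean[g, :] *= np.exp(truth.gene_loadings[g] * factors[m - 1, :])
    for j, (_, row) in enumerate(samples.iterrows()):
        key = (row["condition"], float(row["time_h"]))
        if key in truth.de_truth:
            mean[:, j] *= 2.0 ** truth.de_truth[key]

    size_factors = np.exp(rng.normal(0.0, library_size_sd, size=design.n_samples))
    mean *= size_factors[None, :]

    alpha = truth.nb_dispersion[:, None]
    counts = np.empty_like(mean, dtype=np.int64)
    poisson_rows = truth.nb_dispersion <= 0
    if poisson_rows.any():
        counts[poisson_rows] = rng.poisson(mean[poisson_rows])
    nb_rows = ~poisson_rows
    if nb_rows.any():
        shape = 1.0 / alpha[nb_rows]
        lam = rng.gamma(shape, alpha[nb_rows] * mean[nb_rows])
        counts[nb_rows] = rng.poisson(lam)

    frame = pd.DataFrame(counts, index=truth.gene_ids, columns=design.sample_ids)
    frame.index.name = "gene_id"
    return CountMatrix(counts=frame, design=design)


# ---------------------------------------------------------------------------
# traits

def generate_traits(
    design: ExperimentDesign,
    truth: PlantedTruth,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample trait table: loadings x latent factors + Gaussian noise.

    Returns a sample x trait DataFrame indexed by sample_id.  Traits whose
    loading on a module is large in magnitude are recoverably
    (anti)correlated with that module's eigengene.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = child_rng(seed, "traits")
    factors = truth.latent_factors.to_numpy()  # modules x samples
    loadings = truth.trait_loadings.to_numpy()  # traits x modules
    values = loadings @ factors
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return pd.DataFrame(
        values.T, index=pd.Index(design.sample_ids, name="sample_id"),
        columns=truth.trait_loadings.index,
    )


# ---------------------------------------------------------------------------
# annotation

def generate_annotation(
    n_genes: int,
    truth: PlantedTruth | None = None,
    seed: int = 0,
    mean_gene_length: int = 900,
    intergenic_gap: int = 120,
    operon_max_run: int = 5,
) -> GeneAnnotation:
    """Genome-ordered, non-overlapping gene records plus operon runs.

    Genes are laid on a single circular-chromosome-like contig in index
    order; planted cyanoron members are adjacent by construction since every
    gene is adjacent to its index neighbours.  Operons are random runs of up
    to ``operon_max_run`` consecutive genes, with planted cyanoron intervals
    kept intact as operons of their own (predicted operons and co-expressed
    runs overlap heavily in cyanobacterial genomes).
    """
    if truth is not None:
        needed = max((end for _s, end, _m in truth.cyanoron_truth), default=-1) + 1
        if n_genes < needed:
            raise ValueError(f"n_genes={n_genes} smaller than truth requires ({needed})")
        if n_genes != truth.n_genes:
            raise ValueError("n_genes must equal truth.n_genes")
    rng = child_rng(seed, "annotation")
    lengths = rng.integers(mean_gene_length // 3, mean_gene_length * 5 // 3, size=n_genes)
    gaps = rng.integers(10, 2 * intergenic_gap, size=n_genes)
    starts = np.cumsum(gaps) + np.concatenate([[0], np.cumsum(lengths[:-1])])
    strands = rng.choice(["+", "-"], size=n_genes)
    gene_ids = truth.gene_ids if truth is not None else [f"SYN_{i:05d}" for i in range(n_genes)]
    table = pd.DataFrame(
        dict(
            gene_id=gene_ids,
            start=starts.astype(int) + 1,
            end=(starts + lengths).astype(int),
            strand=strands,
            genome_index=np.arange(n_genes),
        )
    )

    in_cyanoron = np.zeros(n_genes, dtype=bool)
    operons: list[list[str]] = []
    if truth is not None:
        for s, e, _m in truth.cyanoron_truth:
            in_cyanoron[s : e + 1] = True
            operons.append([gene_ids[i] for i in range(s, e + 1)])
    i = 0
    while i < n_genes:
        if in_cyanoron[i]:
            i += 1
            continue
        run = int(rng.integers(1, operon_max_run + 1))
        members = []
        while i < n_genes and len(members) < run and not in_cyanoron[i]:
            members.append(gene_ids[i])
            i += 1
        if len(members) >= 2:
            operons.append(members)
    return GeneAnnotation(table=table, operons=operons)


# ---------------------------------------------------------------------------
# fluorescence kinetics

@dataclass
class FluorescenceSeries:
    """A PSII quantum-yield time course, optionally under a translation
    inhibitor (lincomycin), which blocks D1 repair so the decay reflects
    damage plus repair."""

    times: np.ndarray
    values: np.ndarray
    inhibitor: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values differ in length")
        if len(self.times) and not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")
        if len(self.values) and ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("quantum yields must lie in [0, 1]")


def generate_kinetics(
    k_decay: float,
    k_repair: float,
    y0: float = 0.6,
    times: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[FluorescenceSeries, FluorescenceSeries]:
    """Paired control / inhibitor fluorescence decay series.

    The control arm decays with net coefficient ``k_decay`` (damage partially
    offset by repair); the inhibited arm, where repair is blocked, decays
    with coefficient ``k_decay + k_repair``.  The difference of fitted decay
    coefficients therefore recovers the repair rate.  Gaussian noise is added
    and values truncated to [0, 1].
    """
    if k_decay < 0 or k_repair < 0:
        raise ValueError("rates must be >= 0")
    if not (0 < y0 <= 1):
        raise ValueError("y0 must lie in (0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if times is None:
        times = np.array([0.0, 0.3, 1.0, 2.0, 3.0, 4.5, 6.0])
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("empty times")
    rng = child_rng(seed, "kinetics")
    control = y0 * np.exp(-k_decay * times)
    inhibited = y0 * np.exp(-(k_decay + k_repair) * times)
    if noise_sd > 0:
        control = control + rng.normal(0, noise_sd, size=times.shape)
        inhibited = inhibited + rng.normal(0, noise_sd, size=times.shape)
    control = np.clip(control, 0.0, 1.0)
    inhibited = np.clip(inhibited, 0.0, 1.0)
    return (
        FluorescenceSeries(times, control, inhibitor=False),
        FluorescenceSeries(times, inhibited, inhibitor=True),
    )


# ---------------------------------------------------------------------------
# emission spectra

#: Emission maxima (nm) of phycoerythrin, phycocyanin and the phycobilisome
#: terminal acceptor used to position synthetic spectral peaks.
PE_PEAK_NM = 570.0
PC_PEAK_NM = 650.0
TA_PEAK_NM = 680.0


def generate_spectrum(
    peak_heights: tuple[float, float, float],
    widths: tuple[float, float, float] = (5.0, 5.0, 4.0),
    grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Fluorescence emission spectrum as a sum of Gaussian peaks.

    Peaks sit at the phycoerythrin (570 nm), phycocyanin (650 nm) and
    terminal-acceptor (680 nm) emission maxima on a 545-750 nm grid
    (excitation at 530 nm targets phycoerythrobilin).  Returns a DataFrame
    with columns wavelength_nm and intensity.
    """
    heights = np.asarray(peak_heights, dtype=float)
    if (heights < 0).any():
        raise ValueError("peak heights must be >= 0")
    if grid is None:
        grid = np.arange(545.0, 750.5, 0.5)
    grid = np.asarray(grid, dtype=float)
    centers = (PE_PEAK_NM, PC_PEAK_NM, TA_PEAK_NM)
    for c in centers:
        if not (grid.min() <= c <= grid.max()):
            raise ValueError(f"grid does not cover the {c} nm peak window")
    intensity = np.zeros_like(grid)
    for h, c, w in zip(heights, centers, widths):
        intensity += h * np.exp(-0.5 * ((grid - c) / w) ** 2)
    if noise_sd > 0:
        rng = child_rng(seed, "spectrum")
        intensity = np.clip(intensity + rng.normal(0, noise_sd, size=grid.shape), 0, None)
    return pd.DataFrame({"wavelength_nm": grid, "intensity": intensity})
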