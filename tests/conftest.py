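import numpy as np
import pandas as pd
import pytest

from stresscape import synthetic as syn


@pytest.fixture(scope="session")
def full_design():
    """The complete study design with shared T0 references (154 samples)."""
    return syn.generate_design()


@pytest.fixture(scope="session")
def two_group_design():
    """Minimal 3-vs-3 design: one shift condition, T0 reference and a 6 h
    stress point."""
    cfg = syn.DesignConfig(
        conditions=(syn.ConditionSpec("LL", "LLHL", (0, 6), 3),), share_t0=False
    )
    return syn.generate_design(cfg)


@pytest.fixture(scope="session")
def recovery_dataset(full_design):
    """A module-recovery simulation: 3 planted orthogonal latent-factor
    blocks (modules 1/2 mirrored, module 3 independent), low observation
    noise, no superimposed DE effects."""
    cfg = syn.recovery_truth_config()
    truth = syn.make_planted_truth(full_design, cfg, seed=11)
    counts = syn.generate_counts(full_design, truth, seed=11)
    return truth, counts


def nb_null_counts(rng, design, n_genes=2000, mean=None, dispersion=None, lfc=None):
    """Draw NB counts directly (independent of the package generator) for
    calibration tests: mean/dispersion per gene, optional planted log2FC
    applied to non-reference samples."""
    alpha = dispersion if dispersion is not None else np.exp(
        rng.uniform(np.log(0.01), np.log(0.5), n_genes)
    )
    base = mean if mean is not None else np.exp(rng.normal(5, 1, n_genes))
    base = np.broadcast_to(np.asarray(base, dtype=float), (n_genes,)).copy()
    sf = np.exp(rng.normal(0, 0.15, design.n_samples))
    stress = (design.table["time_h"].to_numpy() != 0).astype(float)
    mu = base[:, None] * sf[None, :]
    if lfc is not None:
        mu = mu * np.where(stress[None, :] > 0, 2.0 ** np.asarray(lfc)[:, None], 1.0)
    lam = rng.gamma(1.0 / alpha[:, None], alpha[:, None] * mu)
    counts = rng.poisson(lam)
    frame = pd.DataFrame(
        counts, index=[f"g{i}" for i in range(n_genes)], columns=design.sample_ids
    )
    return syn.CountMatrix(counts=frame, design=design)
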