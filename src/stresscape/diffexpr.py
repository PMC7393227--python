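"""Negative-binomial differential expression per (condition, time) contrast.

A documented re-specification of the classic count-based DE workflow:
median-of-ratios library-size normalisation, per-gene method-of-moments
dispersion estimation with shrinkage toward a mean-dispersion trend, a Wald
test on the log2 fold change of shrunken group means (delta-method standard
error from the NB variance), Benjamini-Hochberg adjustment, and the DE rule
padj <= 0.05 and |log2FC| >= 1.

Shift contrasts are tested against the acclimation's shared T0 reference;
light/dark-cycle contrasts against the 6 a.m. time point.  This module aims
at calibrated error control on data with the assumed NB structure, not at
output parity with any particular published engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from stresscape.synthetic import CountMatrix, ExperimentDesign

__all__ = [
    "DEResult",
    "size_factors",
    "normalize_counts",
    "estimate_dispersion",
    "wald_test",
    "bh_adjust",
    "call_de",
    "run_de",
    "de_summary",
]

DISPERSION_FLOOR = 1e-8
PSEUDOCOUNT = 0.5


@dataclass
class DEResult:
    """Per-gene, per-contrast DE statistics.

    ``table`` columns: gene_id, condition, time_h, log2fc, se, p, padj,
    status (up / down / ns).  BH adjustment is applied within each
    contrast's p-value vector.
    """

    table: pd.DataFrame
    alpha: float = 0.05
    lfc_min: float = 1.0

    def for_contrast(self, condition: str, time_h: float) -> pd.DataFrame:
        t = self.table
        return t[(t["condition"] == condition) & (np.isclose(t["time_h"], time_h))]

    def log2fc_matrix(self, condition: str) -> pd.DataFrame:
        """Gene x time log2FC matrix for one condition (cyanoron input)."""
        sub = self.table[self.table["condition"] == condition]
        return sub.pivot(index="gene_id", columns="time_h", values="log2fc")

    def de_genes(self, condition: str) -> set[str]:
        """Genes DE (up or down) at >= 1 time point of the condition."""
        sub = self.table[self.table["condition"] == condition]
        return set(sub.loc[sub["status"] != "ns", "gene_id"])


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors.

    For each gene expressed in every sample, the ratio of its count to its
    geometric mean across samples is formed; a sample's factor is the median
    of these ratios.  Genes with a zero anywhere are excluded from the
    factor computation only (they are still tested downstream).  No post-hoc
    renormalisation is applied.
    """
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("no gene has nonzero counts in all samples")
    log_mat = np.log(mat[all_nonzero])
    log_geo_mean = log_mat.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_mat - log_geo_mean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    factors = size_factors(counts) if factors is None else factors
    return counts / factors.to_numpy()[None, :]


def _replicate_groups(design: ExperimentDesign) -> list[list[str]]:
    groups = []
    for _, sub in design.table.groupby(["condition", "time_h"]):
        groups.append(sub["sample_id"].tolist())
    return groups


def estimate_dispersion(
    counts: CountMatrix,
    factors: pd.Series | None = None,
    shrink_weight: float = 0.5,
) -> pd.Series:
    """Per-gene NB dispersion alpha (variance mu + alpha mu^2).

    Method of moments on normalized counts pooled across replicate groups:
    per group, alpha_hat = (s^2 - mu) / mu^2; group estimates are combined
    with degrees-of-freedom weights, floored at zero.  The raw estimates are
    then shrunk toward a trend of dispersion versus mean expression
    (alpha(mu) = a0 + a1/mu, fitted across genes by least squares on the
    positive raw estimates) with weight ``shrink_weight``, stabilizing the
    noisy per-gene moments at the study's small replicate numbers.
    """
    norm = normalize_counts(counts.counts, factors)
    groups = [g for g in _replicate_groups(counts.design) if len(g) >= 2]
    if not groups:
        raise ValueError("no replicated group: cannot estimate dispersion")
    n_genes = norm.shape[0]
    num = np.zeros(n_genes)
    den = np.zeros(n_genes)
    mean_accum = np.zeros(n_genes)
    for g in groups:
        sub = norm[g].to_numpy()
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        w = len(g) - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (s2 - mu) / mu**2
        a = np.where(np.isfinite(a), a, 0.0)
        num += w * a
        den += w
        mean_accum += mu / len(groups)
    raw = np.maximum(num / den, 0.0)

    # trend alpha ~ a0 + a1 / mean, robust to all-zero genes
    mean_expr = np.maximum(mean_accum, 1e-8)
    usable = (raw > 0) & (mean_accum > 0)
    if usable.sum() >= 10:
        X = np.column_stack([np.ones(usable.sum()), 1.0 / mean_expr[usable]])
        coef, *_ = np.linalg.lstsq(X, raw[usable], rcond=None)
        trend = np.maximum(coef[0] + coef[1] / mean_expr, 0.0)
    else:
        trend = np.full(n_genes, raw[usable].mean() if usable.any() else 0.0)
    shrunk = (1 - shrink_weight) * raw + shrink_weight * trend
    shrunk = np.maximum(shrunk, DISPERSION_FLOOR)
    return pd.Series(shrunk, index=counts.counts.index, name="dispersion")


def wald_test(
    counts: CountMatrix,
    condition: str,
    time_h: float,
    dispersion: pd.Series | None = None,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Wald test of one (condition, time) group against its reference.

    log2FC is computed from the group means of normalized counts with a
    pseudocount of 0.5; its standard error comes from the delta method on
    the NB variance of the group means (var(mean) ~ (mu/s_bar + alpha mu^2)/n
    on the normalized scale, with s_bar the group's mean size factor).  The
    p-value is the two-sided normal tail of log2FC / SE.
    """
    design = counts.design
    stress_ids = design.samples_of(condition, time_h)
    ref_ids = design.reference_samples(condition)
    if not stress_ids or not ref_ids:
        raise ValueError(f"contrast ({condition}, {time_h}) has an empty group")
    factors = size_factors(counts.counts) if factors is None else factors
    if dispersion is None:
        dispersion = estimate_dispersion(counts, factors)
    norm = normalize_counts(counts.counts, factors)
    alpha = dispersion.to_numpy()

    out = {}
    for tag, ids in (("stress", stress_ids), ("ref", ref_ids)):
        sub = norm[ids].to_numpy()
        mu = sub.mean(axis=1)
        s_bar = float(factors[ids].mean())
        var_mean = (mu / s_bar + alpha * mu**2) / len(ids)
        out[tag] = (mu, var_mean)
    mu1, v1 = out["stress"]
    mu0, v0 = out["ref"]
    log2fc = np.log2(mu1 + PSEUDOCOUNT) - np.log2(mu0 + PSEUDOCOUNT)
    ln2sq = np.log(2.0) ** 2
    var_lfc = v1 / ((mu1 + PSEUDOCOUNT) ** 2 * ln2sq) + v0 / ((mu0 + PSEUDOCOUNT) ** 2 * ln2sq)
    se = np.sqrt(var_lfc)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.minimum(p, 1.0)
    return pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "condition": condition,
            "time_h": float(time_h),
            "log2fc": log2fc,
            "se": se,
            "p": p,
        }
    )


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values.

    padj_(i) = min over j >= i of min(1, m p_(j) / j) in ascending sort
    order, mapped back to the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted
    return out


def call_de(table: pd.DataFrame, alpha: float = 0.05, lfc_min: float = 1.0) -> pd.DataFrame:
    """Apply the DE rule: up iff padj <= alpha and log2FC >= lfc_min, down
    iff padj <= alpha and log2FC <= -lfc_min, else ns."""
    status = np.full(len(table), "ns", dtype=object)
    sig = table["padj"].to_numpy() <= alpha
    lfc = table["log2fc"].to_numpy()
    status[sig & (lfc >= lfc_min)] = "up"
    status[sig & (lfc <= -lfc_min)] = "down"
    table = table.copy()
    table["status"] = status
    return table


def run_de(
    counts: CountMatrix,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    contrasts: list[tuple[str, float]] | None = None,
) -> DEResult:
    """Run all contrasts of the design: normalize once, estimate dispersion
    once, then Wald-test each (condition, time) group against its reference
    and BH-adjust within each contrast."""
    factors = size_factors(counts.counts)
    dispersion = estimate_dispersion(counts, factors)
    contrasts = counts.design.contrasts() if contrasts is None else contrasts
    pieces = []
    for condition, t in contrasts:
        tab = wald_test(counts, condition, t, dispersion=dispersion, factors=factors)
        tab["padj"] = bh_adjust(tab["p"].to_numpy())
        pieces.append(call_de(tab, alpha=alpha, lfc_min=lfc_min))
    table = pd.concat(pieces, ignore_index=True)
    return DEResult(table=table, alpha=alpha, lfc_min=lfc_min)


def de_summary(result: DEResult) -> pd.DataFrame:
    """Up/down/ns counts per contrast (the stacked-bar summary of the DE
    landscape across conditions and times)."""
    rows = []
    for (cond, t), sub in result.table.groupby(["condition", "time_h"]):
        counts = sub["status"].value_counts()
        rows.append(
            dict(
                condition=cond,
                time_h=t,
                up=int(counts.get("up", 0)),
                down=int(counts.get("down", 0)),
                ns=int(counts.get("ns", 0)),
            )
        )
    return pd.DataFrame(rows).sort_values(["condition", "time_h"]).reset_index(drop=True)
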