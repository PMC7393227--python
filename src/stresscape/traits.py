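"""Module-trait integration: eigengene-trait correlation, PLS/VIP gene
filtering, and exclusive intersection-set classification of DE genes.

Module eigengenes are correlated with per-sample phenotypic traits
(photochemical yield, pigment and phycobilisome ratios, temperature, lipid
metrics, cell-density change) by pairwise-complete Pearson correlation with
a Student t p-value; significance at p <= 1e-3 after BH adjustment across
the module x trait grid.  Within each significant module-trait pair, genes
are ranked by their variable importance in projection (VIP) from a PLS1
regression of the trait on the module's member expression: VIP > 1 marks
genes contributing more than average to the association.  Finally, DE genes
are classified by the exact set of conditions in which they respond
(exclusive intersection semantics, as UpSet plots count them).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from stresscape.coexpression import ModuleAssignment
from stresscape.diffexpr import DEResult, bh_adjust

__all__ = [
    "ModuleTraitCorrelation",
    "VipResult",
    "UpsetMembership",
    "module_trait_corr",
    "pls_vip",
    "upset_classify",
]


@dataclass
class ModuleTraitCorrelation:
    """Long-format module x trait correlation table.

    Columns: module, trait, n (overlapping samples), r, p, padj,
    significant, testable.  Pairs with fewer than ``min_samples``
    overlapping observations are flagged untestable (r, p = NaN).
    """

    table: pd.DataFrame
    threshold: float
    adjusted: bool

    def matrix(self, column: str = "r") -> pd.DataFrame:
        return self.table.pivot(index="module", columns="trait", values=column)


@dataclass
class VipResult:
    """Per-gene VIP scores for one (module, trait) PLS model.

    ``table`` columns: gene_id, vip, vip_flag (VIP > 1).  mean(VIP^2) = 1 by
    construction, so VIP > 1 marks above-average contributors.
    """

    table: pd.DataFrame
    module: int
    trait: str
    n_components: int

    def vip_genes(self) -> list[str]:
        t = self.table
        return t.loc[t["vip_flag"], "gene_id"].tolist()


@dataclass
class UpsetMembership:
    """Exclusive condition-set membership of ever-DE genes.

    ``genes``: gene_id -> frozenset of conditions where the gene is DE at
    >= 1 time point (only genes with a non-empty set appear).
    ``counts``: per (exclusive set, module) gene counts, with sets encoded
    as '+'-joined sorted condition names.
    """

    genes: dict[str, frozenset[str]]
    counts: pd.DataFrame
    universe: tuple[str, ...]


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pairwise-complete Pearson r and Student-t p (n - 2 df)."""
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 4:
        return np.nan, np.nan, n
    xv, yv = x[ok], y[ok]
    if np.std(xv) == 0 or np.std(yv) == 0:
        return np.nan, np.nan, n
    r = float(np.corrcoef(xv, yv)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p), n


def module_trait_corr(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    threshold: float = 1e-3,
    adjust: bool = True,
) -> ModuleTraitCorrelation:
    """Pearson correlation of every module eigengene with every trait.

    ``eigengenes`` is module x sample, ``traits`` sample x trait; samples
    are aligned on the intersection of identifiers.  Missing trait values
    are dropped pairwise.  With ``adjust`` (default) the p-values are BH-
    corrected across the whole module x trait grid before thresholding at
    ``threshold``; raw-p thresholding is available with ``adjust=False``.
    """
    shared = [s for s in eigengenes.columns if s in traits.index]
    if len(shared) < 4:
        raise ValueError("fewer than 4 samples shared between eigengenes and traits")
    rows = []
    for module in eigengenes.index:
        me = eigengenes.loc[module, shared].to_numpy(dtype=float)
        for trait in traits.columns:
            tv = traits.loc[shared, trait].to_numpy(dtype=float)
            r, p, n = _pearson_with_p(me, tv)
            rows.append(dict(module=module, trait=trait, n=n, r=r, p=p,
                             testable=np.isfinite(p)))
    table = pd.DataFrame(rows)
    testable = table["testable"].to_numpy()
    padj = np.full(len(table), np.nan)
    if testable.any():
        padj[testable] = bh_adjust(table.loc[testable, "p"].to_numpy())
    table["padj"] = padj
    crit = table["padj"] if adjust else table["p"]
    table["significant"] = testable & (crit <= threshold)
    return ModuleTraitCorrelation(table=table, threshold=threshold, adjusted=adjust)


def pls_vip(
    module_expr: pd.DataFrame,
    trait: pd.Series,
    n_components: int = 2,
) -> VipResult:
    """VIP scores from a PLS1 regression of one trait on module expression.

    ``module_expr`` is genes x samples (the module's members); ``trait`` is
    indexed by sample.  Predictors are standardized; the model uses
    ``n_components`` latent components (capped at the available rank).  The
    VIP of gene g is

        VIP_g = sqrt( P * sum_c w_gc^2 SS_c / sum_c SS_c )

    with P the number of genes, w_c the unit-norm weight vectors and SS_c
    the trait variance explained by component c, so mean(VIP^2) = 1.
    """
    shared = [s for s in module_expr.columns if s in trait.index]
    tv = trait.loc[shared].to_numpy(dtype=float)
    ok = np.isfinite(tv)
    tv = tv[ok]
    X = module_expr[ [s for s, k in zip(shared, ok) if k] ].to_numpy(dtype=float).T
    n, p = X.shape
    if np.std(tv) == 0:
        raise ValueError("constant trait: PLS undefined")
    n_components = min(n_components, p, max(1, n - 1))
    if n < n_components + 2:
        raise ValueError(
            f"{n} samples with trait values cannot support {n_components} components"
        )
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    ys = tv - tv.mean()

    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xs, ys)
    W = pls.x_weights_  # p x c, unit-norm columns
    T = pls.x_scores_  # n x c
    q = pls.y_loadings_.ravel()  # c
    # trait variance explained by each component
    ss = (q**2) * np.sum(T**2, axis=0)
    if ss.sum() <= 0:
        raise ValueError("PLS explained no trait variance")
    w2 = (W / np.linalg.norm(W, axis=0, keepdims=True)) ** 2
    vip = np.sqrt(p * (w2 @ ss) / ss.sum())
    table = pd.DataFrame(
        {"gene_id": module_expr.index, "vip": vip, "vip_flag": vip > 1.0}
    )
    return VipResult(table=table, module=-1, trait=str(trait.name), n_components=n_components)


def upset_classify(
    de_results: DEResult,
    condition_universe: list[str],
    assignment: ModuleAssignment | None = None,
) -> UpsetMembership:
    """Classify ever-DE genes into exclusive condition sets.

    A condition "hits" a gene iff the gene is DE (up or down) at >= 1 time
    point of that condition.  A gene's exclusive set is exactly its hit set
    (standard UpSet semantics); the sets therefore partition the ever-DE
    genes, and counts are aggregated per (set, module).  DE direction does
    not affect membership.
    """
    if not condition_universe:
        raise ValueError("empty condition universe")
    present = set(de_results.table["condition"])
    missing = [c for c in condition_universe if c not in present]
    if missing:
        raise ValueError(f"DE results lack conditions: {missing}")
    hit_sets: dict[str, set[str]] = {}
    for cond in condition_universe:
        for g in de_results.de_genes(cond):
            hit_sets.setdefault(g, set()).add(cond)
    genes = {g: frozenset(s) for g, s in hit_sets.items()}

    labels = assignment.labels() if assignment is not None else None
    rows: dict[tuple[str, int], int] = {}
    for g, s in genes.items():
        key = "+".join(sorted(s))
        module = int(labels.get(g, 0)) if labels is not None else 0
        rows[(key, module)] = rows.get((key, module), 0) + 1
    counts = pd.DataFrame(
        [dict(set=k, module=m, n_genes=v) for (k, m), v in sorted(rows.items())]
    )
    if counts.empty:
        counts = pd.DataFrame(columns=["set", "module", "n_genes"])
    return UpsetMembership(genes=genes, counts=counts, universe=tuple(condition_universe))
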