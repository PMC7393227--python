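"""Signed weighted co-expression network, modules and eigengenes.

The network weights pairwise Pearson correlations of gene expression
profiles by a soft-threshold power (beta = 12 by default, chosen to optimize
the scale-free topology fit).  In signed mode the correlation is mapped to
[0, 1] via ((1 + r) / 2) ** beta so anti-correlated genes get near-zero
adjacency; unsigned mode uses |r| ** beta.  Modules are detected by
average-linkage hierarchical clustering of the topological-overlap
dissimilarity with a deterministic static tree cut; submodules by
re-clustering within each module at a finer cut.  Each module is summarized
by its eigengene, the first principal component of the standardized member
expression across samples.

Expression input is the variance-stabilizing transform
log2(normalized count + 1) of median-of-ratios normalized counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from stresscape.diffexpr import normalize_counts, size_factors
from stresscape.synthetic import CountMatrix

__all__ = [
    "AdjacencyMatrix",
    "ModuleAssignment",
    "ScaleFreeFit",
    "expression_matrix",
    "soft_adjacency",
    "scale_free_fit",
    "topological_overlap",
    "detect_modules",
    "module_eigengene",
]

GRAY = 0  # label of unassigned genes


@dataclass
class AdjacencyMatrix:
    """Symmetric gene x gene adjacency in [0, 1] with unit diagonal."""

    matrix: pd.DataFrame
    beta: float
    mode: str  # "signed" | "unsigned"

    def __post_init__(self) -> None:
        a = self.matrix.to_numpy()
        if a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if self.mode not in ("signed", "unsigned"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def gene_ids(self) -> list[str]:
        return self.matrix.index.tolist()


@dataclass
class ModuleAssignment:
    """Gene -> (module, submodule) labels plus module eigengenes.

    ``table`` columns: gene_id, module (int, 0 = gray/unassigned), submodule
    (string "module.k", empty for gray).  ``eigengenes``: module x sample,
    unit variance per module, sign-oriented so the mean correlation with
    member-gene profiles is >= 0.
    """

    table: pd.DataFrame
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)

    def labels(self) -> pd.Series:
        return self.table.set_index("gene_id")["module"]

    def members(self, module: int) -> list[str]:
        t = self.table
        return t.loc[t["module"] == module, "gene_id"].tolist()

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.table["module"]) - {GRAY})


@dataclass(frozen=True)
class ScaleFreeFit:
    """Goodness of scale-free topology: R^2 of the log-log regression of
    connectivity-bin frequency on mean connectivity, signed negative when
    the slope is positive (a scale-free network has a falling degree
    distribution)."""

    r2: float
    slope: float
    n_bins: int


def expression_matrix(counts: CountMatrix) -> pd.DataFrame:
    """log2(normalized count + 1), the network's expression input."""
    norm = normalize_counts(counts.counts, size_factors(counts.counts))
    return np.log2(norm + 1.0)


def soft_adjacency(
    expr: pd.DataFrame, beta: float = 12.0, mode: str = "signed"
) -> AdjacencyMatrix:
    """Soft-thresholded correlation adjacency.

    ``expr`` is genes x samples.  Zero-variance genes have undefined
    correlations and are excluded with a warning.
    """
    if mode not in ("signed", "unsigned"):
        raise ValueError(f"unknown mode {mode!r}")
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples to build a correlation network")
    values = expr.to_numpy(dtype=float)
    variances = values.var(axis=1)
    keep = variances > 0
    if not keep.all():
        dropped = [g for g, k in zip(expr.index, keep) if not k]
        warnings.warn(
            f"excluding {len(dropped)} zero-variance gene(s) from the network",
            stacklevel=2,
        )
        values = values[keep]
    gene_ids = [g for g, k in zip(expr.index, keep) if k]
    r = np.corrcoef(values)
    r = np.clip(r, -1.0, 1.0)
    if mode == "signed":
        a = ((1.0 + r) / 2.0) ** beta
    else:
        a = np.abs(r) ** beta
    np.fill_diagonal(a, 1.0)
    frame = pd.DataFrame(a, index=gene_ids, columns=gene_ids)
    return AdjacencyMatrix(matrix=frame, beta=beta, mode=mode)


def scale_free_fit(adjacency: AdjacencyMatrix, n_bins: int = 10) -> ScaleFreeFit:
    """Scale-free topology R^2 from binned connectivities.

    Whole-network connectivity k_i = sum_{j != i} a_ij; genes are binned
    into ``n_bins`` equal-width bins of k, and log10 frequency is regressed
    on log10 mean connectivity over non-empty bins.
    """
    a = adjacency.matrix.to_numpy()
    n = a.shape[0]
    if n < 20:
        raise ValueError(f"need >= 20 genes for a degree-distribution fit, got {n}")
    k = a.sum(axis=1) - np.diag(a)
    if np.ptp(k) == 0:
        raise ValueError("all connectivities identical: scale-free fit undefined")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_freq, log_k = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        mean_k = k[mask].mean()
        if mean_k <= 0:
            continue
        log_freq.append(np.log10(mask.sum() / n))
        log_k.append(np.log10(mean_k))
    if len(log_k) < 3:
        raise ValueError("too few populated connectivity bins for a fit")
    log_k = np.asarray(log_k)
    log_freq = np.asarray(log_freq)
    slope, intercept = np.polyfit(log_k, log_freq, 1)
    pred = intercept + slope * log_k
    ss_res = np.sum((log_freq - pred) ** 2)
    ss_tot = np.sum((log_freq - log_freq.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if slope > 0:
        r2 = -abs(r2)
    return ScaleFreeFit(r2=float(r2), slope=float(slope), n_bins=len(log_k))


def topological_overlap(adjacency: AdjacencyMatrix) -> pd.DataFrame:
    """Topological overlap matrix: shared-neighbour-weighted similarity.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    L_ij = sum_l a_il a_lj over l != i, j; diagonal set to 1.
    """
    a = adjacency.matrix.to_numpy().copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    L = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + a) / denom
    tom = np.where(np.isfinite(tom), tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=adjacency.matrix.index, columns=adjacency.matrix.columns)


def _static_cut(dissimilarity: np.ndarray, cut_height: float, min_size: int) -> np.ndarray:
    """Average-linkage clustering with a cut at ``cut_height`` of the
    maximal merge height; clusters below ``min_size`` become gray (0)."""
    n = dissimilarity.shape[0]
    if n < 2:
        return np.zeros(n, dtype=int)
    condensed = squareform(dissimilarity, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    max_h = link[:, 2].max()
    if max_h <= 0:
        return np.ones(n, dtype=int) if n >= min_size else np.zeros(n, dtype=int)
    raw = hierarchy.fcluster(link, t=cut_height * max_h, criterion="distance")
    labels = np.zeros(n, dtype=int)
    sizes = pd.Series(raw).value_counts()
    next_label = 1
    for cluster_id, size in sizes.items():  # by decreasing size, stable order
        if size < min_size:
            continue
        labels[raw == cluster_id] = next_label
        next_label += 1
    return labels


def _merge_close_modules(
    labels: np.ndarray,
    expr_values: np.ndarray,
    merge_cut_height: float,
) -> np.ndarray:
    """Iteratively merge module pairs whose eigengenes are closer than
    ``merge_cut_height`` in signed correlation dissimilarity 1 - r (signed,
    so anti-correlated mirror modules are maximally distant and never
    merge).  Deterministic: the closest pair merges first, ties broken by
    label order."""

    def eigengene_of(members: np.ndarray) -> np.ndarray:
        sub = expr_values[members]
        mean = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        z = (sub - mean) / sd
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        me = vt[0]
        if np.mean([np.corrcoef(me, row)[0, 1] for row in z]) < 0:
            me = -me  # orient toward members so signed comparison is meaningful
        return me

    labels = labels.copy()
    while True:
        modules = sorted(set(labels) - {GRAY})
        if len(modules) < 2:
            return labels
        eigs = {m: eigengene_of(np.flatnonzero(labels == m)) for m in modules}
        best: tuple[float, int, int] | None = None
        for i, m1 in enumerate(modules):
            for m2 in modules[i + 1 :]:
                diss = 1.0 - float(np.corrcoef(eigs[m1], eigs[m2])[0, 1])
                if best is None or diss < best[0]:
                    best = (diss, m1, m2)
        if best is None or best[0] >= merge_cut_height:
            return labels
        _, m1, m2 = best
        labels[labels == m2] = m1


def _kme_filter(
    labels: np.ndarray, expr_values: np.ndarray, kme_min: float, min_size: int
) -> np.ndarray:
    """Return to gray any member whose signed correlation with its module's
    eigengene (kME) is below ``kme_min``; modules shrinking under
    ``min_size`` dissolve entirely."""
    labels = labels.copy()
    for m in sorted(set(labels) - {GRAY}):
        members = np.flatnonzero(labels == m)
        sub = expr_values[members]
        mean = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        z = (sub - mean) / sd
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        me = vt[0]
        kme = np.array([np.corrcoef(row, me)[0, 1] for row in z])
        if kme.mean() < 0:
            me, kme = -me, -kme
        drop = members[kme < kme_min]
        labels[drop] = GRAY
        if (labels == m).sum() < min_size:
            labels[labels == m] = GRAY
    return labels


def detect_modules(
    adjacency: AdjacencyMatrix,
    min_size: int = 30,
    tree_cut_height: float = 0.9,
    merge_cut_height: float = 0.25,
    use_tom: bool = True,
    kme_min: float = 0.3,
    sub_cut_height: float = 0.7,
    sub_min_size: int = 10,
    expr: pd.DataFrame | None = None,
) -> ModuleAssignment:
    """Detect modules and submodules from an adjacency matrix.

    The clustering distance is topological-overlap dissimilarity (1 - TOM)
    by default, or plain 1 - adjacency with ``use_tom=False``.  The tree is
    cut statically at ``tree_cut_height`` of the maximal merge height;
    clusters smaller than ``min_size`` are merged into the gray module.
    When ``expr`` is given, modules whose eigengenes are closer than
    ``merge_cut_height`` in signed correlation dissimilarity are merged
    (close modules describe one underlying profile), genes whose module
    membership kME -- the correlation of the gene's profile with its
    module's eigengene -- falls below ``kme_min`` are returned to gray
    (the static cut attaches loosely connected genes that do not follow
    the module profile), and eigengenes are attached.  Submodules
    re-cluster each module's members at ``sub_cut_height`` of that
    subtree's height.  The procedure has no stochastic step, so output is
    a pure function of the input.
    """
    if use_tom:
        sim = topological_overlap(adjacency).to_numpy()
    else:
        sim = adjacency.matrix.to_numpy()
    diss = 1.0 - sim
    np.fill_diagonal(diss, 0.0)
    diss = (diss + diss.T) / 2.0  # enforce exact symmetry
    if np.ptp(diss) == 0 and diss.max() == 0:
        raise ValueError("degenerate adjacency: all genes identical")
    labels = _static_cut(diss, tree_cut_height, min_size)
    if expr is not None:
        expr_values = expr.loc[adjacency.gene_ids].to_numpy(dtype=float)
        if merge_cut_height > 0:
            labels = _merge_close_modules(labels, expr_values, merge_cut_height)
        if kme_min > 0:
            labels = _kme_filter(labels, expr_values, kme_min, min_size)
    # relabel 1..K by decreasing size for stable output
    sizes = pd.Series(labels[labels != GRAY]).value_counts()
    remap = {old: new for new, old in enumerate(sizes.index, start=1)}
    labels = np.array([remap.get(l, GRAY) for l in labels])

    gene_ids = adjacency.gene_ids
    sub_labels = np.array([""] * len(gene_ids), dtype=object)
    for module in sorted(set(labels) - {GRAY}):
        members = np.flatnonzero(labels == module)
        sub = _static_cut(diss[np.ix_(members, members)], sub_cut_height, sub_min_size)
        for local, gi in enumerate(members):
            sub_labels[gi] = f"{module}.{sub[local]}" if sub[local] > 0 else f"{module}.0"
    table = pd.DataFrame(
        {"gene_id": gene_ids, "module": labels, "submodule": sub_labels}
    )
    assignment = ModuleAssignment(table=table)
    if expr is not None:
        assignment.eigengenes = module_eigengene(expr, assignment)
    return assignment


def module_eigengene(expr: pd.DataFrame, assignment: ModuleAssignment) -> pd.DataFrame:
    """First principal component of each module's standardized expression.

    Returns a module x sample matrix; each eigengene has unit variance
    across samples and is oriented so that its mean correlation with the
    member genes' standardized profiles is non-negative.
    """
    eigengenes = {}
    for module in assignment.module_ids:
        members = assignment.members(module)
        if len(members) < 2:
            raise ValueError(f"module {module} has fewer than 2 genes")
        sub = expr.loc[members].to_numpy(dtype=float)
        mean = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        z = (sub - mean) / sd
        # PC1 across samples: leading right singular vector of the
        # standardized genes x samples matrix
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        me = vt[0]
        me = me / me.std(ddof=0)
        corrs = np.array([np.corrcoef(me, row)[0, 1] for row in z])
        if np.nanmean(corrs) < 0:
            me = -me
        eigengenes[module] = me
    frame = pd.DataFrame(eigengenes, index=expr.columns).T
    frame.index.name = "module"
    return frame
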