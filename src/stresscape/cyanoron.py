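"""Detection of "cyanorons": runs of genomically adjacent co-expressed genes.

A cyanoron is a maximal run of >= 4 adjacent genes (by genome order) that
(i) belong to the same co-expression module and (ii) respond concordantly
to a stress: at a given time point the run is *supported* iff every member
gene has log2FC above ``lfc`` (all induced) or every member below ``-lfc``
(all repressed), and the run is called iff at least half of the stress's
time points (ceil(T / 2)) support it.  Such runs track operon-like
transcriptional units: in cyanobacterial genomes, co-regulated genes of one
pathway (phycobilisome rods, ribosomal proteins, carboxysome shells, ATP
synthase) are frequently clustered.

Runs are maximal same-module stretches, so within one module labelling they
partition the genome and calls cannot overlap; sub-runs are not emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd

from stresscape.coexpression import GRAY, ModuleAssignment
from stresscape.synthetic import GeneAnnotation

__all__ = [
    "CyanoronCall",
    "find_cyanorons",
    "find_cyanorons_bruteforce",
    "cyanoron_null_rate",
    "calls_to_bed",
]


@dataclass(frozen=True)
class CyanoronCall:
    """One called run: inclusive genome-index interval, its genes and module,
    the stress it responds to, and the supporting time points with their
    concordant direction."""

    start_index: int
    end_index: int
    gene_ids: tuple[str, ...]
    module: int
    condition: str
    supporting_times: tuple[float, ...]
    directions: tuple[str, ...] = field(default=())

    @property
    def length(self) -> int:
        return self.end_index - self.start_index + 1


def _support(
    lfc_block: np.ndarray, times: list[float], lfc: float
) -> tuple[list[float], list[str]]:
    """Time points at which every gene of a run passes the threshold in the
    same direction.  ``lfc_block`` is genes x times."""
    supporting, directions = [], []
    for j, t in enumerate(times):
        col = lfc_block[:, j]
        if (col > lfc).all():
            supporting.append(t)
            directions.append("up")
        elif (col < -lfc).all():
            supporting.append(t)
            directions.append("down")
    return supporting, directions


def _aligned_lfc(
    annotation: GeneAnnotation, log2fc: pd.DataFrame
) -> tuple[np.ndarray, list[float]]:
    """log2FC matrix re-ordered to genome order; raises on missing genes."""
    missing = [g for g in annotation.gene_ids if g not in log2fc.index]
    if missing:
        raise ValueError(
            f"log2FC table lacks {len(missing)} annotated gene(s), e.g. {missing[:3]}"
        )
    times = sorted(float(t) for t in log2fc.columns)
    mat = log2fc.loc[annotation.gene_ids, times].to_numpy(dtype=float)
    if np.isnan(mat).any():
        raise ValueError("log2FC matrix contains missing values")
    return mat, times


def find_cyanorons(
    annotation: GeneAnnotation,
    assignment: ModuleAssignment,
    log2fc_by_stress: dict[str, pd.DataFrame],
    min_run: int = 4,
    lfc: float = 1.0,
) -> list[CyanoronCall]:
    """Call cyanorons for every stress.

    ``log2fc_by_stress`` maps stress name -> gene x time log2FC table.  For
    each stress, the genome is scanned for maximal runs of adjacent genes
    sharing a (non-gray) module label; a run of length >= ``min_run`` is
    emitted iff it is supported (all members concordantly beyond ``lfc``)
    at >= ceil(T/2) of the stress's T time points.
    """
    labels = assignment.labels()
    order = annotation.gene_ids
    module_arr = np.array([int(labels.get(g, GRAY)) for g in order])

    # maximal same-module runs partition the genome once per labelling
    runs: list[tuple[int, int, int]] = []
    start = 0
    for i in range(1, len(order) + 1):
        if i == len(order) or module_arr[i] != module_arr[start]:
            if module_arr[start] != GRAY and i - start >= min_run:
                runs.append((start, i - 1, int(module_arr[start])))
            start = i

    calls: list[CyanoronCall] = []
    for condition in sorted(log2fc_by_stress):
        mat, times = _aligned_lfc(annotation, log2fc_by_stress[condition])
        needed = ceil(len(times) / 2)
        for s, e, module in runs:
            supporting, directions = _support(mat[s : e + 1], times, lfc)
            if len(supporting) >= needed:
                calls.append(
                    CyanoronCall(
                        start_index=s,
                        end_index=e,
                        gene_ids=tuple(order[s : e + 1]),
                        module=module,
                        condition=condition,
                        supporting_times=tuple(supporting),
                        directions=tuple(directions),
                    )
                )
    return calls


def find_cyanorons_bruteforce(
    annotation: GeneAnnotation,
    assignment: ModuleAssignment,
    log2fc_by_stress: dict[str, pd.DataFrame],
    min_run: int = 4,
    lfc: float = 1.0,
) -> list[CyanoronCall]:
    """Independent oracle: enumerate every contiguous window of length >=
    ``min_run``, check the rule directly, and keep only windows that are
    maximal (not extendable in either direction within the same module)."""
    labels = assignment.labels()
    order = annotation.gene_ids
    module_arr = np.array([int(labels.get(g, GRAY)) for g in order])
    n = len(order)
    calls: list[CyanoronCall] = []
    for condition in sorted(log2fc_by_stress):
        mat, times = _aligned_lfc(annotation, log2fc_by_stress[condition])
        needed = ceil(len(times) / 2)
        for s in range(n):
            for e in range(s + min_run - 1, n):
                window = module_arr[s : e + 1]
                if window[0] == GRAY or not (window == window[0]).all():
                    continue
                # maximality within the module labelling
                if s > 0 and module_arr[s - 1] == window[0]:
                    continue
                if e < n - 1 and module_arr[e + 1] == window[0]:
                    continue
                supporting, directions = _support(mat[s : e + 1], times, lfc)
                if len(supporting) >= needed:
                    calls.append(
                        CyanoronCall(
                            start_index=s,
                            end_index=e,
                            gene_ids=tuple(order[s : e + 1]),
                            module=int(window[0]),
                            condition=condition,
                            supporting_times=tuple(supporting),
                            directions=tuple(directions),
                        )
                    )
    return calls


def cyanoron_null_rate(
    annotation: GeneAnnotation,
    assignment: ModuleAssignment,
    times: list[float],
    n_sims: int = 50,
    seed: int = 0,
    lfc_sd: float = 0.5,
    min_run: int = 4,
    lfc: float = 1.0,
) -> tuple[float, float]:
    """Expected false-call count under a null with no planted runs.

    Each simulation permutes the module labels along the genome and draws
    independent N(0, ``lfc_sd``) log2 fold changes, then counts calls.
    Returns (mean, sd) of calls per simulation, contextualizing counts on
    real data.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    order = annotation.gene_ids
    base_labels = assignment.labels().reindex(order).fillna(GRAY).to_numpy(dtype=int)
    counts = []
    for _ in range(n_sims):
        perm = rng.permutation(base_labels)
        table = pd.DataFrame({"gene_id": order, "module": perm, "submodule": ""})
        shuffled = ModuleAssignment(table=table)
        lfc_mat = pd.DataFrame(
            rng.normal(0.0, lfc_sd, size=(len(order), len(times))),
            index=order,
            columns=[float(t) for t in times],
        )
        calls = find_cyanorons(
            annotation, shuffled, {"null": lfc_mat}, min_run=min_run, lfc=lfc
        )
        counts.append(len(calls))
    counts = np.asarray(counts, dtype=float)
    return float(counts.mean()), float(counts.std(ddof=1)) if n_sims > 1 else 0.0


def calls_to_bed(calls: list[CyanoronCall], annotation: GeneAnnotation,
                 chrom: str = "chr") -> pd.DataFrame:
    """BED-style table of calls: 0-based half-open genomic intervals over the
    member genes' coordinates, name = stress:module:length, score =
    supporting-time-point count."""
    t = annotation.table.set_index("gene_id")
    rows = []
    for c in calls:
        start = int(t.loc[c.gene_ids[0], "start"]) - 1  # GFF3 1-based -> BED 0-based
        end = int(t.loc[c.gene_ids[-1], "end"])  # inclusive -> half-open
        rows.append(
            dict(
                chrom=chrom,
                start=start,
                end=end,
                name=f"{c.condition}:{c.module}:{c.length}",
                score=len(c.supporting_times),
                strand=".",
            )
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
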