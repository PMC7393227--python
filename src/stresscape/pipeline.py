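"""End-to-end orchestration: simulate -> de -> network -> integrate ->
cyanorons -> physiology, with a manifest that makes a run reproducible
bit-for-bit from its config and master seed.

The master seed is split deterministically into labelled per-stage streams
(see :func:`stresscape.synthetic.child_rng`); per-stage seeds and the SHA-256
hash of every output file are recorded in the manifest.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from stresscape import __version__, coexpression, cyanoron, diffexpr, physiology
from stresscape import io as sio
from stresscape import synthetic, traits

logger = logging.getLogger("stresscape")

__all__ = ["PipelineConfig", "run_all", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    """All pipeline knobs with their defaults.

    The defaults are the study conditions: the full sampling design with a
    shared T0 per acclimation (154 samples), 2,634 genes, DE rule
    padj <= 0.05 and |log2FC| >= 1, signed network at beta = 12, static tree
    cut at 0.9 of tree height with minimum module size 30 and
    eigengene merge height 0.25, 2 PLS components, module-trait
    significance 1e-3 (BH-adjusted), cyanoron minimum run 4 at |log2FC| > 1.
    """

    seed: int = 0
    # simulate
    n_genes: int = 2634
    share_t0: bool = True
    trait_noise_sd: float = 0.3
    de_fraction: float = 0.1
    effect_lfc: float = 2.0
    n_cyanorons: int = 5
    # de
    alpha: float = 0.05
    lfc_min: float = 1.0
    # network
    beta: float = 12.0
    mode: str = "signed"
    tree_cut_height: float = 0.9
    merge_cut_height: float = 0.25
    min_size: int = 30
    use_tom: bool = True
    # integrate
    n_components: int = 2
    trait_p_threshold: float = 1e-3
    adjust_trait_p: bool = True
    # cyanorons
    min_run: int = 4
    cyanoron_lfc: float = 1.0
    # physiology (kinetics demo parameters: per-hour rates)
    k_decay: float = 0.2
    k_repair: float = 0.3
    kinetics_noise_sd: float = 0.02
    # stage toggles
    stages: tuple[str, ...] = (
        "simulate", "de", "network", "integrate", "cyanorons", "physiology",
    )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)


def load_config(path: Path | str) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(path: Path | str, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    rng = synthetic.child_rng(master, f"stage_{stage}")
    return int(rng.integers(0, 2**31 - 1))


def run_all(config: PipelineConfig, outdir: Path | str) -> dict:
    """Run the toggled stages and return the manifest.

    Each stage writes its outputs under ``outdir`` and the manifest records
    parameters, per-stage seeds and output hashes.  A stage failure raises
    with the stage name attached.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stage_seeds": {},
        "outputs": {},
    }
    state: dict = {}
    for stage in config.stages:
        seed = _stage_seed(config.seed, stage)
        manifest["stage_seeds"][stage] = seed
        logger.info("stage %s (seed %d)", stage, seed)
        runner = _STAGES.get(stage)
        if runner is None:
            raise ValueError(f"unknown stage: {stage}")
        try:
            runner(config, outdir, seed, state)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    for f in sorted(outdir.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    sio.write_json(outdir / "manifest.json", manifest)
    return manifest


# ---------------------------------------------------------------------------
# stage-input resolution: each stage takes its inputs from the in-memory
# state when an earlier stage produced them, else re-reads them from outdir
# so stages can be run individually


def _need_file(outdir: Path, name: str) -> Path:
    path = outdir / name
    if not path.exists():
        raise FileNotFoundError(
            f"required input {path} is missing (run the producing stage or "
            "enable simulation)"
        )
    return path


def _ensure(state: dict, key: str, outdir: Path) -> object:
    if key in state:
        return state[key]
    if key == "design":
        state["design"] = sio.read_design(_need_file(outdir, "design.csv"))
    elif key == "counts":
        design = _ensure(state, "design", outdir)
        state["counts"] = sio.read_counts(_need_file(outdir, "counts.tsv"), design)
    elif key == "trait_table":
        t = sio.read_table(_need_file(outdir, "traits.csv"), sep=",")
        state["trait_table"] = t.set_index("sample_id")
    elif key == "annotation":
        state["annotation"] = sio.read_gff3(_need_file(outdir, "annotation.gff3"))
    elif key == "expr":
        counts = _ensure(state, "counts", outdir)
        state["expr"] = coexpression.expression_matrix(counts)
    elif key == "assignment":
        table = sio.read_table(_need_file(outdir, "modules.tsv"))
        eg = sio.read_table(_need_file(outdir, "eigengenes.csv"), sep=",")
        eg = eg.set_index("module")
        state["assignment"] = coexpression.ModuleAssignment(table=table, eigengenes=eg)
    elif key == "de":
        table = sio.read_table(_need_file(outdir, "de_results.tsv"))
        state["de"] = diffexpr.DEResult(table=table)
    else:
        raise KeyError(f"no loader for pipeline input {key!r}")
    return state[key]


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(config: PipelineConfig, outdir: Path, seed: int, state: dict) -> None:
    design = synthetic.generate_design(synthetic.default_design_config(config.share_t0))
    truth_cfg = synthetic.TruthConfig(
        n_genes=config.n_genes,
        de_fraction=config.de_fraction,
        effect_lfc=config.effect_lfc,
        n_cyanorons=config.n_cyanorons,
    )
    truth = synthetic.make_planted_truth(design, truth_cfg, seed=seed)
    counts = synthetic.generate_counts(design, truth, seed=seed)
    trait_table = synthetic.generate_traits(design, truth, config.trait_noise_sd, seed=seed)
    annotation = synthetic.generate_annotation(config.n_genes, truth, seed=seed)

    sio.write_design(outdir / "design.csv", design, seed=seed)
    sio.write_counts(outdir / "counts.tsv", counts, seed=seed,
                     params={"n_genes": config.n_genes})
    sio.write_table(outdir / "traits.csv", trait_table.reset_index(), stage="simulate",
                    seed=seed, sep=",")
    sio.write_gff3(outdir / "annotation.gff3", annotation)
    sio.write_operons(outdir / "operons.tsv", annotation)
    sio.write_json(
        outdir / "truth.json",
        {
            "module_labels": truth.module_labels,
            "cyanoron_truth": [list(c) for c in truth.cyanoron_truth],
            "gene_ids": truth.gene_ids,
            "trait_loadings": {
                t: truth.trait_loadings.loc[t].to_dict()
                for t in truth.trait_loadings.index
            },
        },
    )
    state.update(design=design, truth=truth, counts=counts,
                 trait_table=trait_table, annotation=annotation)


def _stage_de(config: PipelineConfig, outdir: Path, seed: int, state: dict) -> None:
    counts: synthetic.CountMatrix = _ensure(state, "counts", outdir)
    result = diffexpr.run_de(counts, alpha=config.alpha, lfc_min=config.lfc_min)
    sio.write_table(outdir / "de_results.tsv", result.table, stage="de",
                    params={"alpha": config.alpha, "lfc_min": config.lfc_min})
    sio.write_table(outdir / "de_summary.tsv", diffexpr.de_summary(result), stage="de")
    state["de"] = result


def _stage_network(config: PipelineConfig, outdir: Path, seed: int, state: dict) -> None:
    counts: synthetic.CountMatrix = _ensure(state, "counts", outdir)
    expr = coexpression.expression_matrix(counts)
    adjacency = coexpression.soft_adjacency(expr, beta=config.beta, mode=config.mode)
    fit = coexpression.scale_free_fit(adjacency)
    assignment = coexpression.detect_modules(
        adjacency,
        min_size=config.min_size,
        tree_cut_height=config.tree_cut_height,
        merge_cut_height=config.merge_cut_height,
        use_tom=config.use_tom,
        expr=expr.loc[adjacency.gene_ids],
    )
    sio.write_table(outdir / "modules.tsv", assignment.table, stage="network",
                    params={"beta": config.beta, "mode": config.mode,
                            "tree_cut_height": config.tree_cut_height, "min_size": config.min_size})
    eg = assignment.eigengenes.copy()
    eg.insert(0, "module", eg.index)
    sio.write_table(outdir / "eigengenes.csv", eg, stage="network", sep=",")
    sio.write_json(outdir / "scale_free_fit.json",
                   {"r2": fit.r2, "slope": fit.slope, "n_bins": fit.n_bins,
                    "beta": config.beta, "mode": config.mode})
    state.update(expr=expr, assignment=assignment)


def _stage_integrate(config: PipelineConfig, outdir: Path, seed: int, state: dict) -> None:
    assignment: coexpression.ModuleAssignment = _ensure(state, "assignment", outdir)
    trait_table: pd.DataFrame = _ensure(state, "trait_table", outdir)
    corr = traits.module_trait_corr(
        assignment.eigengenes, trait_table,
        threshold=config.trait_p_threshold, adjust=config.adjust_trait_p,
    )
    sio.write_table(outdir / "module_trait_corr.csv", corr.table, stage="integrate",
                    sep=",", params={"threshold": config.trait_p_threshold})
    expr: pd.DataFrame = _ensure(state, "expr", outdir)
    vip_rows = []
    for _, row in corr.table[corr.table["significant"]].iterrows():
        module = int(row["module"])
        members = assignment.members(module)
        if len(members) < 2:
            continue
        vip = traits.pls_vip(expr.loc[members], trait_table[row["trait"]],
                             n_components=config.n_components)
        t = vip.table.copy()
        t.insert(0, "module", module)
        t.insert(1, "trait", row["trait"])
        vip_rows.append(t)
    vip_table = (pd.concat(vip_rows, ignore_index=True) if vip_rows
                 else pd.DataFrame(columns=["module", "trait", "gene_id", "vip", "vip_flag"]))
    sio.write_table(outdir / "vip.tsv", vip_table, stage="integrate",
                    params={"n_components": config.n_components})

    de: diffexpr.DEResult = _ensure(state, "de", outdir)
    universe = [c for c in _ensure(state, "design", outdir).condition_names() if not c.startswith("LD")]
    upset = traits.upset_classify(de, universe, assignment)
    sio.write_table(outdir / "upset_counts.tsv", upset.counts, stage="integrate")
    state.update(corr=corr, upset=upset, vip_table=vip_table)


def _stage_cyanorons(config: PipelineConfig, outdir: Path, seed: int, state: dict) -> None:
    de: diffexpr.DEResult = _ensure(state, "de", outdir)
    annotation: synthetic.GeneAnnotation = _ensure(state, "annotation", outdir)
    assignment: coexpression.ModuleAssignment = _ensure(state, "assignment", outdir)
    universe = [c for c in _ensure(state, "design", outdir).condition_names() if not c.startswith("LD")]
    lfc_by_stress = {c: de.log2fc_matrix(c) for c in universe}
    calls = cyanoron.find_cyanorons(
        annotation, assignment, lfc_by_stress,
        min_run=config.min_run, lfc=config.cyanoron_lfc,
    )
    detail = pd.DataFrame(
        [
            dict(
                condition=c.condition, module=c.module, start_index=c.start_index,
                end_index=c.end_index, length=c.length,
                n_supporting=len(c.supporting_times),
                supporting_times=",".join(f"{t:g}" for t in c.supporting_times),
                gene_ids=",".join(c.gene_ids),
            )
            for c in calls
        ],
        columns=["condition", "module", "start_index", "end_index", "length",
                 "n_supporting", "supporting_times", "gene_ids"],
    )
    sio.write_table(outdir / "cyanorons.tsv", detail, stage="cyanorons",
                    params={"min_run": config.min_run, "lfc": config.cyanoron_lfc})
    bed = cyanoron.calls_to_bed(calls, annotation)
    sio.write_bed(outdir / "cyanorons.bed", bed,
                  params={"min_run": config.min_run, "lfc": config.cyanoron_lfc})
    state["cyanorons"] = calls


def _stage_physiology(config: PipelineConfig, outdir: Path, seed: int, state: dict) -> None:
    control, inhibited = synthetic.generate_kinetics(
        config.k_decay, config.k_repair, noise_sd=config.kinetics_noise_sd, seed=seed,
    )
    rate = physiology.repair_rate_short(control, inhibited)
    kin = pd.DataFrame(
        {
            "time_h": np.concatenate([control.times, inhibited.times]),
            "value": np.concatenate([control.values, inhibited.values]),
            "inhibitor": [False] * len(control.times) + [True] * len(inhibited.times),
        }
    )
    sio.write_table(outdir / "kinetics.csv", kin, stage="physiology", sep=",",
                    seed=seed, params={"k_decay": config.k_decay, "k_repair": config.k_repair})
    spectrum = synthetic.generate_spectrum((2.0, 1.0, 1.0))
    ratios = physiology.spectrum_ratios(
        spectrum["wavelength_nm"].to_numpy(), spectrum["intensity"].to_numpy()
    )
    sio.write_table(outdir / "spectrum.csv", spectrum, stage="physiology", sep=",")
    sio.write_json(
        outdir / "physiology.json",
        {
            "repair_rate_per_h": rate.rate,
            "k_control_per_h": rate.k_control,
            "k_inhibited_per_h": rate.k_inhibited,
            "pe_pc": ratios.pe_pc,
            "pc_ta": ratios.pc_ta,
        },
    )
    state["repair_rate"] = rate


_STAGES = {
    "simulate": _stage_simulate,
    "de": _stage_de,
    "network": _stage_network,
    "integrate": _stage_integrate,
    "cyanorons": _stage_cyanorons,
    "physiology": _stage_physiology,
}
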