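"""Readers and writers for the pipeline's on-disk formats.

All tabular outputs are plain TSV/CSV with a leading ``#`` comment header
recording the producing stage, its parameters and the seed, so every file
is self-describing and a rerun can be reproduced bit-identically.  Gene
annotations use GFF3 (1-based inclusive coordinates); cyanoron intervals
are exported as BED (0-based half-open).  Malformed input rows are rejected
with their line numbers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from stresscape.synthetic import (
    ConditionSpec,
    CountMatrix,
    DesignConfig,
    ExperimentDesign,
    GeneAnnotation,
)

__all__ = [
    "write_counts",
    "read_counts",
    "write_design",
    "read_design",
    "write_table",
    "read_table",
    "write_gff3",
    "read_gff3",
    "write_operons",
    "read_operons",
    "write_bed",
    "write_json",
    "read_json",
]


def _header(stage: str, params: dict | None = None, seed: int | None = None) -> str:
    parts = [f"# stresscape stage={stage}"]
    if seed is not None:
        parts.append(f"# seed={seed}")
    if params:
        kv = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
        parts.append(f"# params: {kv}")
    return "\n".join(parts) + "\n"


def write_counts(path: Path | str, counts: CountMatrix, stage: str = "simulate",
                 params: dict | None = None, seed: int | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(stage, params, seed))
        counts.counts.to_csv(fh, sep="\t")


def read_counts(path: Path | str, design: ExperimentDesign) -> CountMatrix:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    # locate data line numbers for error reporting
    with open(path) as fh:
        lines = fh.readlines()
    data_lines = [i + 1 for i, ln in enumerate(lines) if not ln.startswith("#")]
    for row_pos, (gene, row) in enumerate(frame.iterrows()):
        vals = row.to_numpy()
        bad = ~np.isfinite(vals.astype(float)) | (vals.astype(float) < 0) \
            | (vals.astype(float) != np.floor(vals.astype(float)))
        if bad.any():
            lineno = data_lines[row_pos + 1] if row_pos + 1 < len(data_lines) else -1
            raise ValueError(
                f"{path}:{lineno}: invalid count for gene {gene!r} "
                f"(counts must be non-negative integers)"
            )
    return CountMatrix(counts=frame.astype(np.int64), design=design)


def write_design(path: Path | str, design: ExperimentDesign, stage: str = "simulate",
                 seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(stage, {"share_t0": design.config.share_t0}, seed))
        design.table.to_csv(fh, index=False)


def read_design(path: Path | str, config: DesignConfig | None = None) -> ExperimentDesign:
    table = pd.read_csv(path, comment="#")
    required = {"sample_id", "acclimation", "condition", "time_h", "replicate"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: design lacks columns {sorted(missing)}")
    if config is None:
        # reconstruct condition specs from the table (reference time = 0 for
        # shifts, the earliest daytime point for diel conditions)
        specs = []
        for cond, sub in table.groupby("condition", sort=True):
            if cond.endswith("_T0"):
                continue
            times = tuple(sorted(sub["time_h"].unique()))
            ref = 0.0 if 0.0 in times or f"{sub['acclimation'].iloc[0]}_T0" in set(table["condition"]) else times[0]
            if cond.startswith("LD"):
                ref = 6.0
            specs.append(
                ConditionSpec(
                    acclimation=sub["acclimation"].iloc[0],
                    condition=cond,
                    times=times,
                    n_replicates=int(sub["replicate"].max()),
                    reference_time=ref,
                )
            )
        has_shared = table["condition"].str.endswith("_T0").any()
        config = DesignConfig(conditions=tuple(specs), share_t0=has_shared)
    return ExperimentDesign(table=table, config=config)


def write_table(path: Path | str, frame: pd.DataFrame, stage: str,
                params: dict | None = None, seed: int | None = None,
                sep: str = "\t", index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_header(stage, params, seed))
        frame.to_csv(fh, sep=sep, index=index)


def read_table(path: Path | str, sep: str = "\t", index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", index_col=index_col)


def write_gff3(path: Path | str, annotation: GeneAnnotation,
               seqid: str = "chromosome", source: str = "stresscape") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, row in annotation.table.iterrows():
            attrs = f"ID={row['gene_id']};genome_index={row['genome_index']}"
            fh.write(
                f"{seqid}\t{source}\tgene\t{row['start']}\t{row['end']}\t.\t"
                f"{row['strand']}\t.\t{attrs}\n"
            )


def read_gff3(path: Path | str) -> GeneAnnotation:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
            seqid, source, ftype, start, end, score, strand, phase, attrs = fields
            if ftype != "gene":
                continue
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if "ID" not in attr_map:
                raise ValueError(f"{path}:{lineno}: gene record lacks an ID attribute")
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start_i < 1 or end_i < start_i:
                raise ValueError(f"{path}:{lineno}: invalid 1-based coordinates")
            rows.append(
                dict(
                    gene_id=attr_map["ID"],
                    start=start_i,
                    end=end_i,
                    strand=strand,
                    genome_index=int(attr_map.get("genome_index", len(rows))),
                )
            )
    table = pd.DataFrame(rows).sort_values("genome_index").reset_index(drop=True)
    return GeneAnnotation(table=table)


def write_operons(path: Path | str, annotation: GeneAnnotation) -> None:
    with open(path, "w") as fh:
        fh.write("# stresscape stage=simulate\noperon_id\tgene_ids\n")
        for i, members in enumerate(annotation.operons):
            fh.write(f"operon_{i:04d}\t{','.join(members)}\n")


def read_operons(path: Path | str) -> list[list[str]]:
    frame = pd.read_csv(path, sep="\t", comment="#")
    return [str(s).split(",") for s in frame["gene_ids"]]


def write_bed(path: Path | str, bed: pd.DataFrame, stage: str = "cyanorons",
              params: dict | None = None, seed: int | None = None) -> None:
    bad = bed[bed["start"] >= bed["end"]]
    if not bad.empty:
        raise ValueError(f"BED intervals must satisfy start < end; offending: {bad.iloc[0].tolist()}")
    with open(path, "w") as fh:
        fh.write(_header(stage, params, seed))
        bed.to_csv(fh, sep="\t", index=False, header=False)


def write_json(path: Path | str, obj: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_json(path: Path | str) -> dict:
    with open(path) as fh:
        return json.load(fh)
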