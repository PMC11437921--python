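"""Plain-text readers and writers for the pipeline's tables.

All tabular artifacts are tab-separated: sample metadata (sample_id,
diagnosis, sex, age, role, batch, channel), abundance matrices (first
column protein_id, one column per sample, missing = empty field),
simulation truth, QC metrics, ROC/classifier reports.  Marker sets use
the GMT convention: one set per line, ``name<TAB>description<TAB>id...``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Sequence, Union

import numpy as np
import pandas as pd

from .datatypes import AbundanceMatrix, SampleMeta, SimulationTruth

PathLike = Union[str, Path]

DESIGN_COLUMNS = ["sample_id", "diagnosis", "sex", "age", "role", "batch", "channel"]


def write_design(design: Sequence[SampleMeta], path: PathLike) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "diagnosis": s.diagnosis or "",
            "sex": s.sex or "",
            "age": "" if s.age is None else f"{s.age:.2f}",
            "role": s.role,
            "batch": "" if s.batch is None else s.batch,
            "channel": s.channel or "",
        }
        for s in design
    ]
    pd.DataFrame(rows, columns=DESIGN_COLUMNS).to_csv(path, sep="\t", index=False)


def read_design(path: PathLike) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        out.append(
            SampleMeta(
                sample_id=r["sample_id"],
                role=r["role"],
                diagnosis=r["diagnosis"] or None,
                sex=r["sex"] or None,
                age=float(r["age"]) if r["age"] else None,
                batch=int(r["batch"]) if r["batch"] else None,
                channel=r["channel"] or None,
            )
        )
    return out


def write_matrix(matrix: AbundanceMatrix, path: PathLike) -> None:
    matrix.data.rename_axis("protein_id").to_csv(path, sep="\t", na_rep="")


def read_matrix(path: PathLike, scale: str = "raw") -> AbundanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col="protein_id")
    return AbundanceMatrix(df, scale)


def write_truth(truth: SimulationTruth, path: PathLike) -> None:
    df = pd.DataFrame(
        {
            "protein_id": truth.protein_ids,
            "effect": truth.effect,
            "baseline": truth.baseline,
            "sigma": truth.sigma,
        }
    ).set_index("protein_id")
    shifts = truth.batch_shift.copy()
    shifts.columns = [f"batch_shift_{b}" for b in shifts.columns]
    df.join(shifts).to_csv(path, sep="\t")


def read_gmt(path: PathLike) -> Dict[str, list[str]]:
    """Read marker sets from a GMT file (name, description, members)."""
    sets: Dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need name, description, >=1 id): {line[:60]!r}")
        sets[fields[0]] = [f for f in fields[2:] if f]
    return sets


def write_gmt(sets: Dict[str, Sequence[str]], path: PathLike, description: str = "") -> None:
    lines = [
        "\t".join([name, description, *members]) for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
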