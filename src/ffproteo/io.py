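"""TSV round-trip for abundance matrices and sample metadata.

The matrix file has a ``row_id`` column followed by one column per protein;
the metadata file has ``row_id, patient_id, group, fluid_id, repeat_index``.
Floats are written with 17 significant digits so a round trip is exact.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .cohort import GROUPS, AbundanceDataset, SampleRecord
from .errors import ParseError

FLOAT_FORMAT = "%.17g"

METADATA_COLUMNS = ["row_id", "patient_id", "group", "fluid_id", "repeat_index"]


def row_ids(dataset: AbundanceDataset) -> list[str]:
    return [f"{r.fluid_id}_r{r.repeat_index}" for r in dataset.rows]


def write_dataset(dataset: AbundanceDataset, matrix_path: str | os.PathLike,
                  metadata_path: str | os.PathLike) -> None:
    dataset.validate()
    ids = row_ids(dataset)
    matrix = pd.DataFrame(dataset.intensities, columns=dataset.protein_ids)
    matrix.insert(0, "row_id", ids)
    matrix.to_csv(matrix_path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    meta = pd.DataFrame(
        {
            "row_id": ids,
            "patient_id": [r.patient_id for r in dataset.rows],
            "group": [r.group for r in dataset.rows],
            "fluid_id": [r.fluid_id for r in dataset.rows],
            "repeat_index": [r.repeat_index for r in dataset.rows],
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_dataset(matrix_path: str | os.PathLike,
                 metadata_path: str | os.PathLike) -> AbundanceDataset:
    try:
        matrix = pd.read_csv(matrix_path, sep="\t", dtype={"row_id": str},
                             float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot parse matrix file: {exc}") from exc
    if matrix.columns[0] != "row_id":
        raise ParseError("matrix header must start with 'row_id'")
    protein_ids = list(matrix.columns[1:])
    if len(set(protein_ids)) != len(protein_ids):
        raise ParseError("duplicate protein ids in matrix header")
    values = matrix.iloc[:, 1:].to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = np.argmax(~np.all(matrix.iloc[:, 1:].map(
            lambda v: isinstance(v, (int, float))).to_numpy(), axis=1))
        raise ParseError("non-numeric intensity", row=int(bad) + 1)
    bad_rows = np.where(~np.all(np.isfinite(values) & (values > 0), axis=1))[0]
    if bad_rows.size:
        raise ParseError("intensity must be finite and strictly positive",
                         row=int(bad_rows[0]) + 1)

    try:
        meta = pd.read_csv(metadata_path, sep="\t",
                           dtype={"row_id": str, "patient_id": str,
                                  "group": str, "fluid_id": str})
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"cannot parse metadata file: {exc}") from exc
    if list(meta.columns) != METADATA_COLUMNS:
        raise ParseError(f"metadata header must be {METADATA_COLUMNS}")
    if len(meta) != len(matrix):
        raise ParseError("metadata and matrix row counts differ")

    meta = meta.set_index("row_id")
    records: list[SampleRecord] = []
    for i, rid in enumerate(matrix["row_id"]):
        if rid not in meta.index:
            raise ParseError(f"matrix row_id {rid!r} missing from metadata",
                             row=i + 1)
        m = meta.loc[rid]
        if m["group"] not in GROUPS:
            raise ParseError(f"unknown group {m['group']!r}", row=i + 1)
        records.append(SampleRecord(str(m["patient_id"]), str(m["group"]),
                                    str(m["fluid_id"]), int(m["repeat_index"])))

    dataset = AbundanceDataset(intensities=values.astype(float), rows=records,
                               protein_ids=protein_ids)
    try:
        dataset.validate()
    except ValueError as exc:
        raise ParseError(str(exc)) from exc
    return dataset
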