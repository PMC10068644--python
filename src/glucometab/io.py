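"""Delimited-text I/O for every pipeline artifact.

All tabular files are TSV with a header row; the pedigree uses PED-like
whitespace-delimited text (see :mod:`glucometab.pedigree`); QC and truth
reports have JSON twins.  Floats are written with a fixed ``%.10g`` format
so repeated runs at the same seed are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .qc import ANNOTATION_COLUMNS, MetaboliteMatrix

FLOAT_FORMAT = "%.10g"


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_matrix(m: MetaboliteMatrix, values_path, annotations_path=None) -> None:
    write_table(m.values, values_path)
    if annotations_path is not None:
        write_table(m.annotations, annotations_path)


def read_matrix(values_path, annotations_path) -> MetaboliteMatrix:
    values = read_table(values_path)
    annotations = read_table(annotations_path)
    missing = set(ANNOTATION_COLUMNS) - set(annotations.columns)
    if missing:
        raise ValueError(f"annotation file missing columns {sorted(missing)}")
    return MetaboliteMatrix(values, annotations)


def write_fsigt_long(records, path) -> None:
    """Long-format FSIGT TSV: individual_id, time_min, glucose_mg_dl, insulin_uU_ml."""
    rows = []
    for rec in records:
        for t, g, i in zip(rec.times, rec.glucose, rec.insulin):
            rows.append((rec.individual_id, t, g, i))
    df = pd.DataFrame(rows, columns=["individual_id", "time_min",
                                     "glucose_mg_dl", "insulin_uU_ml"])
    write_table(df, path, index=False)


def read_fsigt_long(path):
    from .minimal_model import FSIGTRecord

    df = pd.read_csv(path, sep="\t")
    records = []
    for iid, grp in df.groupby("individual_id", sort=True):
        grp = grp.sort_values("time_min")
        records.append(FSIGTRecord(str(iid), grp["time_min"].to_numpy(),
                                   grp["glucose_mg_dl"].to_numpy(),
                                   grp["insulin_uU_ml"].to_numpy()))
    return records
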