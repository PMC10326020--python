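"""Tab-delimited readers and writers for omics matrices and sidecar tables.

Formats (all UTF-8, LF, tab-separated, full ``repr`` float precision):

* matrix TSV — header ``analyte_id<TAB>cond1<TAB>...``, one analyte per row;
* metadata TSV — ``analyte_id<TAB>gene_symbol<TAB>assay``;
* condition-group TSV — ``condition_id<TAB>group``.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import OmicsMatrix


def read_metadata(meta_path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    expected = ["analyte_id", "gene_symbol", "assay"]
    if list(meta.columns) != expected:
        raise ValueError(f"metadata header must be {expected}, got {list(meta.columns)}")
    if meta["analyte_id"].duplicated().any():
        dup = meta.loc[meta["analyte_id"].duplicated(), "analyte_id"].iloc[0]
        raise ValueError(f"duplicate analyte id in metadata: {dup!r}")
    return meta.set_index("analyte_id")


def read_condition_groups(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["condition_id", "group"]:
        raise ValueError("condition-group file needs header condition_id<TAB>group")
    return dict(zip(df["condition_id"], df["group"]))


def read_matrix(
    path: str | Path,
    meta_path: str | Path,
    groups_path: str | Path | None = None,
) -> OmicsMatrix:
    """Read a matrix TSV plus its analyte-metadata table.

    Rejects duplicate ids, non-numeric cells, missing values and analytes
    absent from the metadata (the pipeline requires complete continuous
    matrices).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    ids = [str(i) for i in df.index]
    dups = pd.Index(ids).duplicated()
    if dups.any():
        raise ValueError(f"duplicate analyte id in {path}: {ids[int(np.argmax(dups))]!r}")
    try:
        values = df.astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if np.isnan(values).any():
        r, c = map(int, np.argwhere(np.isnan(values))[0])
        raise ValueError(
            f"missing value in {path} at analyte {ids[r]!r}, condition {df.columns[c]!r}"
        )
    meta = read_metadata(meta_path)
    missing = [a for a in ids if a not in meta.index]
    if missing:
        raise ValueError(f"analytes missing from metadata: {missing}")
    groups = read_condition_groups(groups_path) if groups_path else {}
    groups = {c: g for c, g in groups.items() if c in set(map(str, df.columns))}
    return OmicsMatrix(
        values=values,
        analyte_ids=ids,
        analyte_meta=meta,
        condition_ids=[str(c) for c in df.columns],
        condition_groups=groups,
    )


def write_matrix(
    m: OmicsMatrix,
    path: str | Path,
    meta_path: str | Path | None = None,
    groups_path: str | Path | None = None,
) -> None:
    """Write a matrix (and optionally metadata / groups) with repr-round-trip
    float precision so that ``read_matrix`` reproduces the values bit-exactly."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["analyte_id", *m.condition_ids])
        for aid, row in zip(m.analyte_ids, m.values):
            w.writerow([aid, *(repr(float(v)) for v in row)])
    if meta_path is not None:
        meta = m.analyte_meta.loc[m.analyte_ids, ["gene_symbol", "assay"]]
        with open(meta_path, "w", encoding="utf-8", newline="\n") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["analyte_id", "gene_symbol", "assay"])
            for aid, (gene, assay) in zip(meta.index, meta.to_numpy()):
                w.writerow([aid, gene, assay])
    if groups_path is not None:
        with open(groups_path, "w", encoding="utf-8", newline="\n") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["condition_id", "group"])
            for cid in m.condition_ids:
                if cid in m.condition_groups:
                    w.writerow([cid, m.condition_groups[cid]])
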