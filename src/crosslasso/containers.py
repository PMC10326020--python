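"""Core in-memory containers for paired-omics association inference.

An :class:`OmicsMatrix` holds one omics layer as an analytes x conditions
matrix together with analyte metadata (gene symbol, assay) and optional
condition-group labels (e.g. the ligand applied, or a tumor subtype).
A :class:`PairedInput` couples a response layer ``left`` (Y) with a
predictor layer ``right`` (X) sharing the same ordered condition columns,
the arrangement under which the model Y = beta . X + delta is fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

VALID_ASSAYS = ("rppa", "rnaseq", "atacseq", "other")


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class OmicsMatrix:
    """One omics layer: R analytes (rows) x C conditions (columns).

    Parameters
    ----------
    values
        Real matrix of shape (R, C); must be finite (the pipeline consumes
        continuous, complete matrices — no missing values).
    analyte_ids
        R unique analyte identifiers, in row order.
    analyte_meta
        DataFrame indexed by analyte id with columns ``gene_symbol`` and
        ``assay`` (one of ``rppa``, ``rnaseq``, ``atacseq``, ``other``).
        Must cover every analyte in the matrix.
    condition_ids
        C unique condition identifiers, in column order.
    condition_groups
        Optional map condition id -> group label (ligand, subtype ...).
        Grouping is metadata; condition ids are opaque strings.
    """

    values: np.ndarray
    analyte_ids: list[str]
    analyte_meta: pd.DataFrame
    condition_ids: list[str]
    condition_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.analyte_ids = [str(a) for a in self.analyte_ids]
        self.condition_ids = [str(c) for c in self.condition_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        r, c = self.values.shape
        if len(self.analyte_ids) != r:
            raise ValueError(f"{len(self.analyte_ids)} analyte ids for {r} rows")
        if len(self.condition_ids) != c:
            raise ValueError(f"{len(self.condition_ids)} condition ids for {c} columns")
        _check_unique(self.analyte_ids, "analyte")
        _check_unique(self.condition_ids, "condition")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite; missing values are not supported")
        meta = self.analyte_meta
        if not {"gene_symbol", "assay"}.issubset(meta.columns):
            raise ValueError("analyte_meta needs columns gene_symbol, assay")
        missing = [a for a in self.analyte_ids if a not in meta.index]
        if missing:
            raise ValueError(f"analytes missing from metadata: {missing[:5]}")
        bad = set(meta.loc[self.analyte_ids, "assay"]) - set(VALID_ASSAYS)
        if bad:
            raise ValueError(f"unknown assay labels: {sorted(bad)}")
        unknown_groups = set(self.condition_groups) - set(self.condition_ids)
        if unknown_groups:
            raise ValueError(f"condition_groups refer to unknown conditions: {sorted(unknown_groups)}")

    @property
    def n_analytes(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    def gene_symbol(self, analyte_id: str) -> str:
        return str(self.analyte_meta.loc[analyte_id, "gene_symbol"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.analyte_ids, columns=self.condition_ids)

    def select_rows(self, row_idx: np.ndarray) -> "OmicsMatrix":
        """Row subset preserving order; metadata restricted to survivors."""
        ids = [self.analyte_ids[i] for i in row_idx]
        return replace(
            self,
            values=self.values[row_idx],
            analyte_ids=ids,
            analyte_meta=self.analyte_meta.loc[ids],
        )

    def select_columns(self, col_idx: np.ndarray) -> "OmicsMatrix":
        ids = [self.condition_ids[i] for i in col_idx]
        return replace(
            self,
            values=self.values[:, col_idx],
            condition_ids=ids,
            condition_groups={c: g for c, g in self.condition_groups.items() if c in ids},
        )


@dataclass
class PairedInput:
    """Response layer Y (``left``) and predictor layer X (``right``) with
    identical, identically ordered condition columns."""

    left: OmicsMatrix
    right: OmicsMatrix

    def __post_init__(self) -> None:
        if self.left.condition_ids != self.right.condition_ids:
            raise ValueError(
                "left and right matrices must share the same ordered condition columns"
            )

    @property
    def n_conditions(self) -> int:
        return self.left.n_conditions

    @property
    def condition_ids(self) -> list[str]:
        return self.left.condition_ids

    def groups(self) -> dict[str, str]:
        merged = dict(self.right.condition_groups)
        merged.update(self.left.condition_groups)
        return merged


@dataclass
class PreprocessReport:
    """Bookkeeping for a row-filtering step."""

    n_input_rows: int
    n_retained_rows: int
    variance_fraction: float | None = None
    dropped_zero_rows: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_retained_rows > self.n_input_rows:
            raise ValueError("cannot retain more rows than supplied")


@dataclass(frozen=True)
class StratificationRule:
    """Marker-based sample selection rule, e.g. log2(HER2+1) > 7."""

    marker: str
    transform: str = "identity"  # identity | log2p1
    op: str = ">"  # < | >
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.transform not in ("identity", "log2p1"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.op not in ("<", ">"):
            raise ValueError(f"unknown op {self.op!r}")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def apply(self, values: np.ndarray) -> np.ndarray:
        x = np.log2(values + 1.0) if self.transform == "log2p1" else values
        return x > self.threshold if self.op == ">" else x < self.threshold
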