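"""Preprocessing: variance filtering, centering/normalization, group dropping
and marker-based sample stratification.

The centering pipeline follows the fixed order column-center -> row-center ->
row L2-normalize. It removes magnitude bias so the regression sees only the
shape of each analyte's profile across conditions, and drives the per-row
offsets of the linear model toward zero. The three steps do not commute; the
order is part of the method.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from .containers import OmicsMatrix, PairedInput, PreprocessReport, StratificationRule

#: rows whose post-centering norm falls below this are degenerate (constant
#: offsets only) and are dropped rather than normalized into NaN
ZERO_ROW_TOL = 1e-10

#: default retained fractions per assay, reflecting the relative feature
#: counts of the source platforms (targeted proteomics has far fewer features)
DEFAULT_VARIANCE_FRACTIONS = {"rppa": 0.20, "rnaseq": 0.10, "atacseq": 0.10, "other": 0.10}


def variance_filter(m: OmicsMatrix, fraction: float) -> tuple[OmicsMatrix, PreprocessReport]:
    """Retain the ``ceil(fraction * R)`` rows of highest raw sample variance.

    Variance is the unbiased sample variance of the raw row across columns.
    Ties are broken by input order (stable), and the surviving rows keep
    their original relative order.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    r = m.n_analytes
    if r < 1:
        raise ValueError("matrix has no rows")
    n_keep = math.ceil(fraction * r)
    var = m.values.var(axis=1, ddof=1) if m.n_conditions > 1 else np.zeros(r)
    # stable mergesort on negated variance keeps input order among ties
    order = np.argsort(-var, kind="stable")[:n_keep]
    keep = np.sort(order)
    report = PreprocessReport(
        n_input_rows=r, n_retained_rows=n_keep, variance_fraction=fraction
    )
    return m.select_rows(keep), report


def _center_normalize(m: OmicsMatrix) -> tuple[OmicsMatrix, list[str]]:
    v = m.values.astype(float)
    v = v - v.mean(axis=0, keepdims=True)  # column-center
    v = v - v.mean(axis=1, keepdims=True)  # row-center
    norms = np.linalg.norm(v, axis=1)
    alive = norms >= ZERO_ROW_TOL
    dropped = [a for a, ok in zip(m.analyte_ids, alive) if not ok]
    v = v[alive] / norms[alive, None]
    out = replace(
        m,
        values=v,
        analyte_ids=[a for a, ok in zip(m.analyte_ids, alive) if ok],
        analyte_meta=m.analyte_meta.loc[[a for a, ok in zip(m.analyte_ids, alive) if ok]],
    )
    return out, dropped


def preprocess(
    pair: PairedInput, return_report: bool = False
) -> PairedInput | tuple[PairedInput, dict[str, list[str]]]:
    """Column-center, row-center, then row-normalize both matrices.

    Rows that become numerically zero after the two centerings (constant
    rows up to a column offset) are dropped and listed in the report under
    ``left`` / ``right`` instead of producing NaN. Every surviving row of
    the output has zero mean and unit Euclidean norm.
    """
    if pair.n_conditions < 2:
        raise ValueError("preprocessing needs at least 2 condition columns")
    left, dropped_l = _center_normalize(pair.left)
    right, dropped_r = _center_normalize(pair.right)
    out = PairedInput(left=left, right=right)
    if return_report:
        return out, {"left": dropped_l, "right": dropped_r}
    return out


def drop_condition_group(pair: PairedInput, group: str) -> PairedInput:
    """Remove all condition columns labeled ``group`` from both matrices."""
    groups = pair.groups()
    labels = [groups.get(c) for c in pair.condition_ids]
    if group not in labels:
        raise ValueError(f"unknown condition group {group!r}")
    keep = np.array([i for i, g in enumerate(labels) if g != group])
    if keep.size < 2:
        raise ValueError(f"dropping group {group!r} leaves fewer than 2 columns")
    return PairedInput(
        left=pair.left.select_columns(keep), right=pair.right.select_columns(keep)
    )


def stratify_samples(m: OmicsMatrix, rules: list[StratificationRule]) -> list[str]:
    """Condition (sample) ids satisfying every rule (all-of conjunction).

    Rules address marker rows by analyte id and compare the optionally
    transformed value against a threshold, e.g. receptor-status calls like
    log2(HER2+1) > 7 for amplified samples or the triple-low rule for
    receptor-negative ones. An empty rule list selects all samples.
    """
    mask = np.ones(m.n_conditions, dtype=bool)
    index = {a: i for i, a in enumerate(m.analyte_ids)}
    for rule in rules:
        if rule.marker not in index:
            raise ValueError(f"stratification marker {rule.marker!r} is not a row of the matrix")
        mask &= rule.apply(m.values[index[rule.marker]])
    return [c for c, ok in zip(m.condition_ids, mask) if ok]
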