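"""Leave-one-group-out (LOGO) runs and context-specific association lists.

Holding out one condition group (a ligand, a subtype), refitting the
ensemble on the remaining columns and comparing the resulting robust
coefficient matrix with the FULL-data one isolates the associations whose
inference depends on that group's data: the symmetric difference of the two
supports. Entries present in both runs — even with different coefficients —
are not group-dependent and are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .containers import PairedInput
from .ensemble import (
    LassoFitConfig,
    RobustLassoCoefficientMatrix,
    build_rlcm,
    run_lasso_module,
)
from .preprocess import drop_condition_group, preprocess


@dataclass
class AssociationList:
    """Flat context-specific association records for one held-out group.

    ``records`` columns: y_analyte, x_analyte, weight (the coefficient from
    the run in which the entry exists), layer_pair, origin
    (``full_only`` | ``logo_only``).
    """

    records: pd.DataFrame
    group: str
    layer_pair: str = "generic"

    def __post_init__(self) -> None:
        key = self.records[["y_analyte", "x_analyte"]].apply(tuple, axis=1) if len(self.records) else pd.Series(dtype=object)
        if key.duplicated().any():
            raise ValueError("duplicate (y_analyte, x_analyte) association records")
        if len(self.records) and (self.records["weight"] == 0).any():
            raise ValueError("association weights must be non-zero")

    def __len__(self) -> int:
        return len(self.records)

    def support(self, origin: str | None = None) -> set[tuple[str, str]]:
        df = self.records
        if origin is not None:
            df = df[df["origin"] == origin]
        return set(zip(df["y_analyte"], df["x_analyte"]))

    def write_tsv(self, path: str | Path) -> None:
        cols = ["y_analyte", "x_analyte", "weight", "layer_pair", "origin", "group"]
        df = self.records.copy()
        df["group"] = self.group
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\t".join(cols) + "\n")
            for rec in df[cols].itertuples(index=False):
                fh.write(
                    f"{rec.y_analyte}\t{rec.x_analyte}\t{repr(float(rec.weight))}\t"
                    f"{rec.layer_pair}\t{rec.origin}\t{rec.group}\n"
                )


def run_full(
    pair: PairedInput,
    cfg: LassoFitConfig | None = None,
    n_replicates: int = 100,
    master_seed: int = 0,
    min_frequency: float = 0.5,
    provenance: str = "generic",
    n_jobs: int = 1,
) -> RobustLassoCoefficientMatrix:
    """FULL-data run: preprocess the raw pair and build its RLCM (the
    baseline every LOGO comparison refers to)."""
    prepped = preprocess(pair)
    ens = run_lasso_module(prepped, cfg, n_replicates, master_seed, n_jobs=n_jobs)
    return build_rlcm(ens, min_frequency, provenance=provenance)


def run_logo(
    pair: PairedInput,
    group: str,
    cfg: LassoFitConfig | None = None,
    n_replicates: int = 100,
    master_seed: int = 0,
    min_frequency: float = 0.5,
    provenance: str = "generic",
    n_jobs: int = 1,
) -> RobustLassoCoefficientMatrix:
    """Hold out one condition group and rerun the lasso module.

    The group's columns are removed from the *raw* pair first, then the
    remaining columns are re-centered and normalized (centering depends on
    which columns are present), then the ensemble runs as usual.
    """
    reduced = drop_condition_group(pair, group)
    prepped = preprocess(reduced)
    ens = run_lasso_module(prepped, cfg, n_replicates, master_seed, n_jobs=n_jobs)
    return build_rlcm(ens, min_frequency, provenance=provenance, held_out=group)


def ligand_specific_associations(
    full: RobustLassoCoefficientMatrix,
    logo: RobustLassoCoefficientMatrix,
) -> AssociationList:
    """Symmetric difference of FULL and LOGO supports.

    Each record is tagged ``full_only`` or ``logo_only`` and weighted by the
    coefficient of the run it came from. Entries present in both supports
    are group-independent and excluded regardless of coefficient value.
    """
    if full.y_ids != logo.y_ids or full.x_ids != logo.x_ids:
        raise ValueError("FULL and LOGO matrices come from different analyte universes")
    fsup = full.support()
    lsup = logo.support()
    fmap = dict(zip(zip(full.entries["y_analyte"], full.entries["x_analyte"]), full.entries["coefficient"]))
    lmap = dict(zip(zip(logo.entries["y_analyte"], logo.entries["x_analyte"]), logo.entries["coefficient"]))
    rows = []
    for y, x in sorted(fsup - lsup):
        rows.append((y, x, fmap[(y, x)], full.provenance, "full_only"))
    for y, x in sorted(lsup - fsup):
        rows.append((y, x, lmap[(y, x)], full.provenance, "logo_only"))
    records = pd.DataFrame(
        rows, columns=["y_analyte", "x_analyte", "weight", "layer_pair", "origin"]
    )
    return AssociationList(
        records=records, group=logo.held_out or "", layer_pair=full.provenance
    )
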