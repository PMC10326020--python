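"""Shuffled-input null model and known-interaction benchmarking.

Permuting each analyte row independently across conditions destroys the
cross-feature alignment the lasso exploits while preserving every row's
marginal distribution. Running the same ensemble on shuffled inputs should
therefore select far fewer coefficients than on real inputs; the contrast is
quantified by the two-sample Kolmogorov-Smirnov distance between the
per-replicate support-size distributions, and by the overlap of the
inferred associations with a literature gene-pair list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace as _dc_replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import OmicsMatrix, PairedInput
from .ensemble import (
    LassoFitConfig,
    RobustLassoCoefficientMatrix,
    build_rlcm,
    run_lasso_module,
)
from .preprocess import preprocess, variance_filter


@dataclass
class InteractionList:
    """Unordered known-interaction gene pairs with a source tag."""

    pairs: set[frozenset]
    source: str = "literature"

    def __post_init__(self) -> None:
        for p in self.pairs:
            if len(p) == 1:
                raise ValueError(f"self-pair {set(p)} not allowed (flag separately if needed)")
            if len(p) != 2:
                raise ValueError("pairs must contain exactly two gene symbols")

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        return frozenset(pair) in self.pairs

    @classmethod
    def read_tsv(cls, path: str | Path) -> "InteractionList":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"geneA", "geneB"}.issubset(df.columns):
            raise ValueError("interaction list needs columns geneA, geneB (and optional source)")
        pairs = {frozenset((a, b)) for a, b in zip(df["geneA"], df["geneB"])}
        source = str(df["source"].iloc[0]) if "source" in df.columns and len(df) else "literature"
        return cls(pairs=pairs, source=source)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("geneA\tgeneB\tsource\n")
            for p in sorted(self.pairs, key=lambda q: sorted(q)):
                a, b = sorted(p)
                fh.write(f"{a}\t{b}\t{self.source}\n")


@dataclass
class NullComparison:
    """Real-vs-shuffled ensemble contrast."""

    real_counts: np.ndarray
    shuffled_counts: np.ndarray
    ks_statistic: float
    p_value: float
    real_rlcm_size: int
    shuffled_rlcm_size: int
    mode: str

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mode": self.mode,
            "ks_statistic": self.ks_statistic,
            "p_value": self.p_value,
            "real_rlcm_size": self.real_rlcm_size,
            "shuffled_rlcm_size": self.shuffled_rlcm_size,
            "real_counts": [int(c) for c in self.real_counts],
            "shuffled_counts": [int(c) for c in self.shuffled_counts],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def shuffle_matrix(
    m: OmicsMatrix, seed: int = 0, granularity: str = "within_row"
) -> OmicsMatrix:
    """Permute matrix values, deterministic under ``seed``.

    ``within_row`` (default) permutes each row independently across columns —
    it breaks cross-analyte alignment but leaves every row's value multiset
    (hence its variance) untouched, so a variance filter retains exactly the
    rows it would have retained anyway. ``within_column`` and
    ``whole_matrix`` are provided for sensitivity checks.
    """
    rng = np.random.default_rng(seed)
    v = m.values.copy()
    if granularity == "within_row":
        for i in range(v.shape[0]):
            v[i] = v[i, rng.permutation(v.shape[1])]
    elif granularity == "within_column":
        for j in range(v.shape[1]):
            v[:, j] = v[rng.permutation(v.shape[0]), j]
    elif granularity == "whole_matrix":
        flat = v.ravel()
        v = flat[rng.permutation(flat.size)].reshape(v.shape)
    else:
        raise ValueError(f"unknown granularity {granularity!r}")
    return _dc_replace(m, values=v)


def count_known_overlap(
    rlcm: RobustLassoCoefficientMatrix,
    known: InteractionList,
    meta: pd.DataFrame,
    per_entry: bool = True,
) -> int:
    """Number of retained entries whose unordered gene pair is in ``known``.

    ``per_entry=True`` counts every matrix entry hitting a known pair
    (several analyte pairs may map to the same gene pair and each counts);
    ``per_entry=False`` counts distinct gene pairs instead.
    """
    hits = 0
    seen: set[frozenset] = set()
    for rec in rlcm.entries.itertuples(index=False):
        gy = str(meta.loc[rec.y_analyte, "gene_symbol"])
        gx = str(meta.loc[rec.x_analyte, "gene_symbol"])
        pair = frozenset((gy, gx))
        if len(pair) == 2 and pair in known.pairs:
            if per_entry:
                hits += 1
            else:
                seen.add(pair)
    return hits if per_entry else len(seen)


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov distance D = sup |ECDF_a - ECDF_b| and
    its asymptotic p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def null_experiment(
    pair: PairedInput,
    cfg: LassoFitConfig | None = None,
    n_replicates: int = 100,
    mode: str = "post_selection",
    master_seed: int = 0,
    min_frequency: float = 0.5,
    variance_fractions: tuple[float, float] | None = None,
    n_jobs: int = 1,
) -> NullComparison:
    """Run matched real and shuffled ensembles and compare support sizes.

    ``post_selection`` shuffles the matrices as given (already filtered);
    ``pre_selection`` shuffles first and then applies the variance filter
    with ``variance_fractions = (left_fraction, right_fraction)`` to both
    arms. Both arms share the lasso settings and master seed so the only
    difference is the shuffling.
    """
    if mode not in ("pre_selection", "post_selection"):
        raise ValueError(f"unknown mode {mode!r}")
    cfg = cfg or LassoFitConfig()
    shuf_left = shuffle_matrix(pair.left, seed=np.random.SeedSequence([master_seed, 0]).generate_state(1)[0] % 2**31)
    shuf_right = shuffle_matrix(pair.right, seed=np.random.SeedSequence([master_seed, 1]).generate_state(1)[0] % 2**31)
    real_pair = pair
    shuf_pair = PairedInput(left=shuf_left, right=shuf_right)
    if mode == "pre_selection":
        if variance_fractions is None:
            raise ValueError("pre_selection mode needs variance_fractions")
        fl, fr = variance_fractions
        real_pair = PairedInput(
            left=variance_filter(real_pair.left, fl)[0],
            right=variance_filter(real_pair.right, fr)[0],
        )
        shuf_pair = PairedInput(
            left=variance_filter(shuf_pair.left, fl)[0],
            right=variance_filter(shuf_pair.right, fr)[0],
        )
    real_ens = run_lasso_module(preprocess(real_pair), cfg, n_replicates, master_seed, n_jobs=n_jobs)
    shuf_ens = run_lasso_module(preprocess(shuf_pair), cfg, n_replicates, master_seed, n_jobs=n_jobs)
    d, p = ks_two_sample(real_ens.replicate_nonzero_counts, shuf_ens.replicate_nonzero_counts)
    return NullComparison(
        real_counts=real_ens.replicate_nonzero_counts,
        shuffled_counts=shuf_ens.replicate_nonzero_counts,
        ks_statistic=d,
        p_value=p,
        real_rlcm_size=len(build_rlcm(real_ens, min_frequency)),
        shuffled_rlcm_size=len(build_rlcm(shuf_ens, min_frequency)),
        mode=mode,
    )
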