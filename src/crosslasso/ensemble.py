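"""Replicated cross-validated lasso and the robust coefficient matrix.

For a preprocessed pair (Y, X) of analytes x conditions matrices the model is

    Y = beta . X + delta,

fit one Y-row at a time by minimizing

    sum_i [ y_i - sum_j beta_j X_ji - delta ]^2 + lambda * sum_j |beta_j|,

with lambda chosen per row by K-fold cross-validation over a geometric
lambda path (minimum mean squared prediction error). Refitting the whole
coefficient matrix many times with re-randomized CV fold assignments gives
an ensemble; entries that are non-zero in at least ``min_frequency`` of the
replicates form the Robust Lasso Coefficient Matrix (RLCM), valued by the
mean of their non-zero occurrences. This is a stability-style selection:
support frequency across randomized refits is the retention statistic.

Note the penalized objective above carries no 1/(2C) factor; scikit-learn's
coordinate descent minimizes (1/(2n))RSS + alpha*l1, so alpha = lambda/(2n)
internally and all reported lambdas are in the unscaled convention.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lasso_path

from .containers import PairedInput

#: coefficients below this magnitude are treated as exact zeros
SPARSITY_EPS = 1e-10


@dataclass
class LassoFitConfig:
    """Controls for the per-row cross-validated lasso fit.

    ``lambda_grid=None`` builds a glmnet-style geometric path per row, from
    the smallest lambda that zeroes every coefficient down by a factor
    ``lambda_min_ratio`` (default: 0.01 when conditions < predictors, else
    1e-4) over ``n_lambdas`` points. An explicit grid (possibly a single
    fixed lambda) bypasses the automatic path.
    """

    n_folds: int = 4
    lambda_grid: tuple[float, ...] | None = None
    n_lambdas: int = 100
    lambda_min_ratio: float | None = None
    max_iter: int = 1000
    tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.lambda_grid is not None:
            grid = tuple(float(v) for v in self.lambda_grid)
            if any(v < 0 for v in grid):
                raise ValueError("lambda values must be >= 0")
            self.lambda_grid = grid


def _path_betas(D: np.ndarray, y: np.ndarray, lambdas: np.ndarray, cfg: LassoFitConfig) -> np.ndarray:
    """Lasso solutions (p, L) on centered data for a descending lambda grid.

    Inputs are promoted to the memory layout coordinate descent wants
    (Fortran-ordered float64 design) so per-call validation can be skipped;
    at the small per-row problem sizes this pipeline runs in, validation
    would otherwise dominate the solve time.
    """
    n = D.shape[0]
    alphas = lambdas / (2.0 * n)
    Df = np.asfortranarray(D, dtype=np.float64)
    yc = np.ascontiguousarray(y, dtype=np.float64)
    with warnings.catch_warnings():
        # the path tail (tiny lambda on near-noise rows) may stop at max_iter;
        # those grid points lose the CV comparison anyway
        warnings.simplefilter("ignore", ConvergenceWarning)
        if np.any(alphas <= 0):
            coefs = np.empty((D.shape[1], len(lambdas)))
            for i, a in enumerate(alphas):
                if a <= 0:
                    coefs[:, i] = np.linalg.lstsq(Df, yc, rcond=None)[0]
                else:
                    _, c, _ = lasso_path(
                        Df, yc, alphas=[a], max_iter=cfg.max_iter, tol=cfg.tol,
                        precompute=False, check_input=False,
                    )
                    coefs[:, i] = c[:, 0]
        else:
            _, coefs, _ = lasso_path(
                Df, yc, alphas=alphas, max_iter=cfg.max_iter, tol=cfg.tol,
                precompute=False, check_input=False,
            )
    return coefs


def fit_lasso_row(
    y: np.ndarray,
    X: np.ndarray,
    cfg: LassoFitConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[np.ndarray, float, float]:
    """CV-lasso for one response row.

    Parameters
    ----------
    y
        Response vector, length C (one row of the Y matrix).
    X
        Predictor matrix, R_X rows (analytes) x C columns (conditions);
        conditions are the observations.
    cfg
        Fit controls; defaults to :class:`LassoFitConfig`.
    seed
        Seeds the CV fold assignment, the only stochastic element.

    Returns
    -------
    (beta_row, delta, lambda_selected) — the exactly-sparse coefficient
    vector, the offset, and the selected penalty (unscaled convention).
    """
    cfg = cfg or LassoFitConfig()
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(X))):
        raise ValueError("inputs must be finite")
    D = X.T  # conditions x predictors
    n, p = D.shape
    if y.shape != (n,):
        raise ValueError(f"y has length {y.shape}, expected {n}")
    if cfg.n_folds > n:
        raise ValueError(f"n_folds={cfg.n_folds} exceeds the {n} available conditions")

    xm = D.mean(axis=0)
    ym = float(y.mean())
    Dc = D - xm
    yc = y - ym

    if cfg.lambda_grid is not None:
        grid = np.sort(np.asarray(cfg.lambda_grid, dtype=float))[::-1]
    else:
        lam_max = 2.0 * float(np.abs(Dc.T @ yc).max()) if p else 0.0
        if lam_max <= 0:  # y already explained by the offset alone
            return np.zeros(p), ym, 0.0
        ratio = cfg.lambda_min_ratio
        if ratio is None:
            ratio = 0.01 if n < p else 1e-4
        grid = lam_max * ratio ** (np.arange(cfg.n_lambdas) / (cfg.n_lambdas - 1))

    if len(grid) == 1:
        lam_sel = float(grid[0])
    else:
        rng = np.random.default_rng(seed)
        foldid = rng.permutation(np.resize(np.arange(cfg.n_folds), n))
        sq_err = np.zeros(len(grid))
        for f in range(cfg.n_folds):
            tr = foldid != f
            Dtr, ytr = D[tr], y[tr]
            xmf, ymf = Dtr.mean(axis=0), ytr.mean()
            coefs = _path_betas(Dtr - xmf, ytr - ymf, grid, cfg)
            pred = (D[~tr] - xmf) @ coefs + ymf
            sq_err += ((pred - y[~tr][:, None]) ** 2).sum(axis=0)
        # grid is descending, argmin takes the first (sparser) minimizer on ties
        lam_sel = float(grid[int(np.argmin(sq_err / n))])

    if lam_sel <= 0:
        beta = np.linalg.lstsq(Dc, yc, rcond=None)[0]
    else:
        beta = _path_betas(Dc, yc, np.array([lam_sel]), cfg)[:, 0]
    beta = np.where(np.abs(beta) < SPARSITY_EPS, 0.0, beta)
    delta = ym - float(xm @ beta)
    return beta, delta, lam_sel


@dataclass
class CoefficientMatrix:
    """One lasso solution for a paired input: beta (R_Y x R_X) and per-row
    offsets delta."""

    beta: np.ndarray
    delta: np.ndarray
    seed: int


@dataclass
class EnsembleResult:
    """Aggregated ensemble of coefficient matrices.

    ``occurrence[i, j]`` counts replicates where entry (i, j) was non-zero;
    ``nonzero_mean`` averages the signed values over exactly those
    replicates (undefined positions are reported as 0).
    """

    n_replicates: int
    occurrence: np.ndarray
    nonzero_sum: np.ndarray
    positive_count: np.ndarray
    replicate_nonzero_counts: np.ndarray
    seeds: list[int]
    max_abs_delta: float
    y_ids: list[str]
    x_ids: list[str]

    @property
    def nonzero_mean(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.where(self.occurrence > 0, self.nonzero_sum / np.maximum(self.occurrence, 1), 0.0)
        return m


@dataclass
class RobustLassoCoefficientMatrix:
    """Consensus sparse coefficient matrix (entries stable across replicates).

    ``entries`` columns: y_analyte, x_analyte, coefficient (mean over
    non-zero occurrences), frequency (occurrence / n_replicates), and
    sign_consistency (fraction of non-zero occurrences sharing the majority
    sign — diagnostic, not part of the on-disk triplet format).
    """

    entries: pd.DataFrame
    y_ids: list[str]
    x_ids: list[str]
    n_replicates: int
    min_frequency: float = 0.5
    provenance: str = "generic"
    held_out: str | None = None

    def __len__(self) -> int:
        return len(self.entries)

    def support(self) -> set[tuple[str, str]]:
        return set(zip(self.entries["y_analyte"], self.entries["x_analyte"]))

    def to_dense(self) -> np.ndarray:
        yi = {a: i for i, a in enumerate(self.y_ids)}
        xi = {a: i for i, a in enumerate(self.x_ids)}
        out = np.zeros((len(self.y_ids), len(self.x_ids)))
        for y, x, c in zip(
            self.entries["y_analyte"], self.entries["x_analyte"], self.entries["coefficient"]
        ):
            out[yi[y], xi[x]] = c
        return out

    def write_tsv(self, path: str | Path, sidecar: dict | None = None) -> None:
        """Triplet TSV (y_analyte, x_analyte, coefficient, frequency) plus an
        optional JSON sidecar with run provenance."""
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("y_analyte\tx_analyte\tcoefficient\tfrequency\n")
            for rec in self.entries.itertuples(index=False):
                fh.write(
                    f"{rec.y_analyte}\t{rec.x_analyte}\t{repr(float(rec.coefficient))}\t{repr(float(rec.frequency))}\n"
                )
        if sidecar is not None:
            meta = dict(sidecar)
            meta.update(
                n_replicates=self.n_replicates,
                min_frequency=self.min_frequency,
                provenance=self.provenance,
                held_out=self.held_out,
            )
            Path(str(path) + ".json").write_text(
                json.dumps(meta, indent=2, sort_keys=True) + "\n", encoding="utf-8"
            )

    @classmethod
    def read_tsv(
        cls,
        path: str | Path,
        y_ids: list[str],
        x_ids: list[str],
        n_replicates: int = 0,
        min_frequency: float = 0.5,
        provenance: str = "generic",
    ) -> "RobustLassoCoefficientMatrix":
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"y_analyte": str, "x_analyte": str, "coefficient": float, "frequency": float},
            float_precision="round_trip",
        )
        return cls(
            entries=df,
            y_ids=list(y_ids),
            x_ids=list(x_ids),
            n_replicates=n_replicates,
            min_frequency=min_frequency,
            provenance=provenance,
        )


def _replicate_seed(master_seed: int, r: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master_seed), int(r)])


def _fit_replicate(
    Y: np.ndarray, X: np.ndarray, cfg: LassoFitConfig, master_seed: int, r: int
) -> tuple[np.ndarray, float]:
    beta = np.empty((Y.shape[0], X.shape[0]))
    max_delta = 0.0
    for k in range(Y.shape[0]):
        row, delta, _ = fit_lasso_row(
            Y[k], X, cfg, seed=np.random.SeedSequence([int(master_seed), int(r), int(k)])
        )
        beta[k] = row
        max_delta = max(max_delta, abs(delta))
    return beta, max_delta


class RobustLassoEnsemble(BaseEstimator, RegressorMixin):
    """Stability-selected sparse linear maps via replicated CV-lasso.

    scikit-learn conventions: observations are rows of ``X`` (here the
    experimental conditions), features are predictor analytes, and the
    multi-output target ``Y`` holds the response analytes. ``fit`` runs
    ``n_replicates`` independent CV-lasso sweeps differing only in their
    fold assignments and retains coefficients that were non-zero in at
    least ``min_frequency`` of them.

    Attributes (after ``fit``)
    --------------------------
    occurrence_ : int array (n_targets, n_features)
        Non-zero counts across replicates.
    nonzero_mean_ : array (n_targets, n_features)
        Mean of the signed coefficient over its non-zero occurrences.
    coef_ : array (n_targets, n_features)
        The robust (consensus) coefficient matrix: ``nonzero_mean_`` where
        the retention rule holds, zero elsewhere.
    intercept_ : array (n_targets,)
        Offsets of a single reference replicate (replicate 0); negligible
        on properly centered inputs.
    replicate_nonzero_counts_ : int array (n_replicates,)
        Per-replicate support sizes (used by the shuffled-input null).
    """

    def __init__(
        self,
        n_replicates: int = 100,
        min_frequency: float = 0.5,
        n_folds: int = 4,
        n_lambdas: int = 100,
        lambda_min_ratio: float | None = None,
        lambda_grid: tuple[float, ...] | None = None,
        max_iter: int = 1000,
        tol: float = 1e-4,
        random_state: int = 0,
        n_jobs: int = 1,
    ) -> None:
        self.n_replicates = n_replicates
        self.min_frequency = min_frequency
        self.n_folds = n_folds
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.lambda_grid = lambda_grid
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.n_jobs = n_jobs

    def _cfg(self) -> LassoFitConfig:
        return LassoFitConfig(
            n_folds=self.n_folds,
            lambda_grid=self.lambda_grid,
            n_lambdas=self.n_lambdas,
            lambda_min_ratio=self.lambda_min_ratio,
            max_iter=self.max_iter,
            tol=self.tol,
        )

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "RobustLassoEnsemble":
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must share their observation axis")
        cfg = self._cfg()
        Xrows = X.T  # predictors x conditions, the row-fit convention
        Yrows = Y.T
        n_targets, n_features = Yrows.shape[0], Xrows.shape[0]

        results = Parallel(n_jobs=self.n_jobs)(
            delayed(_fit_replicate)(Yrows, Xrows, cfg, self.random_state, r)
            for r in range(self.n_replicates)
        )
        occurrence = np.zeros((n_targets, n_features), dtype=np.int64)
        nonzero_sum = np.zeros((n_targets, n_features))
        positive = np.zeros((n_targets, n_features), dtype=np.int64)
        counts = np.empty(self.n_replicates, dtype=np.int64)
        max_delta = 0.0
        for r, (beta, d) in enumerate(results):  # fixed order: scheduling-invariant
            nz = beta != 0.0
            occurrence += nz
            nonzero_sum += np.where(nz, beta, 0.0)
            positive += beta > 0.0
            counts[r] = int(nz.sum())
            max_delta = max(max_delta, d)
        if max_delta > 1e-6:
            warnings.warn(
                f"max |offset| {max_delta:.3g} exceeds 1e-6; inputs may not be centered",
                stacklevel=2,
            )
        self.occurrence_ = occurrence
        self.nonzero_sum_ = nonzero_sum
        self.positive_count_ = positive
        self.replicate_nonzero_counts_ = counts
        self.max_abs_delta_ = max_delta
        with np.errstate(invalid="ignore"):
            self.nonzero_mean_ = np.where(
                occurrence > 0, nonzero_sum / np.maximum(occurrence, 1), 0.0
            )
        threshold = math.ceil(self.min_frequency * self.n_replicates)
        self.coef_ = np.where(occurrence >= threshold, self.nonzero_mean_, 0.0)
        ref_beta, _ = results[0]
        self.intercept_ = Y.mean(axis=0) - ref_beta @ X.mean(axis=0)
        self.n_features_in_ = n_features
        self.seeds_ = [
            int(_replicate_seed(self.random_state, r).generate_state(1)[0] % (2**31))
            for r in range(self.n_replicates)
        ]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_.T + self.intercept_


def run_lasso_module(
    pair: PairedInput,
    cfg: LassoFitConfig | None = None,
    n_replicates: int = 100,
    master_seed: int = 0,
    n_jobs: int = 1,
) -> EnsembleResult:
    """Run the replicated lasso over a preprocessed pair (left = Y, right = X).

    Replicate r derives its seed stream deterministically from
    ``(master_seed, r)``, so results are bit-identical regardless of
    execution order or parallelism.
    """
    cfg = cfg or LassoFitConfig()
    est = RobustLassoEnsemble(
        n_replicates=n_replicates,
        n_folds=cfg.n_folds,
        n_lambdas=cfg.n_lambdas,
        lambda_min_ratio=cfg.lambda_min_ratio,
        lambda_grid=cfg.lambda_grid,
        max_iter=cfg.max_iter,
        tol=cfg.tol,
        random_state=master_seed,
        n_jobs=n_jobs,
    )
    est.fit(pair.right.values.T, pair.left.values.T)
    return EnsembleResult(
        n_replicates=n_replicates,
        occurrence=est.occurrence_,
        nonzero_sum=est.nonzero_sum_,
        positive_count=est.positive_count_,
        replicate_nonzero_counts=est.replicate_nonzero_counts_,
        seeds=est.seeds_,
        max_abs_delta=est.max_abs_delta_,
        y_ids=list(pair.left.analyte_ids),
        x_ids=list(pair.right.analyte_ids),
    )


def build_rlcm(
    ens: EnsembleResult,
    min_frequency: float = 0.5,
    provenance: str = "generic",
    held_out: str | None = None,
) -> RobustLassoCoefficientMatrix:
    """Retain entries non-zero in at least ``ceil(min_frequency * N)`` of the
    N replicates; the kept coefficient is the mean over non-zero occurrences."""
    if not 0.0 < min_frequency <= 1.0:
        raise ValueError("min_frequency must be in (0, 1]")
    threshold = math.ceil(min_frequency * ens.n_replicates)
    ii, jj = np.nonzero(ens.occurrence >= threshold)
    mean = ens.nonzero_mean
    occ = ens.occurrence
    pos = ens.positive_count
    records = {
        "y_analyte": [ens.y_ids[i] for i in ii],
        "x_analyte": [ens.x_ids[j] for j in jj],
        "coefficient": mean[ii, jj],
        "frequency": occ[ii, jj] / ens.n_replicates,
        "sign_consistency": np.maximum(pos[ii, jj], occ[ii, jj] - pos[ii, jj])
        / np.maximum(occ[ii, jj], 1),
    }
    entries = pd.DataFrame(records)
    return RobustLassoCoefficientMatrix(
        entries=entries,
        y_ids=list(ens.y_ids),
        x_ids=list(ens.x_ids),
        n_replicates=ens.n_replicates,
        min_frequency=min_frequency,
        provenance=provenance,
        held_out=held_out,
    )
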