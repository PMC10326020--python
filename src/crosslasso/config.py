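"""Structured run configuration and provenance manifests.

A single YAML file (plus CLI flag overrides) drives every pipeline command;
all randomness flows from one ``master_seed``. The manifest written next to
each artifact records the full configuration, the seed, and SHA-256 digests
of every input file, which is sufficient to reproduce the artifact exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .ensemble import LassoFitConfig
from .network import COMPARISON_THRESHOLD, DISPLAY_THRESHOLD


@dataclass
class RunConfig:
    """Pipeline settings; defaults are the desk-scale study conditions
    (the original-scale analysis of the source datasets used 10,000
    ensemble replicates — set ``n_replicates`` accordingly for that)."""

    left_matrix: str = "left.tsv"
    left_meta: str = "left_meta.tsv"
    right_matrix: str = "right.tsv"
    right_meta: str = "right_meta.tsv"
    condition_groups: str | None = None
    outdir: str = "results"

    # variance filter: targeted proteomics keeps a larger share (fewer features)
    left_fraction: float = 1.0
    right_fraction: float = 1.0

    n_folds: int = 4
    n_lambdas: int = 100
    lambda_min_ratio: float | None = None
    max_iter: int = 1000
    tol: float = 1e-4

    n_replicates: int = 100
    min_frequency: float = 0.5
    display_threshold: float = DISPLAY_THRESHOLD
    comparison_threshold: float = COMPARISON_THRESHOLD
    layer_pair: str = "generic"
    holdout_groups: list[str] = field(default_factory=list)
    master_seed: int = 0
    n_jobs: int = 1

    def __post_init__(self) -> None:
        for frac in (self.left_fraction, self.right_fraction):
            if not 0.0 < frac <= 1.0:
                raise ValueError("variance fractions must lie in (0, 1]")
        if not 0.0 < self.min_frequency <= 1.0:
            raise ValueError("min_frequency must lie in (0, 1]")
        paths = [self.left_matrix, self.left_meta, self.right_matrix, self.right_meta]
        if self.condition_groups:
            paths.append(self.condition_groups)
        if len(set(paths)) != len(paths):
            raise ValueError("input paths must be distinct")

    def lasso_config(self) -> LassoFitConfig:
        return LassoFitConfig(
            n_folds=self.n_folds,
            n_lambdas=self.n_lambdas,
            lambda_min_ratio=self.lambda_min_ratio,
            max_iter=self.max_iter,
            tol=self.tol,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8"
        )


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    cfg: RunConfig,
    inputs: list[str | Path],
    outputs: list[str | Path],
    extra: dict | None = None,
) -> None:
    from . import __version__

    payload = {
        "package_version": __version__,
        "config": asdict(cfg),
        "master_seed": cfg.master_seed,
        "input_digests": {str(p): sha256_of(p) for p in inputs if Path(p).exists()},
        "outputs": [str(p) for p in outputs],
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")
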