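"""End-to-end orchestration: simulate or load a cohort, cluster, evaluate, report.

A run produces one output directory containing the cohort (if simulated),
both algorithms' partitions, one evaluation report per rotation per
algorithm, a comparison table and a machine-readable manifest. The whole
bundle is a pure function of (input, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import ROTATION_COLUMNS, Dataset, read_dataset, write_dataset
from .evaluation import EvaluationReport, build_report
from .kmeans import kmeans, standardize
from .pso import PSOConfig, pso_km
from .synthetic import CohortConfig, generate_cohort

log = logging.getLogger(__name__)

ALGORITHMS = ("pso_km", "km")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on."""

    input_path: str | None = None          # if None, a cohort is simulated
    cohort: CohortConfig = field(default_factory=CohortConfig)
    scaling: str = "zscore"                # "zscore" | "raw"
    k: int = 3
    pso: PSOConfig = field(default_factory=PSOConfig)
    km_max_iter: int = 300
    km_tol: float = 1e-6
    rotations: tuple[str, ...] = ROTATION_COLUMNS
    out_dir: str = "psokm_run"
    seed: int = 0

    def validate(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.scaling not in ("zscore", "raw"):
            raise ValueError(f"scaling must be 'zscore' or 'raw', got {self.scaling!r}")
        bad = [r for r in self.rotations if r not in ROTATION_COLUMNS]
        if bad or not self.rotations:
            raise ValueError(f"rotations must be a nonempty subset of {ROTATION_COLUMNS}, got {self.rotations}")


def _features(dataset: Dataset, scaling: str) -> np.ndarray:
    X = dataset.physical_matrix()
    return standardize(X) if scaling == "zscore" else X


def cluster_both(dataset: Dataset, config: RunConfig):
    """Run K-means and the PSO-KM hybrid on the cohort's physical features.

    Both algorithms draw their randomness from ``config.seed``; K-means is
    a single seeded-random start, the hybrid a full swarm search plus
    refinement.
    """
    config.validate()
    X = _features(dataset, config.scaling)
    pso_cfg = PSOConfig(**{**asdict(config.pso), "seed": config.seed})
    partitions = {
        "pso_km": pso_km(X, config.k, pso_cfg, km_max_iter=config.km_max_iter, km_tol=config.km_tol),
        "km": kmeans(X, config.k, seed=config.seed, max_iter=config.km_max_iter, tol=config.km_tol),
    }
    return partitions


def compare_algorithms(reports: dict[str, dict[str, EvaluationReport]]) -> pd.DataFrame:
    """Per-rotation comparison: Rand indices and success-rate deltas.

    ``reports`` maps rotation -> {algorithm -> report}; each rotation must
    carry both algorithms. Deltas are PSO-KM minus KM.
    """
    rows = []
    for rot, pair in reports.items():
        missing = [a for a in ALGORITHMS if a not in pair]
        if missing:
            raise ValueError(f"rotation {rot!r} lacks report(s) for {missing}")
        pso_r, km_r = pair["pso_km"], pair["km"]
        row = {
            "rotation": rot.upper(),
            "rand_pso_km": pso_r.rand_index,
            "rand_km": km_r.rand_index,
            "rand_delta": pso_r.rand_index - km_r.rand_index,
        }
        for c in (1, 2, 3):
            sp, sk = pso_r.success_rates[c], km_r.success_rates[c]
            row[f"success_c{c}_pso_km"] = sp
            row[f"success_c{c}_km"] = sk
            row[f"success_c{c}_delta"] = None if sp is None or sk is None else round(sp - sk, 2)
        rows.append(row)
    return pd.DataFrame(rows)


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> Path:
    """Execute a full run and write the report bundle; returns the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_times: dict[str, float] = {}

    t0 = time.perf_counter()
    if config.input_path:
        log.info("stage load: reading cohort from %s", config.input_path)
        dataset = read_dataset(config.input_path)
        labels = None
    else:
        cohort_cfg = CohortConfig(**{**asdict(config.cohort), "seed": config.seed})
        log.info("stage simulate: generating %d-subject cohort (seed %d)", cohort_cfg.n_total, config.seed)
        dataset, labels = generate_cohort(cohort_cfg)
        write_dataset(dataset, out / "cohort.csv")
        labels.to_csv(out / "labels.csv", index=False)
    stage_times["input"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    log.info("stage cluster: k=%d on %d subjects (%s features)", config.k, dataset.n, config.scaling)
    partitions = cluster_both(dataset, config)
    stage_times["cluster"] = time.perf_counter() - t0

    assign = pd.DataFrame({"id": [s.id for s in dataset]})
    for algo, part in partitions.items():
        assign[algo] = part.assignment
    assign.to_csv(out / "assignments.csv", index=False)

    t0 = time.perf_counter()
    reports: dict[str, dict[str, EvaluationReport]] = {}
    for rot in config.rotations:
        reports[rot] = {}
        for algo, part in partitions.items():
            rep = build_report(dataset, part, rot)
            reports[rot][algo] = rep
            _dump_json(rep.to_dict(), out / f"report_{algo}_{rot}.json")
    comparison = compare_algorithms(reports)
    comparison.to_csv(out / "comparison.csv", index=False)
    stage_times["evaluate"] = time.perf_counter() - t0
    log.info("stage evaluate: %d reports written", len(config.rotations) * len(ALGORITHMS))

    cfg_dict = asdict(config)
    cfg_dict.pop("out_dir")  # the bundle location must not affect its contents
    manifest = {
        "package": "psokm",
        "version": __version__,
        "seed": config.seed,
        "n_subjects": dataset.n,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "sse": {algo: part.sse for algo, part in partitions.items()},
    }
    # wall-times go to the log, not the manifest, so reruns are byte-identical
    log.info("stage wall-times: %s", {k: round(v, 3) for k, v in stage_times.items()})
    _dump_json(manifest, out / "manifest.json")
    return out
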