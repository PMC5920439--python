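"""Cluster-comparison arithmetic: success rates, type rates, accuracies, Rand index.

Conventions used throughout:

* a **success rate** between two subject counts is ``100 * min / max``;
* a **type rate** is a type's share of its cluster, ``100 * count / total``;
* a **general accuracy** compares a real and an algorithmic type rate,
  again as ``100 * min / max`` — computed from the already two-decimal
  rounded rates, since that is how the summary tables chain;
* the **Rand index** between two partitions is the fraction of subject
  pairs on which they agree (both together or both apart), in [0, 1];
* percentages are rounded half-up to two decimals.

Undefined ratios (a zero denominator, or a zero rate in an accuracy)
are reported as ``None`` — the tabular equivalent of a printed dash.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import Dataset
from .kmeans import Partition

CLUSTER_LABELS = (1, 2, 3)
TYPE_LABELS = (1, 2, 3)


def round2(value: float) -> float:
    """Round half-up to two decimals (table convention)."""
    return float(Decimal(repr(float(value))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def success_rate(count_a: int, count_b: int) -> Optional[float]:
    """Percent agreement between two subject counts: 100·min/max.

    Symmetric; equals 100 iff the counts are equal. Undefined (``None``)
    when both counts are zero.
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be >= 0")
    if count_a == 0 and count_b == 0:
        return None
    return round2(100.0 * min(count_a, count_b) / max(count_a, count_b))


def type_rate(type_count: int, cluster_total: int) -> Optional[float]:
    """A type's percentage share of its cluster; ``None`` for an empty cluster."""
    if cluster_total == 0:
        return None
    if not 0 <= type_count <= cluster_total:
        raise ValueError(f"need 0 <= type_count <= cluster_total, got {type_count}/{cluster_total}")
    return round2(100.0 * type_count / cluster_total)


def general_accuracy(rate_real: Optional[float], rate_algo: Optional[float]) -> Optional[float]:
    """Agreement between a real and an algorithmic rate: 100·min/max.

    Both rates must be in (0, 100]; a missing or zero rate yields ``None``
    (the tables print a dash there).
    """
    if rate_real is None or rate_algo is None or rate_real == 0 or rate_algo == 0:
        return None
    if not (0 < rate_real <= 100 and 0 < rate_algo <= 100):
        raise ValueError(f"rates must lie in (0, 100], got ({rate_real}, {rate_algo})")
    return round2(100.0 * min(rate_real, rate_algo) / max(rate_real, rate_algo))


def rand_index(labels_a, labels_b) -> float:
    """Fraction of point pairs on which two partitions agree.

    A pair agrees when both partitions place it in one cluster, or both
    split it. Symmetric and invariant under relabeling; 1 iff the
    partitions are identical up to relabeling. Requires n >= 2.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("Rand index needs at least 2 points")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(contingency, (ai, bi), 1)

    def pairs(x: np.ndarray) -> int:
        return int((x.astype(np.int64) * (x.astype(np.int64) - 1) // 2).sum())

    total = n * (n - 1) // 2
    same_same = pairs(contingency)
    same_a = pairs(contingency.sum(axis=1))
    same_b = pairs(contingency.sum(axis=0))
    disagreements = (same_a - same_same) + (same_b - same_same)
    return (total - disagreements) / total


@dataclass(frozen=True)
class CrossTab:
    """3×3 type-by-cluster count matrix with totals.

    ``counts[t-1, c-1]`` is the number of subjects of rotation type t in
    cluster c.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (3, 3):
            raise ValueError(f"counts must be 3x3, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be >= 0")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:  # per type
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:  # per cluster
        return self.counts.sum(axis=0)

    def cluster_size(self, cluster: int) -> int:
        return int(self.col_totals[cluster - 1])

    def count(self, type_label: int, cluster: int) -> int:
        return int(self.counts[type_label - 1, cluster - 1])

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            self.counts,
            index=[f"Type {t}" for t in TYPE_LABELS],
            columns=[f"Cluster {c}" for c in CLUSTER_LABELS],
        )
        df["Total"] = self.row_totals
        df.loc["Total"] = list(self.col_totals) + [self.n]
        return df


def cross_tabulate(type_labels, cluster_labels) -> CrossTab:
    """Count subjects per (rotation type, cluster) cell."""
    t = np.asarray(type_labels)
    c = np.asarray(cluster_labels)
    if t.shape != c.shape:
        raise ValueError("type and cluster label vectors must have equal length")
    counts = np.zeros((3, 3), dtype=np.int64)
    for ti, ci in zip(t, c):
        if ti not in TYPE_LABELS or ci not in CLUSTER_LABELS:
            raise ValueError(f"labels must be in 1..3, got type={ti}, cluster={ci}")
        counts[ti - 1, ci - 1] += 1
    return CrossTab(counts)


def match_clusters(predicted, reference) -> dict[int, int]:
    """Best bijection from predicted cluster ids to reference labels.

    Maximizes the total overlap on the contingency matrix (optimal
    assignment); returns ``{predicted_id: reference_label}``. Both label
    vectors must use the same number of clusters.
    """
    pred = np.asarray(predicted)
    ref = np.asarray(reference)
    if pred.shape != ref.shape:
        raise ValueError("label vectors must have equal length")
    pred_ids = np.unique(pred)
    ref_ids = np.unique(ref)
    if pred_ids.size != ref_ids.size:
        raise ValueError(
            f"cluster count mismatch: {pred_ids.size} predicted vs {ref_ids.size} reference"
        )
    contingency = np.zeros((pred_ids.size, ref_ids.size), dtype=np.int64)
    pi = {v: i for i, v in enumerate(pred_ids)}
    ri = {v: i for i, v in enumerate(ref_ids)}
    for p, r in zip(pred, ref):
        contingency[pi[p], ri[r]] += 1
    rows, cols = linear_sum_assignment(-contingency)
    return {int(pred_ids[r]): int(ref_ids[c]) for r, c in zip(rows, cols)}


@dataclass
class EvaluationReport:
    """All comparison numbers for one algorithm run against the rule labels."""

    rotation: str
    real_crosstab: CrossTab
    algo_crosstab: CrossTab
    success_rates: Mapping[int, Optional[float]]          # cluster -> %
    real_type_rates: Mapping[int, Mapping[int, Optional[float]]]   # cluster -> type -> %
    algo_type_rates: Mapping[int, Mapping[int, Optional[float]]]
    general_accuracies: Mapping[int, Mapping[int, Optional[float]]]
    rand_index: Optional[float] = None

    def to_dict(self) -> dict:
        def tidy(m):
            return {str(k): (dict((str(kk), vv) for kk, vv in v.items()) if isinstance(v, dict) else v)
                    for k, v in m.items()}

        return {
            "rotation": self.rotation,
            "real_counts": self.real_crosstab.counts.tolist(),
            "algo_counts": self.algo_crosstab.counts.tolist(),
            "success_rates": tidy(self.success_rates),
            "real_type_rates": tidy(self.real_type_rates),
            "algo_type_rates": tidy(self.algo_type_rates),
            "general_accuracies": tidy(self.general_accuracies),
            "rand_index": self.rand_index,
        }


def arithmetic_report(
    real: CrossTab, algo: CrossTab, rotation: str = "", rand: Optional[float] = None
) -> EvaluationReport:
    """Derive every table statistic from a pair of type×cluster count matrices.

    Per cluster: the success rate of the cluster sizes; per cluster and
    type: the real and algorithmic type rates and the general accuracy of
    the rate pair.
    """
    success = {c: success_rate(real.cluster_size(c), algo.cluster_size(c)) for c in CLUSTER_LABELS}
    real_rates = {
        c: {t: type_rate(real.count(t, c), real.cluster_size(c)) for t in TYPE_LABELS}
        for c in CLUSTER_LABELS
    }
    algo_rates = {
        c: {t: type_rate(algo.count(t, c), algo.cluster_size(c)) for t in TYPE_LABELS}
        for c in CLUSTER_LABELS
    }
    accuracies = {
        c: {t: general_accuracy(real_rates[c][t], algo_rates[c][t]) for t in TYPE_LABELS}
        for c in CLUSTER_LABELS
    }
    return EvaluationReport(
        rotation=rotation,
        real_crosstab=real,
        algo_crosstab=algo,
        success_rates=success,
        real_type_rates=real_rates,
        algo_type_rates=algo_rates,
        general_accuracies=accuracies,
        rand_index=rand,
    )


def build_report(dataset: Dataset, partition: Partition, rotation: str) -> EvaluationReport:
    """Evaluate one clustering run against the rule labels, for one rotation.

    Predicted clusters are identified with rule clusters by optimal
    overlap matching; rotation angles are typed by the pathology rule;
    the Rand index compares the partition with the rule labels.
    """
    rule = dataset.rule_clusters()
    types = dataset.rotation_types(rotation)
    mapping = match_clusters(partition.assignment, rule)
    mapped = np.array([mapping[int(a)] for a in partition.assignment])
    real_tab = cross_tabulate(types, rule)
    algo_tab = cross_tabulate(types, mapped)
    rand = rand_index(mapped, rule)
    return arithmetic_report(real_tab, algo_tab, rotation=rotation, rand=rand)
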