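"""Evaluation metrics, seed aggregation, statistical comparison and the
selected-gene re-evaluation workflow.

Metrics follow the usual confusion-matrix definitions with a configurable
positive class (default 1).  AUROC is computed by the rank (Mann-Whitney)
formulation — the probability that a random positive outranks a random
negative, ties counted one half — which is exactly the area under the
empirical ROC curve.  Per-seed results are aggregated as mean +/- population
standard deviation, the convention behind "mean +/- sd" result tables.
Group comparisons use the two-sided Mann-Whitney U test with the
rank-biserial effect size 1 - 2U/(nA*nB).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .bench import ClassifierSpec, repeat_over_seeds
from .fusion import DEFAULT_K_SCALE, fuse_fold
from .preprocess import LabeledCohort

__all__ = [
    "ConfusionCounts",
    "MetricsEntry",
    "MetricsReport",
    "ComparisonResult",
    "confusion_counts",
    "classification_metrics",
    "auroc",
    "aggregate_over_seeds",
    "mann_whitney_compare",
    "pairwise_pearson",
    "pooled_predictions",
    "evaluate_selected_genes",
    "render_report",
]

METRIC_NAMES = ("accuracy", "auroc", "precision_ppv", "recall_sensitivity", "specificity", "f1", "npv")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsEntry:
    """One seed's metric values; ratios with zero denominator are reported as
    0 and listed in ``undefined`` rather than dropped."""

    accuracy: float = float("nan")
    auroc: float = float("nan")
    precision_ppv: float = float("nan")
    recall_sensitivity: float = float("nan")
    specificity: float = float("nan")
    f1: float = float("nan")
    npv: float = float("nan")
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass
class MetricsReport:
    """Per-seed entries plus mean and population sd per metric."""

    per_seed: dict[int, MetricsEntry]
    mean: dict[str, float]
    sd: dict[str, float]


@dataclass(frozen=True)
class ComparisonResult:
    u_statistic: float
    p_value: float
    effect_size: float  # rank-biserial, in [-1, 1]
    group_labels: tuple[str, str]


def confusion_counts(
    y_true: Sequence[int], y_pred: Sequence[int], positive_class: int = 1
) -> ConfusionCounts:
    """The four confusion cells with the configured positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    bad = set(np.unique(np.concatenate([y_true, y_pred]))) - {0, 1}
    if bad:
        raise ValueError(f"labels outside {{0,1}}: {sorted(bad)}")
    pos = y_true == positive_class
    pred_pos = y_pred == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pos & pred_pos)),
        fp=int(np.sum(~pos & pred_pos)),
        tn=int(np.sum(~pos & ~pred_pos)),
        fn=int(np.sum(pos & ~pred_pos)),
    )


def _ratio(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def classification_metrics(c: ConfusionCounts) -> MetricsEntry:
    """Accuracy, PPV/precision, recall/sensitivity, specificity, F1 and NPV
    from the confusion cells."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    undefined: list[str] = []
    precision = _ratio(c.tp, c.tp + c.fp, "precision_ppv", undefined)
    recall = _ratio(c.tp, c.tp + c.fn, "recall_sensitivity", undefined)
    return MetricsEntry(
        accuracy=(c.tp + c.tn) / c.total,
        precision_ppv=precision,
        recall_sensitivity=recall,
        specificity=_ratio(c.tn, c.tn + c.fp, "specificity", undefined),
        f1=_ratio(2 * precision * recall, precision + recall, "f1", undefined),
        npv=_ratio(c.tn, c.tn + c.fn, "npv", undefined),
        undefined=tuple(undefined),
    )


def auroc(y_true: Sequence[int], scores: Sequence[float], positive_class: int = 1) -> float:
    """P(score of a random positive > score of a random negative), ties 1/2;
    computed via mid-ranks (the Mann-Whitney formulation)."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    pos = y_true == positive_class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = stats.rankdata(scores)  # mid-ranks handle ties as 1/2
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def aggregate_over_seeds(per_seed: Mapping[int, MetricsEntry]) -> MetricsReport:
    """Element-wise mean and population sd per metric across seeds."""
    if not per_seed:
        raise ValueError("at least one seed entry required")
    mean, sd = {}, {}
    for name in METRIC_NAMES:
        vals = np.array([getattr(e, name) for e in per_seed.values()], dtype=np.float64)
        mean[name] = float(np.mean(vals))
        sd[name] = float(np.std(vals))  # population convention, matches mean+/-sd tables
    return MetricsReport(per_seed=dict(per_seed), mean=mean, sd=sd)


def mann_whitney_compare(
    a: Sequence[float],
    b: Sequence[float],
    labels: tuple[str, str] = ("A", "B"),
) -> ComparisonResult:
    """Two-sided Mann-Whitney U comparison of two metric samples.

    Exact null distribution for small groups (both sizes <= 8, the typical
    per-seed case), normal approximation with tie correction otherwise.
    Effect size is the rank-biserial correlation 1 - 2U/(nA*nB) with U the
    statistic of group ``a``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if max(a.size, b.size) <= 8 and not _has_ties(a, b) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u = float(res.statistic)
    effect = 1.0 - 2.0 * u / (a.size * b.size)
    return ComparisonResult(u_statistic=u, p_value=float(res.pvalue), effect_size=effect, group_labels=labels)


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return len(np.unique(pooled)) != len(pooled)


def pairwise_pearson(cohort_matrix, gene_ids: Sequence[str]) -> np.ndarray:
    """Symmetric unit-diagonal Pearson correlation matrix over a gene set.

    Constant genes have undefined correlations; those entries are reported as
    0 (diagonal stays 1).
    """
    sub = cohort_matrix.restrict_genes(list(gene_ids))
    X = sub.values
    if X.shape[0] < 2:
        raise ValueError("pairwise correlation needs at least 2 samples")
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.atleast_2d(corr)
    constant = sd == 0
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


def pooled_predictions(
    predictions: Mapping[str, list], k_scale: float = DEFAULT_K_SCALE
) -> dict[str, tuple[list[str], np.ndarray, np.ndarray]]:
    """Pool validation-fold outputs over folds for one seed.

    Returns per approach ("RNA", "CNV", "fused") a tuple of (sample_ids,
    predicted labels, positive-class scores); every cohort sample appears
    exactly once because the folds partition the cohort.
    """
    out = {}
    for modality in ("RNA", "CNV"):
        ids, labels, scores = [], [], []
        for pred in predictions[modality]:
            ids.extend(pred.validation_ids)
            labels.extend(pred.labels.tolist())
            scores.extend(pred.proba[:, 1].tolist())
        out[modality] = (ids, np.array(labels), np.array(scores))
    ids, labels, scores = [], [], []
    for pr, pc in zip(predictions["RNA"], predictions["CNV"]):
        fused, _ = fuse_fold(pr, pc, k_scale=k_scale)
        for f in fused:
            ids.append(f.sample_id)
            labels.append(f.label)
            scores.append(f.p_fused_y1)
    out["fused"] = (ids, np.array(labels), np.array(scores))
    return out


def _seed_entry(
    sample_ids: list[str], pred: np.ndarray, scores: np.ndarray, label_of: Mapping[str, int]
) -> MetricsEntry:
    y_true = np.array([label_of[s] for s in sample_ids])
    entry = classification_metrics(confusion_counts(y_true, pred))
    entry.auroc = auroc(y_true, scores)
    return entry


def evaluate_selected_genes(
    cohort: LabeledCohort,
    gene_set: Sequence[str],
    spec: ClassifierSpec,
    k: int = 5,
    seeds: Sequence[int] = (1, 2, 3, 4, 5),
    k_scale: float = DEFAULT_K_SCALE,
) -> dict[str, MetricsReport]:
    """Re-run the cross-validated benchmark and fusion on a restricted gene
    panel; report per-approach metrics with mean +/- sd over seeds.

    The gene set must be present in both modalities (missing IDs are listed).
    """
    genes = sorted(set(gene_set))
    if not genes:
        raise ValueError("gene set must be non-empty")
    restricted = cohort.restrict_genes(genes)  # raises listing missing IDs
    runs = repeat_over_seeds(restricted, spec, k, seeds)
    label_of = dict(zip(cohort.common_sample_ids, cohort.labels))
    per_seed: dict[str, dict[int, MetricsEntry]] = {"RNA": {}, "CNV": {}, "fused": {}}
    for seed, run in runs.items():
        pooled = pooled_predictions(run["predictions"], k_scale=k_scale)
        for approach, (ids, pred, scores) in pooled.items():
            per_seed[approach][seed] = _seed_entry(ids, pred, scores, label_of)
    return {approach: aggregate_over_seeds(entries) for approach, entries in per_seed.items()}


def _config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def render_report(results: Mapping, config: Mapping | None = None) -> tuple[str, dict]:
    """Deterministic human-readable summary plus machine-readable dict.

    ``results`` maps approach name -> MetricsReport (or plain mapping); the
    text table uses the 'mean+/-sd' 3-decimal convention.  The JSON side
    carries per-seed values, the seeds and a config hash for provenance.
    """
    config = dict(config or {})
    machine: dict = {"config": config, "config_hash": _config_hash(config), "approaches": {}}
    lines = ["approach\t" + "\t".join(METRIC_NAMES)]
    for approach in sorted(results):
        report = results[approach]
        if isinstance(report, MetricsReport):
            mean, sd = report.mean, report.sd
            per_seed = {s: e.as_dict() for s, e in sorted(report.per_seed.items())}
        else:
            mean, sd = report["mean"], report["sd"]
            per_seed = report.get("per_seed", {})
        cells = [f"{mean[n]:.3f}±{sd[n]:.3f}" for n in METRIC_NAMES]
        lines.append(approach + "\t" + "\t".join(cells))
        machine["approaches"][approach] = {"mean": dict(mean), "sd": dict(sd), "per_seed": per_seed}
    return "\n".join(lines), machine
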