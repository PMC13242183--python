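"""Cross-validated per-modality classifier benchmarking.

Each probabilistic binary classifier is trained separately on every modality
under stratified k-fold cross-validation, repeated over several seeds.  The
crucial contract for decision-level fusion is *fold alignment*: one FoldPlan
per seed, shared by both modalities, so that fold i's validation samples are
identical (and identically ordered) in the expression and copy-number runs.
Per fold we record the train-split accuracy (the quantity the fusion weights
are computed from) and the validation-split class probabilities.

Classifiers are thin adapters over established implementations (xgboost and
scikit-learn); the bespoke parts of this package are the harness, the fusion
rule and the selection pipeline, not the models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .preprocess import LabeledCohort, OmicsMatrix

__all__ = [
    "FoldPlan",
    "ClassifierSpec",
    "FoldPrediction",
    "make_fold_plan",
    "run_benchmark",
    "concat_joint_features",
    "repeat_over_seeds",
    "available_models",
]


@dataclass(frozen=True)
class FoldPlan:
    """A stratified k-fold partition of a fixed sample universe."""

    seed: int
    k: int
    folds: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]  # (train_ids, validation_ids)

    def validation_union(self) -> list[str]:
        out: list[str] = []
        for _, val in self.folds:
            out.extend(val)
        return out


@dataclass(frozen=True)
class ClassifierSpec:
    """A named pluggable model with (default) hyperparameters.

    The adapter must expose ``fit(X, y)`` and ``predict_proba(X)`` returning
    per-sample probability pairs, and must accept a seed for its internal
    randomness.
    """

    name: str
    hyperparameters: dict = field(default_factory=dict)

    def build(self, seed: int):
        try:
            factory = _ADAPTERS[self.name]
        except KeyError:
            raise KeyError(
                f"unknown model {self.name!r}; available: {sorted(_ADAPTERS)}"
            ) from None
        return factory(self.hyperparameters, seed)


@dataclass
class FoldPrediction:
    """One modality's outcome on one fold: the train-split accuracy and the
    validation samples' class-probability pairs."""

    modality: str
    fold_index: int
    train_accuracy: float
    validation_ids: list[str]
    proba: np.ndarray  # shape (n_validation, 2), columns (p_y0, p_y1)

    def __post_init__(self) -> None:
        self.proba = np.asarray(self.proba, dtype=np.float64)
        if self.proba.shape != (len(self.validation_ids), 2):
            raise ValueError("proba must be (n_validation, 2)")
        if not np.allclose(self.proba.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("probability pairs must sum to 1")
        if not 0.0 <= self.train_accuracy <= 1.0:
            raise ValueError("train_accuracy must be in [0, 1]")

    @property
    def labels(self) -> np.ndarray:
        """Predicted labels (argmax; ties to class 0)."""
        return (self.proba[:, 1] > self.proba[:, 0]).astype(np.int64)


def _xgb_factory(hp: dict, seed: int):
    from xgboost import XGBClassifier

    params = dict(n_jobs=1, random_state=seed, eval_metric="logloss")
    params.update(hp)
    return XGBClassifier(**params)


def _svc_factory(hp: dict, seed: int):
    from sklearn.svm import SVC

    params = dict(probability=True, random_state=seed)
    params.update(hp)
    return SVC(**params)


def _mlp_factory(hp: dict, seed: int):
    from sklearn.neural_network import MLPClassifier

    params = dict(random_state=seed)
    params.update(hp)
    return MLPClassifier(**params)


_ADAPTERS: dict[str, Callable] = {
    "gradient_boosting": _xgb_factory,
    "kernel_svm": _svc_factory,
    "mlp": _mlp_factory,
}


def available_models() -> list[str]:
    return sorted(_ADAPTERS)


def make_fold_plan(sample_ids: Sequence[str], labels: np.ndarray, k: int, seed: int) -> FoldPlan:
    """Stratified k-fold partition; a pure function of (IDs, labels, k, seed)."""
    from sklearn.model_selection import StratifiedKFold

    labels = np.asarray(labels)
    for cls in np.unique(labels):
        n_cls = int((labels == cls).sum())
        if n_cls < k:
            raise ValueError(f"class {cls} has {n_cls} samples, fewer than k={k}")
    ids = np.asarray(list(sample_ids), dtype=object)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = tuple(
        (tuple(ids[tr]), tuple(ids[va])) for tr, va in skf.split(np.zeros(len(ids)), labels)
    )
    return FoldPlan(seed=seed, k=k, folds=folds)


def _split(m: OmicsMatrix, ids: Sequence[str]) -> np.ndarray:
    pos = {s: i for i, s in enumerate(m.sample_ids)}
    return m.values[[pos[s] for s in ids]]


def run_benchmark(
    cohort: LabeledCohort,
    spec: ClassifierSpec,
    plan: FoldPlan,
    modalities: Sequence[str] = ("RNA", "CNV"),
) -> dict[str, list[FoldPrediction]]:
    """Fit the model per modality per fold under the *same* fold plan.

    Returns ``{modality: [FoldPrediction per fold]}``.  Adapter failures are
    re-raised with fold context.
    """
    label_of = dict(zip(cohort.common_sample_ids, cohort.labels))
    results: dict[str, list[FoldPrediction]] = {m: [] for m in modalities}
    for modality in modalities:
        matrix = cohort.modality(modality)
        for fold_index, (train_ids, val_ids) in enumerate(plan.folds):
            Xt, Xv = _split(matrix, train_ids), _split(matrix, val_ids)
            yt = np.array([label_of[s] for s in train_ids])
            model = spec.build(plan.seed)
            try:
                model.fit(Xt, yt)
                train_acc = float(np.mean(model.predict(Xt) == yt))
                raw = model.predict_proba(Xv)
            except Exception as exc:  # adapter failure: add fold context
                raise RuntimeError(
                    f"model {spec.name!r} failed on {modality} fold {fold_index}: {exc}"
                ) from exc
            # map adapter class order onto the fixed (p_y0, p_y1) convention
            classes = list(getattr(model, "classes_", [0, 1]))
            proba = np.column_stack([raw[:, classes.index(0)], raw[:, classes.index(1)]])
            proba = proba / proba.sum(axis=1, keepdims=True)
            results[modality].append(
                FoldPrediction(modality, fold_index, train_acc, list(val_ids), proba)
            )
    return results


def concat_joint_features(cohort: LabeledCohort) -> OmicsMatrix:
    """Early-integration baseline: column-wise concatenation of the two
    modalities with modality-prefixed gene IDs ("RNA:G1", "CNV:G1")."""
    gene_ids = [f"RNA:{g}" for g in cohort.rna.gene_ids] + [f"CNV:{g}" for g in cohort.cnv.gene_ids]
    values = np.concatenate([cohort.rna.values, cohort.cnv.values], axis=1)
    return OmicsMatrix("JOINT", cohort.common_sample_ids, gene_ids, values)


def repeat_over_seeds(
    cohort: LabeledCohort,
    spec: ClassifierSpec,
    k: int,
    seeds: Sequence[int],
    modalities: Sequence[str] = ("RNA", "CNV"),
) -> dict[int, dict]:
    """One FoldPlan + benchmark per seed.

    Returns ``{seed: {"plan": FoldPlan, "predictions": {modality: [...]}}}``.
    """
    seeds = list(seeds)
    if not seeds:
        raise ValueError("seed list must be non-empty")
    if len(set(seeds)) != len(seeds):
        raise ValueError("duplicate seeds")
    out: dict[int, dict] = {}
    for seed in seeds:
        plan = make_fold_plan(cohort.common_sample_ids, cohort.labels, k, seed)
        out[seed] = {"plan": plan, "predictions": run_benchmark(cohort, spec, plan, modalities)}
    return out
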