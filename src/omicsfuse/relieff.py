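"""ReliefF feature weighting and the cross-validated stability-selection
pipeline for discriminative gene discovery.

Relief estimates how well an attribute separates classes *locally*: for each
instance it finds the nearest same-class neighbor (hit) and nearest
other-class neighbor (miss) and rewards attributes that differ across the
class boundary but not within it,

    W[A] <- W[A] - diff(A, X, Hit)/n + diff(A, X, Miss)/n .

ReliefF replaces the single hit/miss with the k nearest hits and k nearest
misses (averaging the diffs), which makes the weights far more stable in
noisy, high-dimensional data.  For continuous attributes

    diff(A, x, y) = |x_A - y_A| / range_A

(range computed on the training split; zero-range attributes contribute 0),
and the neighbor search uses the Manhattan distance on these range-normalized
attributes, i.e. the sum of diffs.  With every instance scored (the
deterministic full pass used here) the weights are bounded in [-1, 1].

The stability pipeline runs ReliefF per cross-validation fold on the train
split only, sums the per-fold weights per gene into a cumulative score,
keeps the top-N genes per seed, intersects the per-seed sets within each
modality (within-omics stable sets), and finally intersects across the two
modalities to retain genes consistently discriminative in both.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .bench import FoldPlan, make_fold_plan
from .preprocess import LabeledCohort

__all__ = [
    "ReliefConfig",
    "FeatureImportanceList",
    "GeneSelectionResult",
    "diff_matrix",
    "relieff_weights",
    "run_fold_selection",
    "rank_and_aggregate_folds",
    "select_top_n",
    "stable_gene_set",
    "cross_omics_intersection",
    "union_gene_set",
    "stability_selection",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReliefConfig:
    """ReliefF settings.

    ``k_neighbors`` defaults to 100 (the customary large-cohort default); it
    is clipped with a warning to (min class size - 1) when a class is too
    small.  ``n_sampled=None`` scores every instance, which makes the weights
    deterministic; an integer subsamples instances with the config seed.
    """

    k_neighbors: int = 100
    n_sampled: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.n_sampled is not None and self.n_sampled < 1:
            raise ValueError("n_sampled must be >= 1 or None (all instances)")


@dataclass
class FeatureImportanceList:
    """Per-gene ReliefF weights for one (modality, fold, seed)."""

    gene_ids: list[str]
    weights: np.ndarray
    modality: str
    fold_index: int
    seed: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape != (len(self.gene_ids),):
            raise ValueError("one weight per gene required")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.gene_ids, self.weights.tolist()))


@dataclass
class GeneSelectionResult:
    """Everything the stability pipeline produces, down the intersection chain."""

    ranked_lists: dict[str, dict[int, list[tuple[str, float]]]]  # modality -> seed -> ranking
    top_sets: dict[str, dict[int, frozenset[str]]]               # modality -> seed -> top-N
    stable_sets: dict[str, frozenset[str]]                       # modality -> intersection over seeds
    final_genes: frozenset[str]                                  # cross-omics intersection
    union_genes: frozenset[str]                                  # cross-omics union
    top_n: int
    seeds: tuple[int, ...]


def _normalize(X: np.ndarray) -> np.ndarray:
    """Scale each attribute by its range so per-attribute diffs are |xi - yi|;
    zero-range attributes are constant and contribute 0 everywhere."""
    lo, hi = X.min(axis=0), X.max(axis=0)
    rng = hi - lo
    safe = np.where(rng > 0, rng, 1.0)
    Xn = (X - lo) / safe
    Xn[:, rng == 0] = 0.0
    return Xn


def diff_matrix(X: np.ndarray) -> np.ndarray:
    """Range-normalized copy of ``X``: diff(A, i, j) == |Xn[i,A] - Xn[j,A]|."""
    return _normalize(np.asarray(X, dtype=np.float64))


def _k_nearest(dist_row: np.ndarray, candidates: np.ndarray, k: int) -> np.ndarray:
    """Indices (into the full sample set) of the k candidates nearest under
    ``dist_row``; distance ties broken by sample order for determinism."""
    order = np.lexsort((candidates, dist_row[candidates]))
    return candidates[order[:k]]


def relieff_weights(
    X: np.ndarray,
    labels: np.ndarray,
    config: ReliefConfig,
    gene_ids: Sequence[str] | None = None,
    modality: str = "RNA",
    fold_index: int = 0,
) -> FeatureImportanceList:
    """ReliefF weights for a binary-labeled samples-x-genes matrix.

    Deterministic when every instance is scored (``n_sampled=None``).
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    n, m = X.shape
    if gene_ids is None:
        gene_ids = [f"F{j}" for j in range(m)]
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("binary labels required")
    min_class = min(int((labels == c).sum()) for c in classes)
    k = config.k_neighbors
    if min_class < 2:
        raise ValueError("each class needs at least 2 samples (one instance plus one hit)")
    if k > min_class - 1:
        warnings.warn(
            f"k_neighbors={k} exceeds smallest class size - 1 ({min_class - 1}); "
            f"clipping to {min_class - 1} (lower k_neighbors to silence)",
            UserWarning,
            stacklevel=2,
        )
        k = min_class - 1

    Xn = _normalize(X)
    dist = cdist(Xn, Xn, metric="cityblock")

    if config.n_sampled is None or config.n_sampled >= n:
        evaluated = np.arange(n)
    else:
        rng = np.random.default_rng(config.seed)
        evaluated = np.sort(rng.choice(n, size=config.n_sampled, replace=False))
    n_eval = len(evaluated)

    W = np.zeros(m, dtype=np.float64)
    idx_by_class = {c: np.where(labels == c)[0] for c in classes}
    for i in evaluated:
        same = idx_by_class[labels[i]]
        same = same[same != i]  # an instance is never its own hit
        other = idx_by_class[classes[0] if labels[i] == classes[1] else classes[1]]
        hits = _k_nearest(dist[i], same, k)
        misses = _k_nearest(dist[i], other, k)
        hit_diff = np.abs(Xn[hits] - Xn[i]).mean(axis=0)
        miss_diff = np.abs(Xn[misses] - Xn[i]).mean(axis=0)
        W += (miss_diff - hit_diff) / n_eval
    return FeatureImportanceList(list(gene_ids), W, modality, fold_index, config.seed)


def run_fold_selection(
    cohort: LabeledCohort,
    fold_plan: FoldPlan,
    config: ReliefConfig,
    modalities: Sequence[str] = ("RNA", "CNV"),
) -> dict[str, list[FeatureImportanceList]]:
    """ReliefF on each fold's *train split only*, per modality.

    Validation samples never enter the weight computation (no leakage).
    """
    pos = {s: i for i, s in enumerate(cohort.common_sample_ids)}
    out: dict[str, list[FeatureImportanceList]] = {m: [] for m in modalities}
    for modality in modalities:
        matrix = cohort.modality(modality)
        for fold_index, (train_ids, _val_ids) in enumerate(fold_plan.folds):
            rows = [pos[s] for s in train_ids]
            out[modality].append(
                relieff_weights(
                    matrix.values[rows],
                    cohort.labels[rows],
                    config,
                    gene_ids=matrix.gene_ids,
                    modality=modality,
                    fold_index=fold_index,
                )
            )
    return out


def rank_and_aggregate_folds(
    lists: Sequence[FeatureImportanceList],
) -> list[tuple[str, float]]:
    """Cumulative importance = sum of per-fold weights per gene; sorted by
    score descending, score ties broken lexicographically by gene ID."""
    if not lists:
        raise ValueError("at least one importance list required")
    universe = lists[0].gene_ids
    for lst in lists[1:]:
        if lst.gene_ids != universe:
            raise ValueError("importance lists cover different gene universes")
    cumulative = np.sum([lst.weights for lst in lists], axis=0)
    order = sorted(range(len(universe)), key=lambda j: (-cumulative[j], universe[j]))
    return [(universe[j], float(cumulative[j])) for j in order]


def select_top_n(ranked: Sequence[tuple[str, float]], n: int) -> frozenset[str]:
    """First n genes of an aggregated ranking."""
    if n > len(ranked):
        raise ValueError(f"cannot select top {n} from a ranking of {len(ranked)} genes")
    return frozenset(g for g, _ in ranked[:n])


def stable_gene_set(per_seed_sets: Sequence[frozenset[str]]) -> frozenset[str]:
    """Intersection of the per-seed top-N sets for one modality."""
    if not per_seed_sets:
        raise ValueError("at least one per-seed set required")
    stable = frozenset.intersection(*map(frozenset, per_seed_sets))
    if not stable:
        logger.warning("per-seed top-N sets are disjoint; stable set is empty")
    return stable


def cross_omics_intersection(stable_rna: frozenset[str], stable_cnv: frozenset[str]) -> frozenset[str]:
    """Genes consistently top-ranked in *both* modalities."""
    return frozenset(stable_rna) & frozenset(stable_cnv)


def union_gene_set(stable_rna: frozenset[str], stable_cnv: frozenset[str]) -> frozenset[str]:
    """Union counterpart, for the union-vs-intersection comparison."""
    return frozenset(stable_rna) | frozenset(stable_cnv)


def stability_selection(
    cohort: LabeledCohort,
    k: int,
    seeds: Sequence[int],
    top_n: int = 500,
    k_neighbors: int = 100,
    modalities: Sequence[str] = ("RNA", "CNV"),
) -> GeneSelectionResult:
    """The full pipeline: per-seed fold plans -> per-fold ReliefF on train
    splits -> cumulative per-seed rankings -> top-N per seed -> within-omics
    intersection over seeds -> cross-omics intersection (and union)."""
    seeds = tuple(seeds)
    if len(set(seeds)) != len(seeds):
        raise ValueError("duplicate seeds")
    ranked_lists: dict[str, dict[int, list[tuple[str, float]]]] = {m: {} for m in modalities}
    top_sets: dict[str, dict[int, frozenset[str]]] = {m: {} for m in modalities}
    for seed in seeds:
        plan = make_fold_plan(cohort.common_sample_ids, cohort.labels, k, seed)
        config = ReliefConfig(k_neighbors=k_neighbors, seed=seed)
        per_fold = run_fold_selection(cohort, plan, config, modalities)
        for modality in modalities:
            ranking = rank_and_aggregate_folds(per_fold[modality])
            ranked_lists[modality][seed] = ranking
            top_sets[modality][seed] = select_top_n(ranking, top_n)
    stable_sets = {
        m: stable_gene_set([top_sets[m][s] for s in seeds]) for m in modalities
    }
    final = cross_omics_intersection(stable_sets[modalities[0]], stable_sets[modalities[1]])
    union = union_gene_set(stable_sets[modalities[0]], stable_sets[modalities[1]])
    return GeneSelectionResult(
        ranked_lists=ranked_lists,
        top_sets=top_sets,
        stable_sets=stable_sets,
        final_genes=final,
        union_genes=union,
        top_n=top_n,
        seeds=seeds,
    )
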