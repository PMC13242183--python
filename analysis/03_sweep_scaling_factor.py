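"""Sweep the fusion scaling factor k and record the fused-accuracy curve.

Small k keeps the weights near 0.5 (soft voting); large k hands the
decision to the per-fold more-accurate modality.  Writes the per-k pooled
fused accuracy (averaged over seeds) to results/k_sweep.tsv.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
from study_config import CV_SEEDS, K_FOLDS, MODEL_NAME, STUDY

from omicsfuse.bench import ClassifierSpec, repeat_over_seeds
from omicsfuse.fusion import sweep_k
from omicsfuse.synthetic import generate_cohort

ROOT = Path(__file__).resolve().parents[1]
K_GRID = list(range(2, 31))


def main() -> None:
    raw, _ = generate_cohort(STUDY)
    cohort = raw.to_labeled(normalize=True)
    label_of = dict(zip(cohort.common_sample_ids, cohort.labels))
    runs = repeat_over_seeds(cohort, ClassifierSpec(MODEL_NAME), K_FOLDS, CV_SEEDS)

    curves = []
    for run in runs.values():
        preds = run["predictions"]
        curve = sweep_k(preds["RNA"], preds["CNV"], label_of, K_GRID)
        curves.append([acc for _, acc in curve])
    mean_curve = np.mean(curves, axis=0)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    out = results / "k_sweep.tsv"
    with out.open("w") as fh:
        fh.write("k\tfused_accuracy_mean\n")
        for k, acc in zip(K_GRID, mean_curve):
            fh.write(f"{k}\t{acc:.4f}\n")

    lo, hi = mean_curve.min(), mean_curve.max()
    print(f"fused accuracy over k in [{K_GRID[0]}, {K_GRID[-1]}]: "
          f"min {lo:.4f}, max {hi:.4f}, at k=10: {mean_curve[K_GRID.index(10)]:.4f}")
    print(f"-> {out}")


if __name__ == "__main__":
    main()
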