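"""Re-evaluate the classifiers on the discovered gene panel.

Restricts both modalities to the final cross-omics gene set from
analysis/04, reruns the cross-validated benchmark and fusion, compares the
fused panel accuracy against the single-modality panels (Mann-Whitney with
rank-biserial effect size), and summarizes pairwise expression correlations
within the panel.  Writes results/selected_gene_evaluation.json.
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
from study_config import CV_SEEDS, K_FOLDS, K_SCALE, MODEL_NAME, STUDY

from omicsfuse.bench import ClassifierSpec
from omicsfuse.evaluation import (
    evaluate_selected_genes,
    mann_whitney_compare,
    pairwise_pearson,
    render_report,
)
from omicsfuse.synthetic import generate_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    gene_file = ROOT / "results" / "final_genes.txt"
    if not gene_file.exists():
        sys.exit("run analysis/04_select_genes.py first (missing results/final_genes.txt)")
    genes = [g for g in gene_file.read_text().split() if g]

    raw, _ = generate_cohort(STUDY)
    cohort = raw.to_labeled(normalize=True)
    reports = evaluate_selected_genes(
        cohort, genes, ClassifierSpec(MODEL_NAME), k=K_FOLDS, seeds=CV_SEEDS, k_scale=K_SCALE
    )
    text, machine = render_report(
        reports,
        config={"genes": len(genes), "model": MODEL_NAME, "k": K_FOLDS, "seeds": list(CV_SEEDS)},
    )

    comp = mann_whitney_compare(
        [reports["fused"].per_seed[s].accuracy for s in CV_SEEDS],
        [reports["CNV"].per_seed[s].accuracy for s in CV_SEEDS],
        labels=("fused", "CNV"),
    )
    corr = pairwise_pearson(cohort.rna, genes)
    off_diag = corr[~np.eye(len(genes), dtype=bool)]
    machine["fused_vs_cnv_accuracy"] = comp.__dict__
    machine["panel_expression_correlation"] = {
        "mean_abs_offdiag": float(np.mean(np.abs(off_diag))),
        "max_abs_offdiag": float(np.max(np.abs(off_diag))),
    }

    results = ROOT / "results"
    (results / "selected_gene_evaluation.json").write_text(
        json.dumps(machine, indent=1, default=str) + "\n"
    )
    print(text)
    print(f"\nfused vs CNV accuracy on the panel: p={comp.p_value:.3f}, "
          f"effect={comp.effect_size:.2f}")
    print(f"panel expression correlation: mean |r| = "
          f"{machine['panel_expression_correlation']['mean_abs_offdiag']:.3f}")
    print(f"-> {results / 'selected_gene_evaluation.json'}")


if __name__ == "__main__":
    main()
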