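"""Discover discriminative genes by ReliefF stability selection.

Per seed: stratified 5-fold ReliefF on train splits, cumulative scores,
top-N cut; then intersect across seeds within each modality and finally
across modalities.  Compares the recovered sets against the generator's
planted ground truth.  Writes results/gene_selection.json and the final
gene list to results/final_genes.txt.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from study_config import CV_SEEDS, K_FOLDS, STUDY, TOP_N

from omicsfuse.relieff import stability_selection
from omicsfuse.synthetic import generate_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    raw, truth = generate_cohort(STUDY)
    cohort = raw.to_labeled(normalize=True)
    result = stability_selection(
        cohort, k=K_FOLDS, seeds=CV_SEEDS, top_n=TOP_N, k_neighbors=100
    )

    planted = truth.shared_informative | truth.rna_only_informative | truth.cnv_only_informative
    summary = {
        "top_n": TOP_N,
        "seeds": list(CV_SEEDS),
        "stable_set_sizes": {m: len(s) for m, s in result.stable_sets.items()},
        "final_gene_count": len(result.final_genes),
        "union_gene_count": len(result.union_genes),
        "shared_planted_recovered": len(result.final_genes & truth.shared_informative),
        "shared_planted_total": len(truth.shared_informative),
        "noise_genes_in_final": len(result.final_genes - planted),
        "final_genes": sorted(result.final_genes),
    }

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    (results / "gene_selection.json").write_text(json.dumps(summary, indent=1) + "\n")
    (results / "final_genes.txt").write_text("\n".join(sorted(result.final_genes)) + "\n")

    print(f"within-omics stable sets: {summary['stable_set_sizes']}")
    print(f"final cross-omics set: {summary['final_gene_count']} genes "
          f"({summary['shared_planted_recovered']}/{summary['shared_planted_total']} "
          f"shared planted recovered, {summary['noise_genes_in_final']} noise)")
    print(f"union set: {summary['union_gene_count']} genes")
    print(f"-> {results / 'gene_selection.json'}, {results / 'final_genes.txt'}")


if __name__ == "__main__":
    main()
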