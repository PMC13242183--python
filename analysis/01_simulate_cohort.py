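"""Simulate the paired two-modality study cohort and check its shape.

Writes the cohort TSVs (large) to scratch/cohort/ and a small summary of
the harmonization bookkeeping (sample overlap, class balance, planted-gene
counts) to results/cohort_summary.json.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from study_config import STUDY

from omicsfuse.preprocess import find_common_samples
from omicsfuse.synthetic import generate_cohort, write_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    raw, truth = generate_cohort(STUDY)
    common = find_common_samples(raw.rna, raw.cnv)
    cohort = raw.to_labeled(normalize=True)

    out = ROOT / "scratch" / "cohort"
    write_cohort(raw, out)
    (out / "ground_truth.json").write_text(truth.to_json())

    summary = {
        "config": {k: getattr(STUDY, k) for k in STUDY.__dataclass_fields__},
        "n_rna_samples": raw.rna.n_samples,
        "n_cnv_samples": raw.cnv.n_samples,
        "n_common_samples": len(common),
        "class_counts": {
            "0": int((cohort.labels == 0).sum()),
            "1": int((cohort.labels == 1).sum()),
        },
        "n_genes": {"RNA": raw.rna.n_genes, "CNV": raw.cnv.n_genes},
        "planted": {
            "shared": len(truth.shared_informative),
            "rna_only": len(truth.rna_only_informative),
            "cnv_only": len(truth.cnv_only_informative),
        },
    }
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    (results / "cohort_summary.json").write_text(json.dumps(summary, indent=1) + "\n")

    print(f"RNA matrix: {raw.rna.n_samples} x {raw.rna.n_genes}")
    print(f"CNV matrix: {raw.cnv.n_samples} x {raw.cnv.n_genes}")
    print(f"common samples: {len(common)} "
          f"(class 0: {summary['class_counts']['0']}, class 1: {summary['class_counts']['1']})")
    print(f"planted genes: {summary['planted']}")
    print(f"cohort TSVs -> {out}, summary -> {results / 'cohort_summary.json'}")


if __name__ == "__main__":
    main()
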