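"""Synthetic paired-multiomics cohort generator with known planted genes.

Emulates the statistical shape of a paired lung-cancer subtype cohort: two
real-valued gene-by-sample modalities (expression-like and copy-number-like)
over mostly-overlapping sample sets with barcode-like IDs, near-balanced
binary classes, many more genes than samples, and a small set of planted
class-discriminative genes that are either shared between the modalities or
specific to one of them, with unequal per-modality signal strength.

The model is deliberately simple: each gene is standard normal within class,
genes are grouped into equicorrelated blocks (a shared Gaussian factor per
block), and an informative gene shifts its class-1 mean by the configured
effect size in sigma units.  Blocks never straddle the informative/noise
boundary so the ground truth stays unambiguous.  The generator does not
emulate raw read counts, library-size effects, segmentation artifacts,
survival times or batch effects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import OmicsMatrix, load_matrix, load_labels, build_cohort, LabeledCohort

__all__ = [
    "SimConfig",
    "SyntheticGroundTruth",
    "RawCohort",
    "generate_cohort",
    "write_cohort",
    "load_raw_cohort",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic paired cohort.

    Defaults mirror the real cohort this generator emulates: with the default
    dropout fractions the two modalities cover ~1126 and ~1016 samples and
    overlap in ~988 common samples, ~505 vs ~483 per subtype after pairing.
    Gene counts are scaled to 2000 per modality (still a
    high-dimension-low-sample-size shape) and the expression signal is
    stronger than the copy-number signal by default.
    """

    n_class0: int = 590
    n_class1: int = 565
    n_genes_rna: int = 2000
    n_genes_cnv: int = 2000
    n_shared_informative: int = 30
    n_rna_only_informative: int = 10
    n_cnv_only_informative: int = 10
    effect_size_rna: float = 1.5  # class-1 mean shift, sigma units
    effect_size_cnv: float = 1.0
    block_size: int = 10
    block_rho: float = 0.3
    dropout_fraction_rna: float = 0.025  # fraction of samples present only in CNV
    dropout_fraction_cnv: float = 0.12   # fraction of samples present only in RNA
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_class0, self.n_class1, self.n_genes_rna, self.n_genes_cnv,
            self.n_shared_informative, self.n_rna_only_informative,
            self.n_cnv_only_informative, self.block_size,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be nonnegative")
        if self.block_size == 0:
            raise ValueError("block_size must be >= 1")
        n_inf_rna = self.n_shared_informative + self.n_rna_only_informative
        n_inf_cnv = self.n_shared_informative + self.n_cnv_only_informative
        # modality-specific genes of the *other* modality still occupy IDs here
        if n_inf_rna + self.n_cnv_only_informative > self.n_genes_rna:
            raise ValueError("informative gene counts exceed n_genes_rna")
        if n_inf_cnv + self.n_rna_only_informative > self.n_genes_cnv:
            raise ValueError("informative gene counts exceed n_genes_cnv")
        if not (0.0 <= self.block_rho < 1.0):
            raise ValueError("block_rho must be in [0, 1)")
        for f in (self.dropout_fraction_rna, self.dropout_fraction_cnv):
            if not (0.0 <= f < 1.0):
                raise ValueError("dropout fractions must be in [0, 1)")
        if self.dropout_fraction_rna + self.dropout_fraction_cnv >= 1.0:
            raise ValueError("dropout fractions must sum to < 1")


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Oracle for recovery tests: which gene IDs carry planted signal where."""

    shared_informative: frozenset[str]
    rna_only_informative: frozenset[str]
    cnv_only_informative: frozenset[str]
    noise_genes: dict[str, frozenset[str]]  # per modality

    def informative(self, modality: str) -> frozenset[str]:
        if modality == "RNA":
            return self.shared_informative | self.rna_only_informative
        if modality == "CNV":
            return self.shared_informative | self.cnv_only_informative
        raise KeyError(modality)

    def to_json(self) -> str:
        payload = {
            "shared_informative": sorted(self.shared_informative),
            "rna_only_informative": sorted(self.rna_only_informative),
            "cnv_only_informative": sorted(self.cnv_only_informative),
            "noise_genes": {m: sorted(g) for m, g in sorted(self.noise_genes.items())},
        }
        return json.dumps(payload, indent=1)


@dataclass
class RawCohort:
    """Pre-harmonization synthetic dataset: the two modalities may cover
    different (overlapping) sample sets; labels cover every generated sample."""

    rna: OmicsMatrix
    cnv: OmicsMatrix
    labels: pd.Series  # sample_id -> {0,1}, all samples before dropout

    def to_labeled(self, normalize: bool = False) -> LabeledCohort:
        """Harmonize onto common samples via the standard preprocessing path."""
        return build_cohort(self.rna, self.cnv, self.labels, normalize=normalize)


def _barcode(i: int) -> str:
    # PROJ-TT-PPPP-SS, mirroring the 4-field hierarchical barcode layout
    return f"SYN-{i % 90 + 10:02d}-{i:04d}-01"


def _block_noise(rng: np.random.Generator, n: int, n_genes: int, block_size: int, rho: float) -> np.ndarray:
    """Unit-variance Gaussian noise with equicorrelation ``rho`` inside
    consecutive blocks of ``block_size`` genes (shared factor per block)."""
    eps = rng.standard_normal((n, n_genes))
    if rho <= 0.0 or n_genes == 0:
        return eps
    out = np.empty_like(eps)
    s_rho, s_1mrho = np.sqrt(rho), np.sqrt(1.0 - rho)
    for start in range(0, n_genes, block_size):
        stop = min(start + block_size, n_genes)
        factor = rng.standard_normal((n, 1))
        out[:, start:stop] = s_rho * factor + s_1mrho * eps[:, start:stop]
    return out


def generate_cohort(config: SimConfig) -> tuple[RawCohort, SyntheticGroundTruth]:
    """Generate one paired cohort; a pure function of the config (incl. seed).

    Gene IDs live in a single namespace shared by the two modalities (as real
    gene symbols do), with planted genes occupying the leading IDs: first the
    shared-informative block, then the RNA-only block, then the CNV-only
    block, then noise.  Each modality draws independent measurement noise; the
    shared-informative genes carry the configured class-1 mean shift in both
    modalities, the modality-specific ones in theirs only.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_class0 + config.n_class1
    sample_ids = [_barcode(i) for i in range(n)]
    labels = np.concatenate([np.zeros(config.n_class0, np.int64), np.ones(config.n_class1, np.int64)])
    # shuffle so classes are not contiguous in sample order
    perm = rng.permutation(n)
    labels = labels[perm]

    n_sh, n_r, n_c = (
        config.n_shared_informative,
        config.n_rna_only_informative,
        config.n_cnv_only_informative,
    )
    n_planted = n_sh + n_r + n_c
    gene_ids = [f"G{j:05d}" for j in range(max(config.n_genes_rna, config.n_genes_cnv))]
    shared_ids = gene_ids[:n_sh]
    rna_only_ids = gene_ids[n_sh:n_sh + n_r]
    cnv_only_ids = gene_ids[n_sh + n_r:n_planted]

    def one_modality(modality: str, n_genes: int, effect: float, informative_cols: np.ndarray) -> OmicsMatrix:
        # planted region and noise region get separate block structure so no
        # block straddles the informative/noise boundary
        planted = _block_noise(rng, n, n_planted, config.block_size, config.block_rho)
        noise = _block_noise(rng, n, n_genes - n_planted, config.block_size, config.block_rho)
        values = np.concatenate([planted, noise], axis=1)
        if informative_cols.size:
            values[np.ix_(labels == 1, informative_cols)] += effect
        return OmicsMatrix(modality, sample_ids, gene_ids[:n_genes], values)

    rna_cols = np.arange(n_sh + n_r)                       # shared + RNA-only
    cnv_cols = np.concatenate([np.arange(n_sh), np.arange(n_sh + n_r, n_planted)])
    rna = one_modality("RNA", config.n_genes_rna, config.effect_size_rna, rna_cols)
    cnv = one_modality("CNV", config.n_genes_cnv, config.effect_size_cnv, cnv_cols)

    # dropout: disjoint sample subsets present in only the other modality
    n_drop_rna = int(round(config.dropout_fraction_rna * n))
    n_drop_cnv = int(round(config.dropout_fraction_cnv * n))
    order = rng.permutation(n)
    drop_rna = set(order[:n_drop_rna])
    drop_cnv = set(order[n_drop_rna:n_drop_rna + n_drop_cnv])
    keep_rna = [s for i, s in enumerate(sample_ids) if i not in drop_rna]
    keep_cnv = [s for i, s in enumerate(sample_ids) if i not in drop_cnv]
    rna = rna.restrict_samples(keep_rna)
    cnv = cnv.restrict_samples(keep_cnv)

    truth = SyntheticGroundTruth(
        shared_informative=frozenset(shared_ids),
        rna_only_informative=frozenset(rna_only_ids),
        cnv_only_informative=frozenset(cnv_only_ids),
        noise_genes={
            "RNA": frozenset(gene_ids[n_planted:config.n_genes_rna]),
            "CNV": frozenset(gene_ids[n_planted:config.n_genes_cnv]),
        },
    )
    return RawCohort(rna, cnv, pd.Series(labels, index=sample_ids)), truth


def write_cohort(cohort: RawCohort, directory: str | Path) -> dict[str, Path]:
    """Write the cohort as genes-as-rows TSVs plus a labels TSV.

    Round-trips losslessly through :func:`omicsfuse.preprocess.load_matrix`
    (values are written with full float repr).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, m in (("rna", cohort.rna), ("cnv", cohort.cnv)):
        path = directory / f"{name}.tsv"
        df = m.to_frame().T  # genes as rows
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")  # default shortest-repr floats round-trip exactly
        paths[name] = path
    lpath = directory / "labels.tsv"
    pd.DataFrame({"sample_id": cohort.labels.index, "label": cohort.labels.to_numpy()}).to_csv(
        lpath, sep="\t", index=False
    )
    paths["labels"] = lpath
    return paths


def load_raw_cohort(directory: str | Path) -> RawCohort:
    """Inverse of :func:`write_cohort`."""
    directory = Path(directory)
    rna = load_matrix(directory / "rna.tsv", "genes_as_rows", "RNA")
    cnv = load_matrix(directory / "cnv.tsv", "genes_as_rows", "CNV")
    labels = load_labels(directory / "labels.tsv")
    return RawCohort(rna, cnv, labels)
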