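"""Loading, harmonization and normalization of paired omics matrices.

Two modalities (an RNA-seq expression matrix and a GISTIC2-style gene-level
copy-number matrix) are measured over mostly-overlapping sample sets identified
by hierarchical, hyphen-delimited barcodes.  Decision-level fusion needs the
two modalities restricted to the samples present in both, in identical order,
with a binary subtype label per sample.  This module provides the container
types, the TSV loaders for the two common on-disk orientations, the barcode
parser used for sample matching, a missing-value audit, and sample-wise
z-score normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OmicsMatrix",
    "SampleBarcode",
    "LabeledCohort",
    "MissingReport",
    "load_matrix",
    "load_labels",
    "parse_barcode",
    "find_common_samples",
    "zscore_by_sample",
    "audit_missing",
    "build_cohort",
]

MODALITIES = ("RNA", "CNV", "JOINT")


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dupes = set(), []
        for i in ids:
            if i in seen:
                dupes.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what} IDs: {sorted(set(dupes))[:5]}")


@dataclass
class OmicsMatrix:
    """One modality's samples-by-genes real-valued matrix.

    The canonical in-memory orientation is samples x genes regardless of the
    on-disk dialect.  ``values`` may contain NaN until :func:`audit_missing`
    has passed; all downstream analysis steps assume finite values.
    """

    modality: str
    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        self.sample_ids = list(self.sample_ids)
        self.gene_ids = list(self.gene_ids)
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.gene_ids, "gene")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    def restrict_samples(self, ids: Sequence[str]) -> "OmicsMatrix":
        """Subset/reorder samples to ``ids`` (all must be present)."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        idx = [pos[s] for s in ids]
        return OmicsMatrix(self.modality, list(ids), self.gene_ids, self.values[idx])

    def restrict_genes(self, ids: Sequence[str]) -> "OmicsMatrix":
        """Subset/reorder genes to ``ids`` (all must be present)."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in ids if g not in pos]
        if missing:
            raise KeyError(f"genes not in {self.modality} matrix: {missing[:10]}")
        idx = [pos[g] for g in ids]
        return OmicsMatrix(self.modality, self.sample_ids, list(ids), self.values[:, idx])


@dataclass(frozen=True)
class SampleBarcode:
    """Hierarchical sample identifier: project - tissue source site -
    participant - sample, joined with '-'."""

    project: str
    tss: str
    participant: str
    sample: str

    def __str__(self) -> str:
        return "-".join((self.project, self.tss, self.participant, self.sample))


@dataclass
class LabeledCohort:
    """The paired two-modality dataset restricted to common samples.

    Invariant: ``rna.sample_ids == cnv.sample_ids == common_sample_ids`` and
    every common sample carries a binary label.
    """

    rna: OmicsMatrix
    cnv: OmicsMatrix
    labels: np.ndarray
    common_sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.common_sample_ids:
            self.common_sample_ids = list(self.rna.sample_ids)
        if self.rna.sample_ids != self.common_sample_ids or self.cnv.sample_ids != self.common_sample_ids:
            raise ValueError("rna/cnv sample IDs must equal common_sample_ids in order")
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != (len(self.common_sample_ids),):
            raise ValueError("one label per common sample required")
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise ValueError(f"labels must be binary 0/1, got extra values {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.common_sample_ids)

    def modality(self, name: str) -> OmicsMatrix:
        if name == "RNA":
            return self.rna
        if name == "CNV":
            return self.cnv
        raise KeyError(name)

    def restrict_genes(self, gene_ids: Sequence[str]) -> "LabeledCohort":
        return LabeledCohort(
            self.rna.restrict_genes(gene_ids),
            self.cnv.restrict_genes(gene_ids),
            self.labels,
            self.common_sample_ids,
        )


@dataclass(frozen=True)
class MissingReport:
    count: int
    locations: tuple[tuple[str, str], ...]  # first-k (sample, gene) addresses

    @property
    def ok(self) -> bool:
        return self.count == 0


def parse_barcode(sample_id: str) -> SampleBarcode:
    """Split a barcode-like ID positionally into its four leading fields."""
    fields = sample_id.split("-")
    if len(fields) < 4:
        raise ValueError(
            f"barcode {sample_id!r} has {len(fields)} '-'-separated fields; at least 4 required"
        )
    return SampleBarcode(fields[0], fields[1], fields[2], "-".join(fields[3:]))


def load_matrix(path: str | Path, dialect: str, modality: str) -> OmicsMatrix:
    """Read a TSV matrix in either orientation into canonical samples x genes.

    ``genes_as_rows`` is the Xena-style dialect (first column gene ID, one
    column per sample); ``samples_as_rows`` is the transpose.  Blank cells are
    read as NaN and left for :func:`audit_missing`; any other non-numeric cell
    raises with its row/column address.
    """
    if dialect not in ("genes_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    try:
        # numpy's string->float conversion round-trips exactly; blanks are NaN
        numeric = df.astype(np.float64)
    except (ValueError, TypeError):
        for c, col in enumerate(df.columns):
            for r, cell in enumerate(df.iloc[:, c]):
                if isinstance(cell, str) and cell.strip() != "":
                    try:
                        float(cell)
                    except ValueError:
                        raise ValueError(
                            f"non-numeric cell {cell!r} at row {df.index[r]!r}, "
                            f"column {col!r} in {path}"
                        ) from None
        raise
    if dialect == "genes_as_rows":
        numeric = numeric.T  # now samples x genes
    return OmicsMatrix(
        modality,
        [str(s) for s in numeric.index],
        [str(g) for g in numeric.columns],
        numeric.to_numpy(dtype=np.float64),
    )


def load_labels(path: str | Path) -> pd.Series:
    """Read a two-column (sample_id, label) TSV into a Series."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"label table {path} must have two columns (sample_id, label)")
    s = pd.Series(df.iloc[:, 1].to_numpy(dtype=np.int64), index=df.iloc[:, 0].astype(str))
    _check_unique(list(s.index), "label-table sample")
    return s


def find_common_samples(a: OmicsMatrix, b: OmicsMatrix) -> list[str]:
    """Samples present in both matrices, ordered by first appearance in ``a``."""
    in_b = set(b.sample_ids)
    common = [s for s in a.sample_ids if s in in_b]
    if not common:
        raise ValueError("no common samples between the two modalities; fusion impossible")
    return common


def zscore_by_sample(m: OmicsMatrix) -> OmicsMatrix:
    """Scale every sample row to mean 0 and (population) standard deviation 1.

    Constant rows are degenerate and map to all-zero rows rather than raising;
    they carry no within-sample contrast.
    """
    centered = m.values - m.values.mean(axis=1, keepdims=True)
    # second centering pass kills the cancellation residue left when the
    # per-row offset dwarfs the spread
    centered -= centered.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1, keepdims=True)  # population convention (ddof=0)
    out = np.divide(centered, sd, out=np.zeros_like(centered), where=sd > 0)
    return OmicsMatrix(m.modality, m.sample_ids, m.gene_ids, out)


def audit_missing(m: OmicsMatrix, max_locations: int = 10) -> MissingReport:
    """Count NaN cells and report the first few (sample, gene) addresses."""
    mask = np.isnan(m.values)
    count = int(mask.sum())
    locs = []
    if count:
        for r, c in np.argwhere(mask)[:max_locations]:
            locs.append((m.sample_ids[r], m.gene_ids[c]))
    return MissingReport(count, tuple(locs))


def build_cohort(
    rna: OmicsMatrix,
    cnv: OmicsMatrix,
    labels: Mapping[str, int] | pd.Series,
    normalize: bool = True,
) -> LabeledCohort:
    """Restrict both modalities to common samples, attach labels, optionally
    z-score each modality sample-wise.

    Missing values must have been audited away first; normalization (applied
    after restriction, so it sees exactly the analyzed samples) would silently
    propagate NaNs otherwise.
    """
    for m in (rna, cnv):
        rep = audit_missing(m)
        if not rep.ok:
            raise ValueError(
                f"{m.modality} matrix has {rep.count} missing cells "
                f"(first at {rep.locations[0]}); refusing to build cohort"
            )
    common = find_common_samples(rna, cnv)
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    missing = [s for s in common if s not in labels]
    if missing:
        raise ValueError(f"samples without a label: {missing[:5]}")
    y = np.array([labels[s] for s in common], dtype=np.int64)
    rna_c = rna.restrict_samples(common)
    cnv_c = cnv.restrict_samples(common)
    if normalize:
        rna_c = zscore_by_sample(rna_c)
        cnv_c = zscore_by_sample(cnv_c)
    return LabeledCohort(rna_c, cnv_c, y, common)
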