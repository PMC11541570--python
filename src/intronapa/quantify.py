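"""Truncation-ratio (TR) quantification from transcript-level TPM matrices.

Per gene g and sample s,

    TR(g, s) = sum TPM of g's intronic-APA isoforms
               ------------------------------------------------
               sum TPM of all labeled isoforms (APA + full-length)

TR is the central per-gene statistic of the workflow: it is a proportion in
[0, 1], missing wherever the denominator is zero.  No pseudocount is added.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .annotation import APA, FULL_LENGTH, GeneModel


@dataclass
class TruncationRatioMatrix:
    """Genes x samples TR values with the retained numerator/denominator.

    ``tr`` holds NaN where ``total_sum`` is zero.  All three frames share
    index (gene_id) and columns (sample_id).
    """

    tr: pd.DataFrame
    apa_sum: pd.DataFrame
    total_sum: pd.DataFrame

    def __post_init__(self):
        valid = self.total_sum.to_numpy() > 0
        vals = self.tr.to_numpy()
        assert np.all(np.isnan(vals[~valid])), "TR must be missing where total==0"
        finite = vals[valid]
        assert np.all((finite >= 0) & (finite <= 1 + 1e-12)), "TR outside [0,1]"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.tr.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.tr.columns)

    def to_tsv(self, tr_path, parts_path=None) -> None:
        self.tr.to_csv(tr_path, sep="\t", index_label="gene_id")
        if parts_path is not None:
            parts = pd.concat(
                {"apa_sum": self.apa_sum, "total_sum": self.total_sum}, axis=1
            )
            parts.to_csv(parts_path, sep="\t", index_label="gene_id")


def read_expression(path) -> pd.DataFrame:
    """Read a transcript x sample TPM matrix (TSV/CSV, gzip-transparent)."""
    sep = "," if str(path).rstrip(".gz").endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        raise ValueError("duplicate transcript ids in expression matrix")
    if df.columns.has_duplicates:
        raise ValueError("duplicate sample ids in expression matrix")
    if (df.to_numpy() < 0).any():
        raise ValueError("negative expression values")
    return df


def _label_frames(genes: Iterable[GeneModel]) -> pd.DataFrame:
    rows = []
    for g in genes:
        for tid, label in g.labels.items():
            rows.append((g.gene_id, tid, label))
    return pd.DataFrame(rows, columns=["gene_id", "transcript_id", "label"])


def gene_expression(
    expr: pd.DataFrame, genes: Iterable[GeneModel]
) -> tuple[pd.DataFrame, list[str]]:
    """Sum labeled transcript TPM to gene level.

    Transcripts in the annotation but absent from the matrix contribute 0;
    matrix transcripts not claimed by any gene are returned as orphans
    (second element), never an error.
    """
    labels = _label_frames(genes)
    present = labels[labels.transcript_id.isin(expr.index)]
    sub = expr.loc[present.transcript_id]
    sub.index = pd.Index(present.gene_id, name="gene_id")
    gene_tpm = sub.groupby(level=0).sum()
    gene_tpm = gene_tpm.reindex(labels.gene_id.unique(), fill_value=0.0)
    orphans = sorted(set(expr.index) - set(labels.transcript_id))
    return gene_tpm, orphans


def filter_low_expression(gene_matrix: pd.DataFrame, min_tpm: float = 1.0) -> list[str]:
    """Genes retained iff TPM >= min_tpm in at least one sample."""
    keep = (gene_matrix >= min_tpm).any(axis=1)
    return list(gene_matrix.index[keep])


def truncation_ratio(
    expr: pd.DataFrame,
    genes: Iterable[GeneModel],
    min_tpm: float = 1.0,
    apply_filter: bool = True,
) -> TruncationRatioMatrix:
    """Compute the TR matrix over genes passing the low-expression filter.

    Genes with no APA isoform get TR identically 0 (they are kept; the
    differential stage can never call them).  Cells with zero total
    expression are missing (NaN).
    """
    genes = list(genes)
    labels = _label_frames(genes)

    def _sum_for(label_set) -> pd.DataFrame:
        sel = labels[labels.label.isin(label_set)]
        present = sel[sel.transcript_id.isin(expr.index)]
        sub = expr.loc[present.transcript_id]
        sub.index = pd.Index(present.gene_id, name="gene_id")
        out = sub.groupby(level=0).sum()
        return out.reindex(labels.gene_id.unique(), fill_value=0.0)

    apa_sum = _sum_for({APA})
    total_sum = _sum_for({APA, FULL_LENGTH})

    if apply_filter:
        keep = filter_low_expression(total_sum, min_tpm)
        apa_sum = apa_sum.loc[keep]
        total_sum = total_sum.loc[keep]

    with np.errstate(invalid="ignore", divide="ignore"):
        tr = apa_sum / total_sum
    tr = tr.where(total_sum > 0)
    return TruncationRatioMatrix(tr=tr, apa_sum=apa_sum, total_sum=total_sum)
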