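"""RNA-side quantification: TPM, expressed-gene filter, differential
expression classes, regulated-set Venn logic, and relative qPCR fold change.

TPM for gene g in sample s is the length-normalized count rate scaled so
each sample column sums to one million. A gene is "expressed" when its TPM
strictly exceeds 0.5 in at least one sample across all treatments; the
expressed universe (optionally restricted to protein-coding biotypes) is the
set on which differential expression is tested. Differential genes use
FDR < 0.05 with |log2 fold change| >= 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .nbstats import CountMatrix, NBTestResult, classify, nb_wald_test


@dataclass
class ExpressionTable:
    tpm: pd.DataFrame  # genes x samples, columns sum to 1e6
    expressed: pd.Series  # bool per gene (max TPM > threshold)
    threshold: float


@dataclass
class QPCRRecord:
    """Cycle thresholds for one target/control gene pair, one sample."""

    ct_target_treatment: float
    ct_control_treatment: float
    ct_target_vehicle: float
    ct_control_vehicle: float

    def __post_init__(self) -> None:
        for v in (
            self.ct_target_treatment,
            self.ct_control_treatment,
            self.ct_target_vehicle,
            self.ct_control_vehicle,
        ):
            if not np.isfinite(v) or v <= 0:
                raise ValueError("all Ct values must be finite and positive")


def tpm_normalize(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    expressed_threshold: float = 0.5,
    biotype: Optional[pd.Series] = None,
    keep_biotypes: Sequence[str] = ("protein_coding",),
) -> ExpressionTable:
    """Transcripts-per-million normalization with the expressed-gene flag.

    ``gene_lengths`` is transcript length in bp per gene. When a biotype
    series is supplied, genes outside ``keep_biotypes`` are dropped before
    normalization.
    """
    if biotype is not None:
        keep = biotype.reindex(counts.index).isin(set(keep_biotypes))
        counts = counts.loc[keep]
    missing = counts.index[~counts.index.isin(gene_lengths.index)]
    if len(missing):
        raise ValueError(f"missing gene lengths for: {list(missing[:5])}...")
    lengths = gene_lengths.loc[counts.index].astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths / 1000.0, axis=0)
    tpm = rate.div(rate.sum(axis=0), axis=1) * 1e6
    expressed = tpm.max(axis=1) > expressed_threshold
    return ExpressionTable(tpm, expressed, expressed_threshold)


def filter_expressed(table: ExpressionTable, threshold: float | None = None) -> set[str]:
    """Gene ids whose max TPM strictly exceeds the threshold in any sample."""
    thr = table.threshold if threshold is None else threshold
    mask = table.tpm.max(axis=1) > thr
    return set(table.tpm.index[mask])


def differential_expression(
    counts: CountMatrix,
    cond_a: str,
    cond_b: str,
    expressed: set[str],
    fdr_cut: float = 0.05,
    log2fc_cut: float = 0.5,
) -> list[NBTestResult]:
    """NB test restricted to expressed genes, classified at expression cuts."""
    keep = [g for g in counts.counts.index if g in expressed]
    sub = CountMatrix(counts.counts.loc[keep], counts.condition, counts.replicate)
    res = nb_wald_test(sub, cond_a, cond_b)
    return classify(res, fdr_cut=fdr_cut, fc_cut=log2fc_cut, fc_scale="log2")


def venn_gene_sets(sets: dict[str, Sequence[str]]) -> dict[tuple[str, str], dict]:
    """Pairwise shared/unique counts for named gene-id sets."""
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    names = list(sets)
    as_sets = {n: set(s) for n, s in sets.items()}
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            sa, sb = as_sets[a], as_sets[b]
            out[(a, b)] = {
                "shared": len(sa & sb),
                "unique_a": len(sa - sb),
                "unique_b": len(sb - sa),
            }
    return out


def fold_change_ddct(rec: QPCRRecord) -> float:
    """Relative expression by the 2^-(ddCt) method.

    dCt = Ct(target) - Ct(control) within each treatment; ddCt is
    dCt(treatment) - dCt(vehicle); the fold change is 2^-ddCt.
    """
    dct_treatment = rec.ct_target_treatment - rec.ct_control_treatment
    dct_vehicle = rec.ct_target_vehicle - rec.ct_control_vehicle
    return float(2.0 ** -(dct_treatment - dct_vehicle))
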