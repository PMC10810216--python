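"""Headline cistrome classifications: chromatin pre-accessibility of binding
sites, replacement of one factor's sites by another, and peak-to-gene TSS
distance distributions with KS testing.

A binding site is *pre-accessible* when its basal (untreated) accessibility
signal exceeds 1 on the log2 depth-normalized tag scale, and *de novo*
otherwise; sites exactly at the boundary are labelled pre-accessible.
Replacement is quantified from the first factor's perspective: the fraction
of its sites directly overlapped by at least one site of the second factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import PeakSet, overlap
from .nbstats import KSResult, ks_test_two_sample
from .tagsignal import TagLibrary, site_log2_density

ACCESSIBILITY_LOG2_CUT = 1.0


@dataclass
class AccessibilityCall:
    site_id: str
    log2_tags_untreated: float
    label: str  # "pre_accessible" or "de_novo"


@dataclass
class ReplacementSummary:
    n_ar: int
    n_gr: int
    n_ar_replaced: int
    fraction_replaced: float
    fraction_gr_shared: float  # symmetric view: GR sites overlapping AR
    venn: dict  # {"a_only": ..., "shared": ..., "b_only": ...}


@dataclass
class DistanceCDF:
    set_name: str
    bin_edges: np.ndarray  # 0, 10 kb, ..., 100 kb
    cumulative_fraction: np.ndarray
    ks: Optional[KSResult]
    n_genes: int
    n_with_peak: int  # genes with >=1 same-chromosome peak


def classify_accessibility(
    sites: PeakSet,
    basal_accessibility: TagLibrary,
    pseudocount: float = 1.0,
    log2_cut: float = ACCESSIBILITY_LOG2_CUT,
) -> list[AccessibilityCall]:
    """Label each site pre_accessible (log2 tags >= cut) or de_novo (< cut).

    ``basal_accessibility`` must be the untreated/vehicle-condition library;
    log2 tags come from depth-normalized counts over the site interval with
    the given pseudocount.
    """
    dens = site_log2_density(basal_accessibility, sites, pseudocount=pseudocount)
    return [
        AccessibilityCall(
            d.site_id,
            d.log2_density,
            "pre_accessible" if d.log2_density >= log2_cut else "de_novo",
        )
        for d in dens
    ]


def percent_preaccessible(calls: Sequence[AccessibilityCall]) -> float:
    """Percentage of sites labelled pre-accessible."""
    if not calls:
        raise ValueError("no accessibility calls")
    n = sum(1 for c in calls if c.label == "pre_accessible")
    return 100.0 * n / len(calls)


def replacement_fraction(
    ar_sites: PeakSet, gr_sites: PeakSet, min_bp: int = 1
) -> ReplacementSummary:
    """Fraction of the first set's sites directly overlapped by the second.

    Also reports the symmetric fraction and the three Venn counts
    (A-only, shared, B-only) where "shared" counts A intervals hit by B.
    """
    if len(ar_sites) == 0:
        raise ValueError("first site set is empty")
    ov = overlap(ar_sites, gr_sites, min_bp=min_bp)
    return ReplacementSummary(
        n_ar=ov.n_a,
        n_gr=ov.n_b,
        n_ar_replaced=ov.n_a_hit,
        fraction_replaced=ov.n_a_hit / ov.n_a,
        fraction_gr_shared=(ov.n_b_hit / ov.n_b) if ov.n_b else 0.0,
        venn={"a_only": ov.n_a_only, "shared": ov.n_a_hit, "b_only": ov.n_b_only},
    )


def nearest_peak_distances(
    peaks: PeakSet, genes: pd.DataFrame
) -> pd.Series:
    """Per gene, min |TSS - peak center| over same-chromosome peaks (bp).

    ``genes`` needs columns gene_id, chrom, tss. Genes whose chromosome has
    no peak get +inf. Distance is strand-independent linear distance.
    """
    centers: dict[str, np.ndarray] = {}
    for chrom, ivs in peaks.by_chrom().items():
        centers[chrom] = np.sort(np.array([iv.center for iv in ivs], dtype=np.int64))
    out = np.full(len(genes), np.inf)
    tss = genes["tss"].to_numpy()
    for i, (chrom, t) in enumerate(zip(genes["chrom"], tss)):
        c = centers.get(chrom)
        if c is None or c.size == 0:
            continue
        j = np.searchsorted(c, t)
        best = np.inf
        if j < c.size:
            best = abs(int(c[j]) - int(t))
        if j > 0:
            best = min(best, abs(int(c[j - 1]) - int(t)))
        out[i] = best
    return pd.Series(out, index=genes["gene_id"].to_numpy(), name="distance")


def peak_gene_distance_cdf(
    peaks: PeakSet,
    genes: pd.DataFrame,
    regulated_sets: dict[str, Sequence[str]],
    expressed_set: Sequence[str],
    max_kb: int = 100,
    step_kb: int = 10,
    include_far_in_denominator: bool = True,
) -> list[DistanceCDF]:
    """Cumulative nearest-peak distance distributions with KS tests.

    For every named regulated gene set, the CDF of TSS-to-peak-center
    distances over bins 0..max_kb in step_kb intervals, plus a two-sample KS
    test of the raw distances against the expressed-gene reference. Genes
    with no same-chromosome peak (infinite distance) are dropped from the KS
    input; by default they stay in the CDF denominator, so the curve's final
    value can fall short of 1.

    Regulated genes absent from the annotation are skipped with a warning;
    the expressed reference set is evaluated the same way and returned last
    under the name "expressed".
    """
    import warnings

    known = set(genes["gene_id"])
    dist = nearest_peak_distances(peaks, genes)
    edges = np.arange(0, (max_kb + step_kb) * 1000, step_kb * 1000)

    def one(name: str, ids: Sequence[str], ref: Optional[np.ndarray]) -> DistanceCDF:
        ids = list(ids)
        missing = [g for g in ids if g not in known]
        if missing:
            warnings.warn(
                f"{name}: {len(missing)} gene ids absent from annotation; skipped",
                RuntimeWarning,
            )
        present = [g for g in ids if g in known]
        d = dist.loc[present].to_numpy()
        finite = d[np.isfinite(d)]
        denom = len(d) if include_far_in_denominator else max(len(finite), 1)
        cum = np.array([(finite <= e).sum() / max(denom, 1) for e in edges[1:]])
        ks = None
        if ref is not None and finite.size and ref.size:
            ks = ks_test_two_sample(finite, ref)
        return DistanceCDF(name, edges, cum, ks, len(d), int(np.isfinite(d).sum()))

    expr_ids = [g for g in expressed_set if g in known]
    ref_dist = dist.loc[expr_ids].to_numpy()
    ref_finite = ref_dist[np.isfinite(ref_dist)]

    out = [one(name, ids, ref_finite) for name, ids in regulated_sets.items()]
    out.append(one("expressed", expr_ids, None))
    return out


def accessibility_to_frame(calls: Sequence[AccessibilityCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": [c.site_id for c in calls],
            "log2_tags_untreated": [c.log2_tags_untreated for c in calls],
            "label": [c.label for c in calls],
        }
    ).set_index("site_id")


def cdf_to_frame(cdfs: Sequence[DistanceCDF]) -> pd.DataFrame:
    rows = {}
    for c in cdfs:
        rows[c.set_name] = c.cumulative_fraction
    idx = [f"<= {int(e) // 1000} kb" for e in cdfs[0].bin_edges[1:]]
    return pd.DataFrame(rows, index=idx)
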