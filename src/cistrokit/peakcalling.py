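"""Enrichment peak calling and assembly of per-peak count matrices.

The caller scans fixed-width candidate windows centered on tag positions,
greedily keeps local maxima (highest tag count first, leftmost on ties,
suppression radius = peak width), and then applies four filters jointly:

* raw treatment tags in the window  > ``min_tags``;
* tags > ``min_fold`` x depth-normalized control count in the same window;
* tags > ``min_fold`` x expected count from a +/-5 kb local background
  (candidate window excluded);
* Poisson upper-tail p-value against the largest of the control, local and
  genome-wide expectations, BH-adjusted across candidates, q < ``fdr``.

Expected counts are floored at 0.5 tags so fold enrichment is defined even
on empty background. Defaults mirror a stringent factor-style ChIP-seq
configuration: FDR < 0.01, > 25 tags, > 4-fold over control and local
background, 200 bp peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, PeakSet
from .nbstats import CountMatrix, NBTestResult, bh_fdr, classify, nb_wald_test
from .tagsignal import TagLibrary, count_tags_many

EXPECTED_FLOOR = 0.5  # tags; floor for control/local/genome-wide expectations
LOCAL_BG_HALFWIDTH = 5000  # bp on each side of the candidate window


@dataclass
class PeakCall:
    interval: GenomicInterval
    tag_count: int
    fold_over_control: float
    fold_over_local: float
    p: float
    q: float


def _window_counts(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    return np.searchsorted(pos, ends, side="left") - np.searchsorted(
        pos, starts, side="left"
    )


def _greedy_maxima(pos: np.ndarray, counts: np.ndarray, radius: int) -> np.ndarray:
    """Indices of candidate centers kept by greedy non-overlap suppression.

    Candidates are processed highest-count first (leftmost coordinate on
    ties); a candidate is kept when no already-kept center lies within
    ``radius`` bp, so kept windows never overlap.
    """
    order = np.lexsort((pos, -counts))
    kept: list[int] = []
    kept_sorted: list[int] = []  # centers, ascending
    import bisect

    for idx in order:
        c = pos[idx]
        j = bisect.bisect_left(kept_sorted, c)
        if j > 0 and c - kept_sorted[j - 1] < radius:
            continue
        if j < len(kept_sorted) and kept_sorted[j] - c < radius:
            continue
        bisect.insort(kept_sorted, c)
        kept.append(idx)
    return np.array(kept, dtype=np.int64)


def call_peaks(
    treatment: TagLibrary,
    control: TagLibrary | None,
    peak_width: int = 200,
    fdr: float = 0.01,
    min_tags: int = 25,
    min_fold: float = 4.0,
) -> tuple[PeakSet, list[PeakCall]]:
    """Call enrichment peaks; returns (PeakSet, full call table).

    ``control`` may be None or empty, in which case the control-fold filter
    is skipped with a warning and only local/genome-wide backgrounds gate the
    Poisson test.
    """
    if peak_width <= 0:
        raise ValueError("peak_width must be positive")
    if treatment.n_stored == 0:
        return PeakSet([], "peaks"), []
    have_control = control is not None and control.n_stored > 0
    if not have_control:
        warnings.warn("no control library; skipping control-fold filter", RuntimeWarning)

    half = peak_width // 2
    cand_chrom: list[str] = []
    cand_center: list[np.ndarray] = []
    cand_count: list[np.ndarray] = []

    genome_span = sum(
        int(p[-1]) + 1 for p in treatment.positions.values() if p.size
    )
    gw_rate = treatment.n_stored / max(genome_span, 1)

    for chrom in sorted(treatment.positions):
        pos = treatment.positions[chrom]
        if pos.size == 0:
            continue
        centers = np.unique(pos)
        counts = _window_counts(pos, centers - half, centers - half + peak_width)
        keep = _greedy_maxima(centers, counts, peak_width)
        cand_chrom.append(chrom)
        cand_center.append(centers[keep])
        cand_count.append(counts[keep])

    rows = []
    for chrom, centers, counts in zip(cand_chrom, cand_center, cand_count):
        pos = treatment.positions[chrom]
        starts = centers - half
        ends = starts + peak_width
        # local background: +/-5 kb around the window, window itself excluded
        outer = _window_counts(
            pos, starts - LOCAL_BG_HALFWIDTH, ends + LOCAL_BG_HALFWIDTH
        )
        local_exp = (outer - counts) * (peak_width / (2 * LOCAL_BG_HALFWIDTH))
        gw_exp = np.full_like(local_exp, gw_rate * peak_width, dtype=float)
        if have_control:
            cpos = control.positions.get(chrom, np.empty(0, np.int64))
            ctrl_norm = _window_counts(cpos, starts, ends) * (
                treatment.total_tags / control.total_tags
            )
        else:
            ctrl_norm = np.zeros_like(local_exp, dtype=float)
        lam = np.maximum.reduce(
            [ctrl_norm, local_exp, gw_exp, np.full_like(gw_exp, EXPECTED_FLOOR)]
        )
        p = stats.poisson.sf(counts - 1, lam)
        for s, e, n, cn, le, pi in zip(starts, ends, counts, ctrl_norm, local_exp, p):
            rows.append((chrom, int(max(s, 0)), int(e), int(n), float(cn), float(le), float(pi)))

    if not rows:
        return PeakSet([], "peaks"), []
    q = bh_fdr([r[6] for r in rows])
    calls: list[PeakCall] = []
    for (chrom, s, e, n, cn, le, pi), qi in zip(rows, q):
        passes = n > min_tags
        fold_ctrl = n / max(cn, EXPECTED_FLOOR)
        fold_local = n / max(le, EXPECTED_FLOOR)
        if have_control:
            passes = passes and fold_ctrl > min_fold
        passes = passes and fold_local > min_fold and qi < fdr
        if passes:
            iv = GenomicInterval(
                chrom, s, e, name=f"peak_{chrom}_{s}",
                score=float(-np.log10(max(qi, 1e-300))),
            )
            calls.append(PeakCall(iv, n, fold_ctrl, fold_local, pi, float(qi)))
    calls.sort(key=lambda c: c.interval.sort_key())
    return PeakSet([c.interval for c in calls], "peaks"), calls


def calls_to_frame(calls: list[PeakCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.interval.chrom for c in calls],
            "start": [c.interval.start for c in calls],
            "end": [c.interval.end for c in calls],
            "name": [c.interval.name for c in calls],
            "tag_count": [c.tag_count for c in calls],
            "fold_over_control": [c.fold_over_control for c in calls],
            "fold_over_local": [c.fold_over_local for c in calls],
            "p": [c.p for c in calls],
            "q": [c.q for c in calls],
        }
    )


def count_matrix_at_peaks(
    peaks: PeakSet,
    libs: list[TagLibrary],
    condition: dict[str, str],
) -> CountMatrix:
    """Raw tag counts per peak per sample (no normalization).

    ``condition`` maps sample_id -> group label. Peak names (or positional
    ids) become feature ids; duplicated sample ids are rejected.
    """
    ids = [lib.sample_id for lib in libs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated sample_id among libraries")
    data = {}
    for lib in libs:
        data[lib.sample_id] = count_tags_many(lib, peaks)
    feature_ids = [iv.name or f"peak_{i}" for i, iv in enumerate(peaks)]
    counts = pd.DataFrame(data, index=feature_ids)
    cond = pd.Series({s: condition[s] for s in ids})
    return CountMatrix(counts, cond)


def differential_binding(
    matrix: CountMatrix,
    cond_a: str,
    cond_b: str,
    fdr_cut: float = 0.1,
    fc_cut: float = 2.0,
) -> list[NBTestResult]:
    """NB Wald test + BH + UN/UP/DN classification at binding-style cuts.

    Defaults are FDR < 0.1 with linear fold change > 2 (B vs A); UP means
    increased binding in ``cond_b``.
    """
    res = nb_wald_test(matrix, cond_a, cond_b)
    return classify(res, fdr_cut=fdr_cut, fc_cut=fc_cut, fc_scale="linear")
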