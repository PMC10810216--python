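"""End-to-end orchestration: simulate -> call peaks -> differential binding
-> accessibility -> replacement -> expression -> peak-gene distances ->
motifs, with a machine-readable summary.

Every stage writes its table(s) under the output directory and contributes
to ``summary.json``. Because the input data are synthetic with planted
ground truth, the summary also carries recovery metrics (peak recall,
classification sensitivity and realized FDR against the planted labels).
Identical (config, seed) reruns produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import cistrome, expression, motifs, peakcalling, synthetic
from .intervals import PeakSet, overlap, write_bed
from .nbstats import results_to_frame
from .synthetic import SyntheticConfig, SyntheticTruth
from .tagsignal import TagLibrary

logger = logging.getLogger(__name__)

STAGES = ("callpeaks", "diffbind", "access", "replace", "expr", "genes", "motifs")


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "cistrokit_out"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    # peak calling
    peak_width: int = 200
    peak_fdr: float = 0.01
    min_tags: int = 25
    min_fold: float = 4.0
    # differential binding
    binding_fdr: float = 0.1
    binding_fc: float = 2.0
    # accessibility
    access_log2_cut: float = 1.0
    access_pseudocount: float = 1.0
    # replacement
    overlap_min_bp: int = 1
    # expression
    de_fdr: float = 0.05
    de_log2fc: float = 0.5
    tpm_cut: float = 0.5
    # distance CDF
    cdf_max_kb: int = 100
    cdf_step_kb: int = 10
    # motifs
    motif_k: int = 8
    motif_max_mismatch: int = 2
    n_background_regions: int = 50_000
    motif_top: int = 10
    motif_min_seed_frac: float = 0.05

    def resolved(self) -> "PipelineConfig":
        """Copy with the pipeline seed propagated into the generator."""
        syn = dataclasses.replace(self.synthetic, seed=self.seed)
        stages = {s: bool(self.stages.get(s, True)) for s in STAGES}
        return dataclasses.replace(self, synthetic=syn, stages=stages)


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Return a list of problems; empty means the config is runnable."""
    problems = []
    if cfg.peak_width <= 0:
        problems.append("peak_width must be positive")
    if cfg.min_tags < 0:
        problems.append("min_tags must be >= 0")
    if cfg.min_fold <= 0:
        problems.append("min_fold must be positive")
    for name in ("peak_fdr", "binding_fdr", "de_fdr"):
        v = getattr(cfg, name)
        if not 0 < v < 1:
            problems.append(f"{name}={v} outside (0, 1)")
    if cfg.binding_fc <= 1:
        problems.append("binding_fc must exceed 1 (linear fold change)")
    if cfg.de_log2fc <= 0:
        problems.append("de_log2fc must be positive (log2 scale)")
    if cfg.overlap_min_bp < 1:
        problems.append("overlap_min_bp must be >= 1")
    if cfg.cdf_max_kb % cfg.cdf_step_kb != 0:
        problems.append("cdf_step_kb must divide cdf_max_kb")
    if cfg.motif_k > motifs.MAX_K:
        problems.append(f"motif_k exceeds enumeration bound {motifs.MAX_K}")
    if cfg.n_background_regions <= 0:
        problems.append("n_background_regions must be positive")
    problems.extend(cfg.synthetic.validate())
    return problems


def load_config(path) -> PipelineConfig:
    """Load a YAML config; keys mirror the dataclass fields."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    syn_raw = raw.pop("synthetic", {})
    if "gene_length_range" in syn_raw:
        syn_raw["gene_length_range"] = tuple(syn_raw["gene_length_range"])
    syn = SyntheticConfig(**syn_raw)
    return PipelineConfig(synthetic=syn, **raw)


def _truth_peak_labels(
    peaks: PeakSet, truth: SyntheticTruth, column: str
) -> np.ndarray:
    """Per-peak planted label: value of ``column`` for the overlapped site
    (False/0 when the peak overlaps no planted site)."""
    sites = truth.site_peakset()
    ov = overlap(peaks, sites, min_bp=1)
    values = truth.sites[column].to_numpy()
    out = np.zeros(len(peaks), dtype=values.dtype)
    for ia, ib in ov.pairs:
        out[ia] = values[ib] or out[ia]
    return out


def _peak_recall(peaks: PeakSet, site_set: PeakSet) -> float:
    if len(site_set) == 0:
        return float("nan")
    ov = overlap(site_set, peaks, min_bp=1)
    return ov.n_a_hit / ov.n_a


def run_pipeline(cfg: PipelineConfig, write_tags: bool = False) -> dict:
    """Execute enabled stages in dependency order; returns the summary dict.

    Writes per-stage TSV/BED tables plus ``summary.json`` under
    ``cfg.outdir``. ``write_tags`` additionally materializes the simulated
    tag libraries as TSV files with a manifest (off by default: they are the
    bulkiest artifact and are reproducible from the seed).
    """
    cfg = cfg.resolved()
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = dataclasses.asdict(cfg)
    cfg_dict["synthetic"]["gene_length_range"] = list(
        cfg_dict["synthetic"]["gene_length_range"]
    )
    logger.info("pipeline parameters: %s", json.dumps(cfg_dict, sort_keys=True))
    summary: dict = {"config": cfg_dict, "seed": cfg.seed}

    # --- simulate -----------------------------------------------------------
    truth = synthetic.simulate_dataset(cfg.synthetic)
    synthetic.write_dataset(truth, out / "synthetic")
    gr_libs = {
        cond: synthetic.simulate_tags(truth, cond, "chip_gr")
        for cond in ("baseline", "enz")
    }
    ar_libs = synthetic.simulate_tags(truth, "baseline", "chip_ar")
    atac_libs = synthetic.simulate_tags(truth, "baseline", "atac")
    control_libs = synthetic.simulate_tags(truth, "baseline", "control")
    if write_tags:
        all_libs = ar_libs + atac_libs + control_libs + gr_libs["baseline"] + gr_libs["enz"]
        synthetic.write_tag_libraries(all_libs, out / "tags")
    control_pool = TagLibrary.pool(control_libs, "control_pool")
    summary["simulate"] = {
        "n_sites": int(len(truth.sites)),
        "n_gr_sites": int(truth.sites.is_gr.sum()),
        "n_ar_sites": int(truth.sites.is_ar.sum()),
        "n_genes": int(len(truth.genes)),
    }

    gr_peaks = ar_peaks = None
    if cfg.stages["callpeaks"]:
        gr_pool = TagLibrary.pool(gr_libs["enz"], "gr_enz_pool")
        ar_pool = TagLibrary.pool(ar_libs, "ar_baseline_pool")
        gr_peaks, gr_calls = peakcalling.call_peaks(
            gr_pool, control_pool, cfg.peak_width, cfg.peak_fdr,
            cfg.min_tags, cfg.min_fold,
        )
        ar_peaks, ar_calls = peakcalling.call_peaks(
            ar_pool, control_pool, cfg.peak_width, cfg.peak_fdr,
            cfg.min_tags, cfg.min_fold,
        )
        gr_peaks.label, ar_peaks.label = "GR_enz", "AR_baseline"
        write_bed(out / "gr_peaks.bed", gr_peaks)
        write_bed(out / "ar_peaks.bed", ar_peaks)
        peakcalling.calls_to_frame(gr_calls).to_csv(
            out / "gr_peak_calls.tsv", sep="\t", index=False
        )
        peakcalling.calls_to_frame(ar_calls).to_csv(
            out / "ar_peak_calls.tsv", sep="\t", index=False
        )
        summary["callpeaks"] = {
            "n_gr_peaks": len(gr_peaks),
            "n_ar_peaks": len(ar_peaks),
            "gr_recall": _peak_recall(truth.site_peakset(truth.sites.is_gr), gr_peaks),
            "ar_recall": _peak_recall(truth.site_peakset(truth.sites.is_ar), ar_peaks),
        }
    else:
        summary["callpeaks"] = "skipped"

    if cfg.stages["diffbind"] and gr_peaks is not None:
        libs = gr_libs["baseline"] + gr_libs["enz"]
        condition = {
            lib.sample_id: ("enz" if "_enz_" in lib.sample_id else "baseline")
            for lib in libs
        }
        mat = peakcalling.count_matrix_at_peaks(gr_peaks, libs, condition)
        res = peakcalling.differential_binding(
            mat, "baseline", "enz", cfg.binding_fdr, cfg.binding_fc
        )
        frame = results_to_frame(res)
        frame.to_csv(out / "gr_differential_binding.tsv", sep="\t")
        truth_up = _truth_peak_labels(gr_peaks, truth, "is_enz_up")
        called = frame["class"].to_numpy()
        n_truth_up = int(truth_up.sum())
        up_sens = float((called[truth_up] == "UP").mean()) if n_truth_up else float("nan")
        n_called = int((called != "UN").sum())
        realized_fdr = (
            float((~truth_up[called != "UN"]).mean()) if n_called else 0.0
        )
        summary["diffbind"] = {
            "n_un": int((called == "UN").sum()),
            "n_up": int((called == "UP").sum()),
            "n_dn": int((called == "DN").sum()),
            "up_sensitivity": up_sens,
            "updn_realized_fdr": realized_fdr,
        }
    else:
        summary["diffbind"] = "skipped"

    if cfg.stages["access"] and gr_peaks is not None:
        atac_pool = TagLibrary.pool(atac_libs, "atac_baseline_pool")
        calls = cistrome.classify_accessibility(
            gr_peaks, atac_pool, cfg.access_pseudocount, cfg.access_log2_cut
        )
        cistrome.accessibility_to_frame(calls).to_csv(
            out / "gr_accessibility.tsv", sep="\t"
        )
        truth_pre = _truth_peak_labels(gr_peaks, truth, "is_preaccessible")
        summary["access"] = {
            "percent_preaccessible": cistrome.percent_preaccessible(calls),
            "truth_percent_preaccessible": float(100.0 * truth_pre.mean()),
            "config_percent_preaccessible": 100.0 * cfg.synthetic.frac_preaccessible,
        }
    else:
        summary["access"] = "skipped"

    if cfg.stages["replace"] and gr_peaks is not None and len(ar_peaks) > 0:
        rep = cistrome.replacement_fraction(ar_peaks, gr_peaks, cfg.overlap_min_bp)
        pd.DataFrame([rep.venn]).to_csv(out / "replacement_venn.tsv", sep="\t", index=False)
        summary["replace"] = {
            "n_ar": rep.n_ar,
            "n_gr": rep.n_gr,
            "n_ar_replaced": rep.n_ar_replaced,
            "replacement_pct": 100.0 * rep.fraction_replaced,
            "gr_shared_pct": 100.0 * rep.fraction_gr_shared,
            "config_shared_pct": 100.0 * cfg.synthetic.frac_shared_ar_gr,
            "venn": rep.venn,
        }
    else:
        summary["replace"] = "skipped"

    de_up: set = set()
    de_dn: set = set()
    expressed: set = set()
    if cfg.stages["expr"]:
        counts, lengths = synthetic.simulate_expression(truth)
        table = expression.tpm_normalize(
            counts.counts, lengths, cfg.tpm_cut,
            biotype=truth.genes.set_index("gene_id")["biotype"],
        )
        expressed = expression.filter_expressed(table)
        res = expression.differential_expression(
            counts, "veh", "dex", expressed, cfg.de_fdr, cfg.de_log2fc
        )
        frame = results_to_frame(res)
        frame.to_csv(out / "differential_expression.tsv", sep="\t")
        de_up = set(frame.index[frame["class"] == "UP"])
        de_dn = set(frame.index[frame["class"] == "DN"])
        regulated_truth = set(
            truth.genes.loc[truth.genes.is_regulated, "gene_id"]
        ) & expressed
        called = de_up | de_dn
        sens = (
            len(called & regulated_truth) / len(regulated_truth)
            if regulated_truth
            else float("nan")
        )
        rfdr = len(called - regulated_truth) / len(called) if called else 0.0
        venn = expression.venn_gene_sets({"dex_up": de_up, "dex_dn": de_dn})
        summary["expr"] = {
            "n_expressed": len(expressed),
            "n_de_up": len(de_up),
            "n_de_dn": len(de_dn),
            "de_sensitivity": sens,
            "de_realized_fdr": rfdr,
            "venn_up_dn": venn[("dex_up", "dex_dn")],
        }
    else:
        summary["expr"] = "skipped"

    if cfg.stages["genes"] and gr_peaks is not None and expressed:
        regulated = sorted(de_up | de_dn)
        cdfs = cistrome.peak_gene_distance_cdf(
            gr_peaks,
            truth.genes,
            {"dex_regulated": regulated},
            sorted(expressed),
            max_kb=cfg.cdf_max_kb,
            step_kb=cfg.cdf_step_kb,
        )
        cistrome.cdf_to_frame(cdfs).to_csv(out / "distance_cdf.tsv", sep="\t")
        ks = cdfs[0].ks
        summary["genes"] = {
            "ks_d": ks.d if ks else float("nan"),
            "ks_p": ks.p if ks else float("nan"),
            "n_regulated": cdfs[0].n_genes,
            "n_expressed_ref": cdfs[-1].n_genes,
        }
    else:
        summary["genes"] = "skipped"

    if cfg.stages["motifs"] and gr_peaks is not None and len(gr_peaks) > 0:
        from .intervals import center_window

        windows = PeakSet(
            [center_window(iv, cfg.peak_width // 2) for iv in gr_peaks]
        )
        target_seqs = motifs.extract_sequences(truth.genome, windows)
        bg_rng = synthetic.stage_rng(cfg.seed, "background_regions")
        bg = motifs.sample_background_regions(
            truth.genome, cfg.n_background_regions, cfg.peak_width,
            exclude=windows, seed=bg_rng,
        )
        bg_seqs = motifs.extract_sequences(truth.genome, bg)
        min_seed = max(3, int(np.ceil(cfg.motif_min_seed_frac * len(target_seqs))))
        ranked = motifs.denovo_kmer_enrichment(
            target_seqs, bg_seqs, cfg.motif_k, cfg.motif_max_mismatch,
            cfg.motif_top, min_seed_seqs=min_seed,
        )
        motifs.motifs_to_frame(ranked).to_csv(out / "denovo_motifs.tsv", sep="\t")
        planted = cfg.synthetic.motif_consensus
        planted_rank = 0
        for m in ranked:
            k = min(len(planted), len(m.consensus))
            if (
                motifs._hamming(m.consensus[:k], planted[:k]) <= 1
                or motifs._hamming(
                    m.consensus[:k], motifs.reverse_complement(planted)[:k]
                ) <= 1
            ):
                planted_rank = m.rank
                break
        if ranked:
            pwm = motifs.pwm_from_kmer_hits(ranked[0], target_seqs)
            motifs.write_pwm(out / "top_motif.pwm", pwm)
        summary["motifs"] = {
            "n_candidates_ranked": len(ranked),
            "top_consensus": ranked[0].consensus if ranked else "",
            "top_p": ranked[0].p if ranked else float("nan"),
            "planted_consensus": planted,
            "planted_rank": planted_rank,
        }
    else:
        summary["motifs"] = "skipped"

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
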