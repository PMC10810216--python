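"""Synthetic cistrome/transcriptome generator with planted ground truth.

The generator emulates the statistical structure of a two-factor steroid
receptor study in antiandrogen-treated cells: replicated negative-binomial
tag counts at planted binding sites over a low uniform Poisson background,
a configurable fraction of sites shared between an "AR" and a "GR" factor,
a configurable fraction of sites with high basal ("pre-accessible") versus
near-zero ("de novo") accessibility signal, antiandrogen-dependent fold
increases in GR binding ("ENZ-UP" sites), sequence motifs planted into GR
site windows, and gene expression counts whose regulated genes sit
preferentially near planted GR sites.

Every output is reproducible byte-for-byte from (config, seed): each stage
draws from its own generator derived from the root seed and a stage label,
so stages can be re-run independently without perturbing one another.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, PeakSet
from .motifs import PWM, BASES
from .nbstats import CountMatrix
from .tagsignal import TagLibrary, write_tag_file

CONDITIONS = ("baseline", "enz")
ASSAYS = ("chip_ar", "chip_gr", "atac", "control")

# Site means and background rate in SyntheticConfig are defined at these
# nominal sequencing depths; actual library_depth scales them linearly, so
# deeper libraries yield proportionally more raw tags while depth-normalized
# quantities stay put.
NOMINAL_CHIP_DEPTH = 500_000
NOMINAL_ATAC_DEPTH = 10_000_000


@dataclass
class SyntheticConfig:
    """Study conditions for the generator (defaults are the tested scale)."""

    seed: int = 0
    # genome / sites
    n_chrom: int = 2
    chrom_length: int = 2_000_000
    n_sites: int = 2000
    site_width: int = 200
    min_spacing: int = 1000
    # site composition
    frac_ar: float = 0.5  # fraction of sites AR-bound at baseline
    frac_shared_ar_gr: float = 0.58  # fraction of AR sites also GR-bound
    frac_preaccessible: float = 0.9  # fraction of sites in open basal chromatin
    frac_enz_up: float = 0.3  # fraction of GR sites with ENZ-induced binding
    # signal model
    enz_fold: float = 4.0  # linear FC at ENZ-UP sites
    site_base_mean: float = 60.0  # mean tags per site per replicate
    nb_dispersion: float = 0.05
    background_rate: float = 2e-4  # tags per bp, uniform Poisson background
    n_replicates: int = 3
    library_depth: int = 500_000  # total mapped tags per ChIP library
    atac_library_depth: int = 10_000_000  # ATAC libraries are sequenced deeper
    ar_enz_attenuation: float = 0.3  # AR signal multiplier under ENZ
    atac_preaccessible_mean: float = 20.0  # tags per site, basal ATAC
    atac_denovo_mean: float = 0.2  # residual signal kept under the log2=1 call boundary
    tag_jitter: int = 0  # bp beyond site edges for tag placement
    # motif planting
    motif_consensus: str = "AGAACAGA"
    motif_match_prob: float = 0.9
    motif_planted_fraction: float = 0.6
    # expression
    n_genes: int = 2000
    frac_regulated: float = 0.1
    gene_log2fc: float = 1.0
    gene_base_mean: float = 200.0
    gene_base_sigma: float = 0.8  # lognormal spread of per-gene means
    gene_dispersion: float = 0.05
    regulated_link_radius: int = 20_000
    gene_length_range: tuple[int, int] = (500, 5000)

    def validate(self) -> list[str]:
        problems = []
        for name in (
            "frac_ar",
            "frac_shared_ar_gr",
            "frac_preaccessible",
            "frac_enz_up",
            "motif_planted_fraction",
            "frac_regulated",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                problems.append(f"{name}={v} outside [0, 1]")
        for name in (
            "chrom_length", "n_sites", "site_width", "n_replicates",
            "library_depth", "n_genes", "site_base_mean", "gene_base_mean",
        ):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be positive")
        if self.nb_dispersion < 0 or self.background_rate < 0:
            problems.append("dispersion and background_rate must be >= 0")
        per_chrom = -(-self.n_sites // max(self.n_chrom, 1))  # ceil
        if self.chrom_length // max(per_chrom, 1) <= self.site_width + self.min_spacing:
            problems.append(
                "genome too short for n_sites at the requested spacing"
            )
        return problems


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-site flags, per-gene links, genome sequence."""

    sites: pd.DataFrame  # site_id, chrom, start, end, is_ar, is_gr, ...
    genes: pd.DataFrame  # gene_id, chrom, tss, strand, length_bp, ...
    genome: dict[str, str]
    config: SyntheticConfig
    motif_placements: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["site_id", "chrom", "offset", "strand", "instance"]
        )
    )

    def site_peakset(self, mask: Optional[pd.Series] = None, label: str = "") -> PeakSet:
        df = self.sites if mask is None else self.sites[mask]
        return PeakSet(
            [
                GenomicInterval(r.chrom, int(r.start), int(r.end), name=r.site_id)
                for r in df.itertuples()
            ],
            label,
        )


def stage_rng(seed: int, label: str) -> np.random.Generator:
    """Independent generator for a named stage, stable across call order."""
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])
    )


def _exact_mask(n: int, frac: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask with round(frac*n) True entries at random positions."""
    k = int(round(frac * n))
    mask = np.zeros(n, dtype=bool)
    mask[rng.permutation(n)[:k]] = True
    return mask


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def simulate_genome(cfg: SyntheticConfig) -> SyntheticTruth:
    """Random genome, planted non-overlapping sites, gene annotation.

    Sites are laid on an even grid with random jitter so consecutive sites
    keep at least ``min_spacing`` bp between them. Regulated genes get a TSS
    within ``regulated_link_radius`` of a randomly linked GR site; other
    genes are placed uniformly.
    """
    problems = cfg.validate()
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    rng = stage_rng(cfg.seed, "genome")

    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chrom)]
    genome = {c: _random_sequence(rng, cfg.chrom_length) for c in chrom_names}

    # distribute sites over chromosomes proportionally to length
    per_chrom = np.full(cfg.n_chrom, cfg.n_sites // cfg.n_chrom)
    per_chrom[: cfg.n_sites % cfg.n_chrom] += 1

    rows = []
    sid = 0
    for chrom, n_c in zip(chrom_names, per_chrom):
        slot = cfg.chrom_length // int(n_c)
        free = slot - cfg.site_width - cfg.min_spacing
        if free <= 0:
            raise ValueError("site density infeasible for chromosome length")
        jitter = rng.integers(0, free, size=int(n_c))
        starts = np.arange(int(n_c)) * slot + jitter + cfg.min_spacing // 2
        for s in starts:
            rows.append((f"site_{sid:05d}", chrom, int(s), int(s) + cfg.site_width))
            sid += 1
    sites = pd.DataFrame(rows, columns=["site_id", "chrom", "start", "end"])

    n = len(sites)
    is_ar = _exact_mask(n, cfg.frac_ar, rng)
    # shared: exact fraction of AR sites; all non-AR sites are GR-only
    is_gr = ~is_ar
    ar_idx = np.flatnonzero(is_ar)
    shared = ar_idx[
        _exact_mask(ar_idx.size, cfg.frac_shared_ar_gr, rng)
    ]
    is_gr[shared] = True
    gr_idx = np.flatnonzero(is_gr)

    is_pre = np.zeros(n, dtype=bool)
    is_pre[gr_idx[_exact_mask(gr_idx.size, cfg.frac_preaccessible, rng)]] = True
    non_gr = np.flatnonzero(~is_gr)
    is_pre[non_gr[_exact_mask(non_gr.size, cfg.frac_preaccessible, rng)]] = True

    is_up = np.zeros(n, dtype=bool)
    is_up[gr_idx[_exact_mask(gr_idx.size, cfg.frac_enz_up, rng)]] = True

    sites["is_ar"] = is_ar
    sites["is_gr"] = is_gr
    sites["is_preaccessible"] = is_pre
    sites["is_enz_up"] = is_up
    sites["true_fold"] = np.where(is_up, cfg.enz_fold, 1.0)

    # genes
    n_genes = cfg.n_genes
    regulated = _exact_mask(n_genes, cfg.frac_regulated, rng)
    gr_sites = sites[sites.is_gr].reset_index(drop=True)
    lo, hi = cfg.gene_length_range
    grows = []
    for gi in range(n_genes):
        gene_id = f"gene_{gi:05d}"
        strand = "+" if rng.integers(0, 2) else "-"
        length = int(rng.integers(lo, hi + 1))
        if regulated[gi]:
            link = gr_sites.iloc[int(rng.integers(0, len(gr_sites)))]
            center = (int(link.start) + int(link.end)) // 2
            tss = center + int(
                rng.integers(-cfg.regulated_link_radius, cfg.regulated_link_radius + 1)
            )
            tss = int(np.clip(tss, 0, cfg.chrom_length - 1))
            chrom, linked = link.chrom, link.site_id
        else:
            chrom = chrom_names[int(rng.integers(0, cfg.n_chrom))]
            tss = int(rng.integers(0, cfg.chrom_length))
            linked = ""
        direction = int(rng.integers(0, 2)) * 2 - 1 if regulated[gi] else 0
        grows.append(
            (gene_id, chrom, tss, strand, length, bool(regulated[gi]), linked, direction)
        )
    genes = pd.DataFrame(
        grows,
        columns=[
            "gene_id", "chrom", "tss", "strand", "length_bp",
            "is_regulated", "linked_site", "direction",
        ],
    )
    genes["biotype"] = "protein_coding"
    return SyntheticTruth(sites, genes, genome, cfg)


def plant_motifs(
    truth: SyntheticTruth,
    pwm: Optional[PWM] = None,
    fraction: Optional[float] = None,
    seed: Optional[int] = None,
) -> SyntheticTruth:
    """Write PWM-sampled motif instances into a fraction of GR site windows.

    Instances replace the existing sequence at a random offset within the
    site, on a random strand; genome length is unchanged. Placements are
    recorded in ``truth.motif_placements``. Returns ``truth`` (mutated).
    """
    cfg = truth.config
    pwm = pwm or PWM.from_consensus(cfg.motif_consensus, cfg.motif_match_prob)
    fraction = cfg.motif_planted_fraction if fraction is None else fraction
    rng = stage_rng(cfg.seed if seed is None else seed, "motifs")

    gr = truth.sites[truth.sites.is_gr].reset_index(drop=True)
    chosen = gr[_exact_mask(len(gr), fraction, rng)]
    buffers = {c: bytearray(s, "ascii") for c, s in truth.genome.items()}
    from .motifs import reverse_complement

    placements = []
    for r in chosen.itertuples():
        width = int(r.end) - int(r.start)
        offset = int(rng.integers(0, width - pwm.k + 1))
        instance = pwm.sample(rng)
        strand = "+" if rng.integers(0, 2) else "-"
        written = instance if strand == "+" else reverse_complement(instance)
        pos = int(r.start) + offset
        buffers[r.chrom][pos : pos + pwm.k] = written.encode("ascii")
        placements.append((r.site_id, r.chrom, offset, strand, instance))
    truth.genome = {c: b.decode("ascii") for c, b in buffers.items()}
    truth.motif_placements = pd.DataFrame(
        placements, columns=["site_id", "chrom", "offset", "strand", "instance"]
    )
    return truth


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, alpha: float
) -> np.ndarray:
    """NB(mean, dispersion alpha) draws; alpha=0 degenerates to Poisson."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if not pos.any():
        return out
    if alpha <= 0:
        out[pos] = rng.poisson(mean[pos])
    else:
        lam = rng.gamma(shape=1.0 / alpha, scale=mean[pos] * alpha)
        out[pos] = rng.poisson(lam)
    return out


def _site_means(truth: SyntheticTruth, condition: str, assay: str) -> np.ndarray:
    cfg = truth.config
    s = truth.sites
    base = cfg.site_base_mean
    if assay == "chip_ar":
        mult = s.is_ar.to_numpy() * (
            1.0 if condition == "baseline" else cfg.ar_enz_attenuation
        )
        return base * mult
    if assay == "chip_gr":
        gr = s.is_gr.to_numpy()
        up = s.is_enz_up.to_numpy()
        mean = np.where(gr & ~up, base, 0.0)
        # ENZ-UP sites: weak at baseline, full strength (x enz_fold) under ENZ
        weak = base / cfg.enz_fold
        mean = np.where(gr & up, weak if condition == "baseline" else base, mean)
        return mean
    if assay == "atac":
        pre = s.is_preaccessible.to_numpy()
        return np.where(pre, cfg.atac_preaccessible_mean, cfg.atac_denovo_mean)
    if assay == "control":
        return np.zeros(len(s))
    raise ValueError(f"unknown assay {assay!r}")


def simulate_tags(
    truth: SyntheticTruth, condition: str, assay: str
) -> list[TagLibrary]:
    """One TagLibrary per replicate for the given condition and assay.

    Per site, replicate counts are NB(site mean x condition/assay
    multiplier, dispersion); tags fall uniformly within the site (plus
    optional jitter). A uniform Poisson background at ``background_rate``
    tags/bp is added genome-wide. ``total_tags`` is the configured library
    depth (tags mapping outside the simulated loci are counted but not
    stored), or the number of placed tags if that exceeds the depth.
    """
    if condition not in CONDITIONS or assay not in ASSAYS:
        raise ValueError(f"unknown condition/assay {condition}/{assay}")
    cfg = truth.config
    if assay == "atac":
        depth = cfg.atac_library_depth
        depth_scale = depth / NOMINAL_ATAC_DEPTH
    else:
        depth = cfg.library_depth
        depth_scale = depth / NOMINAL_CHIP_DEPTH
    means = _site_means(truth, condition, assay) * depth_scale
    starts = truth.sites["start"].to_numpy()
    chroms = truth.sites["chrom"].to_numpy()
    width = cfg.site_width
    libs = []
    for rep in range(1, cfg.n_replicates + 1):
        rng = stage_rng(cfg.seed, f"tags/{assay}/{condition}/rep{rep}")
        counts = _nb_counts(rng, means, cfg.nb_dispersion)
        pos_by_chrom: dict[str, list[np.ndarray]] = {
            c: [] for c in truth.genome
        }
        for s, chrom, cnt in zip(starts, chroms, counts):
            if cnt == 0:
                continue
            lo = max(0, int(s) - cfg.tag_jitter)
            hi = int(s) + width + cfg.tag_jitter
            pos_by_chrom[chrom].append(rng.integers(lo, hi, size=int(cnt)))
        for chrom, seq_len in ((c, len(truth.genome[c])) for c in truth.genome):
            n_bg = rng.poisson(cfg.background_rate * depth_scale * seq_len)
            if n_bg:
                pos_by_chrom[chrom].append(rng.integers(0, seq_len, size=int(n_bg)))
        positions = {
            c: np.sort(np.concatenate(parts)) if parts else np.empty(0, np.int64)
            for c, parts in pos_by_chrom.items()
        }
        placed = sum(p.size for p in positions.values())
        libs.append(
            TagLibrary(
                positions,
                max(depth, placed),
                f"{assay}_{condition}_rep{rep}",
            )
        )
    return libs


def simulate_expression(truth: SyntheticTruth) -> tuple[CountMatrix, pd.Series]:
    """Replicated NB gene counts for vehicle vs hormone ("dex") conditions.

    Regulated genes shift by ±gene_log2fc (direction planted in the truth
    table) under the hormone condition; all other genes are null. Returns
    the CountMatrix and per-gene transcript lengths.
    """
    cfg = truth.config
    rng = stage_rng(cfg.seed, "expression")
    n = len(truth.genes)
    base = np.exp(
        rng.normal(np.log(cfg.gene_base_mean), cfg.gene_base_sigma, size=n)
    )
    direction = truth.genes["direction"].to_numpy()
    dex_mean = base * np.where(
        truth.genes["is_regulated"], 2.0 ** (direction * cfg.gene_log2fc), 1.0
    )
    data = {}
    for cond, mean in (("veh", base), ("dex", dex_mean)):
        for rep in range(1, cfg.n_replicates + 1):
            rng_rep = stage_rng(cfg.seed, f"expr/{cond}/rep{rep}")
            data[f"{cond}_rep{rep}"] = _nb_counts(rng_rep, mean, cfg.gene_dispersion)
    counts = pd.DataFrame(data, index=truth.genes["gene_id"].to_numpy())
    condition = pd.Series(
        {s: s.split("_")[0] for s in counts.columns}, name="condition"
    )
    lengths = pd.Series(
        truth.genes["length_bp"].to_numpy(),
        index=truth.genes["gene_id"].to_numpy(),
        name="length_bp",
    )
    return CountMatrix(counts, condition), lengths


def simulate_dataset(cfg: SyntheticConfig) -> SyntheticTruth:
    """Genome + sites + genes with motifs planted (tags/expression on demand)."""
    truth = simulate_genome(cfg)
    if cfg.motif_planted_fraction > 0:
        plant_motifs(truth)
    return truth


def write_dataset(truth: SyntheticTruth, outdir) -> None:
    """Write FASTA, BED, annotation/truth TSVs and a config JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in truth.genome.items()
    ]
    SeqIO.write(records, out / "genome.fa", "fasta")
    truth.sites.to_csv(out / "sites_truth.tsv", sep="\t", index=False)
    with open(out / "sites.bed", "w") as fh:
        for r in truth.sites.itertuples():
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.site_id}\n")
    truth.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    cfg_dict = dataclasses.asdict(truth.config)
    cfg_dict["gene_length_range"] = list(cfg_dict["gene_length_range"])
    (out / "config.json").write_text(json.dumps(cfg_dict, indent=2))


def write_tag_libraries(libs: Sequence[TagLibrary], outdir) -> Path:
    """Write tag TSVs plus a manifest; returns the manifest path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for lib in libs:
        fname = f"{lib.sample_id}.tags.tsv"
        write_tag_file(out / fname, lib)
        rows.append((lib.sample_id, fname, lib.total_tags))
    manifest = out / "manifest.tsv"
    pd.DataFrame(rows, columns=["sample_id", "path", "total_tags"]).to_csv(
        manifest, sep="\t", index=False
    )
    return manifest
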