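"""PWM scanning and simplified de novo k-mer motif enrichment.

De novo discovery follows the classical mismatch-string scheme: every k-mer
seen in the target sequences is a candidate; a sequence "contains" a
candidate when any window on either strand lies within a Hamming-distance
budget (default 2 mismatches); enrichment of target hit counts over hit
counts in sampled background regions is scored with an exact binomial tail.
Candidates within Hamming distance 1 of a better-ranked candidate are
collapsed so near-duplicate strings do not flood the ranking. No GC or CpG
matching is applied to the background sample; backgrounds are uniform draws
from the supplied genome that avoid an exclusion set.

Enumeration is exhaustive over observed k-mers, so k is capped at 12.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, PeakSet, overlap

BASES = "ACGT"
_CODE = {c: i for i, c in enumerate(BASES)}
_CODE["N"] = 4
_COMP = {0: 3, 1: 2, 2: 1, 3: 0, 4: 4}

MAX_K = 12


class MotifError(ValueError):
    pass


@dataclass
class PWM:
    """Position probability matrix over A,C,G,T with a background vector."""

    probs: np.ndarray  # (k, 4)
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    name: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise MotifError("PWM probs must be (k, 4)")
        if np.any(self.probs < 0) or np.any(
            np.abs(self.probs.sum(axis=1) - 1) > 1e-9
        ):
            raise MotifError("PWM rows must be non-negative and sum to 1")
        if abs(self.background.sum() - 1) > 1e-9:
            raise MotifError("background must sum to 1")

    @property
    def k(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_consensus(
        cls, consensus: str, match_prob: float = 0.9, name: str = ""
    ) -> "PWM":
        """PWM with ``match_prob`` at each consensus base, rest uniform."""
        k = len(consensus)
        probs = np.full((k, 4), (1 - match_prob) / 3)
        for i, c in enumerate(consensus.upper()):
            probs[i, _CODE[c]] = match_prob
        return cls(probs, name=name or consensus)

    def log_odds(self) -> np.ndarray:
        """(5, k) log2(p/bg) lookup; row 4 (N) is -inf."""
        with np.errstate(divide="ignore"):
            lo = np.log2(self.probs.T / self.background[:, None])
        return np.vstack([lo, np.full((1, self.k), -np.inf)])

    def sample(self, rng: np.random.Generator) -> str:
        idx = [rng.choice(4, p=row) for row in self.probs]
        return "".join(BASES[i] for i in idx)


@dataclass
class KmerMotif:
    consensus: str
    max_mismatch: int  # mismatch budget of the search
    n_target_hit: int
    n_target: int
    n_bg_hit: int
    n_bg: int
    p: float
    rank: int = 0
    radius: int = 0  # mismatch radius at which the reported p was achieved
    n_candidates: int = 0  # candidates scored in the search that produced this


def encode(seq: str) -> np.ndarray:
    """DNA string -> int8 codes (A,C,G,T,N -> 0..4); other letters -> N."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def reverse_complement(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(seq.upper()))


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

def _scores_one_strand(codes: np.ndarray, lut: np.ndarray, k: int) -> np.ndarray:
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0)
    acc = np.zeros(n)
    for j in range(k):
        acc += lut[codes[j : j + n], j]
    return acc


def pwm_scores(seq: str, pwm: PWM) -> tuple[np.ndarray, np.ndarray]:
    """Per-offset log-odds scores on the forward and reverse strands."""
    lut = pwm.log_odds()
    fwd = encode(seq)
    rev = np.array([_COMP[int(c)] for c in fwd[::-1]], dtype=np.int8)
    return (
        _scores_one_strand(fwd, lut, pwm.k),
        _scores_one_strand(rev, lut, pwm.k),
    )


def scan_pwm(
    sequences: Sequence[str], pwm: PWM, score_threshold: float
) -> list[int]:
    """Per-sequence count of offsets scoring >= threshold on either strand.

    The score at an offset is the sum of per-position log2(p/bg); windows
    containing N score -inf. A sequence counts as a hit when it has at least
    one scoring offset.
    """
    lut = pwm.log_odds()  # lut[code, position]
    k = pwm.k
    out = []
    for seq in sequences:
        fwd = encode(seq)
        rev = np.array([_COMP[int(c)] for c in fwd[::-1]], dtype=np.int8)
        n_hits = 0
        for codes in (fwd, rev):
            s = _scores_one_strand(codes, lut, k)
            n_hits += int(np.count_nonzero(s >= score_threshold))
        out.append(n_hits)
    return out


def n_sequences_hit(hit_counts: Iterable[int]) -> int:
    return sum(1 for h in hit_counts if h > 0)


# ---------------------------------------------------------------------------
# Background sampling
# ---------------------------------------------------------------------------

def sample_background_regions(
    genome: dict[str, str],
    n: int = 50_000,
    width: int = 200,
    exclude: Optional[PeakSet] = None,
    seed: int | np.random.Generator = 0,
    max_tries_per_region: int = 50,
) -> PeakSet:
    """Sample n width-bp windows uniformly from the genome, avoiding
    ``exclude`` and windows with non-ACGT characters. Deterministic given
    the seed; raises if the exclusion leaves too little room, reporting how
    many windows were placed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = sorted(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    if np.any(lengths < width):
        chroms = [c for c, L in zip(chroms, lengths) if L >= width]
        lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    if not chroms:
        raise MotifError(f"no chromosome can host a {width} bp window")
    weights = lengths / lengths.sum()
    excl = (exclude or PeakSet()).by_chrom()
    excl_bounds = {
        c: (np.array([iv.start for iv in ivs]), np.array([iv.end for iv in ivs]))
        for c, ivs in excl.items()
    }

    regions: list[GenomicInterval] = []
    budget = n * max_tries_per_region
    while len(regions) < n and budget > 0:
        budget -= 1
        ci = rng.choice(len(chroms), p=weights)
        chrom = chroms[ci]
        start = int(rng.integers(0, len(genome[chrom]) - width + 1))
        end = start + width
        if chrom in excl_bounds:
            starts, ends = excl_bounds[chrom]
            if np.any((starts < end) & (ends > start)):
                continue
        window = genome[chrom][start:end]
        if any(c not in "ACGT" for c in window.upper()):
            continue
        regions.append(GenomicInterval(chrom, start, end, name=f"bg_{len(regions)}"))
    if len(regions) < n:
        raise MotifError(
            f"could not place {n} background windows; achieved {len(regions)}"
        )
    return PeakSet(regions, "background")


def extract_sequences(genome: dict[str, str], peaks: PeakSet) -> list[str]:
    out = []
    for iv in peaks:
        seq = genome[iv.chrom][iv.start : iv.end]
        out.append(seq.upper())
    return out


# ---------------------------------------------------------------------------
# Binomial enrichment
# ---------------------------------------------------------------------------

def binomial_enrichment(
    n_target_hit: int, n_target: int, n_bg_hit: int, n_bg: int
) -> float:
    """Exact binomial upper-tail P(X >= n_target_hit), X ~ Bin(n_target, p0)
    with p0 the background hit rate floored at 1/(2*n_bg)."""
    if not (0 <= n_target_hit <= n_target and 0 <= n_bg_hit <= n_bg):
        raise ValueError("inconsistent hit counts")
    if n_bg <= 0:
        raise ValueError("n_bg must be positive")
    p0 = max(n_bg_hit / n_bg, 1.0 / (2 * n_bg))
    p0 = min(p0, 1.0)
    if n_target_hit == 0:
        return 1.0
    return float(stats.binom.sf(n_target_hit - 1, n_target, p0))


def _conditional_binomial(
    n_target_hit: int, n_target: int, n_bg_hit: int, n_bg: int, min_seed: int
) -> float:
    """Binomial tail with the seeding sequences excluded.

    Candidates are selected for occurring exactly in >= min_seed target
    sequences, which guarantees those sequences are hits at every radius; a
    naive tail over all targets would therefore call every seeded k-mer
    enriched even on null data. The test is run on the remaining
    n_target - min_seed sequences only.
    """
    n_eff = n_target - min_seed
    k_eff = n_target_hit - min_seed
    if n_eff <= 0:
        return 1.0
    return binomial_enrichment(max(k_eff, 0), n_eff, n_bg_hit, n_bg)


# ---------------------------------------------------------------------------
# De novo k-mer enrichment
# ---------------------------------------------------------------------------

def _kmer_code(codes: np.ndarray, k: int) -> np.ndarray:
    """Base-4 integer codes of all N-free k windows in a code array."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    vals = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for j in range(k):
        window = codes[j : j + n].astype(np.int64)
        ok &= window < 4
        vals = vals * 4 + np.where(window < 4, window, 0)
    return vals[ok]


def _code_to_string(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def _revcomp_code(code: int, k: int) -> int:
    out = 0
    for _ in range(k):
        out = out * 4 + (3 - (code % 4))
        code //= 4
    return out


def _hamming_ball(code: int, k: int, radius: int) -> np.ndarray:
    """All base-4 codes within Hamming distance <= radius of ``code``."""
    digits = [(code >> (2 * (k - 1 - i))) & 3 for i in range(k)]
    ball = {code}
    for m in range(1, radius + 1):
        for pos_combo in combinations(range(k), m):
            for repl in product(range(3), repeat=m):
                c = code
                for pos, r in zip(pos_combo, repl):
                    shift = 2 * (k - 1 - pos)
                    old = digits[pos]
                    new = r if r < old else r + 1
                    c = c - (old << shift) + (new << shift)
                ball.add(c)
    return np.fromiter(ball, dtype=np.int64)


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


class _KmerIndex:
    """Sorted (code, seq_id) pairs over both strands of a sequence panel."""

    def __init__(self, sequences: Sequence[str], k: int):
        codes_all = []
        ids_all = []
        self.n_seqs = len(sequences)
        for sid, seq in enumerate(sequences):
            fwd = encode(seq)
            rev = np.array([_COMP[int(c)] for c in fwd[::-1]], dtype=np.int8)
            cs = np.unique(
                np.concatenate([_kmer_code(fwd, k), _kmer_code(rev, k)])
            )
            codes_all.append(cs)
            ids_all.append(np.full(cs.size, sid, dtype=np.int32))
        if codes_all:
            codes = np.concatenate(codes_all)
            ids = np.concatenate(ids_all)
            order = np.argsort(codes, kind="stable")
            self.codes = codes[order]
            self.ids = ids[order]
        else:
            self.codes = np.empty(0, dtype=np.int64)
            self.ids = np.empty(0, dtype=np.int32)

    def n_hit(self, ball: np.ndarray) -> int:
        lo = np.searchsorted(self.codes, ball, side="left")
        hi = np.searchsorted(self.codes, ball, side="right")
        picks = [self.ids[a:b] for a, b in zip(lo, hi) if b > a]
        if not picks:
            return 0
        return int(np.unique(np.concatenate(picks)).size)

    def seq_frequency(self) -> dict[int, int]:
        """code -> number of distinct sequences containing it exactly."""
        if self.codes.size == 0:
            return {}
        uniq, start = np.unique(self.codes, return_index=True)
        counts = np.diff(np.append(start, self.codes.size))
        return dict(zip(uniq.tolist(), counts.tolist()))


def denovo_kmer_enrichment(
    target_seqs: Sequence[str],
    background_seqs: Sequence[str],
    k: int = 8,
    max_mismatch: int = 2,
    top: int = 10,
    min_seed_seqs: int = 3,
) -> list[KmerMotif]:
    """Rank k-mers by exact-binomial enrichment of mismatch hits in targets
    over backgrounds.

    Candidates are k-mers occurring exactly (either strand) in at least
    ``min_seed_seqs`` target sequences; reverse-complement duplicates are
    merged onto the lexicographically smaller strand. Each candidate is
    scored at every mismatch radius 0..max_mismatch (a sequence is a hit
    when any window on either strand lies within the radius) and keeps its
    best binomial p. Scoring at the best radius matters: with a fixed radius
    of 2, strings overlapping a true motif by k-2 bases match all of its
    instances through the free mismatches and can outrank the motif itself,
    while exact-match counts separate them cleanly.

    Because candidates are seeded by their exact target occurrence, the
    binomial tail is conditioned on the seeding event,
    p = P(X >= n_hit | X >= min_seed_seqs); without the conditioning every
    seeded k-mer looks enriched at radius 0 even on null data; and because
    the reported p is the minimum over the radii searched, it carries a
    Bonferroni factor of max_mismatch+1. Ranking is
    ascending by p with ties broken by target hits then string; candidates
    within Hamming distance 1 of a better-ranked survivor are collapsed.
    ``n_candidates`` on each result records how many candidates were scored
    (the multiplicity a Bonferroni adjustment of the top p should use).
    """
    if k > MAX_K:
        raise MotifError(f"k={k} exceeds enumeration bound {MAX_K}")
    if any(len(s) < k for s in target_seqs):
        raise MotifError("all target sequences must be at least k long")
    t_idx = _KmerIndex(target_seqs, k)
    b_idx = _KmerIndex(background_seqs, k)
    n_target = len(target_seqs)
    n_bg = len(background_seqs)

    freq = t_idx.seq_frequency()
    seen: set[int] = set()
    candidates: list[int] = []
    for code, nf in sorted(freq.items()):
        if nf < min_seed_seqs or code in seen:
            continue
        rc = _revcomp_code(code, k)
        seen.add(code)
        seen.add(rc)
        candidates.append(min(code, rc))

    scored = []
    for code in candidates:
        rc = _revcomp_code(code, k)
        best = None
        for radius in range(max_mismatch + 1):
            ball = np.unique(
                np.concatenate(
                    [_hamming_ball(code, k, radius), _hamming_ball(rc, k, radius)]
                )
            )
            nt = t_idx.n_hit(ball)
            nb = b_idx.n_hit(ball)
            p = _conditional_binomial(nt, n_target, nb, n_bg, min_seed_seqs)
            if best is None or p < best[0]:
                best = (p, -nt, _code_to_string(code, k), nt, nb, radius)
        # Bonferroni over the radii searched: the reported p is a minimum
        # over max_mismatch+1 correlated tests
        best = (min(1.0, best[0] * (max_mismatch + 1)),) + best[1:]
        scored.append(best)
    scored.sort()

    kept: list[KmerMotif] = []
    for p, _negnt, s, nt, nb, radius in scored:
        if any(
            _hamming(s, kk.consensus) <= 1
            or _hamming(s, reverse_complement(kk.consensus)) <= 1
            for kk in kept
        ):
            continue
        kept.append(
            KmerMotif(
                consensus=s,
                max_mismatch=max_mismatch,
                n_target_hit=nt,
                n_target=n_target,
                n_bg_hit=nb,
                n_bg=n_bg,
                p=p,
                rank=len(kept) + 1,
                radius=radius,
                n_candidates=len(scored),
            )
        )
        if len(kept) >= top:
            break
    return kept


def pwm_from_kmer_hits(motif: KmerMotif, target_seqs: Sequence[str]) -> PWM:
    """Position-frequency matrix from each sequence's best match to the
    consensus (either strand, min Hamming distance), +0.25 pseudocount."""
    k = len(motif.consensus)
    cons = motif.consensus
    rc_cons = reverse_complement(cons)
    counts = np.full((k, 4), 0.25)
    n_hits = 0
    for seq in target_seqs:
        best = None
        best_d = motif.max_mismatch + 1
        for ref, flip in ((cons, False), (rc_cons, True)):
            for i in range(len(seq) - k + 1):
                w = seq[i : i + k].upper()
                if "N" in w:
                    continue
                d = _hamming(w, ref)
                if d < best_d:
                    best_d = d
                    best = reverse_complement(w) if flip else w
        if best is None:
            continue
        n_hits += 1
        for j, c in enumerate(best):
            counts[j, _CODE[c]] += 1
    if n_hits == 0:
        raise MotifError("motif has no target hits to refine")
    probs = counts / counts.sum(axis=1, keepdims=True)
    return PWM(probs, name=motif.consensus)


def motifs_to_frame(motifs: Sequence[KmerMotif]):
    import pandas as pd

    return pd.DataFrame(
        {
            "rank": [m.rank for m in motifs],
            "consensus": [m.consensus for m in motifs],
            "n_target_hit": [m.n_target_hit for m in motifs],
            "n_target": [m.n_target for m in motifs],
            "n_bg_hit": [m.n_bg_hit for m in motifs],
            "n_bg": [m.n_bg for m in motifs],
            "p": [m.p for m in motifs],
        }
    ).set_index("rank")


def write_pwm(path, pwm: PWM) -> None:
    """JASPAR-style 4-row tab layout (A/C/G/T probabilities per position)."""
    with open(path, "w") as fh:
        fh.write(f">{pwm.name}\n")
        for bi, base in enumerate(BASES):
            row = "\t".join(format(p, ".4f") for p in pwm.probs[:, bi])
            fh.write(f"{base}\t{row}\n")
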