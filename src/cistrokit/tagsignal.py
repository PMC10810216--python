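"""Tag libraries, window counting, depth normalization and binned profiles.

A "tag" is one mapped sequencing read reduced to a single genomic position.
All signal quantities are depth-normalized to a reference library size of
10 million mapped tags; binned profiles are additionally divided by the bin
width so values are tag densities (tags per bp per site, per 10 M tags).

Site-level box-plot quantities are ``log2(normalized count + pseudocount)``
with a default pseudocount of 1. The pseudocount interacts with the
pre-accessibility threshold used downstream (log2 tags > 1), so it is an
explicit parameter everywhere rather than a hidden constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, PeakSet, center_window

logger = logging.getLogger(__name__)

REFERENCE_DEPTH = 10_000_000


class InvalidLibraryError(ValueError):
    pass


@dataclass
class TagLibrary:
    """Per-chromosome sorted tag positions plus the library's total tag count.

    ``total_tags`` may exceed the number of stored positions (tags mapped
    outside the simulated/stored region still count toward depth).
    """

    positions: dict[str, np.ndarray]
    total_tags: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        clean = {}
        n_stored = 0
        for chrom, pos in self.positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            if arr.size and np.any(np.diff(arr) < 0):
                arr = np.sort(arr)
            clean[chrom] = arr
            n_stored += arr.size
        self.positions = clean
        if self.total_tags < n_stored:
            raise InvalidLibraryError(
                f"total_tags={self.total_tags} < stored positions {n_stored}"
            )

    @property
    def n_stored(self) -> int:
        return sum(arr.size for arr in self.positions.values())

    @classmethod
    def pool(cls, libs: Sequence["TagLibrary"], sample_id: str = "pooled") -> "TagLibrary":
        """Concatenate replicate libraries into one (totals add)."""
        chroms = {c for lib in libs for c in lib.positions}
        pos = {
            c: np.sort(
                np.concatenate(
                    [lib.positions.get(c, np.empty(0, np.int64)) for lib in libs]
                )
            )
            for c in chroms
        }
        return cls(pos, sum(lib.total_tags for lib in libs), sample_id)


@dataclass
class SignalMatrix:
    """Sites x bins normalized tag densities around peak centers."""

    site_ids: list[str]
    bin_edges: np.ndarray  # offsets relative to peak center, length n_bins+1
    values: np.ndarray  # (n_sites, n_bins), tags/bp/site per 10M tags


@dataclass
class SiteDensity:
    site_id: str
    raw_count: int
    norm_count: float
    log2_density: float


def count_tags(lib: TagLibrary, iv: GenomicInterval) -> int:
    """Number of tag positions p with start <= p < end (binary search)."""
    pos = lib.positions.get(iv.chrom)
    if pos is None:
        logger.debug("chromosome %s absent from library %s", iv.chrom, lib.sample_id)
        return 0
    lo = np.searchsorted(pos, iv.start, side="left")
    hi = np.searchsorted(pos, iv.end, side="left")
    return int(hi - lo)


def count_tags_many(lib: TagLibrary, peaks: PeakSet) -> np.ndarray:
    """Vectorized count_tags over a PeakSet (same order as the set)."""
    out = np.zeros(len(peaks), dtype=np.int64)
    for i, iv in enumerate(peaks):
        out[i] = count_tags(lib, iv)
    return out


def normalize_to_depth(count: float, total_tags: int) -> float:
    """Scale a raw count to the 10-million-mapped-tags reference depth."""
    if total_tags <= 0:
        raise InvalidLibraryError(f"total_tags must be positive, got {total_tags}")
    return count * REFERENCE_DEPTH / total_tags


def profile_matrix(
    lib: TagLibrary,
    peaks: PeakSet,
    halfwidth: int = 1000,
    bin_size: int = 10,
) -> SignalMatrix:
    """Binned +/-halfwidth tag-density profile around each peak center.

    values[i, j] is the depth-normalized tag count in bin j of site i divided
    by bin_size, i.e. local tag density in tags per bp per site per 10M tags.
    """
    if bin_size <= 0 or (2 * halfwidth) % bin_size != 0:
        raise ValueError(
            f"bin_size {bin_size} must be positive and divide 2*halfwidth {2 * halfwidth}"
        )
    n_bins = 2 * halfwidth // bin_size
    edges = np.arange(-halfwidth, halfwidth + 1, bin_size)
    values = np.zeros((len(peaks), n_bins))
    site_ids = []
    for i, iv in enumerate(peaks):
        site_ids.append(iv.name or f"site_{i}")
        c = iv.center
        pos = lib.positions.get(iv.chrom)
        if pos is None:
            continue
        counts, _ = np.histogram(pos, bins=edges + c)
        values[i] = counts * (REFERENCE_DEPTH / lib.total_tags) / bin_size
    return SignalMatrix(site_ids, edges, values)


def site_log2_density(
    lib: TagLibrary, peaks: PeakSet, pseudocount: float = 1.0
) -> list[SiteDensity]:
    """Per-peak raw count, normalized count, and log2(norm + pseudocount).

    Counts are taken over the peak interval itself (peak-width counting); use
    ``center_window`` upstream to count over a fixed window instead.
    """
    out = []
    for i, iv in enumerate(peaks):
        raw = count_tags(lib, iv)
        norm = normalize_to_depth(raw, lib.total_tags)
        out.append(
            SiteDensity(
                site_id=iv.name or f"site_{i}",
                raw_count=raw,
                norm_count=norm,
                log2_density=float(np.log2(norm + pseudocount)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# I/O: tag files are 2-column TSV (chrom, position); a manifest TSV lists
# sample_id, path, total_tags (+ optional condition/assay columns).
# ---------------------------------------------------------------------------

def read_tag_file(path, total_tags: int | None = None, sample_id: str = "") -> TagLibrary:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos"],
                     dtype={"chrom": str, "pos": np.int64})
    positions = {
        chrom: np.sort(sub["pos"].to_numpy())
        for chrom, sub in df.groupby("chrom", sort=True)
    }
    n = int(df.shape[0])
    return TagLibrary(positions, total_tags if total_tags is not None else n,
                      sample_id or Path(str(path)).stem)


def write_tag_file(path, lib: TagLibrary) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(lib.positions):
            for p in lib.positions[chrom]:
                fh.write(f"{chrom}\t{p}\n")


def read_tag_manifest(path) -> list[tuple[TagLibrary, dict]]:
    """Read a manifest TSV; returns (library, metadata-row) tuples.

    Relative paths in the manifest are resolved against the manifest's parent
    directory.
    """
    man = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "path", "total_tags"}
    missing = required - set(man.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if man["sample_id"].duplicated().any():
        raise ValueError("duplicated sample_id in manifest")
    base = Path(str(path)).parent
    out = []
    for _, row in man.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        lib = read_tag_file(p, int(row["total_tags"]), row["sample_id"])
        out.append((lib, row.to_dict()))
    return out


def write_signal_matrix(path, sm: SignalMatrix) -> None:
    """TSV with a header row of bin start offsets and one row per site."""
    starts = sm.bin_edges[:-1]
    with open(path, "w") as fh:
        fh.write("site_id\t" + "\t".join(str(int(s)) for s in starts) + "\n")
        for sid, row in zip(sm.site_ids, sm.values):
            fh.write(sid + "\t" + "\t".join(format(v, ".6g") for v in row) + "\n")
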