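"""Fixed-width genomic bin grids and per-bin read-count containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .karyotype import CytobandMap

__all__ = ["BinGrid", "BinCounts", "build_bin_grid"]

MIN_BIN_SIZE = 100_000


@dataclass(frozen=True)
class BinGrid:
    """Ordered fixed-width bins tiling each chromosome, with GC fraction."""

    chroms: tuple[str, ...]          # chromosome label per bin
    starts: np.ndarray               # bp, 0-based
    ends: np.ndarray                 # bp, half-open
    gc: np.ndarray                   # fraction in [0, 1]
    bin_size: int
    lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not (len(self.chroms) == len(self.starts) == len(self.ends)
                == len(self.gc)):
            raise ValueError("grid arrays must have equal length")
        if np.any(self.gc < 0) or np.any(self.gc > 1):
            raise ValueError("GC fractions must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.chroms)

    @property
    def chromosomes(self) -> list[str]:
        seen = dict.fromkeys(self.chroms)
        return list(seen)

    def chrom_index(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.chroms) == chrom)

    @property
    def autosomal(self) -> np.ndarray:
        arr = np.asarray(self.chroms)
        return (arr != "X") & (arr != "Y")

    def overlap_fraction(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-bin fraction of the bin covered by [start, end) on chrom."""
        frac = np.zeros(len(self), dtype=float)
        idx = self.chrom_index(chrom)
        lo = np.maximum(self.starts[idx], start)
        hi = np.minimum(self.ends[idx], end)
        widths = (self.ends[idx] - self.starts[idx]).astype(float)
        frac[idx] = np.clip(hi - lo, 0, None) / widths
        return frac


@dataclass(frozen=True)
class BinCounts:
    """Raw per-bin read counts for one blastomere, aligned to a grid."""

    sample_id: str
    counts: np.ndarray
    total_reads: int

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if np.any(counts < 0):
            raise ValueError("negative bin counts")
        if counts.sum() > self.total_reads:
            raise ValueError("sum of bin counts exceeds total reads")


def _synthetic_gc(grid_chroms, starts, lengths, seed) -> np.ndarray:
    """Smooth, spatially correlated synthetic GC landscape per chromosome."""
    rng = np.random.default_rng(seed)
    gc = np.empty(len(grid_chroms))
    arr = np.asarray(grid_chroms)
    for chrom in dict.fromkeys(grid_chroms):
        idx = np.flatnonzero(arr == chrom)
        L = lengths[chrom]
        phase = rng.uniform(0, 2 * np.pi)
        waves = (0.05 * np.sin(2 * np.pi * 2.5 * starts[idx] / L + phase)
                 + 0.02 * np.sin(2 * np.pi * 7.0 * starts[idx] / L + 2 * phase))
        noise = rng.normal(0, 0.035, len(idx))
        kernel = np.ones(9) / 9
        smooth = np.convolve(np.pad(noise, 4, mode="edge"), kernel, "valid")
        gc[idx] = 0.41 + waves + smooth
    return np.clip(gc, 0.30, 0.62)


def build_bin_grid(cytomap: CytobandMap, bin_size: int = 1_000_000,
                   gc_model: str = "synthetic", seed: int = 0,
                   gc: np.ndarray | None = None) -> BinGrid:
    """Tile every chromosome of ``cytomap`` with fixed-width bins.

    The final bin of each chromosome is truncated at the chromosome end.
    GC content per bin is drawn from a smooth synthetic model (``gc_model=
    "synthetic"``), constant 0.40 (``"flat"``), or supplied directly.
    """
    if bin_size < MIN_BIN_SIZE:
        raise ValueError(f"bin size must be >= {MIN_BIN_SIZE} bp")
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for chrom in cytomap.chromosomes:
        L = cytomap.lengths[chrom]
        pos = 0
        while pos < L:
            chroms.append(chrom)
            starts.append(pos)
            ends.append(min(pos + bin_size, L))
            pos += bin_size
    starts_a = np.asarray(starts, dtype=np.int64)
    ends_a = np.asarray(ends, dtype=np.int64)
    if gc is not None:
        gc_a = np.asarray(gc, dtype=float)
    elif gc_model == "flat":
        gc_a = np.full(len(chroms), 0.40)
    elif gc_model == "synthetic":
        gc_a = _synthetic_gc(chroms, starts_a, cytomap.lengths, seed)
    else:
        raise ValueError(f"unknown gc model {gc_model!r}")
    return BinGrid(tuple(chroms), starts_a, ends_a, gc_a, bin_size,
                   dict(cytomap.lengths))
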