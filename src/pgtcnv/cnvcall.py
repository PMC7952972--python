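"""Low-pass single-cell CNV calling from 1 Mb bin counts.

The analysis chain mirrors standard low-pass whole-genome CNV practice for
single-cell PGT: per-sample QC on read yield and profile noise (MAPD),
normalization against a reference panel of euploid samples plus a residual
stratified-median GC correction, recursive binary-split segmentation of the
per-chromosome ratio profile, and integer copy-number / mosaic-fraction
calling.  On the normalized scale a ratio of 1.0 corresponds to two copies,
so a two-to-three-copy gain raises the affected bins by 50% and a
two-to-one loss lowers them by 50%; intermediate shifts are read as mosaic
with fraction f = |c - expected|, and events with f > 0.4 block transfer.

A scikit-learn style estimator, :class:`CopyNumberCaller`, wraps the chain
(``fit`` builds the reference panel from normal samples, ``transform``
normalizes, ``predict`` returns per-embryo call sets).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator

from .bins import BinCounts, BinGrid

__all__ = [
    "CallerConfig",
    "QCResult",
    "ReferencePanel",
    "NormalizedProfile",
    "SegmentCall",
    "EmbryoCallSet",
    "qc_assess",
    "build_reference",
    "normalize",
    "segment",
    "call_segments",
    "call_sample",
    "CopyNumberCaller",
]

_EPS = 1e-9


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds for QC, normalization, segmentation and calling.

    ``mosaic_threshold`` is the clinical 40% rule: events with estimated
    mosaic fraction above it are reported and block transfer.
    ``full_threshold`` separates mosaic from full-dose events at
    |c - expected| >= 0.8.
    """

    min_reads_per_bin: float = 100.0
    max_mapd: float = 0.35
    min_panel_samples: int = 3
    panel_mask_floor: float = 0.1
    max_masked_fraction: float = 0.20
    gc_stratum_width: float = 0.02
    split_threshold: float = 3.5      # in units of estimated bin noise sigma
    sigma_floor: float = 0.01
    merge_delta: float = 0.15
    min_segment_bins: int = 3
    single_bin_amplitude: float = 0.8
    mosaic_threshold: float = 0.4
    full_threshold: float = 0.8
    whole_chrom_cover: float = 0.9
    male_x_threshold: float = 0.75    # X ratio below this implies XY
    female_y_ceiling: float = 0.1


@dataclass(frozen=True)
class QCResult:
    informative: bool
    noise: float                 # MAPD of neighboring raw bin ratios
    usable_reads: int
    reasons: tuple[str, ...] = ()


@dataclass(frozen=True)
class ReferencePanel:
    """Per-bin expected relative depth built from designated normals."""

    factors: np.ndarray          # median-1 over unmasked autosomal bins
    mask: np.ndarray             # True where the bin is unusable
    n_samples: int
    sexes: tuple[str, ...] = ()


@dataclass(frozen=True)
class NormalizedProfile:
    sample_id: str
    ratios: np.ndarray           # 1.0 == two copies
    mask: np.ndarray
    sex: str                     # XX | XY


@dataclass(frozen=True)
class SegmentCall:
    """One segment of the normalized profile with its copy-number call."""

    chrom: str
    start: int
    end: int
    bin_start: int
    bin_end: int
    mean_ratio: float
    copy_number: float = 2.0     # continuous c = 2 * ratio (sex-adjusted)
    expected: float = 2.0
    call: int = 2
    mosaic_fraction: float = 0.0
    mosaic: bool = False
    whole_chromosome: bool = False

    @property
    def n_bins(self) -> int:
        return self.bin_end - self.bin_start

    @property
    def size_mb(self) -> float:
        return (self.end - self.start) / 1e6

    @property
    def delta(self) -> float:
        return self.copy_number - self.expected

    @property
    def sign(self) -> int:
        return 1 if self.delta > 0 else -1


@dataclass(frozen=True)
class EmbryoCallSet:
    sample_id: str
    qc: QCResult
    segments: tuple[SegmentCall, ...]      # abnormal segments only
    chrom_status: dict[str, str] = field(default_factory=dict)
    sex: str = "XX"

    @property
    def euploid(self) -> bool:
        return not self.segments


def _autosomal_baseline(values: np.ndarray, grid: BinGrid,
                        good: np.ndarray) -> float:
    """Robust two-copy baseline: median of per-chromosome medians over
    autosomes.  A plain pooled median is biased on small genomes where a
    single whole-chromosome aneuploidy occupies a large bin fraction."""
    chroms = np.asarray(grid.chroms)
    meds = []
    for chrom in grid.chromosomes:
        if chrom in ("X", "Y"):
            continue
        sel = (chroms == chrom) & good
        if sel.any():
            meds.append(np.nanmedian(values[sel]))
    if not meds:
        return 0.0
    meds = np.asarray(meds)
    m0 = np.median(meds)
    if m0 <= 0:
        return float(m0)
    # average the chromosomes consistent with the central dose; a plain
    # median of 3 medians would land on the extreme normal chromosome
    # whenever one chromosome is aneuploid
    near = meds[np.abs(meds / m0 - 1.0) <= 0.15]
    return float(near.mean()) if near.size else float(m0)


def _mapd(values: np.ndarray, chroms: np.ndarray) -> float:
    """Median absolute pairwise deviation of neighboring bins, computed
    within chromosomes only."""
    same = chroms[1:] == chroms[:-1]
    diffs = np.abs(np.diff(values))[same]
    return float(np.median(diffs)) if diffs.size else np.inf


def qc_assess(counts: BinCounts, grid: BinGrid,
              cfg: CallerConfig | None = None) -> QCResult:
    """Deterministic per-sample QC: read yield and raw-profile noise."""
    cfg = cfg or CallerConfig()
    c = np.asarray(counts.counts, dtype=float)
    if len(c) != len(grid):
        raise ValueError(
            f"counts length {len(c)} does not match grid length {len(grid)}")
    usable = int(c.sum())
    reasons = []
    med = _autosomal_baseline(c, grid, np.ones(len(c), dtype=bool))
    if usable < cfg.min_reads_per_bin * len(grid) or med <= 0:
        reasons.append("reads")
        noise = np.inf
    else:
        ratios = c / med
        noise = _mapd(ratios, np.asarray(grid.chroms))
        if noise > cfg.max_mapd:
            reasons.append("noise")
    return QCResult(not reasons, noise, usable, tuple(reasons))


def _infer_sex_raw(c: np.ndarray, grid: BinGrid) -> str:
    auto_med = _autosomal_baseline(c, grid, np.ones(len(c), dtype=bool))
    x_idx = grid.chrom_index("X")
    if auto_med <= 0 or x_idx.size == 0:
        return "XX"
    x_rel = np.median(c[x_idx]) / auto_med
    return "XY" if x_rel < 0.75 else "XX"


def build_reference(normals: list[BinCounts], grid: BinGrid,
                    cfg: CallerConfig | None = None) -> ReferencePanel:
    """Median per-bin relative depth across euploid samples.

    Autosomal factors use every sample.  X factors use the female subset
    (male subset doubled if no females), Y factors the male subset doubled
    so the panel everywhere expresses two-copy expected depth.  Bins with
    factor below ``panel_mask_floor`` are masked.
    """
    cfg = cfg or CallerConfig()
    if len(normals) < cfg.min_panel_samples:
        raise ValueError(
            f"reference panel needs >= {cfg.min_panel_samples} samples, "
            f"got {len(normals)}")
    mat = np.vstack([np.asarray(s.counts, dtype=float) for s in normals])
    if mat.shape[1] != len(grid):
        raise ValueError("panel counts do not match grid length")
    auto = grid.autosomal
    good = np.ones(mat.shape[1], dtype=bool)
    meds = np.array([_autosomal_baseline(row, grid, good) for row in mat])
    if np.any(meds <= 0):
        raise ValueError("a panel sample has zero autosomal median")
    rel = mat / meds[:, None]
    sexes = tuple(_infer_sex_raw(mat[i], grid) for i in range(len(normals)))
    factors = np.median(rel, axis=0)

    is_female = np.asarray([s == "XX" for s in sexes])
    for chrom, use_female in (("X", True), ("Y", False)):
        idx = grid.chrom_index(chrom)
        if idx.size == 0:
            continue
        sel = is_female if use_female else ~is_female
        if sel.any():
            sub = np.median(rel[sel][:, idx], axis=0)
            factors[idx] = sub if use_female else 2.0 * sub
        elif use_female and (~is_female).any():
            factors[idx] = 2.0 * np.median(rel[~is_female][:, idx], axis=0)
        else:
            factors[idx] = 0.0
    mask = ~np.isfinite(factors) | (factors < cfg.panel_mask_floor)
    scale = np.median(factors[auto & ~mask])
    factors = factors / scale
    return ReferencePanel(factors, mask, len(normals), sexes)


def normalize(counts: BinCounts, panel: ReferencePanel, grid: BinGrid,
              cfg: CallerConfig | None = None,
              force: bool = False) -> NormalizedProfile:
    """Panel + residual-GC normalization to the two-copy == 1.0 scale.

    ratio = (count / autosomal median) / panel factor, then each bin is
    divided by the median ratio of its 2%-wide GC stratum (computed over
    unmasked autosomal bins), then rescaled to autosomal median 1.  Sex is
    inferred from the X and Y median ratios.
    """
    cfg = cfg or CallerConfig()
    qc = qc_assess(counts, grid, cfg)
    if not qc.informative and not force:
        raise ValueError(
            f"sample {counts.sample_id} failed QC ({','.join(qc.reasons)}); "
            "pass force=True to normalize anyway")
    c = np.asarray(counts.counts, dtype=float)
    mask = panel.mask.copy()
    if mask.mean() > cfg.max_masked_fraction:
        raise ValueError("insufficient usable bins: masked fraction "
                         f"{mask.mean():.0%} exceeds {cfg.max_masked_fraction:.0%}")
    # zero-count bins are amplification dropout at this depth (even a
    # one-copy loss retains hundreds of reads per 1 Mb bin), not signal
    mask |= (c == 0) & (panel.factors > 0.3)
    auto = grid.autosomal
    med = _autosomal_baseline(c, grid, ~mask)
    if med <= 0:
        raise ValueError("zero autosomal baseline")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = (c / med) / panel.factors
    ratios[mask] = np.nan

    # residual GC correction: stratified medians of chromosome-centered
    # residuals over autosomal bins, so whole-chromosome aneuploidies do
    # not leak into the per-stratum factors
    chroms_arr = np.asarray(grid.chroms)
    chrom_med = np.ones(len(ratios))
    for chrom in grid.chromosomes:
        sel = (chroms_arr == chrom) & ~mask
        if sel.any():
            cm = np.nanmedian(ratios[sel])
            if np.isfinite(cm) and cm > 0:
                chrom_med[chroms_arr == chrom] = cm
    resid = ratios / chrom_med
    strata = np.floor(grid.gc / cfg.gc_stratum_width).astype(int)
    for s in np.unique(strata):
        in_s = strata == s
        ref = in_s & auto & ~mask
        if ref.sum() >= 5:
            m = np.nanmedian(resid[ref])
            if np.isfinite(m) and m > 0:
                ratios[in_s] = ratios[in_s] / m
    ratios = ratios / _autosomal_baseline(
        np.where(np.isnan(ratios), np.nan, ratios), grid, ~mask)

    sex = _infer_sex(ratios, grid, cfg)
    return NormalizedProfile(counts.sample_id, ratios, mask, sex)


def _infer_sex(ratios: np.ndarray, grid: BinGrid, cfg: CallerConfig) -> str:
    def _chrom_median(chrom: str, default: float) -> float:
        idx = grid.chrom_index(chrom)
        vals = ratios[idx]
        vals = vals[np.isfinite(vals)]
        return float(np.median(vals)) if vals.size else default

    x_ratio = _chrom_median("X", 1.0)
    y_ratio = _chrom_median("Y", 0.0)
    if x_ratio < cfg.male_x_threshold or y_ratio > 0.25:
        return "XY"
    return "XX"


def _cusum_stat(x: np.ndarray) -> tuple[int, float]:
    """Best split point and its two-sided mean-shift statistic
    sqrt(k(n-k)/n) * |mean(left) - mean(right)|."""
    n = len(x)
    cs = np.cumsum(x)
    k = np.arange(1, n)
    mean_l = cs[:-1] / k
    mean_r = (cs[-1] - cs[:-1]) / (n - k)
    t = np.sqrt(k * (n - k) / n) * np.abs(mean_l - mean_r)
    best = int(np.argmax(t))
    return best + 1, float(t[best])


def _binary_split(x: np.ndarray, threshold: float) -> list[int]:
    """Recursive binary segmentation; returns interior boundaries."""
    if len(x) < 2:
        return []
    k, stat = _cusum_stat(x)
    if stat <= threshold:
        return []
    left = _binary_split(x[:k], threshold)
    right = [k + b for b in _binary_split(x[k:], threshold)]
    return left + [k] + right


def estimate_sigma(profile: NormalizedProfile, grid: BinGrid,
                   cfg: CallerConfig) -> float:
    good = ~profile.mask & ~np.isnan(profile.ratios)
    chroms = np.asarray(grid.chroms)[good]
    mapd = _mapd(profile.ratios[good], chroms)
    sigma = mapd / (np.sqrt(2) * 0.6745) if np.isfinite(mapd) else 0.0
    return max(sigma, cfg.sigma_floor)


def segment(profile: NormalizedProfile, grid: BinGrid,
            cfg: CallerConfig | None = None) -> list[SegmentCall]:
    """Segment each chromosome's ratio profile by recursive binary
    splitting with a fixed mean-shift threshold; adjacent segments whose
    mean ratios differ by less than ``merge_delta`` are merged."""
    cfg = cfg or CallerConfig()
    sigma = estimate_sigma(profile, grid, cfg)
    out: list[SegmentCall] = []
    for chrom in grid.chromosomes:
        idx = grid.chrom_index(chrom)
        good = idx[~profile.mask[idx] & ~np.isnan(profile.ratios[idx])]
        if good.size == 0:
            continue
        x = profile.ratios[good]
        bounds = _binary_split(x, cfg.split_threshold * sigma)
        edges = [0] + bounds + [len(x)]
        pieces = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
        # merge adjacent pieces with near-equal means
        merged: list[tuple[int, int]] = []
        for lo, hi in pieces:
            if merged:
                plo, phi = merged[-1]
                if abs(np.mean(x[plo:phi]) - np.mean(x[lo:hi])) < cfg.merge_delta:
                    merged[-1] = (plo, hi)
                    continue
            merged.append((lo, hi))
        n_chrom_bins = idx.size
        for lo, hi in merged:
            bins = good[lo:hi]
            out.append(SegmentCall(
                chrom=chrom,
                start=int(grid.starts[bins[0]]),
                end=int(grid.ends[bins[-1]]),
                bin_start=int(bins[0]),
                bin_end=int(bins[-1]) + 1,
                mean_ratio=float(np.mean(x[lo:hi])),
                whole_chromosome=(hi - lo) >= cfg.whole_chrom_cover * n_chrom_bins,
            ))
    return out


def call_segments(segments: list[SegmentCall], profile: NormalizedProfile,
                  grid: BinGrid,
                  cfg: CallerConfig | None = None) -> EmbryoCallSet:
    """Integer copy-number and mosaic-fraction calls.

    c = 2 * mean ratio; expected copy is 2 on autosomes and sex-dependent
    on X/Y.  |c - expected| >= 0.8 is a full event, 0.4 < |c - expected|
    < 0.8 a mosaic event with fraction f = |c - expected|; below 0.4 no
    call.  Y signal in XX samples is never an event.
    """
    cfg = cfg or CallerConfig()
    expected_by_chrom = {}
    for chrom in grid.chromosomes:
        if chrom == "X":
            expected_by_chrom[chrom] = 2.0 if profile.sex == "XX" else 1.0
        elif chrom == "Y":
            expected_by_chrom[chrom] = 0.0 if profile.sex == "XX" else 1.0
        else:
            expected_by_chrom[chrom] = 2.0

    abnormal: list[SegmentCall] = []
    status = {chrom: "normal" for chrom in grid.chromosomes}
    for seg in segments:
        expected = expected_by_chrom[seg.chrom]
        if seg.chrom == "Y" and profile.sex == "XX":
            continue
        c = 2.0 * seg.mean_ratio
        delta = c - expected
        adelta = abs(delta)
        # dose deviations are resolved to 1% (the reporting resolution of
        # mosaic fractions) before threshold comparison, so the > 40%
        # rule is not tripped by sub-percent numerical error
        adelta_r = round(adelta, 2)
        if adelta_r <= cfg.mosaic_threshold + _EPS:
            continue
        mosaic = adelta_r < cfg.full_threshold - _EPS
        if mosaic:
            call = int(expected + (1 if delta > 0 else -1))
            f = adelta
        else:
            call = int(np.clip(round(c), 0, 6))
            f = min(adelta, 1.0)
        n_bins = seg.n_bins
        if n_bins < cfg.min_segment_bins and adelta_r < cfg.single_bin_amplitude - _EPS:
            continue
        seg = replace(seg, copy_number=c, expected=expected, call=call,
                      mosaic_fraction=f, mosaic=mosaic)
        abnormal.append(seg)
        label = "gain" if delta > 0 else "loss"
        if mosaic:
            label = f"mosaic-{label}"
        if seg.whole_chromosome:
            status[seg.chrom] = label
        elif status[seg.chrom] == "normal":
            status[seg.chrom] = f"segmental-{label}"
    qc = QCResult(True, np.nan, 0)
    return EmbryoCallSet(profile.sample_id, qc, tuple(abnormal), status,
                         profile.sex)


def call_sample(counts: BinCounts, panel: ReferencePanel, grid: BinGrid,
                cfg: CallerConfig | None = None) -> EmbryoCallSet:
    """QC -> normalize -> segment -> call for one sample.

    Non-informative samples come back with an empty call list and their
    QC record; callers exclude them from rates.
    """
    cfg = cfg or CallerConfig()
    qc = qc_assess(counts, grid, cfg)
    if not qc.informative:
        return EmbryoCallSet(counts.sample_id, qc, (), {}, "XX")
    profile = normalize(counts, panel, grid, cfg)
    segs = segment(profile, grid, cfg)
    callset = call_segments(segs, profile, grid, cfg)
    return replace(callset, qc=qc)


class CopyNumberCaller(BaseEstimator):
    """Scikit-learn style front end to the CNV-calling chain.

    ``fit(X)`` builds the reference panel from normal samples, where ``X``
    is a (n_samples, n_bins) count matrix or a list of :class:`BinCounts`;
    ``transform(X)`` returns normalized ratio profiles; ``predict(X)``
    returns one :class:`EmbryoCallSet` per sample.
    """

    def __init__(self, grid: BinGrid | None = None,
                 min_reads_per_bin: float = 100.0, max_mapd: float = 0.35,
                 min_panel_samples: int = 3, split_threshold: float = 3.5,
                 merge_delta: float = 0.15, min_segment_bins: int = 3,
                 mosaic_threshold: float = 0.4, full_threshold: float = 0.8):
        self.grid = grid
        self.min_reads_per_bin = min_reads_per_bin
        self.max_mapd = max_mapd
        self.min_panel_samples = min_panel_samples
        self.split_threshold = split_threshold
        self.merge_delta = merge_delta
        self.min_segment_bins = min_segment_bins
        self.mosaic_threshold = mosaic_threshold
        self.full_threshold = full_threshold

    def _cfg(self) -> CallerConfig:
        return CallerConfig(
            min_reads_per_bin=self.min_reads_per_bin, max_mapd=self.max_mapd,
            min_panel_samples=self.min_panel_samples,
            split_threshold=self.split_threshold, merge_delta=self.merge_delta,
            min_segment_bins=self.min_segment_bins,
            mosaic_threshold=self.mosaic_threshold,
            full_threshold=self.full_threshold)

    def _as_counts(self, X) -> list[BinCounts]:
        if isinstance(X, BinCounts):
            return [X]
        out = []
        for i, row in enumerate(X):
            if isinstance(row, BinCounts):
                out.append(row)
            else:
                arr = np.asarray(row)
                out.append(BinCounts(f"sample{i}", arr, int(arr.sum())))
        return out

    def fit(self, X, y=None):
        if self.grid is None:
            raise ValueError("CopyNumberCaller requires a grid")
        self.reference_panel_ = build_reference(self._as_counts(X), self.grid,
                                                self._cfg())
        return self

    def transform(self, X) -> np.ndarray:
        profiles = [normalize(c, self.reference_panel_, self.grid, self._cfg())
                    for c in self._as_counts(X)]
        return np.vstack([p.ratios for p in profiles])

    def predict(self, X) -> list[EmbryoCallSet]:
        return [call_sample(c, self.reference_panel_, self.grid, self._cfg())
                for c in self._as_counts(X)]
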