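"""Synthetic-data generator for MALBAC-like low-pass blastomere sequencing.

Emulates the data regime of single-blastomere PGT libraries: roughly
3 million single-end 55 bp reads per cell (about 0.04x genome-wide depth),
counted in 1 Mb bins, with a smooth multiplicative GC amplification bias,
negative-binomial overdispersion, sporadic per-bin dropout, and a ~5.7%
whole-sample amplification-failure rate realized as chaotic (extremely
overdispersed, heavily dropped-out) profiles so QC logic is exercised
in-pipeline.  Embryo profiles are composed from parental meiotic gamete
draws, de novo meiotic aneuploidies (most often chromosomes 22, 19, 21 and
16), and mitotic events carrying mosaic fractions.

Every sample's ground truth (gamete modes, expected imbalance regions,
category label under the published classification rules) is recorded
alongside the counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bins import BinCounts, BinGrid, build_bin_grid
from .classify import (
    ClassifierConfig,
    Event,
    categorize_events,
    expected_unbalanced_catalogue,
)
from .karyotype import CytobandMap, Karyotype, parse_karyotype, resolve_breakpoints
from .meiosis import (
    DE_NOVO_MEIOTIC,
    MITOTIC,
    PARENTAL,
    GameteClass,
    ImbalanceProfile,
    ImbalanceRegion,
    SegregationWeights,
    enumerate_gametes,
    gamete_imbalance,
)

__all__ = [
    "SimulationConfig",
    "EmbryoTruth",
    "GroupSpec",
    "CohortSpec",
    "simulate_blastomere_counts",
    "simulate_embryo",
    "simulate_cohort",
    "build_bin_grid",
]

HG19_TOTAL_BP = 3_095_677_412

# relative de novo aneuploidy propensities; chromosomes 22, 19, 21 and 16
# dominate, matching the observed order in cleavage-stage embryos
DEFAULT_DE_NOVO_WEIGHTS = {"22": 3.0, "19": 2.5, "21": 2.0, "16": 2.0}


@dataclass(frozen=True)
class SimulationConfig:
    total_reads: int = 3_000_000        # per cell on the full genome
    read_length: int = 55               # metadata only
    target_depth: float = 0.04          # metadata; reads are primary
    gc_bias: tuple[float, float] = (0.8, -6.0)   # log-linear, log-quadratic
    overdispersion: float = 0.02        # NB: var = mu + a*mu^2
    dropout_prob: float = 0.01
    failure_prob: float = 0.057
    failure_dispersion: float = 3.0
    failure_dropout: float = 0.4
    de_novo_rate: float = 0.7           # Poisson mean events per embryo
    de_novo_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DE_NOVO_WEIGHTS))
    mosaic_rate: float = 0.2            # P(one mitotic event per embryo)
    mosaic_fraction_range: tuple[float, float] = (0.2, 0.8)
    noiseless: bool = False             # counts = rounded expectation

    def __post_init__(self):
        if self.total_reads <= 0:
            raise ValueError("total reads must be positive")
        for p in (self.dropout_prob, self.failure_prob, self.mosaic_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")

    def reads_for(self, grid: BinGrid) -> int:
        """Total reads scaled to the grid's genome size, so reduced
        synthetic genomes keep the per-bin depth of the full regime."""
        total_bp = int(np.sum(grid.ends - grid.starts))
        return max(1, round(self.total_reads * total_bp / HG19_TOTAL_BP))


@dataclass(frozen=True)
class EmbryoTruth:
    sample_id: str
    sex: str
    maternal_modes: tuple[str, ...]
    paternal_modes: tuple[str, ...]
    regions: tuple[ImbalanceRegion, ...]   # all true events incl. mitotic
    provenances: tuple[str, ...]           # parallel to regions
    category: str
    failed: bool
    transferable: bool


def _gc_bias(grid: BinGrid, cfg: SimulationConfig) -> np.ndarray:
    b1, b2 = cfg.gc_bias
    d = grid.gc - 0.40
    return np.exp(b1 * d + b2 * d * d)


def _copy_number(grid: BinGrid, regions, sex: str) -> np.ndarray:
    cn = np.full(len(grid), 2.0)
    chroms = np.asarray(grid.chroms)
    if "X" in grid.lengths:
        cn[chroms == "X"] = 2.0 if sex == "XX" else 1.0
    if "Y" in grid.lengths:
        # residual background mapping on Y in female cells
        cn[chroms == "Y"] = 0.05 if sex == "XX" else 1.0
    for r in regions:
        frac = grid.overlap_fraction(r.chrom, r.start, r.end)
        dose = r.delta * (r.mosaic_fraction if r.mosaic_fraction else 1.0)
        cn += dose * frac
    return np.clip(cn, 0.0, None)


def simulate_blastomere_counts(profile: ImbalanceProfile | list[ImbalanceRegion],
                               sex: str, grid: BinGrid, cfg: SimulationConfig,
                               seed: int | np.random.Generator = 0,
                               failed: bool = False,
                               sample_id: str = "sample") -> BinCounts:
    """Draw per-bin read counts for one blastomere.

    Expected count per bin is proportional to (local copy number / 2) x
    GC bias; counts are negative-binomial (gamma-Poisson) with the
    configured overdispersion, with per-bin dropout.  ``failed`` samples
    use the chaotic failure noise regime.  With ``cfg.noiseless`` the
    rounded expectation is returned.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    regions = (profile.regions if isinstance(profile, ImbalanceProfile)
               else tuple(profile))
    for r in regions:
        if r.chrom not in grid.lengths:
            raise ValueError(f"region chromosome {r.chrom!r} not on grid")
    reads = cfg.reads_for(grid)
    cn = _copy_number(grid, regions, sex)
    weights = (cn / 2.0) * _gc_bias(grid, cfg)
    lam = reads * weights / weights.sum()
    if cfg.noiseless:
        counts = np.round(lam).astype(np.int64)
        return BinCounts(sample_id, counts, int(max(counts.sum(), reads)))
    alpha = cfg.failure_dispersion if failed else cfg.overdispersion
    dropout = cfg.failure_dropout if failed else cfg.dropout_prob
    if alpha > 0:
        lam = lam * rng.gamma(1.0 / alpha, alpha, size=len(lam))
    counts = rng.poisson(lam).astype(np.int64)
    if dropout > 0:
        counts[rng.random(len(counts)) < dropout] = 0
    return BinCounts(sample_id, counts, int(counts.sum()))


def _draw_parent_gametes(k: Karyotype, m: CytobandMap, w: SegregationWeights,
                         rng: np.random.Generator,
                         force_mode: str | None = None
                         ) -> tuple[tuple[str, ...], list[ImbalanceRegion]]:
    """Draw one gamete per rearrangement; nonviable classes (acentric or
    dicentric paracentric recombinants) are excluded and the weights
    renormalized."""
    modes: list[str] = []
    regions: list[ImbalanceRegion] = []
    if not k.rearrangements:
        return ("normal",), []
    for r in k.rearrangements:
        classes = [c for c in enumerate_gametes(r, m, w) if c.viable]
        if force_mode is not None:
            forced = [c for c in classes if c.mode == force_mode]
            if not forced:
                raise ValueError(f"no viable gamete class of mode {force_mode!r}")
            classes = forced
        p = np.array([float(c.weight) for c in classes])
        g: GameteClass = classes[rng.choice(len(classes), p=p / p.sum())]
        modes.append(g.mode)
        regions.extend(gamete_imbalance(g).regions)
    return tuple(modes), regions


def simulate_embryo(km: Karyotype | str, kf: Karyotype | str,
                    grid: BinGrid, m: CytobandMap, cfg: SimulationConfig,
                    seed: int | np.random.Generator = 0,
                    weights: SegregationWeights | None = None,
                    classifier_cfg: ClassifierConfig | None = None,
                    force_maternal_mode: str | None = None,
                    force_paternal_mode: str | None = None,
                    sample_id: str = "embryo") -> tuple[BinCounts, EmbryoTruth]:
    """Simulate one biopsied blastomere of this couple's embryo.

    One gamete per parent is drawn by segregation weights, de novo meiotic
    whole-chromosome aneuploidies are added at the configured rate with
    per-chromosome propensities, an optional mitotic event carries a
    mosaic fraction, and the truth category is assigned by the published
    classification rules applied to the true events.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    w = weights or SegregationWeights()
    ccfg = classifier_cfg or ClassifierConfig()
    km = _as_resolved(km, m)
    kf = _as_resolved(kf, m)

    m_modes, m_regions = _draw_parent_gametes(km, m, w, rng, force_maternal_mode)
    f_modes, f_regions = _draw_parent_gametes(kf, m, w, rng, force_paternal_mode)
    sex = "XX" if rng.random() < 0.5 else "XY"

    regions: list[ImbalanceRegion] = []
    provenances: list[str] = []
    merged: dict[tuple[str, int, int], int] = {}
    for r in m_regions + f_regions:
        key = (r.chrom, r.start, r.end)
        merged[key] = merged.get(key, 0) + r.delta
    for (chrom, start, end), delta in merged.items():
        if delta != 0:
            regions.append(ImbalanceRegion(chrom, start, end, delta))
            provenances.append(PARENTAL)

    autosomes = [c for c in grid.chromosomes if c not in ("X", "Y")]
    taken = {r.chrom for r in regions}
    n_de_novo = rng.poisson(cfg.de_novo_rate)
    pool = [c for c in autosomes if c not in taken]
    wts = np.array([cfg.de_novo_weights.get(c, 1.0) for c in pool])
    for _ in range(min(n_de_novo, len(pool))):
        i = rng.choice(len(pool), p=wts / wts.sum())
        chrom = pool.pop(i)
        wts = np.delete(wts, i)
        sign = 1 if rng.random() < 0.5 else -1
        regions.append(ImbalanceRegion(chrom, 0, grid.lengths[chrom], sign))
        provenances.append(DE_NOVO_MEIOTIC)

    if rng.random() < cfg.mosaic_rate and autosomes:
        chrom = autosomes[rng.choice(len(autosomes))]
        f = rng.uniform(*cfg.mosaic_fraction_range)
        sign = 1 if rng.random() < 0.5 else -1
        regions.append(ImbalanceRegion(chrom, 0, grid.lengths[chrom], sign,
                                       mosaic_fraction=round(float(f), 3)))
        provenances.append(MITOTIC)

    failed = bool(rng.random() < cfg.failure_prob)

    catalogue = expected_unbalanced_catalogue(km, kf, m, w)
    events = [Event.from_region(r, m) for r in regions]
    cls = categorize_events(sample_id, events, catalogue, m, ccfg)

    counts = simulate_blastomere_counts(regions, sex, grid, cfg, rng,
                                        failed=failed, sample_id=sample_id)
    truth = EmbryoTruth(sample_id, sex, m_modes, f_modes, tuple(regions),
                        tuple(provenances), cls.category, failed,
                        cls.transferable)
    return counts, truth


def _as_resolved(k: Karyotype | str, m: CytobandMap) -> Karyotype:
    if isinstance(k, str):
        k = parse_karyotype(k)
    if any(not bp.resolved for r in k.rearrangements for bp in r.breakpoints):
        k = resolve_breakpoints(k, m)
    return k


@dataclass(frozen=True)
class GroupSpec:
    label: str                    # e.g. RecT | RobT | Inv | NoCR
    maternal: str                 # ISCN karyotype string
    paternal: str
    n_embryos: int


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    config: SimulationConfig = SimulationConfig()

    def __post_init__(self):
        if not self.groups:
            raise ValueError("cohort spec lists no groups")


def simulate_cohort(spec: CohortSpec, grid: BinGrid, m: CytobandMap,
                    seed: int = 0,
                    weights: SegregationWeights | None = None,
                    classifier_cfg: ClassifierConfig | None = None
                    ) -> tuple[list[BinCounts], pd.DataFrame]:
    """Simulate a whole cohort; reproducible given the seed.

    Returns the per-sample counts and a truth table with one row per
    embryo (group, sample id, sex, failed flag, true category, true
    events).
    """
    root = np.random.SeedSequence(seed)
    counts_out: list[BinCounts] = []
    rows = []
    streams = root.spawn(sum(g.n_embryos for g in spec.groups))
    i = 0
    for g in spec.groups:
        for j in range(g.n_embryos):
            sid = f"{g.label}_{j:04d}"
            rng = np.random.default_rng(streams[i])
            i += 1
            counts, truth = simulate_embryo(
                g.maternal, g.paternal, grid, m, spec.config, rng,
                weights=weights, classifier_cfg=classifier_cfg, sample_id=sid)
            counts_out.append(counts)
            rows.append({
                "group": g.label,
                "sample_id": sid,
                "sex": truth.sex,
                "failed": truth.failed,
                "category": truth.category,
                "transferable": truth.transferable,
                "n_events": len(truth.regions),
                "events": ";".join(
                    f"{r.chrom}:{r.start}-{r.end}:{r.delta:+d}"
                    + (f"@{r.mosaic_fraction}" if r.mosaic_fraction else "")
                    for r in truth.regions),
                "maternal_modes": ",".join(truth.maternal_modes),
                "paternal_modes": ",".join(truth.paternal_modes),
            })
    return counts_out, pd.DataFrame(rows)
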