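"""Five-category classification of embryo CNV calls for PGT-SR.

Called events are matched against the catalogue of imbalances a carrier
couple's unbalanced gametes can transmit.  Categories:

* **I** — abnormalities related to the parental rearrangement only;
* **II** — de novo abnormalities only;
* **III** — both related and de novo abnormalities;
* **IV** — multiple aneuploidy of chromosomes (MAC): events on at least
  ``mac_threshold`` (default 3) distinct chromosomes, overriding I–III;
* **V** — normal/balanced.

Only category V embryos without a mosaic event above the 40% fraction are
transferable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cnvcall import EmbryoCallSet, SegmentCall
from .karyotype import CytobandMap, Karyotype
from .meiosis import (
    ImbalanceRegion,
    SegregationWeights,
    enumerate_gametes,
    gamete_imbalance,
)

__all__ = [
    "ClassifierConfig",
    "Event",
    "CatalogueEntry",
    "EmbryoClassification",
    "expected_unbalanced_catalogue",
    "match_event",
    "categorize_events",
    "classify_embryo",
]

CATEGORIES = ("I", "II", "III", "IV", "V")
_END_SLACK = 3_000_000  # breakpoints within this of a chromosome end or
                        # centromere are positional anchors, not matched


@dataclass(frozen=True)
class ClassifierConfig:
    mac_threshold: int = 3
    tolerance_mb: float = 5.0
    min_reciprocal_overlap: float = 0.5
    mosaic_floor: float = 0.4


@dataclass(frozen=True)
class Event:
    """One abnormal region, from the caller or from simulation truth."""

    chrom: str
    start: int
    end: int
    sign: int                          # +1 gain, -1 loss
    mosaic_fraction: float | None = None
    whole_chromosome: bool = False

    @property
    def size_mb(self) -> float:
        return (self.end - self.start) / 1e6

    @classmethod
    def from_segment(cls, seg: SegmentCall) -> "Event":
        return cls(seg.chrom, seg.start, seg.end, seg.sign,
                   seg.mosaic_fraction if seg.mosaic else None,
                   seg.whole_chromosome)

    @classmethod
    def from_region(cls, r: ImbalanceRegion, m: CytobandMap) -> "Event":
        whole = (r.end - r.start) >= 0.9 * m.lengths[r.chrom]
        return cls(r.chrom, r.start, r.end, 1 if r.delta > 0 else -1,
                   r.mosaic_fraction, whole)


@dataclass(frozen=True)
class CatalogueEntry:
    chrom: str
    start: int
    end: int
    sign: int
    interior_breakpoints: tuple[int, ...]


@dataclass(frozen=True)
class MatchEvidence:
    event: Event
    origin: str                        # related | de_novo
    overlap: float = 0.0
    breakpoint_distance_mb: float | None = None


@dataclass(frozen=True)
class EmbryoClassification:
    sample_id: str
    category: str
    related: tuple[Event, ...]
    de_novo: tuple[Event, ...]
    mosaic: tuple[Event, ...]
    transferable: bool
    evidence: tuple[MatchEvidence, ...] = ()


def _interior_breakpoints(chrom: str, start: int, end: int,
                          m: CytobandMap) -> tuple[int, ...]:
    """Breakpoints away from the chromosome ends and centromere — the only
    ones informative for matching band-level expectations."""
    length = m.lengths[chrom]
    cen = m.centromere(chrom)
    out = []
    for pos in (start, end):
        if pos <= _END_SLACK or pos >= length - _END_SLACK:
            continue
        if abs(pos - cen) <= _END_SLACK:
            continue
        out.append(pos)
    return tuple(out)


def expected_unbalanced_catalogue(
        km: Karyotype, kf: Karyotype, m: CytobandMap,
        w: SegregationWeights | None = None) -> list[CatalogueEntry]:
    """Zygote-level imbalances transmissible by either parent's unbalanced
    (viable) gametes, deduplicated.

    A carried deletion/duplication enters the catalogue through the
    carrier gamete class, so an inherited microdeletion matches as
    related.
    """
    w = w or SegregationWeights()
    entries: dict[tuple[str, int, int, int], CatalogueEntry] = {}
    for k in (km, kf):
        for r in k.rearrangements:
            for g in enumerate_gametes(r, m, w):
                if g.balanced or not g.viable:
                    continue
                for reg in gamete_imbalance(g).regions:
                    sign = 1 if reg.delta > 0 else -1
                    key = (reg.chrom, reg.start, reg.end, sign)
                    if key not in entries:
                        entries[key] = CatalogueEntry(
                            reg.chrom, reg.start, reg.end, sign,
                            _interior_breakpoints(reg.chrom, reg.start,
                                                  reg.end, m))
    return list(entries.values())


def _reciprocal_overlap(a_start, a_end, b_start, b_end) -> float:
    inter = min(a_end, b_end) - max(a_start, b_start)
    if inter <= 0:
        return 0.0
    return min(inter / (a_end - a_start), inter / (b_end - b_start))


def match_event(event: Event, catalogue: list[CatalogueEntry],
                m: CytobandMap,
                cfg: ClassifierConfig | None = None) -> MatchEvidence:
    """Decide whether a called event is parental-rearrangement related.

    Related iff some catalogue entry on the same chromosome has the same
    sign, reciprocal overlap >= ``min_reciprocal_overlap``, and every
    interior (non-centromeric, non-telomeric) breakpoint of the entry lies
    within ``tolerance_mb`` of a breakpoint of the call.  Matching is
    monotone in the tolerance: enlarging it never turns a related event
    into de novo.
    """
    cfg = cfg or ClassifierConfig()
    tol = cfg.tolerance_mb * 1e6
    best: MatchEvidence | None = None
    for entry in catalogue:
        if entry.chrom != event.chrom or entry.sign != event.sign:
            continue
        ov = _reciprocal_overlap(event.start, event.end,
                                 entry.start, entry.end)
        if ov < cfg.min_reciprocal_overlap:
            continue
        dists = [min(abs(bp - event.start), abs(bp - event.end))
                 for bp in entry.interior_breakpoints]
        if dists and max(dists) > tol:
            continue
        dist_mb = max(dists) / 1e6 if dists else None
        cand = MatchEvidence(event, "related", ov, dist_mb)
        if best is None or cand.overlap > best.overlap:
            best = cand
    return best or MatchEvidence(event, "de_novo")


def categorize_events(sample_id: str, events: list[Event],
                      catalogue: list[CatalogueEntry], m: CytobandMap,
                      cfg: ClassifierConfig | None = None
                      ) -> EmbryoClassification:
    """Apply the category rules to a list of events (called or true).

    Mosaic events at or below ``mosaic_floor`` are below the reporting
    threshold and ignored.  Category IV (MAC) fires when the surviving
    events touch at least ``mac_threshold`` distinct chromosomes and takes
    precedence over I–III; mosaic events keep their I–IV identity but any
    mosaic event above the floor blocks transfer.
    """
    cfg = cfg or ClassifierConfig()
    effective = [e for e in events
                 if e.mosaic_fraction is None
                 or e.mosaic_fraction > cfg.mosaic_floor]
    evidence = tuple(match_event(e, catalogue, m, cfg) for e in effective)
    related = tuple(ev.event for ev in evidence if ev.origin == "related")
    de_novo = tuple(ev.event for ev in evidence if ev.origin == "de_novo")
    mosaic = tuple(e for e in effective if e.mosaic_fraction is not None)

    if not effective:
        category = "V"
    elif len({e.chrom for e in effective}) >= cfg.mac_threshold:
        category = "IV"
    elif related and de_novo:
        category = "III"
    elif related:
        category = "I"
    else:
        category = "II"
    transferable = category == "V" and not mosaic
    return EmbryoClassification(sample_id, category, related, de_novo,
                                mosaic, transferable, evidence)


def classify_embryo(calls: EmbryoCallSet, km: Karyotype, kf: Karyotype,
                    m: CytobandMap,
                    cfg: ClassifierConfig | None = None,
                    catalogue: list[CatalogueEntry] | None = None
                    ) -> EmbryoClassification:
    """Classify one informative embryo's call set into categories I–V."""
    cfg = cfg or ClassifierConfig()
    if not calls.qc.informative:
        raise ValueError(f"no result for sample {calls.sample_id}: "
                         "embryo failed QC and is excluded from rates")
    if catalogue is None:
        catalogue = expected_unbalanced_catalogue(km, kf, m)
    events = [Event.from_segment(s) for s in calls.segments]
    return categorize_events(calls.sample_id, events, catalogue, m, cfg)
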