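"""Meiotic segregation models for structural-rearrangement carriers.

A reciprocal-translocation carrier forms a quadrivalent of four elements
(the two normal homologues A and B and the two derivatives der(A), der(B));
a Robertsonian carrier forms a trivalent (A, B, der(A;B)); an inversion
carrier forms an inversion loop whose crossover products are recombinant.
Gamete classes are enumerated with exact :class:`fractions.Fraction`
probability weights so theoretical euploidy probabilities (e.g. 1/81 for a
couple of two reciprocal-translocation carriers) come out as exact
rationals.

Two counting conventions are exposed for reciprocal translocations:

* ``"counseling"`` (default): the 18-type count used in reproductive
  counseling, with 2 balanced types, hence a balanced-gamete mass of
  2/18 = 1/9 per carrier under uniform weights;
* ``"distinct"``: the 16 distinct element compositions (6 two:two,
  8 three:one, 2 four:zero), balanced mass 2/16 = 1/8.

The 18-type total is realized by assigning the two 4:0 poles two
enumeration slots each; segment bookkeeping is identical under both
conventions — only the uniform weights differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable

from .karyotype import (
    ACROCENTRICS,
    DELETION,
    DUPLICATION,
    INSERTION,
    INVERSION,
    RECIPROCAL,
    ROBERTSONIAN,
    CytobandMap,
    Karyotype,
    Rearrangement,
    Segment,
    segment_partition,
)

__all__ = [
    "GameteClass",
    "ImbalanceRegion",
    "ImbalanceProfile",
    "SegregationWeights",
    "enumerate_gametes",
    "gamete_imbalance",
    "couple_euploid_probability",
    "zygote_profile",
]

PARENTAL = "parental-rearrangement"
DE_NOVO_MEIOTIC = "de-novo-meiotic"
MITOTIC = "mitotic"


@dataclass(frozen=True)
class ImbalanceRegion:
    """One region whose copy number deviates from the diploid expectation.

    ``delta`` is the integer dose change for whole (non-mosaic) events;
    mitotic events additionally carry a mosaic fraction in (0, 1].
    """

    chrom: str
    start: int
    end: int
    delta: int
    mosaic_fraction: float | None = None

    @property
    def size_mb(self) -> float:
        return (self.end - self.start) / 1e6


@dataclass(frozen=True)
class ImbalanceProfile:
    regions: tuple[ImbalanceRegion, ...]
    provenance: str = PARENTAL

    @property
    def balanced(self) -> bool:
        return not self.regions


@dataclass(frozen=True)
class GameteClass:
    """One enumerated meiotic product of a carrier.

    ``segments`` maps each :class:`Segment` of the partitioned
    rearrangement to its copy count in the gamete (uninvolved chromosomes
    are implicitly present once).
    """

    mode: str
    segments: tuple[tuple[Segment, int], ...]
    balanced: bool
    weight: Fraction
    viable: bool = True
    elements: tuple[str, ...] = ()

    def segment_counts(self) -> dict[Segment, int]:
        return dict(self.segments)


@dataclass(frozen=True)
class SegregationWeights:
    """Per-mode probability weights.

    ``reciprocal_convention`` selects the 18-type counseling count or the
    16 distinct compositions.  ``mode_weights`` optionally overrides the
    uniform distribution with per-mode masses (e.g. to down-weight 4:0 to
    zero); masses are renormalized over the emitted classes.
    ``inversion_recombination`` is the probability that an inversion
    carrier's gamete is recombinant (default 1/2, i.e. uniform over the
    four classes).
    """

    reciprocal_convention: str = "counseling"  # or "distinct"
    mode_weights: dict[str, Fraction] | None = None
    inversion_recombination: Fraction = Fraction(1, 2)

    def __post_init__(self):
        if self.reciprocal_convention not in {"counseling", "distinct"}:
            raise ValueError(
                f"unknown convention {self.reciprocal_convention!r}")


def _uniform(classes: list[GameteClass], slots: list[int]) -> list[GameteClass]:
    total = sum(slots)
    return [
        GameteClass(c.mode, c.segments, c.balanced, Fraction(s, total),
                    c.viable, c.elements)
        for c, s in zip(classes, slots)
    ]


def _apply_mode_weights(classes: list[GameteClass],
                        mode_weights: dict[str, Fraction]) -> list[GameteClass]:
    raw = []
    for c in classes:
        share = mode_weights.get(c.mode)
        if share is None:
            raw.append(c.weight)
        else:
            same = sum(1 for d in classes if d.mode == c.mode)
            raw.append(Fraction(share, same))
    total = sum(raw)
    if total == 0:
        raise ValueError("mode weights sum to zero")
    return [
        GameteClass(c.mode, c.segments, c.balanced, w / total, c.viable,
                    c.elements)
        for c, w in zip(classes, raw)
    ]


def enumerate_gametes(r: Rearrangement | None, m: CytobandMap,
                      w: SegregationWeights | None = None) -> list[GameteClass]:
    """Enumerate the gamete classes of a carrier of ``r`` with weights.

    ``r`` may be ``None`` (structurally normal parent): a single balanced
    class of weight 1 is returned.  Weights always sum to 1.
    """
    w = w or SegregationWeights()
    if r is None:
        return [GameteClass("normal", (), True, Fraction(1), True, ("haploid",))]

    if r.kind == RECIPROCAL:
        classes = _reciprocal_classes(r, m)
        if w.reciprocal_convention == "counseling":
            slots = [2 if c.mode == "4:0" else 1 for c in classes]
        else:
            slots = [1] * len(classes)
        classes = _uniform(classes, slots)
    elif r.kind == ROBERTSONIAN:
        classes = _uniform(_robertsonian_classes(r, m), [1] * 8)
    elif r.kind == INVERSION:
        classes = _inversion_classes(r, m, w.inversion_recombination)
    elif r.kind in {DELETION, DUPLICATION}:
        classes = _uniform(_deldup_classes(r, m), [1, 1])
    elif r.kind == INSERTION:
        classes = _uniform(_insertion_classes(r, m), [1, 1, 1, 1])
    else:
        raise ValueError(f"unsupported rearrangement kind {r.kind!r}")

    if w.mode_weights:
        classes = _apply_mode_weights(classes, w.mode_weights)
    assert sum(c.weight for c in classes) == 1
    return classes


def _reciprocal_classes(r: Rearrangement, m: CytobandMap) -> list[GameteClass]:
    parts = segment_partition(r, m)
    Ac, At = parts["A_centric"], parts["A_translocated"]
    Bc, Bt = parts["B_centric"], parts["B_translocated"]
    # quadrivalent elements as multisets of segments
    elements = {
        "A": (Ac, At),
        "B": (Bc, Bt),
        "derA": (Ac, Bt),
        "derB": (Bc, At),
    }
    full = {Ac: 1, At: 1, Bc: 1, Bt: 1}

    def make(mode: str, names: tuple[str, ...]) -> GameteClass:
        counts: dict[Segment, int] = {Ac: 0, At: 0, Bc: 0, Bt: 0}
        for n in names:
            for seg in elements[n]:
                counts[seg] += 1
        balanced = counts == full
        segs = tuple((s, c) for s, c in counts.items())
        return GameteClass(mode, segs, balanced, Fraction(0), True, names)

    classes = [
        make("alternate", ("A", "B")),
        make("alternate", ("derA", "derB")),
        make("adjacent-1", ("A", "derB")),
        make("adjacent-1", ("B", "derA")),
        make("adjacent-2", ("A", "derA")),
        make("adjacent-2", ("B", "derB")),
    ]
    singles = ["A", "B", "derA", "derB"]
    for lone in singles:
        trio = tuple(n for n in singles if n != lone)
        classes.append(make("3:1", trio))
        classes.append(make("3:1", (lone,)))
    classes.append(make("4:0", tuple(singles)))
    classes.append(make("4:0", ()))
    return classes


def _robertsonian_classes(r: Rearrangement, m: CytobandMap) -> list[GameteClass]:
    parts = segment_partition(r, m)
    Aq, Bq = parts["A_q"], parts["B_q"]
    elements = {"A": (Aq,), "B": (Bq,), "der": (Aq, Bq)}
    full = {Aq: 1, Bq: 1}

    def make(mode: str, names: tuple[str, ...]) -> GameteClass:
        counts: dict[Segment, int] = {Aq: 0, Bq: 0}
        for n in names:
            for seg in elements[n]:
                counts[seg] += 1
        return GameteClass(mode, tuple(counts.items()), counts == full,
                           Fraction(0), True, names)

    return [
        make("rob-alternate", ("der",)),
        make("rob-alternate", ("A", "B")),
        make("rob-adjacent", ("der", "A")),
        make("rob-adjacent", ("B",)),
        make("rob-adjacent", ("der", "B")),
        make("rob-adjacent", ("A",)),
        make("rob-3:0", ("der", "A", "B")),
        make("rob-3:0", ()),
    ]


def _inversion_classes(r: Rearrangement, m: CytobandMap,
                       recomb: Fraction) -> list[GameteClass]:
    parts = segment_partition(r, m)
    inv = parts["inverted"]
    p_fl = parts.get("p_flank")
    q_fl = parts.get("q_flank")
    flanks = [s for s in (p_fl, q_fl) if s is not None]
    full = {inv: 1, **{s: 1 for s in flanks}}
    pericentric = r.inversion_subtype == "pericentric"

    def make(mode, counts, balanced, weight, viable, tag):
        return GameteClass(mode, tuple(counts.items()), balanced, weight,
                           viable, tag)

    non_rec = (1 - recomb) / 2
    rec = recomb / 2
    classes = [
        make("non-recombinant", dict(full), True, non_rec, True, ("normal",)),
        make("non-recombinant", dict(full), True, non_rec, True, ("inverted",)),
    ]
    # single crossover within the loop: for a pericentric inversion the two
    # recombinants carry duplication of one flank and deletion of the other;
    # paracentric recombinants are acentric/dicentric and flagged nonviable.
    if pericentric and p_fl is not None and q_fl is not None:
        rec1 = {inv: 1, p_fl: 2, q_fl: 0}
        rec2 = {inv: 1, p_fl: 0, q_fl: 2}
        classes.append(make("recombinant", rec1, False, rec, True, ("dup-p",)))
        classes.append(make("recombinant", rec2, False, rec, True, ("dup-q",)))
    else:
        classes.append(make("recombinant", dict(full), False, rec, False,
                            ("acentric",)))
        classes.append(make("recombinant", dict(full), False, rec, False,
                            ("dicentric",)))
    return classes


def _deldup_classes(r: Rearrangement, m: CytobandMap) -> list[GameteClass]:
    parts = segment_partition(r, m)
    aff = parts["affected"]
    flanks = [parts[k] for k in ("p_flank", "q_flank") if k in parts]
    full = {aff: 1, **{s: 1 for s in flanks}}
    carried = dict(full)
    carried[aff] = 0 if r.kind == DELETION else 2
    return [
        GameteClass("normal", tuple(full.items()), True, Fraction(0), True,
                    ("normal",)),
        GameteClass("carrier", tuple(carried.items()), False, Fraction(0),
                    True, ("carrier",)),
    ]


def _insertion_classes(r: Rearrangement, m: CytobandMap) -> list[GameteClass]:
    parts = segment_partition(r, m)
    ins = parts["inserted"]
    chrom = ins.chrom
    length = m.lengths[chrom]
    rest = [s for s in (Segment(chrom, 0, ins.start) if ins.start > 0 else None,
                        Segment(chrom, ins.end, length) if ins.end < length else None)
            if s is not None]
    full = {ins: 1, **{s: 1 for s in rest}}
    dup = dict(full, **{ins: 2})
    dele = dict(full, **{ins: 0})
    return [
        GameteClass("normal", tuple(full.items()), True, Fraction(0), True,
                    ("normal",)),
        GameteClass("balanced-ins", tuple(full.items()), True, Fraction(0),
                    True, ("carrier",)),
        GameteClass("dup-ins", tuple(dup.items()), False, Fraction(0), True,
                    ("dup",)),
        GameteClass("del-ins", tuple(dele.items()), False, Fraction(0), True,
                    ("del",)),
    ]


def gamete_imbalance(g: GameteClass) -> ImbalanceProfile:
    """Copy-number deltas of a gamete relative to a balanced haploid set.

    Balanced gametes yield an empty profile.  Adjacent regions with equal
    delta are merged.
    """
    regions = [
        ImbalanceRegion(seg.chrom, seg.start, seg.end, count - 1)
        for seg, count in g.segments
        if count != 1
    ]
    return ImbalanceProfile(tuple(_merge_regions(regions)), PARENTAL)


def _merge_regions(regions: Iterable[ImbalanceRegion]) -> list[ImbalanceRegion]:
    out: list[ImbalanceRegion] = []
    for r in sorted(regions, key=lambda x: (x.chrom, x.start)):
        if (out and out[-1].chrom == r.chrom and out[-1].end == r.start
                and out[-1].delta == r.delta
                and out[-1].mosaic_fraction == r.mosaic_fraction):
            out[-1] = ImbalanceRegion(r.chrom, out[-1].start, r.end, r.delta,
                                      r.mosaic_fraction)
        else:
            out.append(r)
    return out


def zygote_profile(gm: ImbalanceProfile | GameteClass,
                   gf: ImbalanceProfile | GameteClass) -> ImbalanceProfile:
    """Combine two parental gamete imbalances into the zygote profile.

    Expected regional copy number is 2 plus the summed parental deltas;
    a region driven below copy 0 raises ``ValueError``.
    """
    profs = [g if isinstance(g, ImbalanceProfile) else gamete_imbalance(g)
             for g in (gm, gf)]
    events: dict[tuple[str, int, int], int] = {}
    for p in profs:
        for r in p.regions:
            key = (r.chrom, r.start, r.end)
            events[key] = events.get(key, 0) + r.delta
    regions = []
    for (chrom, start, end), delta in events.items():
        if 2 + delta < 0:
            raise ValueError(
                f"zygote copy number below zero on {chrom}:{start}-{end}")
        if delta != 0:
            regions.append(ImbalanceRegion(chrom, start, end, delta))
    return ImbalanceProfile(tuple(_merge_regions(regions)), PARENTAL)


def balanced_mass(k: Karyotype, m: CytobandMap,
                  w: SegregationWeights | None = None) -> Fraction:
    """Probability that one gamete of this parent is balanced.

    Independent rearrangements multiply; a structurally normal parent has
    mass 1 (de novo errors are outside the meiotic model).
    """
    w = w or SegregationWeights()
    mass = Fraction(1)
    for r in k.rearrangements:
        classes = enumerate_gametes(r, m, w)
        mass *= sum(c.weight for c in classes if c.balanced)
    return mass


def couple_euploid_probability(km: Karyotype, kf: Karyotype, m: CytobandMap,
                               w: SegregationWeights | None = None) -> Fraction:
    """Theoretical probability that a zygote of this couple is euploid
    (normal or balanced): the product of the parental balanced-gamete
    masses, as an exact rational."""
    return balanced_mass(km, m, w) * balanced_mass(kf, m, w)
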