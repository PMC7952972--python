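"""ISCN karyotype parsing and cytoband coordinate resolution.

Supports the structural-rearrangement constructs seen in PGT-SR referral
karyotypes: reciprocal translocations ``t(A;B)(bandA;bandB)``, Robertsonian
translocations ``rob(A;B)(q10;q10)`` / ``der(A;B)(q10;q10)``, inversions
``inv(N)(band1band2)``, deletions/duplications ``del/dup(N)(band[band])``
and insertions ``ins(A;B)(band;band band)``.  Anything outside this subset
raises :class:`UnsupportedISCNError` rather than being silently skipped.

Coordinates are 0-based half-open base pairs on the bundled synthetic
hg19-compatible cytoband map (real hg19 chromosome lengths; band
boundaries are an approximate, declared convention).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources

__all__ = [
    "CytobandMap",
    "Band",
    "Breakpoint",
    "Rearrangement",
    "Karyotype",
    "Segment",
    "KaryotypeParseError",
    "UnsupportedISCNError",
    "UnknownBandError",
    "load_cytoband_map",
    "reduced_cytoband_map",
    "parse_karyotype",
    "resolve_breakpoints",
    "segment_partition",
]

ACROCENTRICS = frozenset({"13", "14", "15", "21", "22"})

RECIPROCAL = "reciprocal_translocation"
ROBERTSONIAN = "robertsonian_translocation"
INVERSION = "inversion"
DELETION = "deletion"
DUPLICATION = "duplication"
INSERTION = "insertion"

_KINDS_TWO_CHROM = {RECIPROCAL, ROBERTSONIAN, INSERTION}


class KaryotypeParseError(ValueError):
    """A karyotype term could not be parsed; the message names the token."""


class UnsupportedISCNError(KaryotypeParseError):
    """A recognized but unsupported ISCN construct."""


class UnknownBandError(KeyError):
    """A band name absent from the cytoband map."""


@dataclass(frozen=True)
class Band:
    chrom: str
    name: str
    start: int
    end: int


@dataclass(frozen=True)
class Segment:
    """Genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty segment {self}")

    @property
    def length(self) -> int:
        return self.end - self.start


class CytobandMap:
    """Ordered cytogenetic band intervals tiling each chromosome.

    Bands within a chromosome must be sorted, non-overlapping and
    contiguous from 0 to the chromosome length.
    """

    def __init__(self, bands: list[Band], lengths: dict[str, int]):
        self.lengths = dict(lengths)
        self._by_chrom: dict[str, list[Band]] = {}
        for b in bands:
            self._by_chrom.setdefault(b.chrom, []).append(b)
        self._index: dict[tuple[str, str], Band] = {}
        for chrom, blist in self._by_chrom.items():
            blist.sort(key=lambda b: b.start)
            pos = 0
            for b in blist:
                if b.start != pos:
                    raise ValueError(f"bands on {chrom} do not tile at {pos}")
                pos = b.end
                self._index[(chrom, b.name)] = b
            if pos != self.lengths.get(chrom):
                raise ValueError(f"bands on {chrom} do not reach chromosome end")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    def bands(self, chrom: str) -> list[Band]:
        return list(self._by_chrom[chrom])

    def centromere(self, chrom: str) -> int:
        """Centromere position = boundary between the p10 and q10 bands."""
        return self._index[(chrom, "q10")].start

    def band(self, chrom: str, name: str) -> Band:
        """Look up a band; sub-band names fall back to their parent band."""
        if chrom not in self._by_chrom:
            raise UnknownBandError(f"unknown chromosome {chrom!r}")
        candidate = name
        while candidate:
            b = self._index.get((chrom, candidate))
            if b is not None:
                return b
            if "." in candidate:
                candidate = candidate[:-1].rstrip(".")
            elif len(candidate) > 2:  # e.g. q22 -> no further fallback
                candidate = candidate[:-1] if candidate[-1].isdigit() and len(candidate) > 3 else ""
            else:
                candidate = ""
        raise UnknownBandError(f"unknown band {name!r} on chromosome {chrom}")

    def band_interval(self, chrom: str, name: str) -> tuple[int, int]:
        b = self.band(chrom, name)
        return b.start, b.end

    def hull(self, chrom: str, name_a: str, name_b: str) -> tuple[int, int]:
        """Union interval spanned by two (possibly unordered) bands."""
        a = self.band(chrom, name_a)
        b = self.band(chrom, name_b)
        return min(a.start, b.start), max(a.end, b.end)


def load_cytoband_map() -> CytobandMap:
    """Load the bundled synthetic hg19-compatible cytoband map."""
    bands: list[Band] = []
    lengths: dict[str, int] = {}
    ref = resources.files("pgtcnv.data").joinpath("cytobands_synthetic_hg19.tsv")
    with ref.open() as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, name, _stain = line.rstrip("\n").split("\t")
            bands.append(Band(chrom, name, int(start), int(end)))
            lengths[chrom] = max(lengths.get(chrom, 0), int(end))
    return CytobandMap(bands, lengths)


def reduced_cytoband_map(n_autosomes: int = 3, autosome_mb: int = 50,
                         x_mb: int = 30, y_mb: int = 10) -> CytobandMap:
    """Small synthetic genome for fast tests and desk-scale simulation.

    Autosomes plus X and Y, each with a simple symmetric band set around a
    central centromere.
    """
    M = 1_000_000
    bands: list[Band] = []
    lengths: dict[str, int] = {}

    def add(chrom: str, mb: int):
        L = mb * M
        cen_lo, cen_hi = (mb // 2 - 1) * M, (mb // 2 + 1) * M
        mid = (cen_lo + cen_hi) // 2
        p_names = ["p22", "p21", "p11"]
        q_names = ["q11", "q21", "q22"]
        edges = [round(cen_lo * i / 3) for i in range(4)]
        for nm, lo, hi in zip(p_names, edges[:-1], edges[1:]):
            bands.append(Band(chrom, nm, lo, hi))
        bands.append(Band(chrom, "p10", cen_lo, mid))
        bands.append(Band(chrom, "q10", mid, cen_hi))
        edges = [cen_hi + round((L - cen_hi) * i / 3) for i in range(4)]
        for nm, lo, hi in zip(q_names, edges[:-1], edges[1:]):
            bands.append(Band(chrom, nm, lo, hi))
        lengths[chrom] = L

    for i in range(1, n_autosomes + 1):
        add(str(i), autosome_mb)
    add("X", x_mb)
    add("Y", y_mb)
    return CytobandMap(bands, lengths)


@dataclass(frozen=True)
class Breakpoint:
    chrom: str
    band: str
    start: int | None = None  # resolved band interval, bp
    end: int | None = None

    @property
    def resolved(self) -> bool:
        return self.start is not None

    @property
    def midpoint(self) -> int:
        if not self.resolved:
            raise ValueError(f"breakpoint {self.chrom}{self.band} not resolved")
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Rearrangement:
    kind: str
    chromosomes: tuple[str, ...]
    breakpoints: tuple[Breakpoint, ...]
    inversion_subtype: str = "n/a"  # pericentric | paracentric | n/a

    def __post_init__(self):
        n = len(self.chromosomes)
        if self.kind in _KINDS_TWO_CHROM and n != 2:
            raise ValueError(f"{self.kind} requires 2 chromosomes, got {n}")
        if self.kind in {INVERSION, DELETION, DUPLICATION} and n != 1:
            raise ValueError(f"{self.kind} requires 1 chromosome, got {n}")

    def to_iscn(self) -> str:
        abbr = {RECIPROCAL: "t", ROBERTSONIAN: "rob", INVERSION: "inv",
                DELETION: "del", DUPLICATION: "dup", INSERTION: "ins"}[self.kind]
        chroms = ";".join(self.chromosomes)
        if self.kind == ROBERTSONIAN:
            return f"rob({chroms})(q10;q10)"
        if self.kind == RECIPROCAL:
            bands = ";".join(bp.band for bp in self.breakpoints)
            return f"t({chroms})({bands})"
        if self.kind in {INVERSION, DELETION, DUPLICATION}:
            bands = "".join(bp.band for bp in self.breakpoints)
            return f"{abbr}({chroms})({bands})"
        # insertion: ins(A;B)(bandA;bandB1bandB2)
        a = self.breakpoints[0].band
        rest = "".join(bp.band for bp in self.breakpoints[1:])
        return f"ins({chroms})({a};{rest})"


@dataclass(frozen=True)
class Karyotype:
    sex: str  # XX | XY | X | other
    modal_count: int
    rearrangements: tuple[Rearrangement, ...] = ()
    raw: str = ""

    @property
    def is_normal(self) -> bool:
        return not self.rearrangements

    def to_iscn(self) -> str:
        sex_token = {"XX": "XX", "XY": "XY", "X": "X"}.get(self.sex, self.sex)
        parts = [str(self.modal_count), sex_token]
        parts.extend(r.to_iscn() for r in self.rearrangements)
        return ",".join(parts)


_TERM_RE = re.compile(r"^(t|rob|der|inv|del|dup|ins)\(([^)]*)\)(?:\(([^)]*)\))?$")
_BAND_RE = re.compile(r"[pq]\d+(?:\.\d+)?|[pq]ter|cen")
_SEX_RE = re.compile(r"^[XY]+$")


def _split_bands(text: str) -> list[str]:
    bands = _BAND_RE.findall(text)
    if "".join(bands) != text:
        raise KaryotypeParseError(f"cannot parse band list {text!r}")
    return bands


def parse_karyotype(iscn: str) -> Karyotype:
    """Parse an ISCN karyotype string into a :class:`Karyotype`.

    Whitespace-tolerant; raises :class:`KaryotypeParseError` naming the
    offending token, or :class:`UnsupportedISCNError` for recognized but
    unsupported ISCN constructs (mosaic notation, rings, markers, bare
    del/dup without a breakpoint term, ...).
    """
    if not iscn or not iscn.strip():
        raise KaryotypeParseError("empty karyotype string")
    compact = re.sub(r"\s+", "", iscn)
    if "/" in compact:
        raise UnsupportedISCNError("mosaic karyotype notation ('/') is unsupported")
    # split on commas not inside parentheses
    terms, depth, cur = [], 0, []
    for ch in compact:
        if ch == "," and depth == 0:
            terms.append("".join(cur))
            cur = []
        else:
            depth += ch == "("
            depth -= ch == ")"
            cur.append(ch)
    terms.append("".join(cur))
    if len(terms) < 2:
        raise KaryotypeParseError(f"karyotype needs modal count and sex: {iscn!r}")
    try:
        modal = int(terms[0])
    except ValueError:
        raise KaryotypeParseError(f"bad modal count token {terms[0]!r}") from None
    sex_token = terms[1]
    if not _SEX_RE.match(sex_token):
        raise KaryotypeParseError(f"bad sex token {sex_token!r}")
    if sex_token in {"XX", "XY", "X"}:
        sex = sex_token
    elif "Y" in sex_token:
        sex = "XY"
    else:
        sex = "other"

    rearrangements = [_parse_term(t) for t in terms[2:]]
    return Karyotype(sex=sex, modal_count=modal,
                     rearrangements=tuple(rearrangements), raw=iscn.strip())


def _parse_term(term: str) -> Rearrangement:
    m = _TERM_RE.match(term)
    if not m:
        known_unsupported = ("r(", "mar", "add(", "i(", "idic(", "+", "-")
        if any(term.startswith(k) for k in known_unsupported):
            raise UnsupportedISCNError(f"unsupported ISCN construct {term!r}")
        raise KaryotypeParseError(f"unparseable karyotype term {term!r}")
    op, chrom_text, band_text = m.group(1), m.group(2), m.group(3)
    chroms = tuple(chrom_text.split(";"))
    for c in chroms:
        if not re.match(r"^(\d{1,2}|X|Y)$", c):
            raise KaryotypeParseError(f"bad chromosome token {c!r} in {term!r}")

    if op in {"rob", "der"}:
        if len(chroms) != 2:
            raise KaryotypeParseError(f"{op} needs two chromosomes: {term!r}")
        if band_text not in (None, "q10;q10"):
            raise UnsupportedISCNError(
                f"only whole-arm (q10;q10) Robertsonian supported: {term!r}")
        if not set(chroms) <= ACROCENTRICS:
            raise UnsupportedISCNError(
                f"Robertsonian requires acrocentric chromosomes: {term!r}")
        bps = tuple(Breakpoint(c, "q10") for c in chroms)
        return Rearrangement(ROBERTSONIAN, chroms, bps)

    if band_text is None:
        raise UnsupportedISCNError(
            f"{op}(...) without a breakpoint term is unsupported: {term!r}")

    if op == "t":
        bands = band_text.split(";")
        if len(chroms) != 2 or len(bands) != 2:
            raise UnsupportedISCNError(
                f"only two-way reciprocal translocations supported: {term!r}")
        bps = tuple(Breakpoint(c, _single_band(b, term))
                    for c, b in zip(chroms, bands))
        return Rearrangement(RECIPROCAL, chroms, bps)

    if op in {"inv", "del", "dup"}:
        bands = _split_bands(band_text)
        kind = {"inv": INVERSION, "del": DELETION, "dup": DUPLICATION}[op]
        if op == "inv" and len(bands) != 2:
            raise KaryotypeParseError(f"inversion needs two breakpoints: {term!r}")
        if op in {"del", "dup"} and len(bands) not in (1, 2):
            raise KaryotypeParseError(f"{op} needs one or two breakpoints: {term!r}")
        bps = tuple(Breakpoint(chroms[0], b) for b in bands)
        subtype = "n/a"
        if op == "inv":
            arms = {b[0] for b in bands}
            subtype = "pericentric" if arms == {"p", "q"} else "paracentric"
        return Rearrangement(kind, chroms, bps, inversion_subtype=subtype)

    if op == "ins":
        parts = band_text.split(";")
        if len(chroms) != 2 or len(parts) != 2:
            raise UnsupportedISCNError(f"unsupported insertion form: {term!r}")
        receive = Breakpoint(chroms[0], _single_band(parts[0], term))
        donor_bands = _split_bands(parts[1])
        if len(donor_bands) != 2:
            raise KaryotypeParseError(
                f"insertion donor needs two breakpoints: {term!r}")
        donors = tuple(Breakpoint(chroms[1], b) for b in donor_bands)
        return Rearrangement(INSERTION, chroms, (receive,) + donors)

    raise UnsupportedISCNError(f"unsupported ISCN construct {term!r}")


def _single_band(text: str, term: str) -> str:
    bands = _split_bands(text)
    if len(bands) != 1:
        raise KaryotypeParseError(f"expected one band in {text!r} of {term!r}")
    return bands[0]


def resolve_breakpoints(k: Karyotype, m: CytobandMap) -> Karyotype:
    """Return a copy of ``k`` with every breakpoint carrying its band's bp
    interval from ``m`` (sub-band names fall back to their parent band)."""
    resolved = []
    for r in k.rearrangements:
        bps = []
        for bp in r.breakpoints:
            if bp.band == "q10":
                cen = m.centromere(bp.chrom)
                q10 = m.band(bp.chrom, "q10")
                bps.append(replace(bp, start=cen, end=q10.end))
            else:
                start, end = m.band_interval(bp.chrom, bp.band)
                bps.append(replace(bp, start=start, end=end))
        resolved.append(replace(r, breakpoints=tuple(bps)))
    return replace(k, rearrangements=tuple(resolved))


def rearrangement_interval(r: Rearrangement, m: CytobandMap) -> tuple[int, int]:
    """Hull interval of a one-chromosome rearrangement (del/dup/inv)."""
    bps = r.breakpoints
    if len(bps) == 1:
        return bps[0].start, bps[0].end
    return min(bp.start for bp in bps), max(bp.end for bp in bps)


def segment_partition(r: Rearrangement, m: CytobandMap) -> dict[str, Segment]:
    """Partition the involved chromosomes into the segments exchanged or
    altered by ``r``.

    Breakpoints named at band resolution are cut at the band midpoint.

    Returns a mapping of role labels to :class:`Segment`:

    * reciprocal translocation: ``A_centric``, ``A_translocated``,
      ``B_centric``, ``B_translocated`` (centric = the piece retaining the
      centromere);
    * Robertsonian: ``A_q``, ``B_q`` (whole long arms);
    * inversion: ``p_flank``, ``inverted``, ``q_flank`` (flanks may be
      absent at chromosome ends);
    * deletion/duplication: ``affected`` plus flanks.
    """
    for bp in r.breakpoints:
        if not bp.resolved:
            raise ValueError("breakpoints must be resolved first")

    if r.kind == RECIPROCAL:
        out: dict[str, Segment] = {}
        for label, chrom, bp in (("A", r.chromosomes[0], r.breakpoints[0]),
                                 ("B", r.chromosomes[1], r.breakpoints[1])):
            cut = bp.midpoint
            length = m.lengths[chrom]
            cen = m.centromere(chrom)
            low, high = Segment(chrom, 0, cut), Segment(chrom, cut, length)
            if cut > cen:  # breakpoint on q arm: centric piece is the low one
                out[f"{label}_centric"], out[f"{label}_translocated"] = low, high
            else:
                out[f"{label}_centric"], out[f"{label}_translocated"] = high, low
        return out

    if r.kind == ROBERTSONIAN:
        out = {}
        for label, chrom in zip("AB", r.chromosomes):
            cen = m.centromere(chrom)
            out[f"{label}_q"] = Segment(chrom, cen, m.lengths[chrom])
        return out

    if r.kind in {INVERSION, DELETION, DUPLICATION}:
        chrom = r.chromosomes[0]
        length = m.lengths[chrom]
        if r.kind == INVERSION:
            lo = min(bp.midpoint for bp in r.breakpoints)
            hi = max(bp.midpoint for bp in r.breakpoints)
            key = "inverted"
        else:
            lo, hi = rearrangement_interval(r, m)
            key = "affected"
        out = {key: Segment(chrom, lo, hi)}
        if lo > 0:
            out["p_flank"] = Segment(chrom, 0, lo)
        if hi < length:
            out["q_flank"] = Segment(chrom, hi, length)
        return out

    if r.kind == INSERTION:
        chrom = r.chromosomes[1]
        lo, hi = m.hull(chrom, r.breakpoints[1].band, r.breakpoints[2].band)
        return {"inserted": Segment(chrom, lo, hi)}

    raise UnsupportedISCNError(f"no segment model for {r.kind}")
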