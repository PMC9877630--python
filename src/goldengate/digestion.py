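"""Restriction-site discovery and digestion into sticky fragments.

Handles type-IIS enzymes (cut offsets 3' of the recognition sequence,
e.g. BsaI GGTCTC(N1)/(N5)) and classical enzymes (negative offsets, cut
inside/adjacent to the recognition) on linear and circular molecules.

Cut geometry for a plus-strand site occupying [s, e) on the top strand:

    top cut    = e + top_cut_offset
    bottom cut = e + bottom_cut_offset   (in top-strand coordinates)

For a minus-strand site (top strand matches the reverse complement of the
recognition at [s, e)) the roles of the strands swap and offsets run
leftwards:

    top cut    = s - bottom_cut_offset
    bottom cut = s - top_cut_offset

top cut < bottom cut yields a 5' overhang, > yields a 3' overhang, equal
is blunt; the overhang is always read 5'->3' on the protruding strand.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence, Union

from .errors import DigestError, UsageError
from .seq_model import (
    BLUNT,
    FIVE_PRIME,
    THREE_PRIME,
    Feature,
    Overhang,
    Provenance,
    SequenceRecord,
    StickyFragment,
    is_palindromic,
    reverse_complement,
)

__all__ = [
    "EnzymeSpec",
    "RecognitionSite",
    "get_enzyme",
    "load_enzyme_table",
    "find_sites",
    "digest",
    "restriction_map",
    "enumerate_overhangs",
    "expected_site_spacing",
]


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: recognition sequence (top strand) plus the
    cut offsets of each strand, counted 3' of the recognition end."""

    name: str
    recognition: str
    top_cut_offset: int
    bottom_cut_offset: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "recognition", self.recognition.upper())
        if set(self.recognition) - set("ACGT"):
            raise UsageError(
                f"{self.name}: recognition must be concrete ACGT letters"
            )

    @property
    def cut_inside(self) -> bool:
        """Classical enzymes cut within/adjacent to the recognition."""
        return self.top_cut_offset <= 0 or self.bottom_cut_offset <= 0

    @property
    def is_type_iis(self) -> bool:
        return not self.cut_inside

    @property
    def overhang_length(self) -> int:
        return abs(self.bottom_cut_offset - self.top_cut_offset)

    @property
    def overhang_polarity(self) -> str:
        if self.top_cut_offset < self.bottom_cut_offset:
            return FIVE_PRIME
        if self.top_cut_offset > self.bottom_cut_offset:
            return THREE_PRIME
        return BLUNT

    @property
    def is_palindromic(self) -> bool:
        return is_palindromic(self.recognition)


@dataclass(frozen=True)
class RecognitionSite:
    """A recognition match: 0-based start of the match on the top strand
    and the strand carrying the recognition sequence.  A minus-strand site
    is a top-strand match to the reverse complement of the recognition."""

    position: int
    strand: str
    enzyme: EnzymeSpec

    @property
    def end(self) -> int:
        return self.position + len(self.enzyme.recognition)


# ---------------------------------------------------------------------------
# Built-in enzyme table (packaged TSV, user-extensible).
# ---------------------------------------------------------------------------

_ENZYME_CACHE: Optional[dict[str, EnzymeSpec]] = None


def load_enzyme_table(path=None) -> dict[str, EnzymeSpec]:
    """Load an enzyme table (name, recognition, top offset, bottom offset,
    tab-separated, '#' comments).  Without *path*, the packaged table."""
    if path is None:
        text = (
            resources.files("goldengate.data")
            .joinpath("enzymes.tsv")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    table: dict[str, EnzymeSpec] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, recog, top, bottom = line.split("\t")
        table[name] = EnzymeSpec(name, recog, int(top), int(bottom))
    return table


def get_enzyme(name: str) -> EnzymeSpec:
    """Look up a built-in enzyme by name (case-sensitive)."""
    global _ENZYME_CACHE
    if _ENZYME_CACHE is None:
        _ENZYME_CACHE = load_enzyme_table()
    try:
        return _ENZYME_CACHE[name]
    except KeyError:
        raise UsageError(
            f"unknown enzyme {name!r}; built-ins: {sorted(_ENZYME_CACHE)}"
        ) from None


# ---------------------------------------------------------------------------
# Site scanning
# ---------------------------------------------------------------------------


def _scan(haystack: str, needle: str) -> Iterable[int]:
    """All (overlapping) match start positions of *needle* in *haystack*."""
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def find_sites(
    record: Union[SequenceRecord, str], enzyme: EnzymeSpec
) -> list[RecognitionSite]:
    """All recognition sites on both strands, sorted by position.

    Circular records are scanned across the origin (doubled-sequence scan
    deduplicated modulo length).  For palindromic recognitions each
    physical site is reported once, on the plus strand.
    """
    if isinstance(record, str):
        record = SequenceRecord("_anon", record)
    seq = record.residues
    n = len(seq)
    recog = enzyme.recognition
    if n < len(recog):
        return []
    hay = seq + seq[: len(recog) - 1] if record.is_circular else seq
    sites = [
        RecognitionSite(p % n, "+", enzyme) for p in _scan(hay, recog)
    ]
    if not enzyme.is_palindromic:
        rc = reverse_complement(recog)
        sites += [
            RecognitionSite(p % n, "-", enzyme) for p in _scan(hay, rc)
        ]
    uniq = {(s.position, s.strand): s for s in sites}
    return sorted(uniq.values(), key=lambda s: (s.position, s.strand))


# ---------------------------------------------------------------------------
# Digestion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Cut:
    top: int
    bottom: int
    site: RecognitionSite

    @property
    def lo(self) -> int:
        return min(self.top, self.bottom)

    @property
    def hi(self) -> int:
        return max(self.top, self.bottom)

    @property
    def polarity(self) -> str:
        if self.top < self.bottom:
            return FIVE_PRIME
        if self.top > self.bottom:
            return THREE_PRIME
        return BLUNT


def _cuts_for(record: SequenceRecord, site: RecognitionSite) -> _Cut:
    enz = site.enzyme
    if site.strand == "+":
        top = site.end + enz.top_cut_offset
        bottom = site.end + enz.bottom_cut_offset
    else:
        top = site.position - enz.bottom_cut_offset
        bottom = site.position - enz.top_cut_offset
    n = len(record)
    if record.is_circular:
        shift = (min(top, bottom) % n) - min(top, bottom)
        top += shift
        bottom += shift
    else:
        if min(top, bottom) < 0 or max(top, bottom) > n:
            raise DigestError(
                f"{enz.name} site at {site.position} ({site.strand}): cut "
                f"window falls outside the linear molecule"
            )
    window = record.subseq(min(top, bottom), max(top, bottom))
    if set(window) - set("ACGT"):
        raise DigestError(
            f"{enz.name} site at {site.position}: cut window {window!r} "
            f"contains ambiguity codes; overhang identity would not be concrete"
        )
    return _Cut(top, bottom, site)


def _collect_cuts(
    record: SequenceRecord, enzymes: Sequence[EnzymeSpec]
) -> list[_Cut]:
    cuts: dict[tuple[int, int], _Cut] = {}
    for enz in enzymes:
        for site in find_sites(record, enz):
            c = _cuts_for(record, site)
            cuts.setdefault((c.top, c.bottom), c)
    ordered = sorted(cuts.values(), key=lambda c: (c.lo, c.hi))
    n = len(record)
    for a, b in zip(ordered, ordered[1:]):
        if b.lo < a.hi:
            raise DigestError(
                f"cut windows overlap: [{a.lo},{a.hi}) and [{b.lo},{b.hi}); "
                f"no single-molecule outcome is defined"
            )
    if record.is_circular and len(ordered) > 1:
        a, b = ordered[-1], ordered[0]
        if b.lo + n < a.hi:
            raise DigestError("cut windows overlap across the origin")
    return ordered


def _make_fragment(
    record: SequenceRecord,
    prev: _Cut,
    nxt: _Cut,
    unroll: bool,
) -> StickyFragment:
    """Fragment between two consecutive cuts.  *unroll*: nxt lies one turn
    ahead of prev on a circular record."""
    n = len(record)
    span_start = prev.lo
    span_end = (nxt.hi + n) if unroll else nxt.hi
    core = record.subseq(span_start, span_end)
    llen = prev.hi - prev.lo
    rlen = nxt.hi - nxt.lo
    lpol = prev.polarity
    rpol = nxt.polarity
    if lpol == BLUNT:
        left = Overhang("", BLUNT, "left")
    elif lpol == FIVE_PRIME:
        left = Overhang(core[:llen], FIVE_PRIME, "left")
    else:
        left = Overhang(reverse_complement(core[:llen]), THREE_PRIME, "left")
    if rpol == BLUNT:
        right = Overhang("", BLUNT, "right")
    elif rpol == FIVE_PRIME:
        right = Overhang(reverse_complement(core[len(core) - rlen :]),
                         FIVE_PRIME, "right")
    else:
        right = Overhang(core[len(core) - rlen :], THREE_PRIME, "right")
    kept = []
    shifts = (0, n) if record.is_circular else (0,)
    for f in record.features:
        for shift in shifts:
            s, e = f.start + shift, f.end + shift
            if span_start <= s and e <= span_end:
                kept.append(
                    Feature(f.label, s - span_start, e - span_start, f.strand)
                )
                break
    kept = tuple(kept)
    prov = (Provenance(record.id, span_start, span_end, "+"),)
    return StickyFragment(core, left, right, prov, kept)


def digest(
    record: SequenceRecord,
    enzymes: Union[EnzymeSpec, Sequence[EnzymeSpec]],
) -> list[StickyFragment]:
    """Cut a record with one or more enzymes.

    A circular record with k cut positions yields k fragments; a linear
    record yields k+1.  A circular record with zero sites is returned
    intact as a single fragment flagged ``circular_uncut``.
    """
    if isinstance(enzymes, EnzymeSpec):
        enzymes = [enzymes]
    cuts = _collect_cuts(record, enzymes)
    n = len(record)
    if not cuts:
        if record.is_circular:
            return [
                StickyFragment(
                    record.residues,
                    Overhang("", BLUNT, "left"),
                    Overhang("", BLUNT, "right"),
                    (Provenance(record.id, 0, n, "+"),),
                    tuple(record.features),
                    circular_uncut=True,
                )
            ]
        return [
            StickyFragment(
                record.residues,
                Overhang("", BLUNT, "left"),
                Overhang("", BLUNT, "right"),
                (Provenance(record.id, 0, n, "+"),),
                tuple(record.features),
            )
        ]
    frags: list[StickyFragment] = []
    if record.is_circular:
        for i, prev in enumerate(cuts):
            nxt = cuts[(i + 1) % len(cuts)]
            frags.append(_make_fragment(record, prev, nxt,
                                        unroll=(i + 1 == len(cuts))))
    else:
        bound_l = _Cut(0, 0, None)  # type: ignore[arg-type]
        bound_r = _Cut(n, n, None)  # type: ignore[arg-type]
        boundaries = [bound_l] + cuts + [bound_r]
        for prev, nxt in zip(boundaries, boundaries[1:]):
            frags.append(_make_fragment(record, prev, nxt, unroll=False))
    retained = {(f.label, f.strand) for frag in frags for f in frag.features}
    lost = [
        f.label for f in record.features
        if (f.label, f.strand) not in retained
    ]
    if lost:
        # A feature spanning a cut cannot be carried through; predictable
        # drop rather than a guessed split annotation.
        warnings.warn(
            f"{record.id}: feature(s) split by digestion were dropped: "
            f"{lost}",
            stacklevel=2,
        )
    return frags


def restriction_map(
    record: SequenceRecord,
    enzymes: Union[EnzymeSpec, Sequence[EnzymeSpec]],
) -> list:
    """Sorted fragment lengths of a digestion, measured cut-to-cut on the
    top strand so that the lengths sum to the record length.

    A circular record with no site returns ``["uncut", length]``.
    """
    if isinstance(enzymes, EnzymeSpec):
        enzymes = [enzymes]
    cuts = _collect_cuts(record, enzymes)
    n = len(record)
    if not cuts:
        if record.is_circular:
            return ["uncut", n]
        return [n]
    tops = sorted(c.top % n if record.is_circular else c.top for c in cuts)
    if record.is_circular:
        lengths = [
            (b - a) % n or n
            for a, b in zip(tops, tops[1:] + [tops[0]])
        ]
    else:
        edges = [0] + tops + [n]
        lengths = [b - a for a, b in zip(edges, edges[1:]) if b - a > 0]
    return sorted(lengths)


# ---------------------------------------------------------------------------
# Overhang-space utilities
# ---------------------------------------------------------------------------


def enumerate_overhangs(length: int = 4) -> list[str]:
    """All distinct overhang sequences of the given length over {A,C,G,T}
    (4**length of them; 256 for the 4-nt ends a BsaI-class enzyme leaves)."""
    return ["".join(p) for p in itertools.product("ACGT", repeat=length)]


def expected_site_spacing(enzyme: EnzymeSpec) -> int:
    """Expected spacing of one orientation of the recognition sequence in
    uniform random DNA: 4**len(recognition) bp (4096 for a 6-cutter)."""
    return 4 ** len(enzyme.recognition)
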