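"""Core DNA data model, strand arithmetic, and FASTA/GenBank I/O.

Coordinates are 0-based, half-open everywhere inside the toolkit; the
1-based inclusive GenBank convention exists only at the file boundary
(Biopython handles the translation).  Circular records wrap modulo their
length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import ParseError, SequenceError, UsageError

IUPAC_DNA = "ACGTRYSWKMBDHVN"

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)

_DNA_RE = re.compile(r"^[ACGTRYSWKMBDHVN]*$")

FIVE_PRIME = "5p"
THREE_PRIME = "3p"
BLUNT = "blunt"


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an IUPAC DNA string.

    Involution: ``reverse_complement(reverse_complement(s)) == s``.

    Raises
    ------
    SequenceError
        If *seq* contains a non-IUPAC character.
    """
    s = seq.upper()
    if not _DNA_RE.match(s):
        bad = sorted(set(s) - set(IUPAC_DNA))
        raise SequenceError(f"non-DNA character(s) in input: {bad!r}")
    return s.translate(_COMPLEMENT)[::-1]


def is_palindromic(seq: str) -> bool:
    """True iff *seq* equals its own reverse complement."""
    return seq.upper() == reverse_complement(seq)


def coordinate_span(start: int, end: int) -> int:
    """Length of the segment between two printed endpoint coordinates.

    The toolkit's deletion-arithmetic convention is the plain difference of
    the two endpoints (equivalently: 0-based half-open interval length).
    """
    if end < start:
        raise UsageError("end coordinate precedes start coordinate")
    return end - start


def least_rotation(s: str) -> str:
    """Lexicographically least rotation of *s* (Booth's algorithm)."""
    if not s:
        return s
    ss = s + s
    f = [-1] * len(ss)
    k = 0
    for j in range(1, len(ss)):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return ss[k : k + len(s)]


def canonical_circle(seq: str) -> str:
    """Canonical representative of a circular double-stranded sequence:
    the smaller of the least rotations of the top strand and its reverse
    complement.  Two circles are the same molecule iff their canonical
    forms are equal."""
    return min(least_rotation(seq), least_rotation(reverse_complement(seq)))


@dataclass(frozen=True)
class Feature:
    """A (label, start, end, strand) annotation on a record, 0-based
    half-open."""

    label: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class SequenceRecord:
    """A named DNA molecule: id, top-strand residues, topology and
    feature annotations.  The universal currency of the toolkit."""

    id: str
    residues: str
    topology: str = "linear"
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not _DNA_RE.match(self.residues):
            bad = sorted(set(self.residues) - set(IUPAC_DNA))
            raise SequenceError(
                f"record {self.id!r}: non-IUPAC character(s) {bad!r}"
            )
        if self.topology not in ("linear", "circular"):
            raise SequenceError(
                f"record {self.id!r}: topology must be 'linear' or 'circular'"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def subseq(self, start: int, end: int) -> str:
        """Top-strand slice; wraps modulo length on circular records.

        ``start`` may be negative and ``end`` may exceed the length on a
        circular record, as long as ``end - start <= len(self)``.
        """
        n = len(self)
        length = end - start
        # A single staggered cut on a circle releases a linear duplex whose
        # extent exceeds n by the overhang length, so circular slices may
        # wrap a little past one full turn.
        limit = 2 * n if self.is_circular else n
        if length < 0 or length > limit:
            raise UsageError("requested slice longer than the molecule")
        if self.is_circular:
            s = start % n
            return (self.residues + self.residues + self.residues)[s : s + length]
        if start < 0 or end > n:
            raise UsageError(
                f"slice [{start}, {end}) outside linear record of length {n}"
            )
        return self.residues[start:end]

    def rotated(self, offset: int) -> "SequenceRecord":
        """Same circular molecule with the origin shifted by *offset* nt."""
        if not self.is_circular:
            raise UsageError("only circular records can be rotated")
        n = len(self)
        offset %= n
        residues = self.residues[offset:] + self.residues[:offset]
        feats = [
            replace(f, start=(f.start - offset) % n, end=(f.end - offset) % n)
            for f in self.features
        ]
        return SequenceRecord(self.id, residues, "circular", feats)

    def reverse_complement(self) -> "SequenceRecord":
        n = len(self)
        feats = [
            Feature(f.label, n - f.end, n - f.start,
                    "-" if f.strand == "+" else "+")
            for f in self.features
        ]
        return SequenceRecord(self.id, reverse_complement(self.residues),
                              self.topology, feats)


@dataclass(frozen=True)
class Overhang:
    """A single-stranded extension at a fragment end.

    ``sequence`` is read 5'->3' on the protruding strand.  BsaI chemistry
    produces 4-nt 5' overhangs; classical enzymes used for construction
    replay may produce 3' overhangs or blunt ends, so ``polarity`` is one
    of ``"5p"``, ``"3p"`` or ``"blunt"`` (blunt implies an empty sequence).
    """

    sequence: str
    polarity: str = FIVE_PRIME
    end: Optional[str] = None  # "left" | "right" when attached to a fragment

    def __post_init__(self) -> None:
        if self.polarity not in (FIVE_PRIME, THREE_PRIME, BLUNT):
            raise SequenceError(f"bad overhang polarity {self.polarity!r}")
        if self.polarity == BLUNT and self.sequence:
            raise SequenceError("blunt overhang must have empty sequence")
        if self.sequence and not _DNA_RE.match(self.sequence.upper()):
            raise SequenceError("overhang contains non-DNA characters")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_palindromic(self) -> bool:
        return bool(self.sequence) and is_palindromic(self.sequence)


BLUNT_END_LEFT = Overhang("", BLUNT, "left")
BLUNT_END_RIGHT = Overhang("", BLUNT, "right")


@dataclass(frozen=True)
class Provenance:
    """Where a fragment interval came from: source record id, 0-based
    half-open interval in that record's coordinates (the interval of the
    fragment's full double-stranded span), and orientation."""

    source: str
    start: int
    end: int
    orient: str = "+"

    def flipped(self) -> "Provenance":
        return Provenance(self.source, self.start, self.end,
                          "-" if self.orient == "+" else "+")


@dataclass
class StickyFragment:
    """A double-stranded fragment with explicit overhangs at each end.

    ``core`` is the top-strand sequence over the fragment's full extent
    (both overhang regions included exactly once), so the total duplex
    span equals ``len(core)``.  The left overhang sequence is derivable
    from the first bases of ``core`` and the right overhang from the last
    bases, according to each end's polarity:

    * left 5' end: top strand protrudes, overhang == core prefix;
    * left 3' end: bottom strand protrudes, overhang == rc(core prefix);
    * right 5' end: bottom strand protrudes, overhang == rc(core suffix);
    * right 3' end: top strand protrudes, overhang == core suffix.
    """

    core: str
    left_overhang: Overhang = BLUNT_END_LEFT
    right_overhang: Overhang = BLUNT_END_RIGHT
    provenance: tuple[Provenance, ...] = ()
    features: tuple[Feature, ...] = ()
    role: Optional[str] = None  # backbone | cassette | insert | adapter_scrap | derived
    circular_uncut: bool = False  # an intact, site-free circle returned as-is
    n_units: int = 1  # elementary fragments fused into this species

    def __post_init__(self) -> None:
        self.core = self.core.upper()
        lo, ro = self.left_overhang, self.right_overhang
        if len(lo) + len(ro) > len(self.core):
            raise SequenceError("overhangs longer than the fragment")
        # Consistency of stored overhang sequences with the core slices.
        if lo.polarity == FIVE_PRIME and lo.sequence != self.core[: len(lo)]:
            raise SequenceError("left 5' overhang disagrees with core prefix")
        if lo.polarity == THREE_PRIME and lo.sequence != reverse_complement(
            self.core[: len(lo)]
        ):
            raise SequenceError("left 3' overhang disagrees with core prefix")
        if ro.polarity == FIVE_PRIME and ro.sequence != reverse_complement(
            self.core[len(self.core) - len(ro) :]
        ):
            raise SequenceError("right 5' overhang disagrees with core suffix")
        if ro.polarity == THREE_PRIME and ro.sequence != self.core[
            len(self.core) - len(ro) :
        ]:
            raise SequenceError("right 3' overhang disagrees with core suffix")

    def __len__(self) -> int:
        return len(self.core)

    @property
    def top_length(self) -> int:
        """Length of the fragment counting each overhang region once on a
        single reference strand (the restriction-map length)."""
        return len(self.core) - len(self.left_overhang)

    def key(self) -> tuple:
        """Identity of the physical species (sequence + end chemistry +
        provenance)."""
        return (
            self.core,
            self.left_overhang.polarity,
            len(self.left_overhang),
            self.right_overhang.polarity,
            len(self.right_overhang),
            self.provenance,
        )

    def struct_key(self) -> tuple:
        """Identity ignoring provenance (pure sequence + end chemistry)."""
        return self.key()[:5]

    def reverse_complement(self) -> "StickyFragment":
        """The same physical molecule read on the other strand: ends swap,
        polarities are preserved, each new overhang equals the old opposite
        one."""
        n = len(self.core)
        lo, ro = self.left_overhang, self.right_overhang
        new_left = Overhang(ro.sequence, ro.polarity, "left")
        new_right = Overhang(lo.sequence, lo.polarity, "right")
        feats = tuple(
            Feature(f.label, n - f.end, n - f.start,
                    "-" if f.strand == "+" else "+")
            for f in self.features
        )
        prov = tuple(p.flipped() for p in reversed(self.provenance))
        return StickyFragment(
            reverse_complement(self.core), new_left, new_right, prov, feats,
            self.role, self.circular_uncut, self.n_units,
        )

    def can_precede(self, other: "StickyFragment") -> bool:
        """True iff this fragment's right end can ligate to *other*'s left
        end (exact reverse-complement annealing; blunt joins blunt)."""
        ro, lo = self.right_overhang, other.left_overhang
        if self.circular_uncut or other.circular_uncut:
            return False
        if ro.polarity != lo.polarity or len(ro) != len(lo):
            return False
        if ro.polarity == BLUNT:
            return True
        return ro.sequence == reverse_complement(lo.sequence)


def _feature_shift(
    features: Iterable[Feature], lo: int, hi: int, source_len: Optional[int]
) -> tuple[Feature, ...]:
    """Features fully contained in [lo, hi) shifted to local coordinates;
    split features are dropped (the caller warns)."""
    kept = []
    for f in features:
        if lo <= f.start and f.end <= hi:
            kept.append(Feature(f.label, f.start - lo, f.end - lo, f.strand))
    return tuple(kept)


# ---------------------------------------------------------------------------
# File I/O (FASTA and GenBank flat file); all other modules go through here.
# ---------------------------------------------------------------------------

_FORMATS = {"fasta", "genbank"}

_EXT_TO_FORMAT = {
    ".fa": "fasta", ".fasta": "fasta", ".fna": "fasta",
    ".gb": "genbank", ".gbk": "genbank", ".genbank": "genbank",
}


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise UsageError(
                f"unknown format {fmt!r}; expected one of {sorted(_FORMATS)}"
            )
        return fmt
    guess = _EXT_TO_FORMAT.get(path.suffix.lower())
    if guess is None:
        raise UsageError(
            f"cannot infer format from extension {path.suffix!r}; pass format="
        )
    return guess


def read_record(
    path, format: Optional[str] = None, topology: Optional[str] = None
) -> SequenceRecord:
    """Read a single FASTA or GenBank record.

    Topology comes from the GenBank LOCUS line; FASTA defaults to linear
    unless *topology* overrides it.
    """
    p = Path(path)
    fmt = _infer_format(p, format)
    try:
        rec = SeqIO.read(str(p), fmt)
    except (ValueError, FileNotFoundError, IndexError) as exc:
        raise ParseError(f"cannot parse {p} as {fmt}: {exc}") from exc
    if fmt == "genbank":
        topo = rec.annotations.get("topology", "linear")
    else:
        topo = topology or "linear"
    if topology is not None:
        topo = topology
    feats = []
    for f in rec.features:
        if f.type == "source":
            continue
        label = (
            f.qualifiers.get("label", [None])[0]
            or f.qualifiers.get("gene", [None])[0]
            or f.qualifiers.get("note", [f.type])[0]
        )
        strand = "-" if f.location.strand == -1 else "+"
        feats.append(
            Feature(str(label), int(f.location.start), int(f.location.end),
                    strand)
        )
    return SequenceRecord(rec.id, str(rec.seq), topo, feats)


def write_record(record: SequenceRecord, path, format: Optional[str] = None) -> None:
    """Write a record to FASTA or GenBank.  ``read_record(write_record(x))``
    reproduces residues, topology and features (FASTA drops features and
    topology by design of the format)."""
    p = Path(path)
    fmt = _infer_format(p, format)
    bio = _BioSeqRecord(
        Seq(record.residues),
        id=record.id,
        name=re.sub(r"[^A-Za-z0-9_]", "_", record.id)[:16] or "record",
        description="",
    )
    bio.annotations["molecule_type"] = "DNA"
    bio.annotations["topology"] = record.topology
    for f in record.features:
        bio.features.append(
            SeqFeature(
                FeatureLocation(f.start, f.end, 1 if f.strand == "+" else -1),
                type="misc_feature",
                qualifiers={"label": [f.label]},
            )
        )
    try:
        SeqIO.write([bio], str(p), fmt)
    except OSError as exc:
        raise UsageError(f"cannot write {p}: {exc}") from exc
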