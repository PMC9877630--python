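"""pBTR vector registry and synthetic test-input generators.

The packaged registry always ships vector *specs* (names, adapters,
overhangs, markers).  Full plasmid sequences are not redistributed; when a
user supplies GenBank files they are attached to the spec and validated.
All sequence-level workflows that need a physical vector run on
:func:`mock_vector`, which builds a minimal circular vector with the
designed tandem reverse-oriented BsaI junctions of the requested set.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

from .digestion import digest, find_sites, get_enzyme
from .errors import UsageError
from .seq_model import (
    Feature,
    SequenceRecord,
    is_palindromic,
    read_record,
    reverse_complement,
)

__all__ = [
    "VectorSpec",
    "RegistryEntry",
    "SyntheticFdiSpec",
    "load_registry",
    "list_vectors",
    "get_vector",
    "set_overhangs",
    "generate_fdi",
    "generate_cds",
    "mock_vector",
]

SPACER_DEFAULT = "A"  # concretization of the single N in GGTCTCN

# Canonical overhang pairs of the two vector sets (the overexpression
# family); individual registry rows may carry family-specific pairs.
SET_OVERHANGS = {
    "BTR1": ("CATC", "GGAT"),
    "BTR2": ("TCTA", "GAGC"),
}

CATEGORIES = (
    "overexpression_35S",
    "overexpression_Ubi",
    "native_promoter",
    "promoter_GUS",
    "subcellular_GFP",
    "empty_SBTR",
)


@dataclass(frozen=True)
class VectorSpec:
    """A pBTR destination vector: set, plant marker, category, adapter
    pair and the derived vector overhang pair."""

    name: str
    set: str
    category: str
    plant_marker: str
    fwd_adapter: str
    rev_adapter: str
    cassette: Optional[tuple[int, int]] = None  # selection-cassette interval

    def __post_init__(self) -> None:
        if self.set not in ("BTR1", "BTR2"):
            raise UsageError(f"{self.name}: set must be BTR1 or BTR2")
        if self.category not in CATEGORIES:
            raise UsageError(f"{self.name}: unknown category {self.category}")

    @property
    def fwd_fusion(self) -> str:
        """3'-terminal 4-mer of the forward adapter (the insert's left
        overhang after digestion)."""
        return self.fwd_adapter[-4:]

    @property
    def rev_fusion(self) -> str:
        return self.rev_adapter[-4:]

    @property
    def vector_overhangs(self) -> tuple[str, str]:
        """The two 5' overhangs presented by the digested vector backbone,
        each the reverse complement of one adapter fusion 4-mer."""
        return (
            reverse_complement(self.fwd_fusion),
            reverse_complement(self.rev_fusion),
        )


@dataclass
class RegistryEntry:
    """A registry row: the spec plus an optional full sequence record."""

    spec: VectorSpec
    record: Optional[SequenceRecord] = None


_REGISTRY_CACHE: Optional[dict[str, RegistryEntry]] = None


def load_registry() -> dict[str, RegistryEntry]:
    """Parse the packaged vector table into RegistryEntry objects."""
    global _REGISTRY_CACHE
    if _REGISTRY_CACHE is not None:
        return _REGISTRY_CACHE
    text = (
        resources.files("goldengate.data").joinpath("vectors.tsv").read_text()
    )
    reg: dict[str, RegistryEntry] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, vset, category, marker, fwd, rev = line.split("\t")
        reg[name] = RegistryEntry(
            VectorSpec(name, vset, category, marker, fwd, rev)
        )
    _REGISTRY_CACHE = reg
    return reg


def list_vectors() -> list[str]:
    return sorted(load_registry())


def get_vector(name: str, sequence_path=None) -> RegistryEntry:
    """Look up a vector by name; optionally attach and validate a full
    GenBank/FASTA sequence supplied by the user."""
    reg = load_registry()
    try:
        entry = reg[name]
    except KeyError:
        raise UsageError(
            f"unknown vector {name!r}; valid names: {sorted(reg)}"
        ) from None
    if sequence_path is not None:
        record = read_record(sequence_path)
        validate_vector_record(entry.spec, record)
        entry = RegistryEntry(entry.spec, record)
    return entry


def validate_vector_record(spec: VectorSpec, record: SequenceRecord) -> None:
    """Check a full vector sequence against its spec: circular, exactly two
    BsaI sites, and backbone overhangs matching the adapter pair."""
    bsai = get_enzyme("BsaI")
    if not record.is_circular:
        raise UsageError(f"{spec.name}: vector sequence must be circular")
    sites = find_sites(record, bsai)
    if len(sites) != 2:
        raise UsageError(
            f"{spec.name}: expected exactly 2 BsaI sites, found {len(sites)}"
        )
    frags = digest(record, bsai)
    backbones = [
        f for f in frags
        if not find_sites(SequenceRecord("_f", f.core), bsai)
    ]
    if len(backbones) != 1:
        raise UsageError(
            f"{spec.name}: digestion must yield exactly one site-free "
            f"backbone fragment"
        )
    got = {
        backbones[0].left_overhang.sequence,
        backbones[0].right_overhang.sequence,
    }
    if got != set(spec.vector_overhangs):
        raise UsageError(
            f"{spec.name}: backbone overhangs {sorted(got)} do not match the "
            f"registry pair {sorted(spec.vector_overhangs)}"
        )


def set_overhangs(set_name: str) -> tuple[str, str]:
    try:
        return SET_OVERHANGS[set_name]
    except KeyError:
        raise UsageError(
            f"unknown set {set_name!r}; expected BTR1 or BTR2"
        ) from None


# ---------------------------------------------------------------------------
# Synthetic sequence generation
# ---------------------------------------------------------------------------

_BSAI_MOTIFS = ("GGTCTC", "GAGACC")


def _random_dna(rng: random.Random, length: int, gc: float) -> str:
    w_gc = gc / 2.0
    w_at = (1.0 - gc) / 2.0
    return "".join(
        rng.choices("ACGT", weights=[w_at, w_gc, w_gc, w_at], k=length)
    )


def _scrub(
    seq: list[str], rng: random.Random, protected: Sequence[tuple[int, int]]
) -> None:
    """Remove accidental BsaI motifs in place by re-rolling one base per
    match, never touching protected intervals."""
    def in_protected(i: int) -> bool:
        return any(lo <= i < hi for lo, hi in protected)

    for _ in range(1000):
        text = "".join(seq)
        dirty = []
        for motif in _BSAI_MOTIFS:
            for m in re.finditer(f"(?={motif})", text):
                span = (m.start(), m.start() + len(motif))
                if not all(in_protected(i) for i in range(*span)):
                    dirty.append(span)
        if not dirty:
            return
        for lo, hi in dirty:
            candidates = [i for i in range(lo, hi) if not in_protected(i)]
            i = rng.choice(candidates)
            seq[i] = rng.choice([b for b in "ACGT" if b != seq[i]])
    raise UsageError("could not scrub accidental BsaI motifs (pathological spec)")


@dataclass(frozen=True)
class SyntheticFdiSpec:
    """Recipe for a synthetic foreign-DNA-fragment-of-interest with a
    controlled internal BsaI site architecture."""

    length: int
    n_internal_sites: int = 0
    internal_overhangs: object = "random"  # list of 4-mers or "random"
    palindromic: bool = False
    gc_content: float = 0.5
    seed: int = 0

    def resolved_overhangs(self, rng: random.Random) -> list[str]:
        if self.internal_overhangs != "random":
            ovhs = [o.upper() for o in self.internal_overhangs]
            if len(ovhs) != self.n_internal_sites:
                raise UsageError(
                    "internal_overhangs length must equal n_internal_sites"
                )
            return ovhs
        ovhs = []
        for _ in range(self.n_internal_sites):
            while True:
                o = "".join(rng.choices("ACGT", k=4))
                if is_palindromic(o) == self.palindromic:
                    ovhs.append(o)
                    break
        return ovhs


# Margin kept free of implanted sites at each FDI end (primer landing pads).
_END_MARGIN = 50
_SITE_BLOCK = 6 + 1 + 4  # recognition + spacer + overhang


def generate_fdi(spec: SyntheticFdiSpec) -> SequenceRecord:
    """Deterministically generate a linear FDI containing exactly the
    requested internal BsaI site architecture (plus-strand sites of the
    form GGTCTC + spacer + overhang) and no accidental sites."""
    if spec.length < 60:
        raise UsageError("FDI length must be at least 60 nt")
    n = spec.n_internal_sites
    usable = spec.length - 2 * _END_MARGIN
    if n > 0 and usable < n * (_SITE_BLOCK + 20):
        raise UsageError(
            f"{n} internal sites do not fit in a {spec.length}-nt FDI"
        )
    rng = random.Random(spec.seed)
    seq = list(_random_dna(rng, spec.length, spec.gc_content))
    protected: list[tuple[int, int]] = []
    ovhs = spec.resolved_overhangs(rng)
    for i, ovh in enumerate(ovhs):
        pos = _END_MARGIN + (i + 1) * usable // (n + 1) - _SITE_BLOCK // 2
        block = "GGTCTC" + SPACER_DEFAULT + ovh
        seq[pos : pos + _SITE_BLOCK] = block
        protected.append((pos, pos + _SITE_BLOCK))
    _scrub(seq, rng, protected)
    record = SequenceRecord(
        f"fdi_L{spec.length}_s{n}_seed{spec.seed}",
        "".join(seq),
        "linear",
        [
            Feature(f"internal_BsaI_{i}", lo, hi, "+")
            for i, (lo, hi) in enumerate(protected)
        ],
    )
    sites = find_sites(record, get_enzyme("BsaI"))
    if len(sites) != n:
        raise UsageError(
            f"generator produced {len(sites)} sites, expected {n} (spec bug)"
        )
    return record


_STOP_CODONS = ("TAA", "TAG", "TGA")


def generate_cds(n_codons: int, seed: int = 0, stop: bool = True) -> SequenceRecord:
    """A toy coding sequence: ATG + random non-stop codons (+ TGA), free of
    BsaI motifs.  Useful for fusion-design tests."""
    if n_codons < 4:
        raise UsageError("need at least 4 codons")
    rng = random.Random(seed)
    codons = ["ATG"]
    body = n_codons - 1 - (1 if stop else 0)
    while len(codons) < 1 + body:
        c = "".join(rng.choices("ACGT", k=3))
        if c in _STOP_CODONS:
            continue
        codons.append(c)
    if stop:
        codons.append("TGA")
    seq = list("".join(codons))
    # Scrub without breaking the reading frame guarantees: re-roll whole
    # codons containing a motif base.
    for _ in range(200):
        text = "".join(seq)
        hit = None
        for motif in _BSAI_MOTIFS:
            m = re.search(motif, text)
            if m:
                hit = m
                break
        if hit is None:
            break
        ci = (hit.start() // 3) * 3
        if ci == 0:
            ci = 3  # never touch the start codon
        if ci >= len(seq) - 3 and stop:
            ci = len(seq) - 6  # never touch the stop codon
        while True:
            c = "".join(rng.choices("ACGT", k=3))
            if c not in _STOP_CODONS:
                seq[ci : ci + 3] = c
                break
    return SequenceRecord(f"cds_{n_codons}aa_seed{seed}", "".join(seq))


def mock_vector(
    set_or_name: str,
    stuffer_length: int = 300,
    seed: int = 0,
    backbone_length: int = 1200,
) -> SequenceRecord:
    """Minimal circular destination vector for a set (or a registry vector
    name): a random backbone and a mock PnptII::mScarlet-I stuffer flanked
    by the set's designed tandem reverse-oriented BsaI junctions.

    Digesting the result yields a site-free backbone whose overhang pair
    equals the set's pair, and a stuffer-side fragment carrying both
    recognition sequences (so the empty vector cannot self-religate and
    re-formed vectors stay cuttable: the one-way reaction).
    """
    if stuffer_length < 50:
        raise UsageError("stuffer_length must be >= 50")
    if set_or_name in SET_OVERHANGS:
        o1, o2 = SET_OVERHANGS[set_or_name]
        name = f"mock_{set_or_name}"
    else:
        entry = get_vector(set_or_name)
        o1, o2 = entry.spec.vector_overhangs
        name = f"mock_{set_or_name}"
    rng = random.Random(seed)
    backbone = list(_random_dna(rng, backbone_length, 0.5))
    stuffer = list(_random_dna(rng, stuffer_length, 0.5))
    left_junction = reverse_complement(o1) + SPACER_DEFAULT + "GAGACC"
    right_junction = "GGTCTC" + SPACER_DEFAULT + o2
    seq = (
        backbone
        + list(left_junction)
        + stuffer
        + list(right_junction)
    )
    j1 = (backbone_length, backbone_length + len(left_junction))
    j2_start = j1[1] + stuffer_length
    j2 = (j2_start, j2_start + len(right_junction))
    # Scrub accidental motifs anywhere (including across the origin) except
    # inside the two designed junctions; rotate-scan via a doubled pass.
    for _ in range(1000):
        text = "".join(seq)
        doubled = text + text[:5]
        dirty = []
        for motif in _BSAI_MOTIFS:
            for m in re.finditer(f"(?={motif})", doubled):
                span_positions = [
                    (m.start() + k) % len(seq) for k in range(len(motif))
                ]
                if all(
                    j1[0] <= p < j1[1] or j2[0] <= p < j2[1]
                    for p in span_positions
                ):
                    continue
                dirty.append(span_positions)
        if not dirty:
            break
        for positions in dirty:
            free = [
                p for p in positions
                if not (j1[0] <= p < j1[1] or j2[0] <= p < j2[1])
            ]
            p = rng.choice(free)
            seq[p] = rng.choice([b for b in "ACGT" if b != seq[p]])
    record = SequenceRecord(
        name,
        "".join(seq),
        "circular",
        [
            Feature("backbone", 0, backbone_length, "+"),
            Feature("PnptII-mScarlet-I cassette", j1[1], j2[0], "+"),
        ],
    )
    sites = find_sites(record, get_enzyme("BsaI"))
    if len(sites) != 2:
        raise UsageError("mock vector scrubbing failed (pathological seed)")
    return record


def mock_cassette_sequence(vector: SequenceRecord) -> str:
    """The selection-cassette (stuffer) sequence of a mock vector, for
    colony-color prediction."""
    for f in vector.features:
        if "cassette" in f.label:
            return vector.subseq(f.start, f.end)
    raise UsageError(f"{vector.id}: no cassette feature annotated")
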