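"""Ligation and one-pot, one-way digestion-ligation simulation.

The reaction is simulated as species-set logic: the simulator enumerates
which circular ligation products *can* exist from the fragment pool, not
concentration kinetics.  Molar ratios annotate the reaction report only.

A junction forms when an overhang anneals to its exact reverse complement
(equal polarity and length); products still carrying a recognition site of
the type-IIS enzyme are re-digested on the next cycle, so material funnels
one-way toward site-free recombinants.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

from .digestion import EnzymeSpec, digest, find_sites, get_enzyme
from .errors import AssemblyError, LigationError, UsageError
from .seq_model import (
    BLUNT,
    Feature,
    SequenceRecord,
    StickyFragment,
    canonical_circle,
    reverse_complement,
)

__all__ = [
    "ReactionProgram",
    "Molecule",
    "ReactionSpec",
    "AssemblyProduct",
    "ligate",
    "simulate_one_pot",
    "simulate_multiplex",
    "MultiplexCensus",
    "subclone",
]

DEFAULT_MAX_FRAGMENTS = 6

KLASS_DESIRED = "desired"
KLASS_EMPTY = "empty_vector"
KLASS_CASSETTE = "cassette_circle"
KLASS_CHIMERA = "chimera"
KLASS_CONCATEMER = "concatemer"
KLASS_UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ReactionProgram:
    """Thermocycler program: cycles of (temperature C, minutes) steps and
    a terminal hold.

    The default is 10 cycles of (37,3),(16,3),(12,2).  The terminal hold is
    (4,60) — ligation-favouring, required when any FDI carries an internal
    site so its pieces can re-ligate — or (37,10), a final digestion that
    suppresses re-formed empty vectors when no FDI has internal sites.
    """

    n_cycles: int = 10
    cycle_steps: tuple[tuple[float, float], ...] = ((37, 3), (16, 3), (12, 2))
    terminal_hold: tuple[float, float] = (37, 10)

    @property
    def ligation_hold(self) -> bool:
        """True when the terminal hold favours ligation (low temperature)."""
        return self.terminal_hold[0] < 16


@dataclass
class Molecule:
    record: SequenceRecord
    molar_ratio: float = 1.0
    is_destination: bool = False

    def __post_init__(self) -> None:
        if self.molar_ratio <= 0:
            raise UsageError("molar ratios must be positive")


@dataclass
class ReactionSpec:
    """A one-pot reaction: molecules with molar ratios, enzymes, ligase
    flag and a thermocycler program."""

    molecules: list[Molecule]
    enzymes: list[EnzymeSpec]
    ligase: bool = True
    program: ReactionProgram = field(default_factory=ReactionProgram)

    @property
    def destination(self) -> Molecule:
        dests = [m for m in self.molecules if m.is_destination]
        if len(dests) != 1:
            raise UsageError(
                f"exactly one destination vector required, found {len(dests)}"
            )
        return dests[0]

    @property
    def type_iis_enzyme(self) -> EnzymeSpec:
        cands = [e for e in self.enzymes if e.is_type_iis]
        if len(cands) != 1:
            raise UsageError(
                f"exactly one type-IIS enzyme required, found {len(cands)}"
            )
        return cands[0]

    def to_config(self) -> dict:
        return {
            "molecules": [
                {
                    "id": m.record.id,
                    "molar_ratio": m.molar_ratio,
                    "destination": m.is_destination,
                }
                for m in self.molecules
            ],
            "enzymes": [e.name for e in self.enzymes],
            "ligase": self.ligase,
            "program": {
                "n_cycles": self.program.n_cycles,
                "cycle_steps": [list(s) for s in self.program.cycle_steps],
                "terminal_hold": list(self.program.terminal_hold),
            },
        }

    @classmethod
    def from_config(
        cls, config: Union[dict, str], records: dict[str, SequenceRecord]
    ) -> "ReactionSpec":
        """Build a reaction from a plain-text JSON config (see
        :meth:`to_config`) plus the named sequence records."""
        if isinstance(config, str):
            config = json.loads(config)
        mols = []
        for m in config["molecules"]:
            try:
                rec = records[m["id"]]
            except KeyError:
                raise UsageError(
                    f"config names unknown record {m['id']!r}"
                ) from None
            mols.append(
                Molecule(rec, m.get("molar_ratio", 1.0),
                         m.get("destination", False))
            )
        prog_cfg = config.get("program", {})
        program = ReactionProgram(
            prog_cfg.get("n_cycles", 10),
            tuple(tuple(s) for s in prog_cfg.get(
                "cycle_steps", [(37, 3), (16, 3), (12, 2)])),
            tuple(prog_cfg.get("terminal_hold", (37, 10))),
        )
        enzymes = [get_enzyme(n) for n in config.get("enzymes", ["BsaI"])]
        return cls(mols, enzymes, config.get("ligase", True), program)


@dataclass
class AssemblyProduct:
    """A circular ligation product: its sequence record, ordered fragment
    composition (fragment, orientation) and classification."""

    record: SequenceRecord
    composition: tuple[tuple[StickyFragment, str], ...]
    klass: str = KLASS_UNCLASSIFIED
    notes: tuple[str, ...] = ()

    @property
    def canonical_sequence(self) -> str:
        return canonical_circle(self.record.residues)

    def __len__(self) -> int:
        return len(self.record)


# ---------------------------------------------------------------------------
# Ligation enumeration
# ---------------------------------------------------------------------------


def _oriented(frag: StickyFragment, orient: str) -> StickyFragment:
    return frag if orient == "+" else frag.reverse_complement()


def _canonical_composition(
    comp: tuple[tuple[int, str], ...]
) -> tuple[tuple[int, str], ...]:
    """Canonical form of a circular composition under rotation and
    reflection (reflection reverses the order and flips orientations)."""
    def rotations(c):
        return [c[i:] + c[:i] for i in range(len(c))]

    flipped = tuple(
        (i, "-" if o == "+" else "+") for i, o in reversed(comp)
    )
    return min(rotations(comp) + rotations(flipped))


def _circle_sequence(parts: Sequence[StickyFragment]) -> str:
    """Top strand of a circle, each junction's overhang region counted
    once."""
    return "".join(p.core[len(p.left_overhang):] for p in parts)


def _product_from_parts(
    pool: Sequence[StickyFragment],
    comp: tuple[tuple[int, str], ...],
) -> AssemblyProduct:
    parts = [_oriented(pool[i], o) for i, o in comp]
    seq = _circle_sequence(parts)
    feats: list[Feature] = []
    offset = 0
    for p in parts:
        trim = len(p.left_overhang)
        for f in p.features:
            if f.start >= trim:
                feats.append(
                    Feature(f.label, f.start - trim + offset,
                            f.end - trim + offset, f.strand)
                )
        offset += len(p.core) - trim
    digest_tag = hashlib.sha1(canonical_circle(seq).encode()).hexdigest()[:8]
    rec = SequenceRecord(f"assembly_{digest_tag}", seq, "circular", feats)
    return AssemblyProduct(
        rec, tuple((pool[i], o) for i, o in comp)
    )


def ligate(
    fragments: Sequence[StickyFragment],
    max_fragments: int = DEFAULT_MAX_FRAGMENTS,
    allow_blunt: bool = False,
) -> list[AssemblyProduct]:
    """Enumerate all distinct circular products of at most *max_fragments*
    pieces in which every junction joins an overhang to its exact reverse
    complement.

    A fragment species may appear more than once in a product (concatemer
    enumeration), and fused species re-released by digestion count as
    their ``n_units`` elementary pieces, so the bound is on elementary
    fragments.  Rotationally and reflectively equivalent circles are
    deduplicated; linear dead-ends are discarded.  Blunt junctions are
    disabled by default (T4 blunt ligation is excluded from the one-pot
    species model) and enabled for classical subcloning.
    """
    if max_fragments < 1:
        raise UsageError("max_fragments must be >= 1")
    pool = [f for f in fragments if not f.circular_uncut]
    nodes: list[tuple[int, str]] = []
    oriented: dict[tuple[int, str], StickyFragment] = {}
    for i, f in enumerate(pool):
        for o in ("+", "-"):
            nodes.append((i, o))
            oriented[(i, o)] = _oriented(f, o)

    def joinable(a: tuple[int, str], b: tuple[int, str]) -> bool:
        fa, fb = oriented[a], oriented[b]
        if not allow_blunt and fa.right_overhang.polarity == BLUNT:
            return False
        return fa.can_precede(fb)

    succ: dict[tuple[int, str], list[tuple[int, str]]] = {
        a: [b for b in nodes if joinable(a, b)] for a in nodes
    }

    seen: set[tuple[tuple[int, str], ...]] = set()
    products: list[AssemblyProduct] = []

    def close(path: list[tuple[int, str]]) -> None:
        comp = _canonical_composition(tuple(path))
        if comp in seen:
            return
        seen.add(comp)
        products.append(_product_from_parts(pool, comp))

    def extend(path: list[tuple[int, str]], units: int) -> None:
        last = path[-1]
        if joinable(last, path[0]):
            close(path)
        for nxt in succ[last]:
            u = units + pool[nxt[0]].n_units
            if u > max_fragments:
                continue
            path.append(nxt)
            extend(path, u)
            path.pop()

    for start in nodes:
        if pool[start[0]].n_units <= max_fragments:
            extend([start], pool[start[0]].n_units)
    products.sort(key=lambda p: (len(p.composition), p.record.id))
    return products


# ---------------------------------------------------------------------------
# Fragment labelling and product classification
# ---------------------------------------------------------------------------


def _has_recognition(seq: str, enzyme: EnzymeSpec, circular: bool) -> bool:
    rec = SequenceRecord("_probe", seq, "circular" if circular else "linear")
    return bool(find_sites(rec, enzyme))


def _label_destination_fragments(
    frags: list[StickyFragment], enzyme: EnzymeSpec
) -> None:
    site_free = [
        f for f in frags if not _has_recognition(f.core, enzyme, False)
    ]
    if len(site_free) != 1:
        raise AssemblyError(
            "destination vector must digest into exactly one site-free "
            f"backbone fragment (found {len(site_free)})"
        )
    for f in frags:
        f.role = "backbone" if f is site_free[0] else "cassette"


def _label_fdi_fragments(
    frags: list[StickyFragment], record: SequenceRecord
) -> None:
    """Terminal fragments of a digested amplicon (the constant adapter
    scraps) vs the internal insert fragment(s)."""
    n = len(record)
    if len(frags) == 1:
        frags[0].role = "insert"
        return
    for f in frags:
        p = f.provenance[0]
        if p.start == 0 or p.end >= n:
            f.role = "adapter_scrap"
        else:
            f.role = "insert"


def _insert_chain_info(
    frags: list[StickyFragment],
) -> dict[str, tuple[tuple[tuple[int, int], ...], str]]:
    """Per-FDI expected insert architecture: the ordered provenance
    intervals of its insert fragments."""
    info: dict[str, list[tuple[int, int]]] = {}
    for f in frags:
        if f.role != "insert":
            continue
        p = f.provenance[0]
        info.setdefault(p.source, []).append((p.start, p.end))
    return {
        src: (tuple(sorted(iv)), "+") for src, iv in info.items()
    }


def classify_product(
    product: AssemblyProduct,
    insert_chains: dict,
    destination_id: Optional[str] = None,
) -> AssemblyProduct:
    """Assign a class from the labelled composition.

    desired        backbone + the complete, correctly ordered insert
                   fragment chain of exactly one FDI
    empty_vector   backbone without any FDI material (incl. the re-formed
                   original vector: backbone + cassette)
    cassette_circle  cassette material only
    concatemer     any species used more than once, or several backbones
    chimera        everything else (partial inserts, mixed FDIs, scraps)
    """
    comp = list(product.composition)
    roles = [f.role for f, _ in comp]
    keys = [f.key() for f, _ in comp]
    notes: list[str] = []
    if len(set(keys)) < len(keys) or roles.count("backbone") > 1:
        klass = KLASS_CONCATEMER
    elif "backbone" not in roles:
        if set(roles) <= {"cassette"}:
            klass = KLASS_CASSETTE
        else:
            klass = KLASS_CHIMERA
    else:
        others = [(f, o) for f, o in comp if f.role != "backbone"]
        if not others or all(f.role == "cassette" for f, _ in others):
            klass = KLASS_EMPTY
        elif any(f.role in ("adapter_scrap", "cassette", "derived", None)
                 for f, _ in others):
            klass = KLASS_CHIMERA
        else:
            sources = {f.provenance[0].source for f, _ in others}
            if len(sources) != 1:
                klass = KLASS_CHIMERA
                notes.append("fragments from more than one FDI")
            else:
                src = sources.pop()
                expected = insert_chains.get(src, ((), "+"))[0]
                # Normalize so the backbone reads forward, then the insert
                # fragments must appear as the complete expected chain in
                # source order and a single orientation.
                bidx = roles.index("backbone")
                rot = comp[bidx:] + comp[:bidx]
                if rot[0][1] == "-":
                    rot = [
                        (f, "-" if o == "+" else "+") for f, o in
                        reversed(rot)
                    ]
                    rot = rot[-1:] + rot[:-1]  # keep backbone first
                chain = [(f.provenance[0].start, f.provenance[0].end, o)
                         for f, o in rot[1:]]
                fwd = tuple((s, e) for s, e, o in chain)
                orients = {o for _, _, o in chain}
                # Desired means the complete chain, in source order, every
                # piece forward relative to the backbone (directional
                # cloning); anything else is a mis-join.
                if orients == {"+"} and fwd == expected:
                    klass = KLASS_DESIRED
                else:
                    klass = KLASS_CHIMERA
                    notes.append(
                        "insert fragments mis-ordered or incomplete "
                        "(junction collision)"
                    )
    product.klass = klass
    product.notes = tuple(notes)
    return product


def _redigest_product(
    product: AssemblyProduct, enzyme: EnzymeSpec
) -> list[StickyFragment]:
    """Digest a circular product and annotate the released fragments with
    the number of elementary constituents each one fuses (for the unit cap
    in subsequent ligation rounds) and a 'derived' role."""
    frags = digest(product.record, enzyme)
    # Offsets of each constituent's junction-trimmed span in the circle.
    spans = []
    offset = 0
    for f, o in product.composition:
        part = f if o == "+" else f.reverse_complement()
        length = len(part.core) - len(part.left_overhang)
        spans.append((offset, offset + length, f.n_units))
        offset += length
    total = offset
    for frag in frags:
        p = frag.provenance[0]
        units = 0
        for s, e, u in spans:
            # Overlap in circular coordinates (provenance may be unrolled).
            for shift in (0, total):
                if s + shift < p.end and p.start < e + shift:
                    units += u
                    break
        frag.role = "derived"
        frag.n_units = max(1, units)
    return frags


# ---------------------------------------------------------------------------
# One-pot simulation
# ---------------------------------------------------------------------------


def simulate_one_pot(
    reaction: ReactionSpec,
    max_fragments: int = DEFAULT_MAX_FRAGMENTS,
) -> list[AssemblyProduct]:
    """Iterate digest -> ligate to a fixpoint and return the terminal
    circular products, classified.

    Any product still containing a recognition site of the type-IIS enzyme
    is re-digested on the next cycle.  With a low terminal hold (4 C) the
    final step is a ligation: split FDIs may re-ligate into the intact
    insert, and all enumerable circles are collected.  With a 37 C hold the
    final step is a digestion: only site-free circles survive, which
    suppresses re-formed empty vectors.
    """
    dest = reaction.destination
    enzyme = reaction.type_iis_enzyme
    if not reaction.ligase:
        raise UsageError("one-pot simulation requires ligase in the tube")

    pool: list[StickyFragment] = []
    pool_keys: set[tuple] = set()
    total_sites = 0
    for mol in reaction.molecules:
        total_sites += len(find_sites(mol.record, enzyme))
        frags = digest(mol.record, enzyme)
        if mol.is_destination:
            _label_destination_fragments(frags, enzyme)
        else:
            _label_fdi_fragments(frags, mol.record)
        for f in frags:
            if f.key() not in pool_keys:
                pool_keys.add(f.key())
                pool.append(f)
    insert_chains = _insert_chain_info(pool)

    bound = total_sites + 2
    circles: list[AssemblyProduct] = []
    for _iteration in range(bound):
        circles = ligate(pool, max_fragments)
        grew = False
        for prod in circles:
            if not _has_recognition(prod.record.residues, enzyme, True):
                continue
            for f in _redigest_product(prod, enzyme):
                sk = f.struct_key()
                match = next(
                    (g for g in pool if g.struct_key() == sk), None
                )
                if match is None:
                    if f.key() not in pool_keys:
                        pool_keys.add(f.key())
                        pool.append(f)
                        grew = True
        if not grew:
            break
    else:
        cyclic = [p.record.id for p in circles]
        raise AssemblyError(
            f"digestion-ligation fixpoint not reached within {bound} "
            f"iterations; cyclic species: {cyclic}"
        )

    if reaction.program.ligation_hold:
        terminal = list(circles)
    else:
        terminal = [
            p for p in circles
            if not _has_recognition(p.record.residues, enzyme, True)
        ]
    # The same circle may be enumerable both from elementary fragments and
    # from fused re-digestion species; keep one representative per molecule,
    # preferring the fully elementary composition (it classifies exactly).
    by_seq: dict[str, AssemblyProduct] = {}
    for p in terminal:
        derived = sum(1 for f, _ in p.composition if f.role == "derived")
        key = p.canonical_sequence
        best = by_seq.get(key)
        if best is None:
            by_seq[key] = p
        else:
            best_derived = sum(
                1 for f, _ in best.composition if f.role == "derived"
            )
            if (derived, -len(p.composition)) < (
                best_derived, -len(best.composition)
            ):
                by_seq[key] = p
    terminal = list(by_seq.values())
    terminal = [
        classify_product(p, insert_chains, dest.record.id) for p in terminal
    ]
    collisions = [p for p in terminal if p.klass == KLASS_CHIMERA]
    if collisions:
        warnings.warn(
            f"{len(collisions)} chimeric junction-collision product(s) "
            f"enumerable; consider switching vector sets",
            stacklevel=2,
        )
    order = {KLASS_DESIRED: 0, KLASS_EMPTY: 1, KLASS_CASSETTE: 2,
             KLASS_CHIMERA: 3, KLASS_CONCATEMER: 4}
    terminal.sort(key=lambda p: (order.get(p.klass, 9), p.record.id))
    return terminal


@dataclass
class MultiplexCensus:
    """Outcome of a multiplexed one-pot reaction: every terminal product
    plus the desired single-insert construct per FDI."""

    products: list[AssemblyProduct]
    desired_by_insert: dict[str, AssemblyProduct]

    @property
    def n_desired(self) -> int:
        return len(self.desired_by_insert)


def simulate_multiplex(
    reaction: ReactionSpec,
    max_fragments: int = DEFAULT_MAX_FRAGMENTS,
) -> MultiplexCensus:
    """One-pot reaction with k FDIs sharing one adapter pair: the desired
    terminal products are exactly k single-insert constructs (no
    multi-insert stacking is possible, since every insert presents the
    same two overhangs the backbone accepts once)."""
    enzyme = reaction.type_iis_enzyme
    fdis = [m for m in reaction.molecules if not m.is_destination]
    end_pairs = set()
    for m in fdis:
        frags = digest(m.record, enzyme)
        _label_fdi_fragments(frags, m.record)
        inserts = [f for f in frags if f.role == "insert"]
        if not inserts:
            continue
        first = min(inserts, key=lambda f: f.provenance[0].start)
        last = max(inserts, key=lambda f: f.provenance[0].end)
        end_pairs.add(
            (first.left_overhang.sequence, last.right_overhang.sequence)
        )
    if len(end_pairs) > 1:
        raise UsageError(
            f"FDIs carry mismatched adapter sets: {sorted(end_pairs)}"
        )
    products = simulate_one_pot(reaction, max_fragments)
    desired: dict[str, AssemblyProduct] = {}
    for p in products:
        if p.klass != KLASS_DESIRED:
            continue
        src = {
            f.provenance[0].source
            for f, _ in p.composition
            if f.role == "insert"
        }.pop()
        if src in desired:
            raise AssemblyError(
                f"two distinct desired products for insert {src!r}"
            )
        desired[src] = p
    return MultiplexCensus(products, desired)


# ---------------------------------------------------------------------------
# Classical subcloning replay
# ---------------------------------------------------------------------------

Selector = Union[str, int, Callable[[list[StickyFragment]], StickyFragment]]


def _select(frags: list[StickyFragment], rule: Selector) -> list[StickyFragment]:
    if rule == "all":
        return list(frags)
    if rule == "largest":
        return [max(frags, key=len)]
    if rule == "smallest":
        return [min(frags, key=len)]
    if isinstance(rule, int):
        return [frags[rule]]
    if callable(rule):
        picked = rule(frags)
        return list(picked) if isinstance(picked, (list, tuple)) else [picked]
    raise UsageError(f"unknown selection rule {rule!r}")


def _describe_end(ov) -> str:
    if ov.polarity == BLUNT:
        return "blunt"
    return f"{ov.polarity} {ov.sequence}"


def subclone(
    vector: SequenceRecord,
    insert_source: Optional[SequenceRecord],
    enzymes: Sequence[EnzymeSpec],
    keep: Optional[dict] = None,
) -> SequenceRecord:
    """Replay a classical digestion-ligation step: digest both molecules,
    keep the selected fragments (default: largest of the vector, largest of
    the insert source) and return the circular recombinant.

    With ``insert_source=None`` the selected vector fragment self-religates
    (e.g. a deletion between two sites of the same enzyme).
    """
    keep = keep or {}
    vec_frags = [f for f in digest(vector, list(enzymes))
                 if not f.circular_uncut]
    selected = _select(vec_frags, keep.get("vector", "largest"))
    if insert_source is not None:
        ins_frags = [f for f in digest(insert_source, list(enzymes))
                     if not f.circular_uncut]
        selected += _select(ins_frags, keep.get("insert", "largest"))
    circles = ligate(selected, max_fragments=len(selected), allow_blunt=True)
    wanted = [
        c for c in circles
        if {f.key() for f, _ in c.composition}
        == {f.key() for f in selected}
    ]
    if not wanted:
        ends = "; ".join(
            f"{f.provenance[0].source}[{f.provenance[0].start}:"
            f"{f.provenance[0].end}] ends "
            f"({_describe_end(f.left_overhang)}, "
            f"{_describe_end(f.right_overhang)})"
            for f in selected
        )
        raise LigationError(
            f"selected fragments cannot circularize; {ends}"
        )
    wanted.sort(key=lambda c: (len(c.composition), c.record.id))
    return wanted[0].record
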