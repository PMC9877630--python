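import itertools
import warnings
from collections import Counter

import pytest

import goldengate as gg
from goldengate.assembly import (
    Molecule,
    ReactionProgram,
    ReactionSpec,
)
from goldengate.errors import LigationError, UsageError
from goldengate.registry import SyntheticFdiSpec
from goldengate.seq_model import Overhang, StickyFragment

from conftest import dna_without

# ---------------------------------------------------------------------------
# Independent brute-force oracle for circular ligation products.
#
# Written against the raw annealing chemistry, not the package's graph
# search: enumerate every tuple of (fragment, orientation) up to a length
# bound with itertools.product, check every junction by complementing the
# protruding strands by hand, and identify circles by their canonical
# rotated/reflected sequence.
# ---------------------------------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _rc(s):
    return "".join(_COMP[c] for c in reversed(s))


def _ends(frag, orient):
    """(seq, left_len, right_len, left_pol, right_pol) of an oriented
    fragment, computed from first principles."""
    seq = frag.core if orient == "+" else _rc(frag.core)
    if orient == "+":
        lo, ro = frag.left_overhang, frag.right_overhang
    else:
        lo, ro = frag.right_overhang, frag.left_overhang
    return seq, len(lo), len(ro), lo.polarity, ro.polarity


def _junction_ok(a, ao, b, bo, allow_blunt):
    aseq, _, arlen, _, arpol = _ends(a, ao)
    bseq, bllen, _, blpol, _ = _ends(b, bo)
    if arpol != blpol or arlen != bllen:
        return False
    if arpol == "blunt":
        return allow_blunt
    # Both 5' overhangs: a's bottom strand protrudes rc(suffix), b's top
    # strand protrudes its prefix; annealing means the suffix equals the
    # prefix.  The 3' case reduces to the same sequence condition.
    return aseq[-arlen:] == bseq[:bllen]


def _circle_seq(frags_orients):
    out = []
    for frag, orient in frags_orients:
        seq, llen, _, _, _ = _ends(frag, orient)
        out.append(seq[llen:])
    return "".join(out)


def _canon(seq):
    rots = [seq[i:] + seq[:i] for i in range(len(seq))]
    rc = _rc(seq)
    rots += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(rots)


def brute_force_circles(fragments, max_pieces, allow_blunt=False):
    """Canonical sequences of every circular product of <= max_pieces."""
    nodes = [(f, o) for f in fragments for o in ("+", "-")]
    found = set()
    for n in range(1, max_pieces + 1):
        for combo in itertools.product(nodes, repeat=n):
            ok = all(
                _junction_ok(combo[i][0], combo[i][1],
                             combo[(i + 1) % n][0], combo[(i + 1) % n][1],
                             allow_blunt)
                for i in range(n)
            )
            if ok:
                found.add(_canon(_circle_seq(combo)))
    return found


def frag(core, left, right, pol="5p"):
    return StickyFragment(
        core,
        Overhang(left, pol if left else "blunt", "left"),
        Overhang(right, pol if right else "blunt", "right"),
    )


def backbone_insert_pair():
    backbone = frag("GGAT" + "C" * 20 + "GATG", "GGAT", "CATC")
    insert = frag("GATG" + "T" * 12 + "GGAT", "GATG", "ATCC")
    return backbone, insert


class TestLigate:
    def test_unique_complementary_pairing(self):
        backbone, insert = backbone_insert_pair()
        products = gg.ligate([backbone, insert], max_fragments=2)
        assert len(products) == 1
        (p,) = products
        assert len(p.composition) == 2
        # junctions CATC.GATG and GGAT.ATCC, each overhang counted once
        assert len(p) == len(backbone.core) + len(insert.core) - 8

    def test_backbone_alone_cannot_self_religate(self):
        backbone, _ = backbone_insert_pair()
        assert gg.ligate([backbone], max_fragments=2) == []

    def test_palindromic_ends_self_circle_and_dimer(self):
        pal = frag("GATC" + "A" * 10 + "GATC", "GATC", "GATC")
        products = gg.ligate([pal], max_fragments=2)
        got = {p.canonical_sequence for p in products}
        expected = brute_force_circles([pal], 2)
        assert got == expected
        # self-circle and head-to-head dimer are both enumerated (brute
        # force also finds the tandem head-to-tail dimer: with both ends
        # palindromic every junction pairing is legal)
        self_circle = _canon(pal.core[4:])
        head_to_head = _canon(pal.core[4:] + _rc(pal.core)[4:])
        assert self_circle in got
        assert head_to_head in got
        assert len(products) == 3

    def test_max_fragments_below_one_rejected(self):
        with pytest.raises(UsageError):
            gg.ligate([], max_fragments=0)

    def test_linear_dead_ends_discarded(self):
        # incompatible sticky ends: no circle at all
        a = frag("AAAA" + "G" * 10 + "CCCC", "AAAA", "GGGG")
        assert gg.ligate([a], max_fragments=3) == []

    def test_blunt_joins_only_when_allowed(self):
        b = frag("A" * 12, "", "")
        assert gg.ligate([b], max_fragments=1) == []
        assert len(gg.ligate([b], max_fragments=1, allow_blunt=True)) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_oracle_equivalence_random_pools(self, seed, rng):
        rng.seed(seed)
        ovhs = ["GATG", "GGAT", "TCTA", "GATC", "AATT"]
        pool = []
        for i in range(4):
            left = rng.choice(ovhs)
            right = rng.choice(ovhs)
            mid = dna_without(rng, rng.randrange(8, 20))
            core = left + mid + gg.reverse_complement(right)
            pool.append(frag(core, left, right))
        got = {
            p.canonical_sequence
            for p in gg.ligate(pool, max_fragments=4)
        }
        assert got == brute_force_circles(pool, 4)

    def test_oracle_equivalence_six_fragment_pool(self, rng):
        rng.seed(99)
        backbone, insert = backbone_insert_pair()
        pal = frag("GATC" + "AA" + "GATC", "GATC", "GATC")
        extra = frag("TCTA" + "GG" + "GCTC", "TCTA", "GAGC")
        blunt_sticky = frag("GATG" + "CCAA", "GATG", "")
        other = frag("GAGC" + "TT" + "TAGA", "GAGC", "TCTA")
        pool = [backbone, insert, pal, extra, blunt_sticky, other]
        got = {
            p.canonical_sequence for p in gg.ligate(pool, max_fragments=4)
        }
        assert got == brute_force_circles(pool, 4)


def one_pot(entry, vector, fdi_specs, max_fragments=6):
    fdis = [gg.generate_fdi(s) for s in fdi_specs]
    amps = [gg.simulate_pcr(f, gg.design_primers(f, entry.spec)) for f in fdis]
    reaction = gg.plan_reaction(
        fdis, entry.spec, vector_record=vector, amplicons=amps
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fdis, amps, gg.simulate_one_pot(reaction, max_fragments)


class TestSimulateOnePot:
    def test_no_internal_site_warm_hold_no_empty_vectors(
        self, btr1_entry, btr1_vector
    ):
        fdis, amps, products = one_pot(
            btr1_entry, btr1_vector, [SyntheticFdiSpec(600, 0, seed=7)]
        )
        classes = Counter(p.klass for p in products)
        assert classes["desired"] == 1
        assert classes["empty_vector"] == 0
        desired = next(p for p in products if p.klass == "desired")
        # amplicon insert (between the two cuts) present in full
        insert_core = amps[0].residues[11:-11]
        assert insert_core in desired.record.residues * 2
        assert gg.find_sites(desired.record, gg.get_enzyme("BsaI")) == []

    def test_internal_sites_cold_hold_full_insert_restored(
        self, btr2_entry, btr2_vector
    ):
        spec = SyntheticFdiSpec(900, 2, ["ACGT", "TTAC"], seed=11)
        fdis, amps, products = one_pot(btr2_entry, btr2_vector, [spec])
        desired = [p for p in products if p.klass == "desired"]
        assert len(desired) == 1
        insert_core = amps[0].residues[11:-11]
        assert insert_core in desired[0].record.residues * 2
        # the two internal junctions are restored: exactly 2 sites remain
        sites = gg.find_sites(desired[0].record, gg.get_enzyme("BsaI"))
        assert len(sites) == 2

    def test_junction_collision_reports_chimeras_and_warns(
        self, btr1_entry, btr1_vector
    ):
        spec = SyntheticFdiSpec(800, 1, ["GATG"], seed=9)
        fdi = gg.generate_fdi(spec)
        amp = gg.simulate_pcr(fdi, gg.design_primers(fdi, btr1_entry.spec))
        reaction = gg.plan_reaction(
            [fdi], btr1_entry.spec, vector_record=btr1_vector, amplicons=[amp]
        )
        with pytest.warns(UserWarning, match="switching vector sets"):
            products = gg.simulate_one_pot(reaction)
        assert any(p.klass == "chimera" for p in products)

    def test_missing_destination_is_usage_error(self, plain_fdi):
        reaction = ReactionSpec(
            [Molecule(plain_fdi, 1.0)], [gg.get_enzyme("BsaI")]
        )
        with pytest.raises(UsageError):
            gg.simulate_one_pot(reaction)

    def test_requires_exactly_one_type_iis(self, btr1_vector, plain_fdi):
        reaction = ReactionSpec(
            [Molecule(btr1_vector, 1.0, True), Molecule(plain_fdi, 1.0)],
            [gg.get_enzyme("HindIII")],
        )
        with pytest.raises(UsageError):
            gg.simulate_one_pot(reaction)

    def test_one_way_property_desired_sites(self, btr1_entry, btr1_vector,
                                            btr2_entry, btr2_vector):
        # site count of the desired product == FDI internal site count
        cases = [
            (btr1_entry, btr1_vector, SyntheticFdiSpec(500, 0, seed=31), 0),
            (btr2_entry, btr2_vector,
             SyntheticFdiSpec(900, 2, ["ACGT", "TTAC"], seed=32), 2),
        ]
        for entry, vector, spec, n_sites in cases:
            _, _, products = one_pot(entry, vector, [spec])
            desired = next(p for p in products if p.klass == "desired")
            assert len(
                gg.find_sites(desired.record, gg.get_enzyme("BsaI"))
            ) == n_sites

    def test_conservation_of_length(self, btr1_entry, btr1_vector):
        _, _, products = one_pot(
            btr1_entry, btr1_vector, [SyntheticFdiSpec(400, 0, seed=41)]
        )
        for p in products:
            total = sum(
                len(f.core) - len(f.left_overhang) for f, _ in p.composition
            )
            assert len(p) == total

    def test_program_presets(self):
        default = ReactionProgram()
        assert default.n_cycles == 10
        assert default.cycle_steps == ((37, 3), (16, 3), (12, 2))
        assert not ReactionProgram(terminal_hold=(37, 10)).ligation_hold
        assert ReactionProgram(terminal_hold=(4, 60)).ligation_hold


class TestMultiplex:
    def test_four_fdis_four_single_insert_constructs(
        self, btr2_entry, btr2_vector
    ):
        specs = [SyntheticFdiSpec(400 + 50 * i, 0, seed=20 + i)
                 for i in range(4)]
        fdis = [gg.generate_fdi(s) for s in specs]
        amps = [
            gg.simulate_pcr(f, gg.design_primers(f, btr2_entry.spec))
            for f in fdis
        ]
        reaction = gg.plan_reaction(
            fdis, btr2_entry.spec, vector_record=btr2_vector, amplicons=amps
        )
        census = gg.simulate_multiplex(reaction)
        assert census.n_desired == 4
        assert set(census.desired_by_insert) == {a.id for a in amps}
        # no single-backbone multi-insert stack exists
        for p in census.products:
            backbones = [f for f, _ in p.composition if f.role == "backbone"]
            inserts = {
                f.provenance[0].source
                for f, _ in p.composition if f.role == "insert"
            }
            if len(backbones) == 1:
                assert len(inserts) <= 1

    def test_single_fdi_degenerate_multiplex(self, btr1_entry, btr1_vector):
        fdi = gg.generate_fdi(SyntheticFdiSpec(500, 0, seed=55))
        amp = gg.simulate_pcr(fdi, gg.design_primers(fdi, btr1_entry.spec))
        reaction = gg.plan_reaction(
            [fdi], btr1_entry.spec, vector_record=btr1_vector, amplicons=[amp]
        )
        census = gg.simulate_multiplex(reaction)
        assert census.n_desired == 1

    def test_zero_fdis_backbone_stays_linear(self, btr1_vector):
        reaction = ReactionSpec(
            [Molecule(btr1_vector, 1.0, True)], [gg.get_enzyme("BsaI")],
            program=ReactionProgram(terminal_hold=(37, 10)),
        )
        census = gg.simulate_multiplex(reaction)
        assert census.n_desired == 0
        assert all(p.klass != "desired" for p in census.products)

    def test_mismatched_adapters_rejected(
        self, btr1_entry, btr2_entry, btr2_vector
    ):
        f1 = gg.generate_fdi(SyntheticFdiSpec(400, 0, seed=61))
        f2 = gg.generate_fdi(SyntheticFdiSpec(450, 0, seed=62))
        a1 = gg.simulate_pcr(f1, gg.design_primers(f1, btr1_entry.spec))
        a2 = gg.simulate_pcr(f2, gg.design_primers(f2, btr2_entry.spec))
        reaction = ReactionSpec(
            [
                Molecule(btr2_vector, 1.0, True),
                Molecule(a1, 1.0),
                Molecule(a2, 1.0),
            ],
            [gg.get_enzyme("BsaI")],
        )
        with pytest.raises(UsageError, match="mismatched adapter"):
            gg.simulate_multiplex(reaction)


class TestSubclone:
    def test_hindiii_religation_deletes_inter_site_arc(self, hindiii, rng):
        body = dna_without(rng, 360, ("AAGCTT",))
        seq = body[:200] + "AAGCTT" + body[200:260] + "AAGCTT" + body[260:]
        toy = gg.SequenceRecord("toy", seq, "circular")
        out = gg.subclone(toy, None, [hindiii], keep={"vector": "largest"})
        assert out.topology == "circular"
        assert len(out) == len(toy) - 66  # 60-nt arc + one 6-nt site

    def test_two_enzyme_insert_swap(self, rng):
        xbai = gg.get_enzyme("XbaI")
        saci = gg.get_enzyme("SacI")
        motifs = ("TCTAGA", "GAGCTC")
        vb = dna_without(rng, 300, motifs)
        vec = gg.SequenceRecord(
            "vec", vb[:150] + "TCTAGA" + vb[150:180] + "GAGCTC" + vb[180:],
            "circular",
        )
        ib = dna_without(rng, 200, motifs)
        src = gg.SequenceRecord(
            "src", ib[:20] + "TCTAGA" + ib[20:150] + "GAGCTC" + ib[150:],
        )
        out = gg.subclone(vec, src, [xbai, saci],
                          keep={"vector": "largest", "insert": "largest"})
        assert out.topology == "circular"
        # vector backbone keeps everything but its 30-nt stuffer arc
        assert len(out) == (300 + 12 - 30 - 6) + (130 + 6)

    def test_blunt_sticky_mismatch_names_the_blunt_end(self, rng):
        pmei = gg.get_enzyme("PmeI")
        psti = gg.get_enzyme("CTGCAG" and "PstI")
        motifs = ("GTTTAAAC", "CTGCAG")
        vb = dna_without(rng, 240, motifs)
        vec = gg.SequenceRecord(
            "vec", vb[:100] + "GTTTAAAC" + vb[100:140] + "CTGCAG" + vb[140:],
            "circular",
        )
        ib = dna_without(rng, 160, motifs)
        # insert cut by PstI on both sides: one end can never match the
        # blunt PmeI end of the vector backbone
        src = gg.SequenceRecord(
            "src", ib[:10] + "CTGCAG" + ib[10:120] + "CTGCAG" + ib[120:],
        )
        with pytest.raises(LigationError, match="blunt"):
            gg.subclone(vec, src, [pmei, psti],
                        keep={"vector": "largest", "insert": "largest"})


class TestReactionConfig:
    def test_round_trip(self, btr1_vector, plain_fdi):
        reaction = ReactionSpec(
            [Molecule(btr1_vector, 1.0, True), Molecule(plain_fdi, 3.0)],
            [gg.get_enzyme("BsaI")],
            program=ReactionProgram(terminal_hold=(4, 60)),
        )
        cfg = reaction.to_config()
        back = ReactionSpec.from_config(
            cfg, {btr1_vector.id: btr1_vector, plain_fdi.id: plain_fdi}
        )
        assert back.destination.record.id == btr1_vector.id
        assert back.program.terminal_hold == (4, 60)
        assert [m.molar_ratio for m in back.molecules] == [1.0, 3.0]

    def test_unknown_record_rejected(self, btr1_vector):
        reaction = ReactionSpec(
            [Molecule(btr1_vector, 1.0, True)], [gg.get_enzyme("BsaI")]
        )
        with pytest.raises(UsageError):
            ReactionSpec.from_config(reaction.to_config(), {})

    def test_nonpositive_ratio_rejected(self, btr1_vector):
        with pytest.raises(UsageError):
            Molecule(btr1_vector, 0.0)
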