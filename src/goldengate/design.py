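"""Adapter-tailed primer design, vector-set selection, reaction planning,
and C-terminal GFP fusion design.

Primer anatomy (15-nt constant adapter + gene-specific region)::

    5'-[protective 4 nt][GGTCTC][spacer N][fusion 4-mer][gene specific 18-28]-3'

The protective bases default to ``CAGT`` and the single spacer to ``A``;
both are configurable (any base is chemically valid).  The fusion 4-mer is
taken verbatim from the vector's registry row, so after PCR and BsaI
digestion the insert's overhangs are the exact reverse complements of the
vector's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Seq import Seq

from .assembly import Molecule, ReactionProgram, ReactionSpec
from .digestion import find_sites, get_enzyme
from .errors import DesignError, UsageError
from .registry import SET_OVERHANGS, VectorSpec, mock_vector
from .seq_model import (
    Feature,
    SequenceRecord,
    is_palindromic,
    reverse_complement,
)

__all__ = [
    "PrimerPair",
    "FusionSpec",
    "SetChoice",
    "design_primers",
    "simulate_pcr",
    "select_vector_set",
    "plan_reaction",
    "build_fusion",
    "translate",
    "LINKER_DNA",
    "LINKER_PEPTIDE",
    "EGFP_CDS",
]

PROTECTIVE_DEFAULT = "CAGT"
SPACER_DEFAULT = "A"
TM_TARGET_DEFAULT = 55.0
GENE_SPECIFIC_MIN = 18
GENE_SPECIFIC_MAX = 28

STOP_CODONS = ("TAA", "TAG", "TGA")

# GGSGGS peptide linker between the FDI and eGFP in fusion constructs.
LINKER_DNA = "GGTGGATCCGGAGGTTCT"
LINKER_PEPTIDE = "GGSGGS"

# Canonical eGFP coding sequence (no stop), used to predict fusion ORFs.
EGFP_CDS = (
    "ATGGTGAGCAAGGGCGAGGAGCTGTTCACCGGGGTGGTGCCCATCCTGGTCGAGCTGGACGGCGAC"
    "GTAAACGGCCACAAGTTCAGCGTGTCCGGCGAGGGCGAGGGCGATGCCACCTACGGCAAGCTGACC"
    "CTGAAGTTCATCTGCACCACCGGCAAGCTGCCCGTGCCCTGGCCCACCCTCGTGACCACCCTGACC"
    "TACGGCGTGCAGTGCTTCAGCCGCTACCCCGACCACATGAAGCAGCACGACTTCTTCAAGTCCGCC"
    "ATGCCCGAAGGCTACGTCCAGGAGCGCACCATCTTCTTCAAGGACGACGGCAACTACAAGACCCGC"
    "GCCGAGGTGAAGTTCGAGGGCGACACCCTGGTGAACCGCATCGAGCTGAAGGGCATCGACTTCAAG"
    "GAGGACGGCAACATCCTGGGGCACAAGCTGGAGTACAACTACAACAGCCACAACGTCTATATCATG"
    "GCCGACAAGCAGAAGAACGGCATCAAGGTGAACTTCAAGATCCGCCACAACATCGAGGACGGCAGC"
    "GTGCAGCTCGCCGACCACTACCAGCAGAACACCCCCATCGGCGACGGCCCCGTGCTGCTGCCCGAC"
    "AACCACTACCTGAGCACCCAGTCCGCCCTGAGCAAAGACCCCAACGAGAAGCGCGATCACATGGTC"
    "CTGCTGGAGTTCGTGACCGCCGCCGGGATCACTCTCGGCATGGACGAGCTGTACAAG"
)


def translate(dna: str) -> str:
    """Translate an in-frame DNA string (standard code, '*' for stops)."""
    if len(dna) % 3:
        raise DesignError("translation input length is not a multiple of 3")
    return str(Seq(dna).translate())


def wallace_tm(seq: str) -> float:
    """Wallace/GC-rule melting-temperature estimate: 2(A+T) + 4(G+C).

    Deliberately simple (no nearest-neighbour thermodynamics); used only to
    pick a gene-specific length inside the allowed 18-28 nt window.
    """
    s = seq.upper()
    return 2.0 * (s.count("A") + s.count("T")) + 4.0 * (
        s.count("G") + s.count("C")
    )


@dataclass(frozen=True)
class Primer:
    protective: str
    spacer: str
    fusion: str
    gene_specific: str

    @property
    def sequence(self) -> str:
        return (
            self.protective + "GGTCTC" + self.spacer + self.fusion
            + self.gene_specific
        )

    @property
    def adapter(self) -> str:
        """The 15-nt constant tail."""
        return self.protective + "GGTCTC" + self.spacer + self.fusion

    @property
    def tm_estimate(self) -> float:
        return wallace_tm(self.gene_specific)


@dataclass(frozen=True)
class PrimerPair:
    forward: Primer
    reverse: Primer
    vector: VectorSpec
    stop_codon_removed: bool = False
    notes: tuple[str, ...] = ()


def _pick_gene_specific(
    candidates: str, tm_target: float
) -> str:
    """Shortest prefix length in 18-28 nt whose Wallace Tm reaches the
    target, else the full 28."""
    for k in range(GENE_SPECIFIC_MIN, GENE_SPECIFIC_MAX + 1):
        if wallace_tm(candidates[:k]) >= tm_target:
            return candidates[:k]
    return candidates[:GENE_SPECIFIC_MAX]


def design_primers(
    fdi: SequenceRecord,
    vector: VectorSpec,
    protective: str = PROTECTIVE_DEFAULT,
    spacer: str = SPACER_DEFAULT,
    tm_target: float = TM_TARGET_DEFAULT,
) -> PrimerPair:
    """Design the adapter-tailed primer pair that clones *fdi* into
    *vector*.

    For subcellular-GFP vectors the FDI must end in a stop codon, which is
    removed before the reverse adapter is appended (C-terminal fusion).
    """
    if len(protective) != 4 or len(spacer) != 1:
        raise UsageError("protective bases must be 4 nt and the spacer 1 nt")
    seq = fdi.residues
    notes: list[str] = []
    stop_removed = False
    if vector.category == "subcellular_GFP":
        if seq[-3:] not in STOP_CODONS:
            raise DesignError(
                f"{fdi.id}: GFP-fusion cloning requires a terminal stop "
                f"codon (found {seq[-3:]!r})"
            )
        seq = seq[:-3]
        stop_removed = True
    if len(seq) < 36:
        raise DesignError(
            f"{fdi.id}: FDI too short to design 18-nt primers on both ends"
        )
    fwd = Primer(protective.upper(), spacer.upper(), vector.fwd_fusion,
                 _pick_gene_specific(seq, tm_target))
    rev = Primer(protective.upper(), spacer.upper(), vector.rev_fusion,
                 _pick_gene_specific(reverse_complement(seq), tm_target))
    if vector.fwd_fusion == "GATG" and seq.startswith("ATG"):
        notes.append(
            "forward fusion GATG carries an ATG adjacent to the insert's "
            "own start codon; the adapter is applied verbatim and the "
            "initiation context is not deduplicated"
        )
    return PrimerPair(fwd, rev, vector, stop_removed, tuple(notes))


def simulate_pcr(template: SequenceRecord, pair: PrimerPair) -> SequenceRecord:
    """The amplicon the designed pair produces on its own template:
    forward tail + template (stop-stripped if the design removed it) +
    reverse-complemented reverse tail."""
    seq = template.residues
    if pair.stop_codon_removed:
        seq = seq[:-3]
    if not seq.startswith(pair.forward.gene_specific):
        raise DesignError(
            "forward primer does not anneal at the template 5' end"
        )
    if not seq.endswith(reverse_complement(pair.reverse.gene_specific)):
        raise DesignError(
            "reverse primer does not anneal at the template 3' end"
        )
    amplicon = (
        pair.forward.adapter + seq + reverse_complement(pair.reverse.adapter)
    )
    # The template termini must not conspire with the constant tails to
    # create extra recognition sites: digestion of such an amplicon is
    # ill-defined (overlapping cut windows) or mis-programmed.
    n_expected = 2 + len(find_sites(SequenceRecord("_t", seq), get_enzyme("BsaI")))
    n_actual = len(find_sites(SequenceRecord("_a", amplicon), get_enzyme("BsaI")))
    if n_actual != n_expected:
        raise DesignError(
            f"{template.id}: adapter/template junction creates "
            f"{n_actual - n_expected:+d} accidental recognition site(s); "
            f"adjust the protective bases or spacer"
        )
    off = len(pair.forward.adapter)
    return SequenceRecord(
        f"{template.id}_amplicon",
        amplicon,
        "linear",
        [Feature("insert", off, off + len(seq), "+")],
    )


# ---------------------------------------------------------------------------
# Vector-set selection
# ---------------------------------------------------------------------------


@dataclass
class SetChoice:
    chosen: Optional[str]
    admissible: list[str]
    internal_overhangs: list[str]
    palindromic_overhangs: list[str]
    notes: list[str] = field(default_factory=list)


def internal_overhangs(fdi: SequenceRecord) -> list[str]:
    """The 4-nt junction overhang produced at each internal BsaI site of
    the FDI (sites whose cut window falls off a linear end are ignored)."""
    bsai = get_enzyme("BsaI")
    out = []
    n = len(fdi)
    for site in find_sites(fdi, bsai):
        if site.strand == "+":
            lo, hi = site.end + 1, site.end + 5
        else:
            lo, hi = site.position - 5, site.position - 1
        if 0 <= lo and hi <= n:
            out.append(fdi.subseq(lo, hi))
    return out


def select_vector_set(
    fdi: SequenceRecord,
    sets: Sequence[str] = ("BTR1", "BTR2"),
) -> SetChoice:
    """Pick a vector set whose junction overhangs do not collide with any
    internal-site overhang of the FDI.

    A set is admissible iff no internal overhang equals (or reverse-
    complements) either set overhang.  The first admissible set is chosen
    (BTR1 by default).  Palindromic internal overhangs are flagged: no set
    switch avoids their self-ligation, only a raised FDI:vector molar
    ratio mitigates it.
    """
    ovhs = internal_overhangs(fdi)
    palindromic = [o for o in ovhs if is_palindromic(o)]
    admissible = []
    notes: list[str] = []
    for s in sets:
        o1, o2 = SET_OVERHANGS[s]
        clash_space = {o1, o2, reverse_complement(o1), reverse_complement(o2)}
        clashes = [o for o in ovhs
                   if o in clash_space or reverse_complement(o) in clash_space]
        if clashes:
            notes.append(
                f"{s} inadmissible: internal overhang(s) "
                f"{sorted(set(clashes))} collide with its junctions"
            )
        else:
            admissible.append(s)
    chosen = admissible[0] if admissible else None
    if chosen is None:
        notes.append(
            "both sets collide with the FDI's internal overhangs; expect "
            "junction-collision chimeras whichever set is used"
        )
    if palindromic:
        notes.append(
            f"palindromic internal overhang(s) {sorted(set(palindromic))} "
            f"can self-ligate regardless of set; raise the FDI:vector molar "
            f"ratio to 3-5:1"
        )
    return SetChoice(chosen, admissible, ovhs, palindromic, notes)


# ---------------------------------------------------------------------------
# Reaction planning
# ---------------------------------------------------------------------------


def plan_reaction(
    fdis: Sequence[SequenceRecord],
    vector: VectorSpec,
    vector_record: Optional[SequenceRecord] = None,
    amplicons: Optional[Sequence[SequenceRecord]] = None,
) -> ReactionSpec:
    """Plan the one-pot reaction for one or more FDIs and a destination
    vector.

    Molar ratio is 1:1 by default and 3:1 (recommended range 3-5:1) when
    any FDI internal site yields a palindromic overhang.  The terminal
    hold is (4 C, 60 min) iff any FDI carries an internal site — so split
    inserts can re-ligate — else (37 C, 10 min) to suppress empty vectors.

    *amplicons* are the adapter-tailed PCR products entering the tube; by
    default they are derived by designing primers against *vector* and
    simulating the PCR.  When *vector_record* is omitted a mock vector of
    the right set is used.
    """
    if not fdis:
        raise UsageError("at least one FDI is required")
    any_internal = False
    any_palindromic = False
    for fdi in fdis:
        ovhs = internal_overhangs(fdi)
        any_internal = any_internal or bool(ovhs)
        any_palindromic = any_palindromic or any(
            is_palindromic(o) for o in ovhs
        )
    hold = (4, 60) if any_internal else (37, 10)
    ratio = 3.0 if any_palindromic else 1.0
    program = ReactionProgram(10, ((37, 3), (16, 3), (12, 2)), hold)
    if vector_record is None:
        vector_record = mock_vector(vector.name)
    if amplicons is None:
        amplicons = [
            simulate_pcr(fdi, design_primers(fdi, vector)) for fdi in fdis
        ]
    molecules = [Molecule(vector_record, 1.0, is_destination=True)]
    molecules += [Molecule(a, ratio) for a in amplicons]
    return ReactionSpec(molecules, [get_enzyme("BsaI")], True, program)


# ---------------------------------------------------------------------------
# GFP fusion design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FusionSpec:
    linker_dna: str = LINKER_DNA
    linker_peptide: str = LINKER_PEPTIDE
    stop_codon_removed: bool = True


def build_fusion(
    fdi_no_stop: SequenceRecord,
    vector: VectorSpec,
    fusion: FusionSpec = FusionSpec(),
) -> SequenceRecord:
    """Predicted C-terminal eGFP fusion ORF: FDI (stop already removed) +
    GGSGGS linker + eGFP + one terminal stop, in frame throughout."""
    if vector.category != "subcellular_GFP":
        raise UsageError(
            f"{vector.name} is not a subcellular-GFP fusion vector"
        )
    seq = fdi_no_stop.residues
    if len(seq) % 3:
        raise DesignError(
            f"{fdi_no_stop.id}: length {len(seq)} is not a multiple of 3 "
            f"(frameshift)"
        )
    if seq[-3:] in STOP_CODONS:
        raise DesignError(
            f"{fdi_no_stop.id}: stop codon must be removed before fusion"
        )
    orf = seq + fusion.linker_dna + EGFP_CDS + "TAA"
    protein = translate(orf)
    if "*" in protein[:-1]:
        raise DesignError(
            "internal stop codon in the fusion ORF; check the reading frame"
        )
    n_fdi_aa = len(seq) // 3
    feats = [
        Feature(fdi_no_stop.id, 0, len(seq), "+"),
        Feature("GGSGGS linker", len(seq), len(seq) + len(fusion.linker_dna),
                "+"),
        Feature("eGFP", len(seq) + len(fusion.linker_dna),
                len(orf) - 3, "+"),
    ]
    rec = SequenceRecord(
        f"{fdi_no_stop.id}_eGFP_fusion", orf, "linear", feats
    )
    assert protein[n_fdi_aa : n_fdi_aa + 6] == fusion.linker_peptide
    return rec
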