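"""Colony-phenotype and restriction-digest screening predictions.

Recombinant screening is structural: a plasmid forms a reddish-pink
colony iff it still carries the intact selection cassette (promoter +
red-fluorescent-protein CDS, either orientation); any plasmid where the
cassette is absent or disrupted gives a white colony.  No quantitative
white:pink ratio is predicted — the wet-lab rates are not desk-scale
quantities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

from .digestion import EnzymeSpec, restriction_map
from .errors import UsageError
from .seq_model import SequenceRecord, reverse_complement

__all__ = ["ColonyPrediction", "BandMatch", "ScreenReport",
           "predict_colony", "screen_by_digest"]

REDDISH_PINK = "reddish_pink"
WHITE = "white"


@dataclass(frozen=True)
class ColonyPrediction:
    color: str
    basis: str
    fluorescence_note: str

    @property
    def is_recombinant_phenotype(self) -> bool:
        return self.color == WHITE


def predict_colony(
    plasmid: SequenceRecord,
    cassette: Union[str, SequenceRecord],
) -> ColonyPrediction:
    """Predict colony colour from the presence of the full-length
    selection cassette (searched on both strands, across the origin)."""
    if not plasmid.is_circular:
        raise UsageError(
            f"{plasmid.id}: colony prediction needs a circular plasmid"
        )
    cas = cassette.residues if isinstance(cassette, SequenceRecord) else (
        cassette.upper()
    )
    if not cas:
        raise UsageError("cassette sequence is empty")
    doubled = plasmid.residues + plasmid.residues
    intact = cas in doubled or reverse_complement(cas) in doubled
    if intact:
        return ColonyPrediction(
            REDDISH_PINK,
            "intact selection cassette present",
            "bright red under green excitation",
        )
    return ColonyPrediction(
        WHITE,
        "selection cassette absent or disrupted",
        "no red fluorescence under green excitation",
    )


@dataclass(frozen=True)
class BandMatch:
    expected: int
    observed: Union[int, None]
    delta: Union[int, None]
    ok: bool


@dataclass
class ScreenReport:
    passed: bool
    bands: list[BandMatch]
    unmatched_observed: list[int]
    tolerance: int

    def as_table(self) -> str:
        lines = ["expected\tobserved\tdelta\tok"]
        for b in self.bands:
            lines.append(
                f"{b.expected}\t{b.observed if b.observed is not None else '-'}"
                f"\t{b.delta if b.delta is not None else '-'}"
                f"\t{'yes' if b.ok else 'NO'}"
            )
        for o in self.unmatched_observed:
            lines.append(f"-\t{o}\t-\tNO")
        lines.append(f"result\t{'PASS' if self.passed else 'FAIL'}")
        return "\n".join(lines)


def screen_by_digest(
    plasmid: SequenceRecord,
    enzymes: Sequence[EnzymeSpec],
    expected: Sequence[int],
    tolerance: int = 0,
) -> ScreenReport:
    """Compare the predicted restriction map of *plasmid* to an expected
    band list, band by band, within +/- *tolerance* nt."""
    if not expected:
        raise UsageError("expected band list must not be empty")
    if any(e <= 0 for e in expected):
        raise UsageError("expected band lengths must be positive")
    observed = restriction_map(plasmid, list(enzymes))
    observed = [o for o in observed if isinstance(o, int)]
    remaining = sorted(observed)
    bands: list[BandMatch] = []
    for want in sorted(expected):
        best = None
        for o in remaining:
            if best is None or abs(o - want) < abs(best - want):
                best = o
        if best is not None and abs(best - want) <= tolerance:
            remaining.remove(best)
            bands.append(BandMatch(want, best, best - want, True))
        else:
            bands.append(
                BandMatch(want, best, None if best is None else best - want,
                          False)
            )
    passed = all(b.ok for b in bands) and not remaining
    return ScreenReport(passed, bands, remaining, tolerance)
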