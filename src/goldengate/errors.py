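"""Exception hierarchy for the toolkit."""


class GoldenGateError(Exception):
    """Base class for all toolkit errors."""


class SequenceError(GoldenGateError):
    """Invalid DNA input (non-IUPAC characters, bad topology, ...)."""


class ParseError(GoldenGateError):
    """Malformed sequence file."""


class DigestError(GoldenGateError):
    """Digestion cannot proceed (ambiguous cut window, overlapping cuts,
    cut window outside a linear molecule)."""


class LigationError(GoldenGateError):
    """Requested ligation is impossible (incompatible ends)."""


class AssemblyError(GoldenGateError):
    """One-pot simulation failed (no fixpoint, bad reaction spec)."""


class DesignError(GoldenGateError):
    """Primer/fusion design precondition violated."""


class UsageError(GoldenGateError):
    """Caller supplied an invalid argument (unknown format, empty list, ...)."""
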