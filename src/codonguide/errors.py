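"""Exception hierarchy for codonguide.

Every user-facing failure mode has its own class so the CLI can map each to a
clear message and a nonzero exit code.
"""


class CodonGuideError(Exception):
    """Base class for all codonguide errors."""


class InvalidSequenceError(CodonGuideError):
    """A sequence contains a character outside the accepted DNA alphabet."""

    def __init__(self, char: str, position: int, context: str = "sequence"):
        self.char = char
        self.position = position
        super().__init__(
            f"invalid character {char!r} at position {position} in {context}"
        )


class NoExonsError(CodonGuideError):
    """The locus contains no uppercase (exonic) characters."""


class CdsMismatchError(CodonGuideError):
    """The exon-derived CDS differs from the user-supplied CDS.

    Signals that the intron-exon structure of the locus (its case encoding)
    does not match the coding sequence and should be checked.
    """

    def __init__(self, index: int):
        self.index = index
        super().__init__(
            "derived CDS does not match the supplied CDS "
            f"(first difference at CDS index {index}); check the intron-exon "
            "case encoding of the locus"
        )


class FrameError(CodonGuideError):
    """A CDS length is not divisible by 3."""


class PositionError(CodonGuideError):
    """A residue position falls outside the protein."""


class GenomeLoadError(CodonGuideError):
    """The genome file exists but could not be parsed as FASTA."""


class MissingGenomeError(GenomeLoadError):
    """The genome file path does not exist."""


class OutputError(CodonGuideError):
    """The report could not be written to the requested path."""


class FixtureError(CodonGuideError):
    """A synthetic-gene construction request is geometrically infeasible."""
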