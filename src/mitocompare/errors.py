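"""Exception hierarchy.

Every failure mode that callers are expected to branch on gets its own
class; gene-order arithmetic silently corrupts if misnamed or duplicated
genes slip through, so naming problems are hard errors, never warnings.
"""


class MitocompareError(Exception):
    """Base class for all package errors."""


class GenomeFormatError(MitocompareError):
    """A GenBank/FASTA record could not be parsed."""


class UnknownGeneError(MitocompareError):
    """A feature label could not be mapped to the canonical vocabulary."""

    def __init__(self, raw_label: str, message: str | None = None):
        self.raw_label = raw_label
        super().__init__(message or f"unknown gene label: {raw_label!r}")


class DuplicateGeneError(MitocompareError):
    """The same canonical gene was annotated more than once."""


class MissingGeneError(MitocompareError):
    """A requested gene is not annotated in the genome/order."""


class BoundsError(MitocompareError):
    """A feature lies outside its genome's sequence."""


class IncomparableOrdersError(MitocompareError):
    """Two gene orders do not share enough genes to be compared."""


class UnclassifiableOrderError(MitocompareError):
    """A gene order lacks the diagnostic genes for arrangement typing."""


class NumtSuspectError(MitocompareError):
    """A coding sequence contains internal stop codons (possible nuclear copy)."""

    def __init__(self, positions, message: str | None = None):
        self.positions = list(positions)
        super().__init__(
            message or f"internal stop codon(s) at codon index {self.positions}"
        )


class CorrectionUndefinedError(MitocompareError):
    """A substitution proportion is too large for the Jukes-Cantor correction."""


class FrameError(MitocompareError):
    """Alignment length incompatible with the requested codon frame."""


class SpecError(MitocompareError):
    """A simulation spec is internally inconsistent or infeasible."""
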