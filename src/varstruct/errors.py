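"""Exception hierarchy shared across the toolkit."""


class VarstructError(Exception):
    """Base class for all package errors."""


class InputError(VarstructError):
    """Malformed or unusable user input (files, patterns, variants)."""


class InvalidCodonError(InputError):
    """Codon is not three ACGT bases."""


class BuildMismatchError(InputError):
    """Variant and transcript carry different genome-build labels."""


class NonCodingError(VarstructError):
    """Position does not fall inside the CDS of the transcript.

    ``region`` distinguishes ``"intronic"`` (inside the transcript span but
    between coding exons) from ``"outside"`` (beyond the transcript span).
    """

    def __init__(self, message: str, region: str):
        super().__init__(message)
        self.region = region


class RefMismatchError(InputError):
    """Stated reference base disagrees with the transcript/genome sequence."""

    def __init__(self, message: str, expected: str, given: str):
        super().__init__(message)
        self.expected = expected
        self.given = given


class IndelError(InputError):
    """Only single-nucleotide substitutions are supported."""


class RangeError(VarstructError):
    """Index outside the valid coordinate range."""


class ParseError(InputError):
    """Malformed file content; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


class EmptyStructureError(InputError):
    """PDB input contained no usable ATOM records."""


class MappingFailureError(VarstructError):
    """SEQRES vs ATOM sequences could not be reconciled within budget."""


class UnknownResidueError(VarstructError):
    """Residue identifier not present in the structure."""


class DegenerateGeometryError(VarstructError):
    """Atom centers (near-)coincident; surface partition undefined."""


class IncompleteBackboneError(VarstructError):
    """Residue lacks one of N, CA, C needed for side-chain construction."""


class GrammarError(InputError):
    """Motif pattern not parseable; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"position {position}: {message}")
        self.position = position
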