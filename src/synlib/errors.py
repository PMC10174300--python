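"""Exception hierarchy for synlib."""


class SynlibError(Exception):
    """Base class for all synlib errors."""


class FastaParseError(SynlibError):
    """A FASTA file could not be parsed; message names the offending record."""


class AlphabetError(SynlibError):
    """A sequence contains a character outside the declared alphabet."""

    def __init__(self, message: str, record: str | None = None, position: int | None = None):
        super().__init__(message)
        self.record = record
        self.position = position


class ScaffoldConfigError(SynlibError):
    """A scaffold configuration is missing required keys or malformed."""


class ScaffoldIntegrityError(SynlibError):
    """A scaffold violates its own invariants (e.g. nt does not translate to aa)."""


class ExtractionError(SynlibError):
    """CDR extraction failed; carries the CDR whose anchor could not be matched."""

    def __init__(self, message: str, cdr: str | None = None):
        super().__init__(message)
        self.cdr = cdr


class DesignError(SynlibError):
    """A cassette design is unrealizable (e.g. all residue mass excluded at a position)."""


class CodonTableError(SynlibError):
    """A codon table does not cover a required residue or codon."""


class AssemblyError(SynlibError):
    """A clone could not be assembled (incompatible CDR lengths or residues)."""


class FusionConfigError(SynlibError):
    """Fusion-partner sequences are malformed (e.g. not a multiple of 3)."""


class FixtureSpecError(SynlibError):
    """A synthetic-fixture specification is internally inconsistent."""


class StateError(SynlibError):
    """An operation was applied to an object in the wrong state (e.g. unfused clone)."""
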