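"""Exception hierarchy shared across the package."""


class TrnamodError(Exception):
    """Base class for all package-specific errors."""


class FastaFormatError(TrnamodError):
    """A FASTA record could not be parsed (header or sequence content)."""


class AnticodonNotFoundError(TrnamodError):
    """The anticodon named in a header does not occur in the sequence."""


class AlignmentError(TrnamodError):
    """Invalid read content or alignment outside reference bounds."""


class PileupError(TrnamodError):
    """Inconsistent pileup access (unknown gene, out-of-range position)."""


class QuantError(TrnamodError):
    """Invalid LC-MS nucleoside table (missing canonicals, bad areas)."""


class TableError(TrnamodError):
    """Malformed expression / Cq / codon table input."""
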