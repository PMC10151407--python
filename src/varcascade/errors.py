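"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError (and any
reference/parse problem encountered while reading data) -> 3.
"""


class VarCascadeError(Exception):
    """Base class for all package errors."""


class ParseError(VarCascadeError):
    """Malformed input text (GFF line, HGVS string, catalog row)."""


class ModelError(VarCascadeError):
    """Inconsistent gene model (e.g. CDS outside the exon union)."""


class ReferenceMismatchError(VarCascadeError):
    """A stated reference allele disagrees with the attached sequence."""


class OutOfRangeError(VarCascadeError):
    """Position outside the transcript span plus flank window."""


class ConfigError(VarCascadeError):
    """Invalid run configuration (missing sample, bad path, bad threshold)."""


class DataError(VarCascadeError):
    """Invalid data values (e.g. zero depth with a non-missing genotype)."""
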