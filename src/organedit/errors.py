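"""Exception hierarchy shared across the pipeline."""


class OrganeditError(Exception):
    """Base class for all package-specific errors."""


class FormatError(OrganeditError):
    """A file does not follow the expected dialect (FASTA/tbl/VCF/TSV)."""


class RangeError(OrganeditError):
    """A coordinate lies outside the genome."""


class DataError(OrganeditError):
    """Inconsistent data content (conflicting alleles, impossible depths...)."""


class PreconditionError(OrganeditError):
    """An operation's stated precondition was violated by the caller."""


class ConfigError(OrganeditError):
    """Invalid or infeasible configuration."""
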