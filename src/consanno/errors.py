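"""Exception hierarchy."""


class ConsannoError(Exception):
    """Base class for all package errors."""


class Gff3ParseError(ConsannoError):
    """Malformed GFF3 content (bad coordinates, missing columns, ...)."""


class StructuralError(ConsannoError):
    """GFF3 parsed, but the gene/transcript/CDS hierarchy is inconsistent."""


class ConfigError(ConsannoError):
    """Invalid run configuration (CLI exit code 2)."""


class DataError(ConsannoError):
    """Invalid input data discovered at run time (CLI exit code 3)."""
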