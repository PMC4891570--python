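"""Exception hierarchy."""


class RefstabError(Exception):
    """Base class for all refstab errors."""


class FormatError(RefstabError, ValueError):
    """Malformed input file: missing columns, duplicate labels, unparseable cells."""


class DataError(RefstabError, ValueError):
    """Input violates a precondition of an analysis (too few genes/samples,
    nonpositive quantities, incomplete matrix, ...)."""
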