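"""Exception types shared across the package."""


class ScreenhitError(Exception):
    """Base class for all package errors."""


class InputError(ScreenhitError):
    """Invalid or empty input data."""


class ConfigurationError(ScreenhitError):
    """Unresolvable configuration, e.g. a missing column mapping."""


class FastqParseError(InputError):
    """Malformed FASTQ record; message names the file and record index."""


class DegenerateSplitError(InputError):
    """An expression split cannot produce two admissible groups."""
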