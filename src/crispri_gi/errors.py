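"""Exception hierarchy for the screen-analysis pipeline."""


class CrisprGiError(Exception):
    """Base class for all pipeline errors."""


class FormatError(CrisprGiError):
    """A malformed input table: duplicate ids, bad cells, missing columns."""


class DataError(CrisprGiError):
    """Structurally valid input that cannot be analysed (e.g. a sample with
    zero total reads, or a background with no surviving control guides)."""


class ResourceError(CrisprGiError):
    """A computation whose exact form would exceed a configured budget."""
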