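"""Exception hierarchy for vocabrank.

All package-raised errors derive from :class:`VocabRankError` so callers can
catch one type at the pipeline boundary.
"""


class VocabRankError(Exception):
    """Base class for all vocabrank errors."""


class FormatError(VocabRankError):
    """A file or table is structurally malformed (e.g. a missing column)."""


class ValidationError(VocabRankError):
    """Data is structurally fine but violates a domain invariant."""
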