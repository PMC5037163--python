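"""Exception hierarchy for the colocalization toolkit."""


class EmcolocError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EmcolocError):
    """Malformed input table or image (missing column, bad label, out-of-window row)."""


class ResultsError(EmcolocError):
    """Invalid results object (e.g. nothing to write)."""


class UndefinedCoefficientError(EmcolocError):
    """A coefficient's average has no defined terms (every image was excluded)."""


class ResourceGuardError(EmcolocError):
    """A simulation request would generate an unreasonable number of points."""
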