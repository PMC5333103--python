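"""Exception hierarchy for netprio.

``NetworkParseError`` covers malformed input files (always carries the
offending line number when one exists); ``DataError`` covers inputs that
parse but violate a domain contract (empty disease sets, out-of-range
confidence scores passed programmatically, and so on).
"""


class NetprioError(Exception):
    """Base class for all netprio errors."""


class NetworkParseError(NetprioError):
    """A text input file could not be parsed.

    Parameters
    ----------
    message : str
        Human-readable description of the problem.
    path : str, optional
        File being parsed.
    line : int, optional
        1-based line number of the offending line.
    """

    def __init__(self, message, path=None, line=None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += str(path)
        if line is not None:
            prefix += f":{line}"
        if prefix:
            message = f"{prefix}: {message}"
        super().__init__(message)


class DataError(NetprioError):
    """Input parsed correctly but violates a domain precondition."""
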