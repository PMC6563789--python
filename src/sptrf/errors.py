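"""Exception hierarchy shared across the package."""


class SptrfError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SptrfError, ValueError):
    """Malformed external file content (FASTA, CSV)."""


class NameParseError(SptrfError, ValueError):
    """Sequence id does not follow the <S|C|M><animal>-<pattern>-<variant> dialect."""


class IntegrityError(SptrfError, ValueError):
    """Table-level consistency violation (duplicate keys, missing reference rows)."""


class ContractError(SptrfError, ValueError):
    """Caller violated a documented precondition."""


class SaturationError(SptrfError, ArithmeticError):
    """Observed mismatch fraction at or beyond 0.75: no finite Jukes-Cantor distance."""


class LowConfidenceError(SptrfError, ValueError):
    """Refusing to align sequences whose element decomposition is low-confidence."""
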