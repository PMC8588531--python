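"""Exception hierarchy shared across the toolkit."""


class M2HSNError(Exception):
    """Base class for all toolkit errors."""


class FormatError(M2HSNError):
    """Malformed input file (non-monotone wavelengths, ragged rows, bad header)."""


class UnsupportedDialectError(FormatError):
    """A file variant outside the supported subset (e.g. BIP interleave)."""


class DimensionError(M2HSNError):
    """Mismatched grids, shapes or vector lengths."""


class SizeError(M2HSNError):
    """A requested size is impossible (M > N, splits exceed the scene, ...)."""


class DegenerateGridError(M2HSNError):
    """An operation would leave an empty wavelength grid."""


class CoverageError(M2HSNError):
    """A target band has no source band within the allowed gap."""


class InputError(M2HSNError):
    """Invalid argument values (zero columns, missing classes, T = 0, ...)."""


class ConditioningError(M2HSNError):
    """A linear system is too ill-conditioned to solve meaningfully."""


class BudgetError(M2HSNError):
    """A combinatorial search exceeded its instance-size budget."""
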