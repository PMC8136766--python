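"""Exception hierarchy for the ccmorph pipeline.

Every error raised by the library derives from :class:`CCMorphError` so
callers can catch pipeline failures with a single except clause while the
CLI maps data errors vs. config errors onto distinct exit codes.
"""


class CCMorphError(Exception):
    """Base class for all ccmorph errors."""


# --- curve / mask errors -------------------------------------------------

class NoForegroundError(CCMorphError):
    """Mask contains no foreground pixels."""


class MultipleComponentsError(CCMorphError):
    """Mask contains more than one 4-connected foreground component."""

    def __init__(self, n_components: int):
        self.n_components = n_components
        super().__init__(f"expected 1 foreground component, found {n_components}")


class BorderTouchError(CCMorphError):
    """Foreground component touches the image border."""


class DegenerateCurveError(CCMorphError):
    """Polygon has (numerically) zero area."""


class InvalidCurveError(CCMorphError):
    """Curve violates a basic invariant (e.g. fewer than 3 points)."""


class EmptyCohortError(CCMorphError):
    """An operation requiring at least one curve received none."""


class TooFewPointsError(CCMorphError):
    """Down-sampling would leave fewer than 3 points."""


class ParseError(CCMorphError):
    """Malformed curve file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# --- registration errors -------------------------------------------------

class InvalidKernelError(CCMorphError):
    """Kernel width must be strictly positive."""


class NumericalBlowupError(CCMorphError):
    """Flow integration produced non-finite positions."""

    def __init__(self, timestep: int):
        self.timestep = timestep
        super().__init__(f"non-finite positions at timestep {timestep}")


class OptimizationError(CCMorphError):
    """Line search failed at the very first iteration."""


# --- statistics errors ---------------------------------------------------

class SingularDesignError(CCMorphError):
    """Design matrix is rank deficient; names the collinear columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"rank-deficient design; collinear columns: {self.columns}")


class TooFewPermutationsError(CCMorphError):
    """Permutation test requires at least 100 permutations."""


class InvalidGroupingError(CCMorphError):
    """Group variable must contain both levels."""


class LengthMismatchError(CCMorphError):
    """Up-sampling with factor 1 requires matching lengths."""


class UndefinedErrorMetric(CCMorphError):
    """Overall-error denominator is zero."""


# --- evaluation errors ---------------------------------------------------

class OutOfBoundsError(CCMorphError):
    """Curve does not fit inside the rasterization grid."""


class ShapeMismatchError(CCMorphError):
    """Two masks have different shapes."""


# --- synthetic-data errors -----------------------------------------------

class InvalidParamsError(CCMorphError):
    """Generator parameters produce an invalid (e.g. self-intersecting) shape."""


class ConfigError(CCMorphError):
    """Invalid pipeline configuration (CLI exit code 2)."""
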