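"""Typed exceptions and warning categories used across the package."""


class KinmarkError(Exception):
    """Base class for all package-specific errors."""


class InvalidCountsError(KinmarkError, ValueError):
    """A pair-count summary violates its invariants (negative counts, m > n_J, ...)."""


class ZeroPairsError(KinmarkError):
    """A required parent-offspring pair count is zero, so the estimator is undefined.

    Attributes
    ----------
    which : tuple of str
        Names of the offending counts, e.g. ``("m_FC",)`` or ``("m_FC", "m_MC")``.
    """

    def __init__(self, which: tuple[str, ...]):
        self.which = tuple(which)
        super().__init__(
            f"population size cannot be estimated: zero pair count(s) {', '.join(self.which)}"
        )


class InvalidPedigreeError(KinmarkError, ValueError):
    """A parent reference does not resolve, or a juvenile lacks parent identifiers."""


class DegenerateBootstrapError(KinmarkError):
    """Too few bootstrap resamples yielded a defined estimate for interval estimation."""


class InsufficientReplicatesError(KinmarkError):
    """No Monte Carlo replicate was estimable; a summary cannot be formed."""


class InsufficientLociError(KinmarkError, ValueError):
    """Parentage assignment refused: no (or too few) loci available for comparison."""


class AmbiguityWarning(UserWarning):
    """A juvenile had multiple non-excluded candidate parents of the same sex."""
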