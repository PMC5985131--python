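"""Exception hierarchy.

Every error raised by the package derives from :class:`FetalicaError` so
callers can catch the whole family with one clause.  Validation problems
(bad shapes, non-finite values, out-of-range parameters) raise
:class:`ValidationError`; numerical degeneracies inside the ICA iteration
have their own subclasses so the caller can distinguish "your input is
wrong" from "the iteration hit a singular point and may be retried".
"""

from __future__ import annotations


class FetalicaError(Exception):
    """Base class for all package errors."""


class ValidationError(FetalicaError, ValueError):
    """Input violates a documented precondition or invariant."""


class FormatError(FetalicaError, ValueError):
    """Unrecognised or unsupported file format."""


class RankDeficiencyError(ValidationError):
    """Covariance eigenvalue below the floor — channels are linearly dependent."""


class SingularJacobianError(FetalicaError, ArithmeticError):
    """The scalar Jacobian of the fixed-point residual is numerically zero."""


class DegenerateUpdateError(FetalicaError, ArithmeticError):
    """A weight-vector update produced a (near-)zero vector before normalisation."""


class SelectionError(FetalicaError, RuntimeError):
    """No component/channel satisfied a physiological selection rule.

    Carries per-candidate diagnostics in :attr:`diagnostics`.
    """

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics if diagnostics is not None else []


class ExtractionError(FetalicaError, RuntimeError):
    """Deflation failed part-way; ``partial`` lists the recovered components."""

    def __init__(self, message: str, partial=None):
        super().__init__(message)
        self.partial = partial if partial is not None else []


class StageError(FetalicaError, RuntimeError):
    """A pipeline stage failed; ``stage`` names it, ``__cause__`` holds the original."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
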