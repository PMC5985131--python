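"""Fixed-point ICA core: centring, PCA whitening, FastICA updates, and the
overrelaxation-accelerated variant.

The separation model is the classic noiseless ICA model ``X = A S`` with
statistically independent, non-Gaussian sources ``S``.  After centring and
whitening, a single source is recovered as ``y = w^T z`` by driving ``w``
to a maximum of non-Gaussianity measured through the negentropy proxy
``J(y) ≈ (E{G(y)} − E{G(ν)})²`` with the quartic contrast ``G(y) = y⁴/4``,
i.e. nonlinearity ``g(y) = y³``.  Stationary points satisfy the
Kuhn–Tucker condition

    F(w) = E{z g(w^T z)} − β w = 0,   β = E{w^T z · g(w^T z)},

and the approximated Newton iteration on ``F`` simplifies (because the
data are white) to the familiar fixed-point update

    w ← E{z g(w^T z)} − E{g'(w^T z)} w,   w ← w / ‖w‖.

The accelerated variant damps the sensitivity of this iteration to the
random initial vector by an overrelaxation factor ``α ∈ (1, 2)`` chosen by
a grid search over ``α_k = 1 + k/N`` that minimises the residual norm of
the overrelaxed Newton step (see :func:`select_overrelaxation`), followed
by a two-stage predictor/corrector update (:func:`improved_update`).

All expectations are sample means over the full sample; the sample
covariance uses the 1/n convention so that whitening is exact for the
statistics the updates consume.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    DegenerateUpdateError,
    ExtractionError,
    RankDeficiencyError,
    SingularJacobianError,
    ValidationError,
)

__all__ = [
    "MultichannelRecording",
    "WhiteningModel",
    "IcaConfig",
    "SeparationResult",
    "center",
    "whiten",
    "contrast_g",
    "residual_and_jacobian",
    "conventional_update",
    "select_overrelaxation",
    "improved_update",
    "extract_component",
    "extract_all",
]

#: Relative floor under which a covariance eigenvalue is treated as zero.
EIGENVALUE_FLOOR_REL = 1e-10

#: Attempts to re-randomise a failing initial vector before giving up.
RERANDOMIZE_BUDGET = 5


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class MultichannelRecording:
    """A channels × samples signal matrix with its sampling rate.

    Parameters
    ----------
    data
        Real matrix of shape ``(n_channels, n_samples)``.
    fs
        Sampling rate in Hz, > 0.
    labels
        Channel names; generated as ``ch0 .. chN-1`` when omitted.
    """

    data: np.ndarray
    fs: float
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("recording data must be 2-D (channels × samples)")
        n_ch, n_s = self.data.shape
        if n_ch < 1:
            raise ValidationError("recording needs at least one channel")
        if n_s <= n_ch:
            raise ValidationError(
                f"n_samples ({n_s}) must exceed n_channels ({n_ch})"
            )
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("recording contains non-finite values")
        if not self.labels:
            self.labels = [f"ch{i}" for i in range(n_ch)]
        if len(self.labels) != n_ch:
            raise ValidationError("number of labels must match number of channels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass
class WhiteningModel:
    """PCA whitening parameters: ``z = transform @ (x − mean)``.

    ``E`` holds orthonormal covariance eigenvectors (columns), ``D`` the
    matching positive eigenvalues, and ``transform`` the composed
    whitening matrix ``E D^{-1/2} E^T``.
    """

    mean: np.ndarray
    E: np.ndarray
    D: np.ndarray
    transform: np.ndarray

    def apply(self, x: np.ndarray) -> np.ndarray:
        return self.transform @ (np.asarray(x, float) - self.mean[:, None])


@dataclass
class IcaConfig:
    """Knobs of the fixed-point iteration.

    eps is the convergence tolerance on the (sign-invariant) distance
    between successive unit vectors; alpha_grid_N sets the overrelaxation
    grid ``1 + k/N, k = 1..N−1``; ``update_sign`` switches the sign
    convention of the two-stage update between the one consistent with
    the conventional fixed point (``standard_minus``) and the literal
    plus-sign form (``printed_plus``).
    """

    nonlinearity: str = "cubic"
    eps: float = 1e-4
    max_iter: int = 1000
    alpha_grid_N: int = 100
    method: str = "improved"
    seed: int = 0
    update_sign: str = "standard_minus"
    realpha_each_iter: bool = False

    def __post_init__(self):
        if self.nonlinearity != "cubic":
            raise ValidationError("only the cubic nonlinearity g(y)=y^3 is supported")
        if not (0.0 < self.eps < 1.0):
            raise ValidationError(f"eps must lie in (0, 1), got {self.eps}")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.alpha_grid_N < 2:
            raise ValidationError("alpha_grid_N must be >= 2")
        if self.method not in ("conventional", "improved"):
            raise ValidationError(f"unknown method {self.method!r}")
        if self.update_sign not in ("standard_minus", "printed_plus"):
            raise ValidationError(f"unknown update_sign {self.update_sign!r}")

    def replace(self, **kw) -> "IcaConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SeparationResult:
    """Outcome of deflationary extraction.

    Rows of ``W`` are unit-norm unmixing vectors in whitened space
    (mutually orthogonal), ``Y = W @ Z`` the separated sources,
    ``iterations``/``converged``/``alpha_used`` the per-component
    iteration counts, convergence flags and overrelaxation factors
    (``alpha_used`` is NaN for the conventional method).
    """

    W: np.ndarray
    Y: np.ndarray
    iterations: list[int]
    converged: list[bool]
    alpha_used: list[float]

    @property
    def total_iterations(self) -> int:
        return int(sum(self.iterations))

    @property
    def n_components(self) -> int:
        return self.W.shape[0]


# ---------------------------------------------------------------------------
# Centring and whitening
# ---------------------------------------------------------------------------


def center(recording) -> tuple[np.ndarray, np.ndarray]:
    """Remove the per-channel mean.

    Accepts a :class:`MultichannelRecording` or a plain channels × samples
    array; returns ``(centered, mean)`` where ``mean`` is the per-channel
    mean vector needed for the inverse transform.
    """
    x = recording.data if isinstance(recording, MultichannelRecording) else np.asarray(
        recording, dtype=float
    )
    if x.ndim != 2:
        raise ValidationError("expected a channels × samples matrix")
    if not np.all(np.isfinite(x)):
        raise ValidationError("input contains non-finite values")
    mean = x.mean(axis=1)
    return x - mean[:, None], mean


def whiten(
    centered: np.ndarray,
    mean: np.ndarray | None = None,
    eigenvalue_floor_rel: float = EIGENVALUE_FLOOR_REL,
) -> tuple[np.ndarray, WhiteningModel]:
    """PCA-whiten zero-mean data: ``Z = E D^{-1/2} E^T X̄``.

    The sample covariance (1/n convention) is eigendecomposed into
    orthonormal eigenvectors ``E`` and eigenvalues ``D``; the returned
    ``Z`` has sample covariance exactly the identity.  ``mean`` is stored
    in the model for bookkeeping (zeros when not given).

    Raises
    ------
    RankDeficiencyError
        If any eigenvalue falls below ``eigenvalue_floor_rel`` times the
        largest one, i.e. the channels are linearly dependent.
    """
    x = np.asarray(centered, dtype=float)
    if x.ndim != 2:
        raise ValidationError("expected a channels × samples matrix")
    n_ch, n_s = x.shape
    row_means = np.abs(x.mean(axis=1))
    scale = max(np.abs(x).max(), 1.0)
    if np.any(row_means > 1e-8 * scale):
        raise ValidationError("whiten() requires zero-mean rows; call center() first")
    cov = (x @ x.T) / n_s
    d, e = np.linalg.eigh(cov)
    order = np.argsort(d)[::-1]
    d, e = d[order], e[:, order]
    floor = eigenvalue_floor_rel * d[0]
    n_bad = int(np.sum(d <= floor))
    if n_bad:
        raise RankDeficiencyError(
            f"covariance is rank deficient: {n_bad} of {n_ch} channels are "
            f"linearly dependent (eigenvalue floor {floor:.3e})"
        )
    transform = (e * (d ** -0.5)) @ e.T  # E D^{-1/2} E^T
    z = transform @ x
    model = WhiteningModel(
        mean=np.zeros(n_ch) if mean is None else np.asarray(mean, float),
        E=e,
        D=d,
        transform=transform,
    )
    return z, model


# ---------------------------------------------------------------------------
# Contrast and fixed-point residual
# ---------------------------------------------------------------------------


def contrast_g(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cubic nonlinearity: returns ``(g(u), g'(u)) = (u³, 3u²)`` elementwise."""
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValidationError("contrast input contains non-finite values")
    return u**3, 3.0 * u**2


def residual_and_jacobian(
    w: np.ndarray, Z: np.ndarray, *, check_norm: bool = True
) -> tuple[np.ndarray, float]:
    """Kuhn–Tucker residual ``F(w)`` and scalar approximate Jacobian.

    ``F = E{z g(w^T z)} − β w`` with ``β = E{w^T z · g(w^T z)}``; the full
    Jacobian ``E{z z^T g'} − β I`` is approximated for white data by the
    scalar diagonal ``jf = E{g'(w^T z)} − β``.

    Raises :class:`SingularJacobianError` when ``|jf| < 1e-12`` (the
    caller may re-randomise ``w``).
    """
    w = np.asarray(w, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if check_norm and abs(np.linalg.norm(w) - 1.0) > 1e-6:
        raise ValidationError("residual_and_jacobian expects a unit-norm w")
    s = w @ Z
    g, gp = contrast_g(s)
    beta = float(np.mean(s * g))
    F = Z @ g / Z.shape[1] - beta * w
    jf = float(np.mean(gp)) - beta
    if abs(jf) < 1e-12:
        raise SingularJacobianError(
            f"approximate Jacobian {jf:.3e} is numerically singular"
        )
    return F, jf


# ---------------------------------------------------------------------------
# Updates
# ---------------------------------------------------------------------------


def _normalize(v: np.ndarray, context: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if not np.isfinite(n) or n < 1e-12:
        raise DegenerateUpdateError(f"{context}: update vector has near-zero norm")
    return v / n


def conventional_update(w: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """One simplified fixed-point step: ``w⁺ ∝ E{z g(w^T z)} − E{g'(w^T z)} w``."""
    w = np.asarray(w, dtype=float)
    s = w @ Z
    g, gp = contrast_g(s)
    w_new = Z @ g / Z.shape[1] - float(np.mean(gp)) * w
    return _normalize(w_new, "conventional_update")


def select_overrelaxation(w: np.ndarray, Z: np.ndarray, N: int = 100) -> float:
    """Grid search for the overrelaxation factor ``α ∈ (1, 2)``.

    Candidates are ``α_k = 1 + k/N`` for ``k = 1..N−1``.  With the Newton
    direction ``Δw = F(w)/jf``, a candidate is admissible when it strictly
    decreases the residual, ``‖F(w − α_k Δw)‖² < ‖F(w)‖²``; among the
    admissible candidates the one minimising ``TF = ‖F(w − α_k Δw)‖`` is
    returned.  If no candidate is admissible (e.g. ``w`` is already a
    fixed point) the plain Newton step ``α = 1`` is returned; a residual
    norm already at floating-point noise (< 1e-12) short-circuits to 1
    for the same reason.

    The residual at each trial point is re-evaluated in full (β refreshed
    at the trial point).
    """
    F0, jf = residual_and_jacobian(w, Z)
    dw = F0 / jf
    f0_sq = float(F0 @ F0)
    if f0_sq < 1e-24:  # already at a fixed point: any decrease is fp noise
        return 1.0
    best_alpha = 1.0
    best_tf = np.inf
    for k in range(1, N):
        alpha_k = 1.0 + k / N
        wt = w - alpha_k * dw
        s = wt @ Z
        g = s**3
        beta = float(np.mean(s * g))
        Ft = Z @ g / Z.shape[1] - beta * wt
        ft_sq = float(Ft @ Ft)
        if ft_sq < f0_sq and ft_sq < best_tf**2:
            best_tf = np.sqrt(ft_sq)
            best_alpha = alpha_k
    return best_alpha


def improved_update(
    w: np.ndarray,
    Z: np.ndarray,
    alpha: float,
    update_sign: str = "standard_minus",
) -> np.ndarray:
    """Two-stage overrelaxed fixed-point step.

    Stage 1 (predictor) applies the overrelaxation factor to the weight
    term; stage 2 (corrector) repeats the step with the derivative
    expectation re-evaluated at the predicted direction::

        w'  = E{z g(w^T z)} ∓ α E{g'(w^T z)} w
        w'' = E{z g(w^T z)} ∓ E{g'(w'^T z)} w
        w⁺  = w'' / ‖w''‖

    ``update_sign='standard_minus'`` (default) uses the minus sign of the
    conventional fixed point; ``'printed_plus'`` uses plus throughout.
    The predictor is renormalised before the corrector evaluates
    ``g'(w'^T z)``: the corrector coefficient is a second-moment
    statistic of the projection, and only the predicted *direction* is
    meaningful (its raw norm would otherwise scale the coefficient
    quadratically and stall the iteration at spiky sources).
    """
    if not (1.0 <= alpha < 2.0):
        raise ValidationError(f"alpha must lie in [1, 2), got {alpha}")
    sign = -1.0 if update_sign == "standard_minus" else 1.0
    w = np.asarray(w, dtype=float)
    n = Z.shape[1]
    s = w @ Z
    g, gp = contrast_g(s)
    m1 = Z @ g / n  # E{z g(w^T z)}, shared by both stages
    w_pred = _normalize(m1 + sign * alpha * float(np.mean(gp)) * w, "improved_update/predictor")
    _, gp_pred = contrast_g(w_pred @ Z)
    w_corr = m1 + sign * float(np.mean(gp_pred)) * w
    return _normalize(w_corr, "improved_update")


# ---------------------------------------------------------------------------
# Deflationary extraction
# ---------------------------------------------------------------------------


def _orthogonalize(w: np.ndarray, basis: np.ndarray | None) -> np.ndarray:
    """Gram–Schmidt against accepted rows, then renormalise."""
    if basis is not None and len(basis):
        w = w - basis.T @ (basis @ w)
    return _normalize(w, "deflation orthogonalization")


def extract_component(
    Z: np.ndarray,
    w0: np.ndarray,
    config: IcaConfig,
    constraints: np.ndarray | None = None,
) -> tuple[np.ndarray, int, bool, float]:
    """Iterate the configured update from ``w0`` until convergence.

    Convergence is sign-invariant: the loop stops once
    ``min(‖w⁺−w‖, ‖w⁺+w‖) < eps`` (fixed points of the iteration are
    defined up to sign).  For ``method='improved'`` the overrelaxation
    factor is selected once from ``w0`` before iterating, or at every
    iteration when ``config.realpha_each_iter`` is set.  ``constraints``
    (rows of previously accepted components) are projected out after
    every update.

    Returns ``(w, n_iter, converged, alpha_used)``; ``alpha_used`` is NaN
    for the conventional method.  Hitting ``max_iter`` returns
    ``converged=False`` rather than raising.
    """
    w = _orthogonalize(np.asarray(w0, dtype=float), constraints)
    alpha = float("nan")
    if config.method == "improved":
        alpha = select_overrelaxation(w, Z, config.alpha_grid_N)
    n_iter = 0
    converged = False
    for _ in range(config.max_iter):
        if config.method == "improved":
            if config.realpha_each_iter and n_iter > 0:
                alpha = select_overrelaxation(w, Z, config.alpha_grid_N)
            w_new = improved_update(w, Z, alpha, config.update_sign)
        else:
            w_new = conventional_update(w, Z)
        w_new = _orthogonalize(w_new, constraints)
        n_iter += 1
        delta = min(np.linalg.norm(w_new - w), np.linalg.norm(w_new + w))
        w = w_new
        if delta < config.eps:
            converged = True
            break
    return w, n_iter, converged, alpha


def extract_all(
    Z: np.ndarray, n_components: int, config: IcaConfig
) -> SeparationResult:
    """Deflationary FastICA: extract ``n_components`` sources in turn.

    Each component starts from a fresh random unit vector drawn from the
    seeded generator; degenerate updates or singular Jacobians trigger a
    re-randomised restart (up to 5 per component).  Accepted directions
    are kept mutually orthogonal by Gram–Schmidt inside the iteration.
    """
    Z = np.asarray(Z, dtype=float)
    d = Z.shape[0]
    if not (1 <= n_components <= d):
        raise ValidationError(
            f"n_components must lie in [1, {d}], got {n_components}"
        )
    rng = np.random.default_rng(config.seed)
    rows: list[np.ndarray] = []
    iterations: list[int] = []
    converged: list[bool] = []
    alphas: list[float] = []
    for idx in range(n_components):
        basis = np.array(rows) if rows else None
        last_err: Exception | None = None
        for _attempt in range(RERANDOMIZE_BUDGET):
            w0 = rng.standard_normal(d)
            try:
                w, n_iter, ok, alpha = extract_component(Z, w0, config, basis)
            except (DegenerateUpdateError, SingularJacobianError) as err:
                last_err = err
                continue
            rows.append(w)
            iterations.append(n_iter)
            converged.append(ok)
            alphas.append(alpha)
            break
        else:
            raise ExtractionError(
                f"component {idx} failed after {RERANDOMIZE_BUDGET} restarts "
                f"({last_err}); recovered {len(rows)} of {n_components} components",
                partial=rows,
            )
    W = np.array(rows)
    return SeparationResult(
        W=W, Y=W @ Z, iterations=iterations, converged=converged, alpha_used=alphas
    )
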