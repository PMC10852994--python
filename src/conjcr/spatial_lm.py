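"""Spatially varying linear models fitted independently at every lattice point.

For each study condition the data at pixel ``s`` follow ``Y(s) = X b(s) + e(s)``
with a design matrix shared across pixels.  The fit produces the contrast
estimate field, its standard-error field, the CLT rate ``tau_n = n**-0.5``
and the decorrelated residual stack consumed by the wild t-bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .fields import GridSpec, ScalarField

__all__ = ["ConditionModel", "SpatialLMFit", "fit_spatial_lm", "standardised_field"]


@dataclass(frozen=True)
class ConditionModel:
    """Responses, design and contrast for one study condition.

    Parameters
    ----------
    responses
        Array of shape ``(n, *grid.shape)``: n response images.
    design
        ``(n, p)`` design matrix, full column rank with ``n > p``.
    contrast
        ``(p,)`` contrast vector defining the target function ``L'b(s)``.
    covariance
        ``None`` selects the i.i.d. (OLS) error model, in which the
        observation covariance at each pixel is ``sigma^2(s) I`` with
        ``sigma^2(s)`` estimated from the residuals.  Alternatively an
        explicit ``(n, n)`` plug-in covariance matrix may be supplied and is
        used, unscaled, for GLS estimation at every pixel.
    """

    responses: np.ndarray
    design: np.ndarray
    contrast: np.ndarray
    covariance: np.ndarray | None = None

    def __post_init__(self) -> None:
        y = np.asarray(self.responses)
        x = np.asarray(self.design, dtype=np.float64)
        l = np.atleast_1d(np.asarray(self.contrast, dtype=np.float64))
        if x.ndim != 2:
            raise ValueError("design must be a 2-D (n, p) matrix")
        n, p = x.shape
        if y.ndim < 2 or y.shape[0] != n:
            raise ValueError("responses must have shape (n, *grid); first axis must match the design")
        if l.shape != (p,):
            raise ValueError(f"contrast must have shape ({p},)")
        if n <= p:
            raise ValueError("need more observations than design columns")
        if np.linalg.matrix_rank(x) < p:
            raise ValueError("design matrix is rank deficient")
        if self.covariance is not None:
            cov = np.asarray(self.covariance, dtype=np.float64)
            if cov.shape != (n, n):
                raise ValueError(f"covariance must have shape ({n}, {n})")
            object.__setattr__(self, "covariance", cov)
        object.__setattr__(self, "responses", y)
        object.__setattr__(self, "design", x)
        object.__setattr__(self, "contrast", l)

    @property
    def n_obs(self) -> int:
        return self.design.shape[0]

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.responses.shape[1:])


@dataclass(frozen=True)
class SpatialLMFit:
    """Per-pixel contrast estimate, standard error and decorrelated residuals.

    ``se`` is the contrast standard-error field; ``sigma`` is the same field
    rescaled by ``tau_n**-1`` and matches the scaling field of the
    standardised map (for an intercept-only OLS fit it is simply the sample
    standard deviation).  ``residuals`` holds the n decorrelated residual
    fields, i.e. raw residuals whitened by the (estimated) observation
    covariance.
    """

    mu_hat: ScalarField
    se: ScalarField
    tau_n: float
    residuals: np.ndarray = field(repr=False)
    n_obs: int

    def __post_init__(self) -> None:
        if self.residuals.shape[0] != self.n_obs:
            raise ValueError("residual stack must have one layer per observation")
        if np.any(self.se.values <= 0):
            raise ValueError("standard errors must be strictly positive")

    @property
    def sigma(self) -> ScalarField:
        """Scaling field of the standardised map: ``se / tau_n``."""
        return ScalarField(self.se.values / self.tau_n, self.se.grid)

    @property
    def grid(self) -> GridSpec:
        return self.mu_hat.grid


def fit_spatial_lm(model: ConditionModel) -> SpatialLMFit:
    """Fit the spatially varying linear model at every pixel.

    Under the OLS error model (the default), the estimator at each pixel is
    ``b = (X'X)^-1 X'Y`` with residual variance ``sigma^2 = RSS / (n - p)``
    (unbiased convention), contrast standard error
    ``sigma * sqrt(L'(X'X)^-1 L)`` and decorrelated residuals
    ``(Y - Xb) / sigma``.  With a plug-in covariance ``S``, GLS is used:
    ``b = (X'S^-1 X)^-1 X'S^-1 Y``, the standard error is the constant
    ``sqrt(L'(X'S^-1 X)^-1 L)`` and residuals are whitened by ``S^-1/2``.

    Raises
    ------
    ValueError
        For a rank-deficient design, ``n <= p``, or a pixel with exactly
        zero residual variance (which breaks the standardisation).
    """
    x = model.design
    l = model.contrast
    n, p = x.shape
    y = np.asarray(model.responses, dtype=np.float64)
    grid_shape = y.shape[1:]
    yflat = y.reshape(n, -1)
    tau_n = float(n) ** -0.5

    if model.covariance is None:
        xtx_inv = np.linalg.inv(x.T @ x)
        beta = xtx_inv @ (x.T @ yflat)
        resid = yflat - x @ beta
        sigma2 = np.einsum("ij,ij->j", resid, resid) / (n - p)
        if np.any(sigma2 <= 0):
            raise ValueError("zero residual variance encountered; cannot standardise")
        sigma = np.sqrt(sigma2)
        se = np.sqrt(float(l @ xtx_inv @ l) * sigma2)
        mu = l @ beta
        decorrelated = resid / sigma
    else:
        cov = model.covariance
        # whiten with the inverse symmetric square root of the plug-in covariance
        w = np.asarray(linalg.sqrtm(np.linalg.inv(cov)).real, dtype=np.float64)
        xw = w @ x
        yw = w @ yflat
        xtx_inv = np.linalg.inv(xw.T @ xw)
        beta = xtx_inv @ (xw.T @ yw)
        mu = l @ beta
        se_scalar = float(np.sqrt(l @ xtx_inv @ l))
        se = np.full(yflat.shape[1], se_scalar)
        decorrelated = w @ (yflat - x @ beta)

    return SpatialLMFit(
        mu_hat=ScalarField(mu.reshape(grid_shape)),
        se=ScalarField(se.reshape(grid_shape)),
        tau_n=tau_n,
        residuals=decorrelated.reshape((n,) + grid_shape),
        n_obs=n,
    )


def standardised_field(fit: SpatialLMFit, threshold: float) -> ScalarField:
    """Standardised excursion map ``g = (mu_hat - c) / sigma``.

    ``sigma = se / tau_n``, so ``tau_n**-1 * g`` is the contrast
    t-statistic against the threshold, and the excursion set of ``g`` at
    level 0 equals the excursion set of ``mu_hat`` at level ``c``.
    """
    return ScalarField((fit.mu_hat.values - threshold) * fit.tau_n / fit.se.values, fit.grid)
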