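"""Wild t-bootstrap for the supremum statistic calibrating the confidence regions.

Each bootstrap instance multiplies the decorrelated residual fields by a
shared vector of two-point random multipliers, re-studentises at every
boundary point, takes the minimum over the conditions owning each boundary
segment, and records the largest absolute value over the whole boundary.
The empirical upper quantile of these realisations is the constant used to
threshold the confidence-region masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .excursion_geometry import BoundarySegmentSet

__all__ = [
    "MultiplierSpec",
    "BootstrapRun",
    "EmptyBoundaryError",
    "draw_multipliers",
    "bootstrap_G",
    "bootstrap_H",
    "estimate_quantile",
    "run_wild_bootstrap",
]

_SQRT5 = math.sqrt(5.0)
#: Mammen two-point law: values and probability of the negative value.
MAMMEN_NEGATIVE = -(_SQRT5 - 1.0) / 2.0
MAMMEN_POSITIVE = (_SQRT5 + 1.0) / 2.0
MAMMEN_P_NEGATIVE = (_SQRT5 + 1.0) / (2.0 * _SQRT5)


class EmptyBoundaryError(RuntimeError):
    """The estimated conjunction set has no boundary; the method is inapplicable."""


@dataclass(frozen=True)
class MultiplierSpec:
    """Two-point multiplier law (``rademacher`` or ``mammen``) plus RNG seed."""

    kind: str = "rademacher"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("rademacher", "mammen"):
            raise ValueError(f"unknown multiplier kind {self.kind!r}")


def draw_multipliers(
    spec: MultiplierSpec | str,
    n: int,
    size: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw i.i.d. bootstrap multipliers.

    Returns shape ``(n,)`` or ``(size, n)``.  Rademacher multipliers are
    ±1 with equal probability; Mammen multipliers take the two golden-ratio
    values preserving the first three moments (mean 0, variance 1, third
    moment 1).  Draws are reproducible under a fixed seed / generator.
    """
    if n < 1:
        raise ValueError("need at least one multiplier")
    if isinstance(spec, str):
        spec = MultiplierSpec(spec)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    shape = (n,) if size is None else (int(size), n)
    if spec.kind == "rademacher":
        return rng.integers(0, 2, size=shape).astype(np.float64) * 2.0 - 1.0
    u = rng.random(shape)
    return np.where(u < MAMMEN_P_NEGATIVE, MAMMEN_NEGATIVE, MAMMEN_POSITIVE)


def _t_bootstrap_batch(resid_at_points: np.ndarray, multipliers: np.ndarray) -> np.ndarray:
    """Studentised multiplier sums: (n, P) residuals x (B, n) multipliers -> (B, P)."""
    r = np.asarray(resid_at_points, dtype=np.float64)
    m = np.asarray(multipliers, dtype=np.float64)
    n = r.shape[0]
    if m.shape[-1] != n:
        raise ValueError("multiplier count must equal the number of observations")
    s = m @ r                      # (B, P) sums of r_l * R_l
    q = (m**2) @ (r**2)            # (B, P) sums of (r_l * R_l)^2
    var = (q - s**2 / n) / (n - 1)  # 1/(n-1) sample variance of the multiplied sample
    if np.any(var <= 0):
        raise ValueError("degenerate bootstrap sample: zero standard deviation at a boundary point")
    return s / np.sqrt(n * var)


def bootstrap_G(
    residuals: np.ndarray,
    multipliers: np.ndarray,
    points: list | None = None,
) -> np.ndarray:
    """One (or a batch of) bootstrap noise-field realisations at boundary points.

    At every lattice pixel the bootstrap field is the multiplier sum of the
    decorrelated residuals scaled by ``n**-0.5`` and divided by the standard
    deviation of the multiplied sample at that pixel (t-standardisation).
    The field is then evaluated at sub-pixel boundary points by linear
    interpolation along each point's lattice edge — the same way the
    observed studentised statistic is evaluated there, so the two share the
    interpolation variance profile.

    ``residuals`` is either a stack ``(n, *grid)`` together with ``points``,
    or an ``(n, P)`` matrix of residuals already gathered at lattice
    positions (no interpolation).  ``multipliers`` has shape ``(n,)`` for a
    single bootstrap instance or ``(B, n)`` for a batch.
    """
    r = np.asarray(residuals, dtype=np.float64)
    m = np.atleast_2d(np.asarray(multipliers, dtype=np.float64))
    if points is not None:
        from .excursion_geometry import boundary_edge_arrays

        p, q, w = boundary_edge_arrays(points)
        ndim = p.shape[1]
        rp = r[(slice(None),) + tuple(p[:, d] for d in range(ndim))]
        rq = r[(slice(None),) + tuple(q[:, d] for d in range(ndim))]
        out = (1.0 - w) * _t_bootstrap_batch(rp, m) + w * _t_bootstrap_batch(rq, m)
    else:
        if r.ndim != 2:
            raise ValueError("residuals must be an (n, n_points) matrix when no points are given")
        out = _t_bootstrap_batch(r, m)
    return out[0] if np.asarray(multipliers).ndim == 1 else out


def bootstrap_H(
    g_values: Mapping[int, np.ndarray] | Sequence[np.ndarray],
    segments: BoundarySegmentSet,
) -> float | np.ndarray:
    """Boundary-partitioned supremum statistic of one bootstrap instance.

    For each nonempty boundary segment labelled by a condition subset
    ``phi``, take the pointwise minimum over ``{g_values[i] : i in phi}``,
    then its absolute value, then the maximum over the segment's points;
    return the maximum over segments.  Accepts per-condition value arrays of
    shape ``(P,)`` (returns a float) or ``(B, P)`` (returns shape ``(B,)``).

    Raises
    ------
    EmptyBoundaryError
        If there are no boundary points at all.
    """
    if isinstance(g_values, Mapping):
        values = {int(i): np.asarray(v, dtype=np.float64) for i, v in g_values.items()}
    else:
        values = {i: np.asarray(v, dtype=np.float64) for i, v in enumerate(g_values)}
    if segments.n_points == 0 or not segments.segments:
        raise EmptyBoundaryError("the conjunction boundary is empty")
    batched = next(iter(values.values())).ndim == 2
    best: np.ndarray | None = None
    for phi, idx in segments.segments.items():
        if not idx:
            continue
        sub = np.stack([values[i][..., idx] for i in sorted(phi)])
        seg = np.abs(sub.min(axis=0)).max(axis=-1)
        best = seg if best is None else np.maximum(best, seg)
    if best is None:
        raise EmptyBoundaryError("all boundary segments are empty")
    return best if batched else float(best)


def estimate_quantile(h_samples: np.ndarray, alpha: float) -> float:
    """Upper (1 - alpha) empirical quantile of the bootstrap statistic.

    Returns the ``ceil((1 - alpha) * B)``-th order statistic — the higher
    (conservative) convention rather than an interpolated quantile.
    """
    h = np.asarray(h_samples, dtype=np.float64).ravel()
    b = h.size
    if b < 1:
        raise ValueError("need at least one bootstrap sample")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    # guard against float fuzz in (1 - alpha) * B just below/above an integer
    k = int(math.ceil((1.0 - alpha) * b - 1e-9))
    k = min(max(k, 1), b)
    return float(np.partition(h, k - 1)[k - 1])


@dataclass(frozen=True)
class BootstrapRun:
    """All realisations of the bootstrap statistic plus the estimated quantile."""

    h_samples: np.ndarray = field(repr=False)
    n_boot: int
    alpha: float
    quantile_a: float
    multiplier: str = "rademacher"

    def __post_init__(self) -> None:
        if self.h_samples.shape != (self.n_boot,):
            raise ValueError("h_samples must have one entry per bootstrap instance")
        if np.any(self.h_samples < 0) or self.quantile_a < 0:
            raise ValueError("the bootstrap statistic is non-negative by construction")


def run_wild_bootstrap(
    residual_stacks: Sequence[np.ndarray],
    points: list,
    segments: BoundarySegmentSet,
    n_boot: int = 5000,
    alpha: float = 0.05,
    multiplier: str = "rademacher",
    rng: np.random.Generator | int | None = None,
    signs: Sequence[float] | None = None,
) -> BootstrapRun:
    """Estimate the calibration quantile from ``n_boot`` bootstrap instances.

    ``residual_stacks[i]`` holds condition ``i``'s decorrelated residual
    fields, shape ``(n, *grid)``.  One multiplier vector per bootstrap
    instance is shared across all conditions, preserving the
    cross-condition covariance of the residuals.  ``signs`` optionally
    flips individual conditions' bootstrap fields (negation queries).
    """
    rng = np.random.default_rng(rng)
    stacks = [np.asarray(r, dtype=np.float64) for r in residual_stacks]
    n = stacks[0].shape[0]
    for r in stacks:
        if r.shape != stacks[0].shape:
            raise ValueError("all conditions need residual stacks of identical shape")
    if signs is None:
        signs = np.ones(len(stacks))
    multipliers = draw_multipliers(multiplier, n, size=n_boot, rng=rng)
    g = {i: s * bootstrap_G(r, multipliers, points) for i, (s, r) in enumerate(zip(signs, stacks))}
    h = np.asarray(bootstrap_H(g, segments))
    return BootstrapRun(
        h_samples=h,
        n_boot=int(n_boot),
        alpha=float(alpha),
        quantile_a=estimate_quantile(h, alpha),
        multiplier=multiplier if isinstance(multiplier, str) else multiplier.kind,
    )
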