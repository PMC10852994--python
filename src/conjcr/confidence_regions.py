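"""Nested confidence-region masks for conjunctions, disjunctions and negations.

The upper and lower confidence regions are level sets of the studentised
minimum map at ``+a`` and ``-a``, where ``a`` is the bootstrap quantile.
Disjunction and negation queries are reduced to conjunctions by sign-flipping
the standardised maps and complementing the output masks (De Morgan).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conjunction_bootstrap import BootstrapRun, EmptyBoundaryError, run_wild_bootstrap
from .excursion_geometry import (
    BoundarySegmentSet,
    ExcursionMask,
    extract_zero_boundary,
    min_standardised_field,
    partition_boundary,
)
from .fields import ScalarField, as_values
from .spatial_lm import ConditionModel, SpatialLMFit, fit_spatial_lm, standardised_field

__all__ = [
    "LogicalQuery",
    "CONJUNCTION",
    "DISJUNCTION",
    "ConfidenceRegions",
    "InferenceResult",
    "EmptyConjunctionError",
    "construct_crs",
    "logical_transform",
    "conjunction_inference",
]


class EmptyConjunctionError(RuntimeError):
    """The estimated target set is empty; no confidence regions can be built."""


@dataclass(frozen=True)
class LogicalQuery:
    """Which combination of exceedance statements is being bounded.

    ``kind`` is ``"conjunction"`` (all conditions exceed), ``"disjunction"``
    (at least one exceeds) or ``"custom"``.  ``negate`` optionally flags,
    per condition, that the *non*-exceedance set is meant instead.
    """

    kind: str = "conjunction"
    negate: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("conjunction", "disjunction", "custom"):
            raise ValueError(f"unknown query kind {self.kind!r}")

    def signs(self, n_cond: int) -> np.ndarray:
        """Per-condition sign applied to the standardised maps."""
        negate = self.negate or (False,) * n_cond
        if len(negate) != n_cond:
            raise ValueError("negation pattern length must match the number of conditions")
        signs = np.where(np.asarray(negate, dtype=bool), -1.0, 1.0)
        if self.kind == "disjunction":
            signs = -signs
        return signs

    @property
    def complemented(self) -> bool:
        """Whether output masks are complements of the internal conjunction masks."""
        return self.kind == "disjunction"


CONJUNCTION = LogicalQuery("conjunction")
DISJUNCTION = LogicalQuery("disjunction")


@dataclass(frozen=True)
class ConfidenceRegions:
    """Nested masks bounding the target set with asymptotic probability 1 - alpha.

    ``upper`` is contained in the point estimate, which is contained in
    ``lower``; the nesting is validated at construction.
    """

    upper: ExcursionMask
    point_estimate: ExcursionMask
    lower: ExcursionMask
    a: float | None
    alpha: float | None = None
    query: LogicalQuery = CONJUNCTION

    def __post_init__(self) -> None:
        if self.a is not None and self.a < 0:
            raise ValueError("the quantile a must be non-negative")
        if not (self.upper.issubset(self.point_estimate) and self.point_estimate.issubset(self.lower)):
            raise ValueError("confidence regions must be nested: upper within point estimate within lower")


def construct_crs(
    min_field: ScalarField | np.ndarray,
    tau_n: float,
    a: float,
    alpha: float | None = None,
    query: LogicalQuery = CONJUNCTION,
) -> ConfidenceRegions:
    """Threshold the studentised minimum map at ``+a``, 0 and ``-a``.

    ``min_field`` is the pointwise minimum of the (transformed) standardised
    maps; the studentised statistic is ``min_field / tau_n``.  For a
    complemented (disjunction) query the three masks are complemented and
    upper/lower swap roles.
    """
    if a < 0:
        raise ValueError("a must be non-negative")
    t = as_values(min_field) / tau_n
    upper = ExcursionMask(t >= a)
    point = ExcursionMask(t >= 0.0)
    lower = ExcursionMask(t >= -a)
    if query.complemented:
        upper, lower = lower.complement(), upper.complement()
        point = point.complement()
    return ConfidenceRegions(
        upper=upper, point_estimate=point, lower=lower, a=float(a), alpha=alpha, query=query
    )


def logical_transform(
    fields: list[ScalarField],
    query: LogicalQuery,
) -> list[ScalarField]:
    """Sign-flip standardised maps so the query becomes a plain conjunction.

    Negated conditions have their map negated (``mu >= c`` becomes
    ``mu < c`` up to the lattice boundary convention); a disjunction
    additionally negates every map, and its output masks must then be
    complemented with upper/lower swapped (handled by :func:`construct_crs`).
    """
    signs = query.signs(len(fields))
    shape = as_values(fields[0]).shape
    for f in fields:
        if as_values(f).shape != shape:
            raise ValueError("all fields must share a grid")
    return [ScalarField(s * as_values(f)) for s, f in zip(signs, fields)]


@dataclass(frozen=True)
class InferenceResult:
    """Everything produced by one end-to-end confidence-region run."""

    regions: ConfidenceRegions
    bootstrap: BootstrapRun
    segments: BoundarySegmentSet
    fits: tuple[SpatialLMFit, ...]
    statistic: ScalarField = field(repr=False)
    """Studentised minimum map of the (transformed) standardised fields."""


def conjunction_inference(
    models: list,
    threshold,
    alpha: float = 0.05,
    n_boot: int = 5000,
    multiplier: str = "rademacher",
    seed: np.random.Generator | int | None = None,
    boundary: str = "estimated",
    delta: float | None = None,
    true_fields: list[ScalarField] | None = None,
    query: LogicalQuery | None = None,
) -> InferenceResult:
    """End-to-end confidence regions for a combination of excursion sets.

    Fits the per-condition spatial linear models (or accepts pre-computed
    fits), standardises against the threshold(s), extracts and partitions the
    boundary of the estimated target set, estimates the calibration quantile
    by the wild t-bootstrap, and thresholds the studentised minimum map.
    Deterministic for a fixed seed.

    Parameters
    ----------
    models
        One :class:`ConditionModel` or :class:`SpatialLMFit` per condition;
        all conditions must share the observation count.
    threshold
        Scalar, or one threshold per condition.
    boundary
        ``"estimated"`` (default) extracts the boundary from the fitted
        maps; ``"true"`` uses the supplied noiseless ``true_fields``
        (validation mode).
    delta
        Tolerance for assigning boundary points to shared segments;
        defaults to ``tau_n``, which shrinks at the CLT rate.
    """
    if len(models) == 0:
        raise ValueError("need at least one condition")
    fits = tuple(m if isinstance(m, SpatialLMFit) else fit_spatial_lm(m) for m in models)
    m_cond = len(fits)
    n = fits[0].n_obs
    if any(f.n_obs != n for f in fits):
        raise ValueError("all conditions must share the same number of observations")
    tau_n = fits[0].tau_n

    thresholds = np.broadcast_to(np.asarray(threshold, dtype=np.float64), (m_cond,))
    query = query or CONJUNCTION
    signs = query.signs(m_cond)

    g_fields = [standardised_field(f, c) for f, c in zip(fits, thresholds)]
    g_fields = [ScalarField(s * g.values) for s, g in zip(signs, g_fields)]
    g_min = min_standardised_field(g_fields)
    if not np.any(g_min.values >= 0):
        raise EmptyConjunctionError(
            "the estimated target set is empty; the bootstrap boundary method cannot be applied"
        )

    if boundary == "estimated":
        boundary_fields = g_fields
    elif boundary == "true":
        if true_fields is None:
            raise ValueError('boundary="true" requires the noiseless true fields')
        boundary_fields = [
            ScalarField(s * (as_values(f) - c)) for s, f, c in zip(signs, true_fields, thresholds)
        ]
    else:
        raise ValueError('boundary must be "estimated" or "true"')
    boundary_min = min_standardised_field(boundary_fields)
    points = extract_zero_boundary(boundary_min)
    if not points:
        raise EmptyBoundaryError("the target-set boundary contains no lattice crossings")
    segments = partition_boundary(points, boundary_fields, tau_n if delta is None else delta)

    run = run_wild_bootstrap(
        [f.residuals for f in fits],
        points,
        segments,
        signs=signs,
        n_boot=n_boot,
        alpha=alpha,
        multiplier=multiplier,
        rng=seed,
    )
    regions = construct_crs(g_min, tau_n, run.quantile_a, alpha=alpha, query=query)
    return InferenceResult(
        regions=regions,
        bootstrap=run,
        segments=segments,
        fits=fits,
        statistic=ScalarField(g_min.values / tau_n),
    )
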