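"""Monte-Carlo coverage studies for the conjunction confidence regions.

Reproduces the three synthetic simulation studies at configurable scale:
generate signal-plus-noise data, run the full pipeline, check the nested
inclusion (upper region inside the true conjunction set inside the lower
region) by pixel nesting plus interpolation along the true boundary, and
tabulate empirical coverage with binomial confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .confidence_regions import (
    ConfidenceRegions,
    EmptyConjunctionError,
    InferenceResult,
    LogicalQuery,
    conjunction_inference,
)
from .conjunction_bootstrap import EmptyBoundaryError
from .excursion_geometry import ExcursionMask, extract_zero_boundary, interpolate_at_boundary
from .fields import GridSpec, ScalarField, as_values
from .field_synthesis import NoiseSpec, SignalSpec, generate_noise, make_signal
from .spatial_lm import ConditionModel

__all__ = [
    "SimulationConfig",
    "CoverageResult",
    "simulation_signals",
    "check_inclusion",
    "run_simulation",
    "binomial_ci",
    "naive_intersection_crs",
    "ring_conjunction_signals",
    "run_naive_comparison",
]

HIGH_SNR_MAGNITUDE = 3.0
LOW_SNR_FACTOR = 0.25
HIGH_SNR_THRESHOLD = 2.0
LOW_SNR_THRESHOLD = 0.5
SIGNAL_FWHM = 5.0
NOISE_FWHM = 3.0
RAMP_GRADIENT = 1.0 / 50.0
RAMP_OFFSET = 1.0
SQUARE_SEPARATION = 20.0

#: Default (single representative) sweep value per simulation:
#: circle separation, noise cross-correlation, ramp-gradient divisor.
DEFAULT_SWEEP = {1: 20.0, 2: 0.0, 3: 1.0}
#: Full sweep grids used by the original studies.
FULL_SWEEP = {
    1: tuple(np.arange(0.0, 50.0 + 1e-9, 2.0)),
    2: tuple(np.round(np.arange(-1.0, 1.0 + 1e-9, 0.1), 10)),
    3: tuple(np.round(np.arange(0.25, 1.75 + 1e-9, 0.05), 10)),
}
FULL_N_GRID = tuple(range(40, 501, 20))


def simulation_signals(
    simulation: int,
    snr: str,
    sweep_value: float,
    grid: GridSpec | None = None,
):
    """True signals, threshold and noise correlation for one simulation setting.

    Simulation 1 sweeps the circle separation, simulation 2 the noise
    cross-correlation (square signals at fixed separation), simulation 3 the
    divisor applied to the ramp gradients.  Low-SNR settings scale the
    high-SNR signal by 1/4 and use threshold 1/2 instead of 2.
    """
    if simulation not in (1, 2, 3):
        raise ValueError("simulation must be 1, 2 or 3")
    if snr not in ("high", "low"):
        raise ValueError('snr must be "high" or "low"')
    grid = grid or GridSpec((100, 100))
    rho = 0.0
    if simulation == 1:
        spec = SignalSpec("circle", magnitude=HIGH_SNR_MAGNITUDE, separation=float(sweep_value), smoothing_fwhm=SIGNAL_FWHM)
    elif simulation == 2:
        spec = SignalSpec("square", magnitude=HIGH_SNR_MAGNITUDE, separation=SQUARE_SEPARATION, smoothing_fwhm=SIGNAL_FWHM)
        rho = float(sweep_value)
    else:
        if sweep_value <= 0:
            raise ValueError("the ramp-gradient divisor must be positive")
        spec = SignalSpec("ramp", gradient=RAMP_GRADIENT / float(sweep_value), ramp_offset=RAMP_OFFSET)
    threshold = HIGH_SNR_THRESHOLD
    if snr == "low":
        spec = spec.scaled(LOW_SNR_FACTOR)
        threshold = LOW_SNR_THRESHOLD
    signals = [make_signal(spec, grid, i) for i in range(2)]
    return signals, threshold, rho


@dataclass(frozen=True)
class SimulationConfig:
    """Settings for one coverage study (desk-scaled defaults)."""

    simulation: int = 1
    snr: str = "high"
    n: tuple[int, ...] = (100,)
    sweep: tuple[float, ...] | None = None
    instances: int = 500
    n_boot: int = 1000
    alpha: float = 0.05
    seed: int | None = None
    boundary: str = "estimated"
    multiplier: str = "rademacher"
    delta: float | None = None
    grid: GridSpec = field(default_factory=lambda: GridSpec((100, 100)))
    noise_fwhm: float = NOISE_FWHM
    noise_scale: float = 1.0
    noise_distribution: str = "gaussian"

    def __post_init__(self) -> None:
        if self.instances < 1:
            raise ValueError("need at least one simulation instance")
        object.__setattr__(self, "n", tuple(int(v) for v in np.atleast_1d(self.n)))
        sweep = self.sweep
        if sweep is None:
            sweep = (DEFAULT_SWEEP[self.simulation],)
        object.__setattr__(self, "sweep", tuple(float(v) for v in np.atleast_1d(sweep)))

    def full_scale(self) -> "SimulationConfig":
        """The original study's settings: full sweep and n grids, B = 5000, 2500 instances."""
        return replace(self, sweep=FULL_SWEEP[self.simulation], n=FULL_N_GRID, instances=2500, n_boot=5000)


@dataclass(frozen=True)
class CoverageResult:
    """Per-(sweep, n) empirical coverage with binomial confidence bounds."""

    table: pd.DataFrame
    config: SimulationConfig

    def coverage(self, sweep_value: float, n: int) -> float:
        row = self.table[(self.table["sweep"] == sweep_value) & (self.table["n"] == n)]
        return float(row["coverage"].iloc[0])


def binomial_ci(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation (Wald) binomial interval, clipped to [0, 1]."""
    if trials < 1:
        raise ValueError("need at least one trial")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    p = successes / trials
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    half = z * np.sqrt(p * (1.0 - p) / trials)
    return (max(0.0, p - half), min(1.0, p + half))


def _interpolated_inclusion_ok(
    stat_values: list[np.ndarray],
    a_values: list[float],
) -> bool:
    """Interpolation check along the true boundary.

    At every sub-pixel point of the true boundary the upper region must not
    reach it (``min_i(stat_i - a_i) < 0``, strict) and the lower region must
    still cover it (``min_i(stat_i + a_i) >= 0``).
    """
    over = np.minimum.reduce([sv - av for sv, av in zip(stat_values, a_values)])
    under = np.minimum.reduce([sv + av for sv, av in zip(stat_values, a_values)])
    return bool(np.all(over < 0) and np.all(under >= 0))


def _studentised_at_points(fit, threshold: float, points) -> np.ndarray:
    """Sub-pixel studentised statistic: interpolate the estimate and SE maps
    separately along each edge and form the ratio.

    Interpolating the ratio field directly would leave a spurious residual
    of the (cancelling) deterministic parts whenever the SE differs between
    the two edge pixels — in the noiseless limit the check would then fail
    even though the regions are exact.  Ratio-of-interpolants is exact there.
    """
    mu = interpolate_at_boundary(fit.mu_hat, points)
    se = interpolate_at_boundary(fit.se, points)
    return (mu - threshold) / se


def _true_margin(true_fields: list[ScalarField], threshold) -> np.ndarray:
    thresholds = np.broadcast_to(np.asarray(threshold, dtype=np.float64), (len(true_fields),))
    return np.minimum.reduce([as_values(f) - c for f, c in zip(true_fields, thresholds)])


def _nested_ok(true_mask: np.ndarray, upper: ExcursionMask, lower: ExcursionMask) -> bool:
    return bool(np.all(true_mask | ~upper.inside) and np.all(lower.inside | ~true_mask))


def check_inclusion(
    true_fields: list[ScalarField],
    threshold,
    regions: ConfidenceRegions,
    fits,
    a: float | None = None,
) -> bool:
    """Does the inclusion (upper within true set within lower) hold?

    True iff (i) every upper-region pixel lies in the true conjunction set
    and every true-set pixel lies in the lower region, and (ii) at every
    sub-pixel point of the true boundary (linear interpolation of
    ``min_i mu_i - c`` along lattice edges) the studentised statistic —
    the minimum over conditions of the ratio of the interpolated contrast
    estimate minus the threshold to the interpolated standard error — is
    strictly below ``a`` and at least ``-a``.

    ``fits`` holds the per-condition model fits (e.g.
    ``InferenceResult.fits``) whose estimate and SE maps are interpolated.

    Raises
    ------
    ValueError
        If the true conjunction set is empty.
    """
    margin = _true_margin(true_fields, threshold)
    true_mask = margin >= 0
    if not true_mask.any():
        raise ValueError("the true conjunction set is empty; coverage is undefined")
    a = regions.a if a is None else a
    if not _nested_ok(true_mask, regions.upper, regions.lower):
        return False
    points = extract_zero_boundary(margin)
    if not points:
        return True
    thresholds = np.broadcast_to(np.asarray(threshold, dtype=np.float64), (len(fits),))
    stat = np.minimum.reduce(
        [_studentised_at_points(f, c, points) for f, c in zip(fits, thresholds)]
    )
    return _interpolated_inclusion_ok([stat], [float(a)])


def naive_intersection_crs(regions_list: list[ConfidenceRegions]) -> ConfidenceRegions:
    """Pixelwise intersection of per-condition confidence regions.

    Provided only as a comparator: intersecting separately calibrated
    single-condition regions is *not* a valid conjunction procedure and its
    asymptotic coverage can land anywhere in ``[1 - M * alpha, 1]``.
    """
    if len(regions_list) == 0:
        raise ValueError("need at least one set of regions")
    upper = regions_list[0].upper
    point = regions_list[0].point_estimate
    lower = regions_list[0].lower
    for r in regions_list[1:]:
        if r.upper.inside.shape != upper.inside.shape:
            raise ValueError("all regions must share a grid")
        upper = upper.intersection(r.upper)
        point = point.intersection(r.point_estimate)
        lower = lower.intersection(r.lower)
    return ConfidenceRegions(
        upper=upper,
        point_estimate=point,
        lower=lower,
        a=None,
        alpha=regions_list[0].alpha,
        query=LogicalQuery("custom"),
    )


def _check_naive_inclusion(
    true_fields: list[ScalarField],
    threshold,
    naive: ConfidenceRegions,
    singles: list[InferenceResult],
) -> bool:
    """Inclusion check for intersected per-condition regions.

    The upper check fails only where *all* per-condition statistics exceed
    their own quantiles; the lower check fails where *any* falls below the
    negated quantile.
    """
    margin = _true_margin(true_fields, threshold)
    true_mask = margin >= 0
    if not true_mask.any():
        raise ValueError("the true conjunction set is empty; coverage is undefined")
    if not _nested_ok(true_mask, naive.upper, naive.lower):
        return False
    points = extract_zero_boundary(margin)
    if not points:
        return True
    thresholds = np.broadcast_to(np.asarray(threshold, dtype=np.float64), (len(singles),))
    stat_at_points = [
        _studentised_at_points(s.fits[0], c, points) for s, c in zip(singles, thresholds)
    ]
    a_values = [float(s.regions.a) for s in singles]
    return _interpolated_inclusion_ok(stat_at_points, a_values)


def _intercept_models(
    signals: list[ScalarField],
    threshold: float,
    n: int,
    noise_spec: NoiseSpec,
    rng: np.random.Generator,
    noise_scale: float = 1.0,
) -> list[ConditionModel]:
    """Draw one synthetic instance and wrap it in intercept-only condition models."""
    grid = signals[0].grid
    noise = generate_noise(n, len(signals), grid, noise_spec, rng, dtype=np.float32)
    if noise_scale != 1.0:
        noise *= np.float32(noise_scale)
    design = np.ones((n, 1))
    contrast = np.ones(1)
    return [
        ConditionModel(sig.values[None, ...] + noise[i], design, contrast)
        for i, sig in enumerate(signals)
    ]


def _simulate_instance(
    signals: list[ScalarField],
    threshold: float,
    n: int,
    rho: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> str:
    noise_spec = NoiseSpec(
        fwhm=config.noise_fwhm, cross_correlation=rho, distribution=config.noise_distribution
    )
    models = _intercept_models(signals, threshold, n, noise_spec, rng, config.noise_scale)
    try:
        res = conjunction_inference(
            models,
            threshold,
            alpha=config.alpha,
            n_boot=config.n_boot,
            multiplier=config.multiplier,
            seed=rng,
            boundary=config.boundary,
            delta=config.delta,
            true_fields=signals if config.boundary == "true" else None,
        )
    except (EmptyConjunctionError, EmptyBoundaryError):
        return "empty"
    ok = check_inclusion(signals, threshold, res.regions, res.fits)
    return "success" if ok else "violation"


def run_simulation(config: SimulationConfig, n_jobs: int = 1) -> CoverageResult:
    """Run a full coverage study over the configured sweep and sample-size grids.

    Each instance draws fresh noise, fits intercept-only models per
    condition, runs the conjunction pipeline and records the inclusion
    outcome.  Instances use RNG substreams spawned deterministically from
    the master seed, so results are reproducible and independent of
    ``n_jobs``.  Instances whose estimated target set is empty are recorded
    as the ``empty`` failure category, never dropped.
    """
    master = np.random.SeedSequence(config.seed)
    cells = [(sv, n) for sv in config.sweep for n in config.n]
    children = master.spawn(len(cells) * config.instances)
    rows = []
    for ci, (sweep_value, n) in enumerate(cells):
        signals, threshold, rho = simulation_signals(config.simulation, config.snr, sweep_value, config.grid)
        seeds = children[ci * config.instances : (ci + 1) * config.instances]

        def one(ss):
            return _simulate_instance(signals, threshold, n, rho, config, np.random.default_rng(ss))

        if n_jobs == 1:
            outcomes = [one(ss) for ss in seeds]
        else:
            from joblib import Parallel, delayed

            outcomes = Parallel(n_jobs=n_jobs)(delayed(one)(ss) for ss in seeds)
        successes = sum(o == "success" for o in outcomes)
        empties = sum(o == "empty" for o in outcomes)
        lo, hi = binomial_ci(successes, config.instances)
        rows.append(
            {
                "sweep": sweep_value,
                "n": n,
                "instances": config.instances,
                "successes": successes,
                "violations": config.instances - successes - empties,
                "empty": empties,
                "coverage": successes / config.instances,
                "ci_lo": lo,
                "ci_hi": hi,
            }
        )
    return CoverageResult(table=pd.DataFrame(rows), config=config)


def ring_conjunction_signals(
    grid: GridSpec | None = None,
    threshold: float = 2.0,
    r_inner: float = 30.0,
    r_outer: float = 40.0,
    slope: float = 0.1,
) -> list[ScalarField]:
    """A constructed two-condition setting whose conjunction set is an annulus.

    Condition 0 exceeds the threshold inside radius ``r_outer``; condition 1
    exceeds it outside radius ``r_inner``.  The conjunction boundary then
    consists of two circles, each contributed entirely by a single
    condition, so each condition's whole excursion boundary is
    conjunction-relevant — the configuration in which intersecting
    separately calibrated regions loses the most coverage.
    """
    grid = grid or GridSpec((100, 100))
    ny, nx = grid.shape
    rows, cols = np.mgrid[0:ny, 0:nx].astype(np.float64)
    r = np.hypot(rows - (ny - 1) / 2.0, cols - (nx - 1) / 2.0)
    mu0 = threshold + slope * (r_outer - r)
    mu1 = threshold + slope * (r - r_inner)
    return [ScalarField(mu0, grid), ScalarField(mu1, grid)]


def run_naive_comparison(
    signals: list[ScalarField],
    threshold: float,
    n: int,
    instances: int,
    n_boot: int = 500,
    alpha: float = 0.05,
    seed: int | None = None,
    noise_spec: NoiseSpec | None = None,
) -> pd.DataFrame:
    """Empirical coverage of the joint method versus naive intersection.

    For every instance the same data feed (a) the joint conjunction pipeline
    and (b) per-condition single-field pipelines whose regions are then
    intersected.  Returns one row per method with successes, coverage and
    the binomial confidence interval.
    """
    noise_spec = noise_spec or NoiseSpec(fwhm=NOISE_FWHM)
    children = np.random.SeedSequence(seed).spawn(instances)
    joint_success = 0
    naive_success = 0
    for ss in children:
        rng = np.random.default_rng(ss)
        models = _intercept_models(signals, threshold, n, noise_spec, rng)
        res = conjunction_inference(
            models, threshold, alpha=alpha, n_boot=n_boot, seed=rng
        )
        singles = [
            conjunction_inference([m], threshold, alpha=alpha, n_boot=n_boot, seed=rng)
            for m in models
        ]
        naive = naive_intersection_crs([s.regions for s in singles])
        joint_success += check_inclusion(signals, threshold, res.regions, res.fits)
        naive_success += _check_naive_inclusion(signals, threshold, naive, singles)
    rows = []
    for name, succ in (("joint", joint_success), ("naive", naive_success)):
        lo, hi = binomial_ci(succ, instances)
        rows.append(
            {"method": name, "instances": instances, "successes": succ, "coverage": succ / instances, "ci_lo": lo, "ci_hi": hi}
        )
    return pd.DataFrame(rows)


def plot_coverage(result: CoverageResult, path: str, by: str = "n") -> None:
    """Coverage-versus-n (or sweep) plot with the nominal band; needs matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = result.table
    nominal = 1.0 - result.config.alpha
    fig, ax = plt.subplots(figsize=(6, 4))
    for key, sub in tab.groupby("sweep" if by == "n" else "n"):
        sub = sub.sort_values(by)
        ax.plot(sub[by], sub["coverage"], marker="o", label=f"{'sep' if by == 'n' else 'n'}={key}")
        ax.fill_between(sub[by], sub["ci_lo"], sub["ci_hi"], alpha=0.2)
    ax.axhline(nominal, ls="--", color="k", lw=1)
    ax.set_xlabel(by)
    ax.set_ylabel("empirical coverage")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
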