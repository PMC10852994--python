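# conjcr

Confidence regions for **combinations of excursion sets** in imaging data.

Given `n` observations of `M` spatially aligned response images (one sample
per study condition), `conjcr` builds nested upper/lower confidence masks
that bound — with asymptotic probability `1 − α` — the region where **all**
target functions exceed a threshold `c` (conjunction, `min_i μ_i ≥ c`), or,
via De Morgan transforms, where **at least one** exceeds it (disjunction),
with arbitrary per-condition negation patterns. No assumption is made about
the dependence between conditions.

The pipeline:

1. **Spatial linear model** — at every pixel, fit `Y_i(s) = X_i β_i(s) + ε_i(s)`
   per condition (OLS by default, plug-in GLS hook available), producing the
   contrast estimate `μ̂_i`, its standard error, the CLT rate `τ_n = n^{-1/2}`
   and decorrelated residual fields.
2. **Excursion geometry** — standardise each map, take the pointwise minimum,
   extract the sub-pixel zero boundary by linear interpolation along lattice
   edges, and partition it by which subset of conditions attains the minimum
   (tolerance `δ = τ_n` by default).
3. **Wild t-bootstrap** — multiply residuals by shared Rademacher (or Mammen)
   multipliers, re-studentise per pixel, evaluate along the boundary, take
   `max_φ sup_{∂_φ} |min_{i∈φ} G̃_i|`, and estimate the `(1 − α)` quantile `a`
   from `B` realisations.
4. **Confidence regions** — threshold the studentised minimum map at `±a`
   to obtain masks `upper ⊆ point estimate ⊆ lower`.

A synthetic-data module (circle/square/ramp signals plus smoothed,
optionally cross-correlated or heavy-tailed noise) and a Monte-Carlo
coverage harness reproduce the validation simulations end to end, entirely
offline.

## Python API

```python
import numpy as np
from conjcr import (ConditionModel, GridSpec, NoiseSpec, SignalSpec,
                    conjunction_inference, generate_noise, make_signal)

grid = GridSpec((100, 100))
spec = SignalSpec("circle", magnitude=3.0, separation=20.0, smoothing_fwhm=5.0)
signals = [make_signal(spec, grid, i) for i in range(2)]
noise = generate_noise(200, 2, grid, NoiseSpec(fwhm=3.0), rng=0)

models = [ConditionModel(sig.values[None] + noise[i], np.ones((200, 1)), np.ones(1))
          for i, sig in enumerate(signals)]
res = conjunction_inference(models, threshold=2.0, alpha=0.05, n_boot=5000, seed=1)
res.regions.upper, res.regions.point_estimate, res.regions.lower  # nested masks
res.regions.a                                                     # bootstrap quantile
```

Disjunction / negation queries: pass `query=DISJUNCTION` or
`LogicalQuery("conjunction", negate=(False, True))`.

## Command line

```sh
conjcr simulate-data --signal circle --n 60 --snr high --seed 1 --out data/
conjcr fit  --responses data/condition0 --threshold 2.0 --out fit/
conjcr crs  --responses data/condition0 data/condition1 \
            --threshold 2.0 --alpha 0.05 --boot 5000 --seed 1 --out crs/
conjcr simulate --sim 1 --snr high --n 100 --instances 500 --boot 1000 \
            --seed 1 --out sim/        # add --full for the original scale
```

Images are plain-text grids by default (`--format nifti` for NIfTI).
`conjcr crs` writes the three masks, an optional bootstrap-sample CSV and a
JSON sidecar with `a`, `α`, `B`, seed, multiplier, query and per-segment
boundary point counts.

## Conventions worth knowing

- Condition indices are 0-based throughout; boundary segment labels are
  `frozenset`s of condition indices.
- Exact zeros count as *inside* every excursion set (closed-set convention).
- The boundary is 4-neighbour lattice edges only; each crossing is located
  by linear interpolation and carries a weight `w = f(p)/(f(p) − f(q))`.
- The bootstrap field is studentised per pixel and then interpolated to the
  boundary, matching how the observed studentised statistic is evaluated.
- `FWHM = 2 sqrt(2 ln 2) · σ` converts smoothing widths; noise is generated
  on a padded grid, smoothed, cropped, and rescaled to unit pointwise
  variance.
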