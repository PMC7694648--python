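"""Flux uncertainty: chi-square cutoffs, profile-likelihood confidence
intervals, 2-D confidence-region rasters, and Monte-Carlo sampling.

A candidate flux vector is statistically acceptable when its SSR stays
below SSR_min + chi2(alpha, df).  Profiling a single flux — stepping it
away from the best fit while re-optimizing all other free fluxes until the
SSR crosses the cutoff — yields its confidence interval; scanning the SSR
over a 2-D grid of two free fluxes yields the confidence region used to
compare tracers.  Per-flux profiles and the default 2-D region both use
df = 1, so with a perfect fit the acceptance rule reduces to SSR <= 3.84
at the 95% level; the conventional df = 2 region is available via a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .fit import FitResult
from .model import ModelError

__all__ = [
    "chi2_cutoff",
    "ConfidenceInterval",
    "ConfidenceRegion",
    "profile_ci",
    "region_grid",
    "mc_sample",
]


def chi2_cutoff(alpha: float, df: int) -> float:
    """alpha quantile of the chi-square distribution with df degrees of freedom."""
    if not 0 < alpha < 1:
        raise ModelError(f"alpha must lie in (0, 1), got {alpha}")
    if df < 1:
        raise ModelError(f"df must be >= 1, got {df}")
    return float(stats.chi2.ppf(alpha, df))


@dataclass(frozen=True)
class ConfidenceInterval:
    flux_id: str
    level: float
    lower: float
    upper: float
    best: float
    hit_lower_bound: bool = False
    hit_upper_bound: bool = False


@dataclass
class ConfidenceRegion:
    x_id: str
    y_id: str
    x_values: np.ndarray
    y_values: np.ndarray
    ssr: np.ndarray  # shape (len(y), len(x))
    threshold: float

    @property
    def mask(self) -> np.ndarray:
        return self.ssr <= self.threshold


def _profiled_ssr(fit: FitResult, k: int, value: float, warm: np.ndarray) -> tuple[float, np.ndarray]:
    """Minimum SSR with free flux k pinned at ``value`` (others re-optimized)."""
    pred = fit.predictor
    lb = np.array([b[0] for b in pred.free_spec.bounds])
    ub = np.array([b[1] for b in pred.free_spec.bounds])
    others = [j for j in range(len(fit.free_ids)) if j != k]
    if not others:
        x = np.array([value])
        return pred.ssr_at(x, fit.measurements), x

    def residuals(u):
        x = np.empty(len(fit.free_ids))
        x[k] = value
        x[others] = u
        return pred.residuals(x, fit.measurements)

    u0 = np.clip(warm[others], lb[others], ub[others])
    res = least_squares(residuals, u0, bounds=(lb[others], ub[others]), method="trf",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
    x = np.empty(len(fit.free_ids))
    x[k] = value
    x[others] = res.x
    return float(2 * res.cost), x


def profile_ci(fit: FitResult, flux_id: str, alpha: float = 0.95) -> ConfidenceInterval:
    """Profile-likelihood confidence interval for one free flux.

    Walks the target flux away from its best-fit value with a doubling
    step (initially 1% of the best value), re-optimizing all other free
    fluxes at each point, until the profiled SSR crosses
    SSR_min + chi2(alpha, df=1); the crossing is then located by bisection
    to 3 significant figures.  Profiles that reach an optimization bound
    before crossing set the corresponding flag instead of erroring.
    """
    if flux_id not in fit.free_ids:
        raise ModelError(f"{flux_id!r} is not a free flux ({fit.free_ids})")
    k = fit.free_ids.index(flux_id)
    cutoff = fit.ssr + chi2_cutoff(alpha, df=1)
    best = float(fit.free_values[k])
    lo_bound, hi_bound = fit.predictor.free_spec.bounds[k]

    def crossing(direction: int) -> tuple[float, bool]:
        step = 0.01 * abs(best) if best != 0 else 1.0
        warm = np.asarray(fit.free_values, dtype=float).copy()
        inner, s_inner = best, fit.ssr
        while True:
            value = inner + direction * step
            hit = False
            if direction < 0 and value <= lo_bound:
                value, hit = lo_bound, True
            elif direction > 0 and value >= hi_bound:
                value, hit = hi_bound, True
            s, warm = _profiled_ssr(fit, k, value, warm)
            if s >= cutoff:
                break
            inner, s_inner = value, s
            if hit:
                return value, True
            step *= 2.0
        outer = value
        # bisect between inner (below cutoff) and outer (at/above cutoff)
        while abs(outer - inner) > max(1e-3 * abs(outer), 1e-9):
            mid = 0.5 * (inner + outer)
            s, warm = _profiled_ssr(fit, k, mid, warm)
            if s >= cutoff:
                outer = mid
            else:
                inner = mid
        return 0.5 * (inner + outer), False

    lower, hit_lo = crossing(-1)
    upper, hit_hi = crossing(+1)
    return ConfidenceInterval(
        flux_id=flux_id, level=alpha, lower=lower, upper=upper, best=best,
        hit_lower_bound=hit_lo, hit_upper_bound=hit_hi,
    )


def region_grid(
    fit: FitResult,
    flux_pair: tuple[str, str],
    ranges: tuple[tuple[float, float], tuple[float, float]],
    resolution: int | tuple[int, int] = 100,
    alpha: float = 0.95,
    df: int = 1,
) -> ConfidenceRegion:
    """SSR raster over two free fluxes with chi-square acceptance mask.

    Any additional free fluxes are re-optimized at every grid cell.  The
    default threshold follows the df = 1 convention (pass ``df=2`` for the
    conventional joint region).  An empty acceptance region warns rather
    than raising.
    """
    x_id, y_id = flux_pair
    for fid in (x_id, y_id):
        if fid not in fit.free_ids:
            raise ModelError(f"{fid!r} is not a free flux ({fit.free_ids})")
    kx = fit.free_ids.index(x_id)
    ky = fit.free_ids.index(y_id)
    if kx == ky:
        raise ModelError("flux_pair must name two distinct free fluxes")
    if isinstance(resolution, int):
        resolution = (resolution, resolution)
    xs = np.linspace(ranges[0][0], ranges[0][1], resolution[0])
    ys = np.linspace(ranges[1][0], ranges[1][1], resolution[1])
    others = [j for j in range(len(fit.free_ids)) if j not in (kx, ky)]
    pred = fit.predictor
    lb = np.array([b[0] for b in pred.free_spec.bounds])
    ub = np.array([b[1] for b in pred.free_spec.bounds])
    grid = np.empty((len(ys), len(xs)))
    warm = np.asarray(fit.free_values, dtype=float).copy()
    x = warm.copy()
    for iy, yv in enumerate(ys):
        for ix, xv in enumerate(xs):
            x[kx], x[ky] = xv, yv
            if not others:
                grid[iy, ix] = pred.ssr_at(x, fit.measurements)
            else:
                def residuals(u, xv=xv, yv=yv):
                    z = x.copy()
                    z[others] = u
                    return pred.residuals(z, fit.measurements)
                res = least_squares(
                    residuals, np.clip(warm[others], lb[others], ub[others]),
                    bounds=(lb[others], ub[others]), method="trf",
                )
                grid[iy, ix] = float(2 * res.cost)
                warm[others] = res.x
    threshold = fit.ssr + chi2_cutoff(alpha, df)
    region = ConfidenceRegion(
        x_id=x_id, y_id=y_id, x_values=xs, y_values=ys, ssr=grid, threshold=threshold
    )
    if not region.mask.any():
        warnings.warn("confidence region is empty on the supplied grid", stacklevel=2)
    return region


def mc_sample(
    fit: FitResult,
    n_samples: int = 1000,
    seed: int = 0,
    method: str = "metropolis",
    levels: tuple[float, ...] = (0.025, 0.975),
):
    """Monte-Carlo flux uncertainty.

    ``metropolis``: seeded random-walk sampling in free-flux space with
    log-density -SSR/2, Gaussian proposals adapted during burn-in toward
    ~30% acceptance (a warning is issued if the final rate leaves
    [0.05, 0.8]).  ``measurement_perturbation``: repeatedly add Gaussian
    noise (the measurement SDs) to the measured fractions and refit.

    Returns ``(samples, intervals)``: an (n_samples, n_free) array and a
    dict flux_id -> quantile tuple at ``levels``.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    pred = fit.predictor
    nf = len(fit.free_ids)
    lb = np.array([b[0] for b in pred.free_spec.bounds])
    ub = np.array([b[1] for b in pred.free_spec.bounds])

    if method == "metropolis":
        step = 0.05 * np.maximum(np.abs(fit.free_values), 1.0)
        x = np.asarray(fit.free_values, dtype=float).copy()
        logp = -0.5 * fit.ssr
        burn = max(200, n_samples // 4)
        draws = np.empty((n_samples, nf))
        accepted = 0
        proposed = 0
        for i in range(-burn, n_samples):
            prop = x + rng.normal(0.0, step)
            if np.all(prop >= lb) & np.all(prop <= ub):
                lp = -0.5 * pred.ssr_at(prop, fit.measurements)
                proposed += 1
                if np.log(rng.uniform()) < lp - logp:
                    x, logp = prop, lp
                    accepted += 1
            else:
                proposed += 1
            if i < 0:
                if (i + burn + 1) % 50 == 0 and proposed:
                    rate = accepted / proposed
                    step *= np.exp(rate - 0.3)
                    accepted = proposed = 0
            else:
                draws[i] = x
        rate = accepted / proposed if proposed else 0.0
        if not 0.05 <= rate <= 0.8:
            warnings.warn(
                f"Metropolis acceptance rate {rate:.2f} outside [0.05, 0.8]",
                stacklevel=2,
            )
    elif method == "measurement_perturbation":
        from .fit import fit as run_fit
        from .model import Measurement, MeasurementSet

        draws = np.empty((n_samples, nf))
        for i in range(n_samples):
            noisy = MeasurementSet()
            for m in fit.measurements:
                fracs = np.array([f for _, f in m.mids])
                fracs = np.clip(fracs + rng.normal(0.0, m.sds), 0.0, None)
                fracs /= fracs.sum()
                noisy.append(
                    Measurement(
                        emu=m.emu,
                        mids=tuple((mass, fr) for (mass, _), fr in zip(m.mids, fracs)),
                        sds=m.sds,
                        time=m.time,
                    )
                )
            r = run_fit(
                pred.model, noisy, pred.tracer, fixed=pred.free_spec.fixed,
                n_starts=1, seed=int(rng.integers(2**31)),
                x0=fit.free_values,
            )
            draws[i] = r.free_values
    else:
        raise ModelError(f"unknown mc_sample method {method!r}")

    samples = pd.DataFrame(draws, columns=list(fit.free_ids))
    intervals = {
        fid: tuple(float(np.quantile(samples[fid], q)) for q in levels)
        for fid in fit.free_ids
    }
    return samples, intervals
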