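"""Flux estimation from measured MIDs.

The inverse problem is solved as variance-weighted least squares: predict
the measured MIDs from a candidate free-flux vector, form the residuals
(measured - predicted)/SD, and minimize their squared sum (SSR) with
bounded derivative-based local optimization from multiple seeded random
starting points.  The SSR at the optimum is the chi-square statistic used
downstream for confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .emu import EMU, decompose
from .model import (
    FluxState,
    FreeFluxSpec,
    MeasurementSet,
    ModelError,
    NetworkModel,
    TracerSpec,
    derive_free_fluxes,
)
from .simulate import MID, solve_steady

__all__ = ["SteadyStatePredictor", "ssr", "FitResult", "StartRecord", "fit"]

DEFAULT_BOUNDS = (0.0, 1e4)
DEFAULT_N_STARTS = 10
SSR_TIE_TOL = 1e-9
# soft penalty keeping dependent (non-free) fluxes nonnegative during search
_NEG_PENALTY = 1e4


class SteadyStatePredictor:
    """Maps free-flux vectors to predicted MIDs for a fixed set of targets.

    Decomposes the EMU network once; each prediction is then a pair of
    small linear solves, which keeps grid scans and profiles cheap.
    """

    def __init__(
        self,
        model: NetworkModel,
        tracer: TracerSpec,
        targets: list[str],
        free_spec: FreeFluxSpec,
    ):
        self.model = model
        self.tracer = tracer
        self.free_spec = free_spec
        self.target_labels = list(targets)
        self.emunet = decompose(model, self.target_labels)
        self._canonical = {
            label: emu for label, emu in zip(self.target_labels, self.emunet.targets)
        }

    def predict(self, free_values) -> dict[str, MID]:
        full = self.free_spec.full_vector(free_values)
        fluxes = dict(zip(self.free_spec.all_ids, full))
        mids = solve_steady(self.emunet, fluxes, self.tracer)
        return {label: mids[emu] for label, emu in self._canonical.items()}

    def residuals(self, free_values, measurements: MeasurementSet) -> np.ndarray:
        pred = self.predict(free_values)
        res = []
        for m in measurements:
            if m.emu not in pred:
                raise ModelError(f"no prediction available for measured EMU {m.emu}")
            p = pred[m.emu]
            for (mass, frac), sd in zip(m.mids, m.sds):
                if mass >= len(p):
                    raise ModelError(f"{m.emu}: predicted MID has no M+{mass} fraction")
                res.append((frac - p[mass]) / sd)
        # hinge penalty: dependent fluxes must stay nonnegative
        full = self.free_spec.full_vector(free_values)
        for v in full:
            if v < 0:
                res.append(_NEG_PENALTY * (-v))
        return np.asarray(res)

    def ssr_at(self, free_values, measurements: MeasurementSet) -> float:
        return float(np.sum(self.residuals(free_values, measurements) ** 2))


def ssr(predicted: dict[str, MID], measured: MeasurementSet) -> float:
    """Variance-weighted sum of squared residuals with diagonal covariance.

    R = sum over measured fractions of ((measured - predicted) / SD)^2.
    """
    total = 0.0
    for m in measured:
        if m.emu not in predicted:
            raise ModelError(f"no prediction for measured EMU {m.emu}")
        p = predicted[m.emu]
        for (mass, frac), sd in zip(m.mids, m.sds):
            if mass >= len(p):
                raise ModelError(f"{m.emu}: predicted MID has no M+{mass} fraction")
            total += ((frac - p[mass]) / sd) ** 2
    return total


@dataclass(frozen=True)
class StartRecord:
    index: int
    x0: tuple[float, ...]
    x: tuple[float, ...]
    ssr: float
    converged: bool
    message: str = ""


@dataclass
class FitResult:
    free_ids: tuple[str, ...]
    free_values: np.ndarray
    fluxes: FluxState
    ssr: float
    starts: list[StartRecord]
    predictions: dict[str, MID]
    predictor: SteadyStatePredictor = field(repr=False)
    measurements: MeasurementSet = field(repr=False)

    @property
    def n_converged(self) -> int:
        return sum(1 for s in self.starts if s.converged)


def _initial_points(rng: np.random.Generator, n_starts, lb, ub) -> np.ndarray:
    """Log-uniform draws within the bounds (floor tiny lower bounds)."""
    lo = np.log(np.maximum(lb, 1e-2))
    hi = np.log(ub)
    return np.exp(rng.uniform(lo, hi, size=(n_starts, len(lb))))


def fit(
    model: NetworkModel,
    measurements: MeasurementSet,
    tracer: TracerSpec,
    fixed: dict[str, float] | None = None,
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = 0,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    tol: float = 1e-10,
    x0: np.ndarray | None = None,
) -> FitResult:
    """Estimate free fluxes by multi-start weighted least squares.

    Runs ``n_starts`` bounded local optimizations (trust-region reflective
    on the residual vector, finite-difference Jacobian) from seeded
    log-uniform random starting points; ``x0``, when given, replaces the
    first random start.  Among endpoints whose SSR ties within 1e-9 the
    one with the smallest Euclidean norm is reported; all endpoints are
    retained.  Deterministic given (seed, n_starts).
    """
    if not measurements:
        raise ModelError("no measurements to fit")
    steady = [m for m in measurements if m.time is None]
    if len(steady) != len(measurements):
        raise ModelError("fit() handles steady-state measurements only")
    free_spec = derive_free_fluxes(model, fixed, bounds=bounds)
    targets = sorted({m.emu for m in measurements})
    predictor = SteadyStatePredictor(model, tracer, targets, free_spec)
    nf = len(free_spec.free_ids)
    if nf == 0:
        raise ModelError("model has no free fluxes; nothing to fit")
    lb = np.array([b[0] for b in free_spec.bounds])
    ub = np.array([b[1] for b in free_spec.bounds])
    rng = np.random.default_rng(seed)
    points = _initial_points(rng, n_starts, lb, ub)
    if x0 is not None:
        points[0] = np.clip(np.asarray(x0, dtype=float), lb, ub)

    starts: list[StartRecord] = []
    for i, p0 in enumerate(points):
        try:
            res = least_squares(
                predictor.residuals,
                p0,
                args=(measurements,),
                bounds=(lb, ub),
                method="trf",
                xtol=tol,
                ftol=tol,
                gtol=tol,
            )
            starts.append(
                StartRecord(
                    index=i,
                    x0=tuple(p0),
                    x=tuple(res.x),
                    ssr=float(2 * res.cost),
                    converged=bool(res.success),
                    message=res.message,
                )
            )
        except (ModelError, np.linalg.LinAlgError) as exc:
            starts.append(
                StartRecord(
                    index=i, x0=tuple(p0), x=tuple(p0), ssr=np.inf,
                    converged=False, message=str(exc),
                )
            )
    converged = [s for s in starts if s.converged]
    if not converged:
        raise ModelError(
            "no optimization start converged; messages: "
            + "; ".join(s.message for s in starts)
        )
    best_ssr = min(s.ssr for s in converged)
    tied = [s for s in converged if s.ssr <= best_ssr + SSR_TIE_TOL]
    best = min(tied, key=lambda s: float(np.linalg.norm(s.x)))
    x = np.asarray(best.x)
    return FitResult(
        free_ids=free_spec.free_ids,
        free_values=x,
        fluxes=free_spec.flux_state(x),
        ssr=best.ssr,
        starts=starts,
        predictions=predictor.predict(x),
        predictor=predictor,
        measurements=measurements,
    )
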