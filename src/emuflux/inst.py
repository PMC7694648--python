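"""Isotopically non-stationary labeling: EMU ODEs with metabolite pools.

After switching the carbon source to a labeled tracer at t = 0, each EMU's
MID relaxes toward the steady-state flux-weighted average at a rate set by
its metabolite's pool:

    dm/dt = sum_i f_i (m_i - m) / c

where c is the pool amount (concentration times volume, tracked jointly in
nmol) and f_i are absolute production fluxes (nmol per unit time).  Pool
sizes govern only the labeling kinetics, never the t -> infinity labeling.
When metabolic steady state is dropped, the pool itself evolves with the
net production flux, d(cV)/dt = f_NetPro * V, and the same labeling
equation holds with a time-varying c — growth dilutes the incoming label.

Fitting time-resolved MIDs (kinetic flux profiling) reuses the multi-start
weighted least-squares machinery, with pool amounts optionally among the
free parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .emu import EMU, EMUNetwork, decompose
from .fit import FitResult, StartRecord, _initial_points
from .model import (
    FluxState,
    MeasurementSet,
    ModelError,
    NetworkModel,
    TracerSpec,
    balance_constraints,
    derive_free_fluxes,
)
from .simulate import MID, solve_steady, tracer_mid

__all__ = [
    "PoolState",
    "Trajectory",
    "simulate_timecourse",
    "simulate_nonstationary_pools",
    "simulate_to_steady",
    "fit_timecourse",
    "InstFitResult",
]

RTOL = 1e-8
ATOL = 1e-10
DRIFT_TOL = 1e-7


class PoolState(dict):
    """Mapping metabolite -> pool amount c*V (nmol)."""

    def __init__(self, values: dict[str, float]):
        for k, v in values.items():
            if not v > 0:
                raise ModelError(f"pool of {k} must be positive, got {v}")
        super().__init__(values)

    @classmethod
    def from_model(cls, model: NetworkModel, overrides: dict[str, float] | None = None):
        pools = {
            m.name: m.pool_size for m in model.metabolites if m.pool_size is not None
        }
        pools.update(overrides or {})
        return cls(pools)


@dataclass
class Trajectory:
    """Time-resolved MIDs (and optionally pool amounts) per EMU."""

    times: np.ndarray
    mids: dict[str, np.ndarray]  # EMU label -> (n_times, size+1)
    pools: dict[str, np.ndarray] | None = None

    def mid_at(self, emu: str, index: int) -> MID:
        return MID(tuple(self.mids[emu][index]))

    def final(self) -> dict[str, MID]:
        return {label: MID(tuple(arr[-1])) for label, arr in self.mids.items()}


class _OdeSystem:
    """EMU labeling ODE assembled once per (network, pools) pair."""

    def __init__(
        self,
        model: NetworkModel,
        emunet: EMUNetwork,
        tracer: TracerSpec,
    ):
        self.model = model
        self.emunet = emunet
        self.unknown = [e for e in emunet.emus if e not in emunet.source_emus]
        self.offsets = {}
        pos = 0
        for e in self.unknown:
            self.offsets[e] = (pos, pos + e.size + 1)
            pos += e.size + 1
        self.n_state = pos
        self.source_mids = {
            e: tracer_mid(model, tracer, e).as_array() for e in emunet.source_emus
        }
        self.incoming = {
            e: [edge for edge in emunet.edges if edge.target == e] for e in self.unknown
        }
        for e in self.unknown:
            if model.metabolite(e.metabolite).pool_size is None:
                pass  # pools supplied separately; validated by caller

    def initial_state(self, prelabeled: dict[str, MID] | None = None) -> np.ndarray:
        y0 = np.zeros(self.n_state)
        for e in self.unknown:
            a, b = self.offsets[e]
            if prelabeled and str(e) in prelabeled:
                y0[a:b] = prelabeled[str(e)].as_array()
            else:
                y0[a] = 1.0  # fully unlabeled before the tracer switch
        return y0

    def _mid_of(self, emu: EMU, y: np.ndarray) -> np.ndarray:
        if emu in self.source_mids:
            return self.source_mids[emu]
        a, b = self.offsets[emu]
        return y[a:b]

    def rhs(self, y: np.ndarray, fluxes: dict, pools: dict) -> np.ndarray:
        dy = np.zeros_like(y)
        for e in self.unknown:
            a, b = self.offsets[e]
            m = y[a:b]
            c = pools[e.metabolite]
            acc = np.zeros(e.size + 1)
            for edge in self.incoming[e]:
                f = float(fluxes[edge.flux_id]) * edge.weight
                if f == 0.0:
                    continue
                src = self._mid_of(edge.sources[0], y)
                for s in edge.sources[1:]:
                    src = np.convolve(src, self._mid_of(s, y))
                acc += f * (src - m)
            dy[a:b] = acc / c
        return dy


def _require_pools(system: _OdeSystem, pools: PoolState):
    for e in system.unknown:
        if e.metabolite not in pools:
            raise ModelError(f"no pool size given for required metabolite {e.metabolite}")


def _targets_or_default(model: NetworkModel, targets) -> list:
    if targets is not None:
        return list(targets)
    return [
        str(EMU(m.name, tuple(range(1, m.n_atoms + 1))))
        for m in model.metabolites
        if m.role == "balanced"
    ]


def _pack_trajectory(system: _OdeSystem, times, Y, pools=None) -> Trajectory:
    mids = {}
    for e in system.unknown:
        a, b = system.offsets[e]
        arr = Y[:, a:b]
        sums = arr.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > DRIFT_TOL):
            raise ModelError(
                f"integrator drift on {e}: worst MID sum deviation "
                f"{np.abs(sums - 1.0).max():.2e}"
            )
        arr = np.clip(arr, 0.0, None)
        arr /= arr.sum(axis=1, keepdims=True)
        mids[str(e)] = arr
    return Trajectory(times=np.asarray(times, dtype=float), mids=mids, pools=pools)


def simulate_timecourse(
    model: NetworkModel,
    fluxes: FluxState | dict,
    pools: PoolState | dict,
    tracer: TracerSpec,
    times,
    targets: list | None = None,
    prelabeled: dict[str, MID] | None = None,
) -> Trajectory:
    """Labeling kinetics after a tracer switch at metabolic steady state.

    ``times`` must be nonnegative and strictly increasing.  ``targets``
    defaults to the full-molecule EMUs of every balanced metabolite.  The
    initial state is fully unlabeled unless ``prelabeled`` supplies MIDs
    keyed by EMU label.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 1 or np.any(np.diff(times) <= 0):
        raise ModelError("times must be strictly increasing")
    if times[0] < 0:
        raise ModelError("times must be nonnegative")
    if isinstance(fluxes, FluxState):
        fluxes.check_balance(model)
    pools = pools if isinstance(pools, PoolState) else PoolState(dict(pools))
    emunet = decompose(model, _targets_or_default(model, targets))
    system = _OdeSystem(model, emunet, tracer)
    _require_pools(system, pools)
    y0 = system.initial_state(prelabeled)
    t_span = (0.0, float(times[-1]) if times[-1] > 0 else 1e-12)
    sol = solve_ivp(
        lambda t, y: system.rhs(y, fluxes, pools),
        t_span,
        y0,
        method="LSODA",
        t_eval=times,
        rtol=RTOL,
        atol=ATOL,
    )
    if not sol.success:
        raise ModelError(f"integrator failure: {sol.message}")
    return _pack_trajectory(system, times, sol.y.T)


def simulate_nonstationary_pools(
    model: NetworkModel,
    fluxes: FluxState | dict,
    initial_pools: PoolState | dict,
    tracer: TracerSpec,
    times,
    targets: list | None = None,
) -> Trajectory:
    """Co-integrate labeling with evolving pool amounts.

    The pool of each balanced metabolite changes with its net production
    flux, d(cV)/dt = f_NetPro, while the labeling obeys the same balance
    equation with the time-varying pool.  Integration aborts with an error
    if any pool reaches zero within the horizon.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 1 or np.any(np.diff(times) <= 0):
        raise ModelError("times must be strictly increasing")
    pools0 = initial_pools if isinstance(initial_pools, PoolState) else PoolState(dict(initial_pools))
    emunet = decompose(model, _targets_or_default(model, targets))
    system = _OdeSystem(model, emunet, tracer)
    _require_pools(system, pools0)

    net_pro = {}
    for met, eq in balance_constraints(model).items():
        net_pro[met] = sum(c * float(fluxes[f]) for f, c in eq.items())
    pool_mets = sorted({e.metabolite for e in system.unknown})
    npool = len(pool_mets)
    y0 = np.concatenate([system.initial_state(), [pools0[m] for m in pool_mets]])

    def rhs(t, y):
        pools = {m: y[system.n_state + i] for i, m in enumerate(pool_mets)}
        dy = np.empty_like(y)
        dy[: system.n_state] = system.rhs(y[: system.n_state], fluxes, pools)
        for i, m in enumerate(pool_mets):
            dy[system.n_state + i] = net_pro.get(m, 0.0)
        return dy

    # trigger just above zero: the labeling rhs divides by the pool, so the
    # system becomes singular before the pool itself crosses zero
    floor = 1e-6 * min(pools0[m] for m in pool_mets)

    def pool_floor(t, y):
        return float(np.min(y[system.n_state:])) - floor

    pool_floor.terminal = True
    pool_floor.direction = -1
    sol = solve_ivp(
        rhs,
        (0.0, float(times[-1]) if times[-1] > 0 else 1e-12),
        y0,
        method="LSODA",
        t_eval=times,
        rtol=RTOL,
        atol=ATOL,
        events=pool_floor,
    )
    if sol.status == 1:
        t_ev = sol.t_events[0][0]
        raise ModelError(f"a metabolite pool reached zero at t = {t_ev:g}")
    if not sol.success:
        raise ModelError(f"integrator failure: {sol.message}")
    pool_traj = {
        m: sol.y[system.n_state + i, :] for i, m in enumerate(pool_mets)
    }
    return _pack_trajectory(system, times, sol.y[: system.n_state].T, pools=pool_traj)


def simulate_to_steady(
    model: NetworkModel,
    fluxes: FluxState | dict,
    pools: PoolState | dict,
    tracer: TracerSpec,
    targets: list | None = None,
    dm_tol: float = 1e-9,
    max_turnovers: float = 50.0,
) -> dict[str, MID]:
    """Integrate until isotopic steady state (max |dm/dt| < dm_tol) or
    ``max_turnovers`` upstream turnover times, whichever comes first."""
    pools = pools if isinstance(pools, PoolState) else PoolState(dict(pools))
    emunet = decompose(model, _targets_or_default(model, targets))
    system = _OdeSystem(model, emunet, tracer)
    _require_pools(system, pools)
    turnover = 0.0
    for e in system.unknown:
        inflow = sum(
            float(fluxes[edge.flux_id]) * edge.weight for edge in system.incoming[e]
        )
        if inflow <= 0:
            raise ModelError(f"EMU {e} has zero inflow")
        turnover = max(turnover, pools[e.metabolite] / inflow)
    horizon = max_turnovers * turnover
    y = system.initial_state()
    t = 0.0
    while t < horizon:
        t_next = min(horizon, t + 5 * turnover)
        sol = solve_ivp(
            lambda tt, yy: system.rhs(yy, fluxes, pools),
            (t, t_next),
            y,
            method="LSODA",
            rtol=RTOL,
            atol=ATOL,
        )
        if not sol.success:
            raise ModelError(f"integrator failure: {sol.message}")
        y = sol.y[:, -1]
        t = t_next
        if np.abs(system.rhs(y, fluxes, pools)).max() < dm_tol:
            break
    out = {}
    for e in system.unknown:
        a, b = system.offsets[e]
        out[str(e)] = MID(tuple(np.clip(y[a:b], 0.0, None)))
    return out


@dataclass
class InstFitResult(FitResult):
    """Fit over free fluxes plus any pools declared free."""

    free_pool_ids: tuple[str, ...] = ()
    pools: PoolState | None = None


def fit_timecourse(
    model: NetworkModel,
    measurements: MeasurementSet,
    tracer: TracerSpec,
    fixed: dict[str, float] | None = None,
    pools: PoolState | dict | None = None,
    free_pools: list[str] | None = None,
    n_starts: int = 5,
    seed: int = 0,
    bounds: tuple[float, float] = (0.0, 1e4),
    pool_bounds: tuple[float, float] = (1.0, 1e5),
    tol: float = 1e-10,
    x0: np.ndarray | None = None,
) -> InstFitResult:
    """Estimate fluxes (and optionally pool sizes) from timed MIDs.

    Minimizes the variance-weighted SSR summed over all time points with
    the same multi-start contract as the steady-state fit.  ``free_pools``
    lists metabolites whose pool amounts join the parameter vector; the
    remaining pools are taken from ``pools`` / the model.  Requires
    measurements at two or more distinct times.
    """
    timed = [m for m in measurements if m.time is not None]
    if len(timed) != len(measurements):
        raise ModelError("fit_timecourse requires time-stamped measurements")
    times = sorted({m.time for m in timed})
    if len(times) < 2:
        raise ModelError("need measurements at >= 2 distinct time points")
    free_pools = list(free_pools or [])
    base_pools = PoolState.from_model(model, dict(pools or {}))
    free_spec = derive_free_fluxes(model, fixed, bounds=bounds)
    nf = len(free_spec.free_ids)
    targets = sorted({m.emu for m in timed})
    emunet = decompose(model, targets)
    system = _OdeSystem(model, emunet, tracer)
    canonical = {lab: emu for lab, emu in zip(targets, emunet.targets)}

    time_arr = np.asarray(times, dtype=float)
    by_time = {t: [m for m in timed if m.time == t] for t in times}

    def unpack(theta):
        fluxes = dict(zip(free_spec.all_ids, free_spec.full_vector(theta[:nf])))
        p = dict(base_pools)
        for i, met in enumerate(free_pools):
            p[met] = float(theta[nf + i])
        return fluxes, p

    def residuals(theta):
        fluxes, p = unpack(theta)
        for e in system.unknown:
            if e.metabolite not in p:
                raise ModelError(f"no pool size for required metabolite {e.metabolite}")
        t_eval = time_arr if time_arr[0] > 0 else time_arr[1:]
        sol = solve_ivp(
            lambda tt, yy: system.rhs(yy, fluxes, p),
            (0.0, float(time_arr[-1])),
            system.initial_state(),
            method="LSODA",
            t_eval=t_eval,
            rtol=1e-8,
            atol=1e-10,
        )
        if not sol.success:
            raise ModelError(f"integrator failure: {sol.message}")
        states = {}
        j = 0
        if time_arr[0] == 0.0:
            states[times[0]] = system.initial_state()
        for t in times:
            if t in states:
                continue
            states[t] = sol.y[:, j]
            j += 1
        res = []
        for t in times:
            y = states[t]
            for m in by_time[t]:
                emu = canonical[m.emu]
                a, b = system.offsets[emu]
                mid = y[a:b]
                for (mass, frac), sd in zip(m.mids, m.sds):
                    res.append((frac - mid[mass]) / sd)
        full = free_spec.full_vector(theta[:nf])
        for v in full:
            if v < 0:
                res.append(1e4 * (-v))
        return np.asarray(res)

    lb = np.concatenate([[b[0] for b in free_spec.bounds], [pool_bounds[0]] * len(free_pools)])
    ub = np.concatenate([[b[1] for b in free_spec.bounds], [pool_bounds[1]] * len(free_pools)])
    rng = np.random.default_rng(seed)
    points = _initial_points(rng, n_starts, lb, ub)
    if x0 is not None:
        points[0] = np.clip(np.asarray(x0, dtype=float), lb, ub)
    starts: list[StartRecord] = []
    for i, p0 in enumerate(points):
        try:
            res = least_squares(
                residuals, p0, bounds=(lb, ub), method="trf",
                xtol=tol, ftol=tol, gtol=tol,
            )
            starts.append(
                StartRecord(i, tuple(p0), tuple(res.x), float(2 * res.cost),
                            bool(res.success), res.message)
            )
        except (ModelError, np.linalg.LinAlgError) as exc:
            starts.append(StartRecord(i, tuple(p0), tuple(p0), np.inf, False, str(exc)))
    converged = [s for s in starts if s.converged]
    if not converged:
        raise ModelError(
            "no optimization start converged; messages: "
            + "; ".join(s.message for s in starts)
        )
    best_ssr = min(s.ssr for s in converged)
    tied = [s for s in converged if s.ssr <= best_ssr + 1e-9]
    best = min(tied, key=lambda s: float(np.linalg.norm(s.x)))
    theta = np.asarray(best.x)
    fluxes, p = unpack(theta)
    from .fit import SteadyStatePredictor  # predictions at isotopic steady state

    return InstFitResult(
        free_ids=free_spec.free_ids,
        free_values=theta[:nf],
        fluxes=free_spec.flux_state(theta[:nf]),
        ssr=best.ssr,
        starts=starts,
        predictions={},
        predictor=SteadyStatePredictor(model, tracer, targets, free_spec),
        measurements=measurements,
        free_pool_ids=tuple(free_pools),
        pools=PoolState({k: float(v) for k, v in p.items()}),
    )
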