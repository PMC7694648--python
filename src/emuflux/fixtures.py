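"""Canonical example networks and synthetic measurement generation.

The upper-glycolysis toy network — glucose uptake, reversible aldolase
(FBP <-> DHAP + GAP) and reversible triose phosphate isomerase
(DHAP <-> GAP), with GAP drained to lower glycolysis — is the standard
demonstration model for 13C-MFA: with the 1,2-13C2-glucose tracer the FBP
MID (M+0/M+2/M+4) encodes the two exchange fluxes.  The non-stationary
variant adds an explicit Glc6P node (lumping Fruc6P) whose pool size sets
how fast downstream labeling equilibrates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .emu import EMU, decompose
from .inst import PoolState
from .model import (
    FluxState,
    Measurement,
    MeasurementSet,
    ModelError,
    NetworkModel,
    TracerSpec,
    parse_model,
)
from .simulate import solve_steady

__all__ = [
    "FixtureBundle",
    "UPPER_GLYCOLYSIS_TEXT",
    "INST_GLYCOLYSIS_TEXT",
    "build_upper_glycolysis",
    "build_inst_glycolysis",
    "tracer_12_13c2_glucose",
    "tracer_u13c_mixture",
    "generate_synthetic_measurements",
]

UPPER_GLYCOLYSIS_TEXT = """\
# Upper glycolysis with reversible aldolase and TPI.
# Fluxes in nmol/h; glucose uptake f1 is measured at 100.
Glc, 6, source
FBP, 6, balanced
DHAP, 3, balanced
GAP, 3, balanced
Lower, 3, sink
f1: Glc (abcdef) -> FBP (abcdef)
f2: FBP (abcdef) -> DHAP (abc) + GAP (def)
f3: DHAP (abc) + GAP (def) -> FBP (abcdef)
f4: DHAP (abc) -> GAP (cba)
f5: GAP (abc) -> DHAP (cba)
f6: GAP (abc) -> Lower (abc)
"""

INST_GLYCOLYSIS_TEXT = """\
# Upper glycolysis with an explicit Glc6P node (Fruc6P lumped in) and
# pool sizes for non-stationary labeling simulation.  Pools in nmol.
Glc, 6, source
Glc6P, 6, balanced, pool=400
FBP, 6, balanced, pool=1000
DHAP, 3, balanced, pool=1000
GAP, 3, balanced, pool=1000
Lower, 3, sink
f0: Glc (abcdef) -> Glc6P (abcdef)
f1: Glc6P (abcdef) -> FBP (abcdef)
f2: FBP (abcdef) -> DHAP (abc) + GAP (def)
f3: DHAP (abc) + GAP (def) -> FBP (abcdef)
f4: DHAP (abc) -> GAP (cba)
f5: GAP (abc) -> DHAP (cba)
f6: GAP (abc) -> Lower (abc)
"""


@dataclass
class FixtureBundle:
    model: NetworkModel
    tracer: TracerSpec
    fluxes: FluxState
    fixed: dict[str, float]
    pools: PoolState | None
    reference_measurements: MeasurementSet


def tracer_12_13c2_glucose() -> TracerSpec:
    """100% glucose labeled at C1 and C2."""
    return TracerSpec.single("Glc", {1, 2})


def tracer_u13c_mixture(labeled_fraction: float = 0.5) -> TracerSpec:
    """Mixture of uniformly labeled and unlabeled glucose."""
    return TracerSpec(
        {
            "Glc": (
                (frozenset(range(1, 7)), labeled_fraction),
                (frozenset(), 1.0 - labeled_fraction),
            )
        }
    )


def _reference_measurements(model, fluxes, tracer, targets, sd=0.01) -> MeasurementSet:
    net = decompose(model, targets)
    mids = solve_steady(net, fluxes, tracer)
    out = MeasurementSet()
    for label, emu in zip(targets, net.targets):
        mid = mids[emu]
        masses = [k for k in range(len(mid)) if mid[k] > 1e-12]
        out.append(
            Measurement(
                emu=label,
                mids=tuple((k, mid[k]) for k in masses),
                sds=tuple(sd for _ in masses),
            )
        )
    return out


def build_upper_glycolysis(f3: float = 50.0, f5: float = 150.0) -> FixtureBundle:
    """Steady-state upper-glycolysis bundle with reference fluxes.

    Glucose uptake is fixed at 100 nmol/h; the aldolase and TPI reverse
    fluxes default to the canonical reference values (f3 = 50, f5 = 150),
    under which the predicted FBP MID is 5.00% M+0, 83.33% M+2, 11.67% M+4.
    """
    model = parse_model(UPPER_GLYCOLYSIS_TEXT, name="upper_glycolysis")
    fluxes = FluxState(
        {
            "f1": 100.0,
            "f2": 100.0 + f3,
            "f3": f3,
            "f4": 100.0 + f5,
            "f5": f5,
            "f6": 200.0,
        }
    )
    fluxes.check_balance(model)
    tracer = tracer_12_13c2_glucose()
    return FixtureBundle(
        model=model,
        tracer=tracer,
        fluxes=fluxes,
        fixed={"f1": 100.0},
        pools=None,
        reference_measurements=_reference_measurements(
            model, fluxes, tracer, ["FBP[1-6]"]
        ),
    )


def build_inst_glycolysis(glc6p_pool: float = 400.0) -> FixtureBundle:
    """Non-stationary bundle with an explicit Glc6P node.

    FBP, DHAP and GAP pools are 1000 nmol each; the Glc6P pool is the
    knob that slows or speeds downstream labeling (400 vs 3000 nmol in
    the canonical comparison).  Reference fluxes reuse the steady-state
    bundle's values, with the uptake split as f0 = f1 = 100.
    """
    if not glc6p_pool > 0:
        raise ModelError("glc6p_pool must be positive")
    model = parse_model(INST_GLYCOLYSIS_TEXT, name="inst_glycolysis")
    fluxes = FluxState(
        {
            "f0": 100.0,
            "f1": 100.0,
            "f2": 150.0,
            "f3": 50.0,
            "f4": 250.0,
            "f5": 150.0,
            "f6": 200.0,
        }
    )
    fluxes.check_balance(model)
    tracer = tracer_12_13c2_glucose()
    pools = PoolState.from_model(model, {"Glc6P": glc6p_pool})
    return FixtureBundle(
        model=model,
        tracer=tracer,
        fluxes=fluxes,
        fixed={"f0": 100.0},
        pools=pools,
        reference_measurements=_reference_measurements(
            model, fluxes, tracer, ["FBP[1-6]"]
        ),
    )


def generate_synthetic_measurements(
    model: NetworkModel,
    fluxes: FluxState | dict,
    tracer: TracerSpec,
    targets: list[str],
    sd: float = 0.01,
    seed: int = 0,
    times=None,
    pools: PoolState | dict | None = None,
    record_sd: float | None = None,
) -> MeasurementSet:
    """Predicted MIDs plus independent Gaussian noise per fraction.

    With ``times`` given (requires ``pools``), time-resolved MIDs are
    simulated and each time point becomes a timed measurement entry.
    Noisy fractions are clipped at zero and renormalized; the recorded SD
    column is the nominal ``sd`` (or ``record_sd`` when noiseless data
    should still carry weights).  Reproducible given ``seed``.
    """
    if sd < 0:
        raise ModelError("sd must be nonnegative")
    rec_sd = record_sd if record_sd is not None else (sd if sd > 0 else 0.01)
    rng = np.random.default_rng(seed)
    out = MeasurementSet()

    def add_entry(label, fractions, time=None):
        arr = np.asarray(fractions, dtype=float)
        if sd > 0:
            arr = np.clip(arr + rng.normal(0.0, sd, size=arr.shape), 0.0, None)
        arr = arr / arr.sum()
        out.append(
            Measurement(
                emu=label,
                mids=tuple((k, float(v)) for k, v in enumerate(arr)),
                sds=tuple(rec_sd for _ in arr),
                time=time,
            )
        )

    if times is None:
        net = decompose(model, targets)
        mids = solve_steady(net, fluxes, tracer)
        for label, emu in zip(targets, net.targets):
            add_entry(label, mids[emu].as_array())
    else:
        if pools is None:
            raise ModelError("time-resolved generation requires pool sizes")
        from .inst import simulate_timecourse

        traj = simulate_timecourse(model, fluxes, pools, tracer, times, targets=targets)
        for label in traj.mids:
            if label not in targets:
                continue
            for i, t in enumerate(traj.times):
                add_entry(label, traj.mids[label][i], time=float(t))
    return out
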