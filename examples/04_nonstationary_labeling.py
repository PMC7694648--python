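"""Isotopically non-stationary labeling and kinetic flux profiling.

Simulates the tracer-switch labeling kinetics with an explicit Glc6P pool
(400 vs 3000 nmol), showing that pool size sets the labeling speed but not
the endpoint, then recovers fluxes and the Glc6P pool from a noiseless
time course.
"""

import numpy as np

import emuflux as ef

times = np.array([10.0, 30.0, 60.0, 120.0, 300.0])
print("FBP M+2 after switching to 1,2-13C2-glucose:")
print("   time   Glc6P=400   Glc6P=3000")
trajs = {}
for pool in (400.0, 3000.0):
    b = ef.build_inst_glycolysis(pool)
    trajs[pool] = ef.simulate_timecourse(b.model, b.fluxes, b.pools, b.tracer, times)
for i, t in enumerate(times):
    a = trajs[400.0].mids["FBP[1-6]"][i][2]
    c = trajs[3000.0].mids["FBP[1-6]"][i][2]
    print(f"  {t:5.0f}     {a:.4f}      {c:.4f}")
print("The small-pool network labels faster at every time; both converge")
print("to the same steady state (83.33% M+2).")

b = ef.build_inst_glycolysis(400.0)
measured = ef.generate_synthetic_measurements(
    b.model, b.fluxes, b.tracer, ["FBP[1-6]"], sd=0.0, seed=1,
    times=[10.0, 20.0, 40.0, 80.0], pools=b.pools,
)
result = ef.fit_timecourse(
    b.model, measured, b.tracer, fixed={"f0": 100.0}, pools=b.pools,
    free_pools=["Glc6P"], n_starts=3, seed=7,
)
print(f"\nKinetic fit: f3 = {result.free_values[0]:.2f}, "
      f"f5 = {result.free_values[1]:.2f}, "
      f"Glc6P pool = {result.pools['Glc6P']:.0f} nmol (truth: 50, 150, 400)")
print("Unlike steady-state MFA, the transient data pin down the pool size.")
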