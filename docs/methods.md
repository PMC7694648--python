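# Methods

## Model and assumptions

`emuflux` models an atom-mapped metabolic network at three levels of
resolution, all built on the same labeling-balance principle: the rate of
change of a metabolite's labeling is driven only by its *production*
fluxes, each pulling the labeling toward that substrate's pattern.

Assumptions inherited from the standard ¹³C-MFA framework:

- **No kinetic isotope effect.** Fluxes act identically on labeled and
  unlabeled species; every balance is linear in the labeled fractions.
  (For ¹³C the effect is small; for ²H it can be large — such tracers are
  outside this package's intended accuracy.)
- **Well-mixed pools.** Each metabolite is one homogeneous pool with one
  MID; compartments or channeling must be modeled as distinct metabolite
  names.
- **Tracer purity 100%.** Tracer mixtures are exact combinatorics over
  labeled-position sets. Natural isotope abundance is *not* modeled;
  measured MIDs are expected to be abundance-corrected upstream.
- Reversible reactions are written as two irreversible steps with
  separate nonnegative fluxes (e.g. aldolase forward/reverse). No
  net/exchange reparameterization is offered; this keeps every equation
  in the code in exactly the flux coordinates of the model file.

## Free-flux parameterization

Steady-state balance gives one homogeneous equation per balanced
metabolite (production − consumption = 0). Together with any externally
fixed fluxes these form a linear system `A f = b`; the full flux vector
is affine in the remaining degrees of freedom. Dependent fluxes are
chosen by greedy Gaussian elimination over columns in the model's flux
order, so the free set is deterministic and reproducible: on the
upper-glycolysis fixture with the uptake fixed, the free fluxes come out
as the aldolase and TPI reverse fluxes (f3, f5) and the map reduces to
f2 = 100 + f3, f4 = 100 + f5, f6 = 200. Inconsistent fixed assignments
(e.g. fixing both uptake and output to incompatible values) are detected
by residual check and rejected.

## EMU decomposition and symmetry

Measurement targets are traced backward through the reaction atom maps;
each producing reaction contributes an edge whose sources are the
substrate EMUs supplying the target's atoms, with condensations becoming
convolution source terms. The resulting network is minimal (only EMUs on
backward paths appear) and independent of reaction order in the input.

Rotationally symmetric metabolites (succinate-like, declared with an
involutive atom permutation) are handled by splitting every producing
edge 50/50 between the two atom orientations and mapping each EMU to a
canonical orbit representative. This is the exact infinite-rate limit of
the "flipping flux" device and avoids choosing an arbitrary large flux
magnitude. Prochiral metabolites (citrate-like) simply carry no symmetry
flag. Predictions are symmetrized; measurements are not — a measured MID
on a symmetric metabolite is compared against the symmetrized
prediction, which is what an MS measurement of the mixed orientations
reports anyway.

## Steady-state solver

EMU sizes are processed in ascending order. Within one size the unknown
MIDs satisfy a dense linear system: the diagonal holds each EMU's total
inflow, same-size single-EMU sources couple off-diagonally (this handles
cycles such as DHAP ↔ GAP), and tracer sources plus convolutions of
already-solved smaller EMUs form the right-hand side. Systems are tiny
(a handful of EMUs per size); `numpy.linalg.solve` is used directly. An
EMU with zero total inflow makes the system singular and raises an error
naming the EMU and its inflow fluxes. Round-off negatives down to
−1e−12 are clipped and the MID renormalized; anything more negative is
an error.

Because the balances are homogeneous in the fluxes, scaling all fluxes
by a positive constant leaves every MID unchanged; this is asserted as a
property test, as is equivalence (within 1e−6) with an independent
brute-force solver that tracks the complete 2ⁿ isotopomer distribution
of every metabolite and relaxes the unit-pool master equations to their
fixed point by damped iteration. The brute-force path is exponential in
atom count and refuses metabolites above 8 traced atoms; it exists to
validate the EMU path, not to replace it.

## Fitting

The residual vector ((measured − predicted)/SD, diagonal covariance
only) is minimized with SciPy's bounded trust-region-reflective least
squares and a finite-difference Jacobian, from `n_starts` log-uniform
random initial points drawn from a seeded generator (default 10 starts,
bounds [0, 10⁴] per free flux, convergence tolerances 1e−10). Exposing
residuals rather than the scalar SSR to the optimizer converges much
faster near the optimum. Dependent fluxes are kept nonnegative by a
hinge penalty appended to the residuals — inactive at any feasible
optimum. Endpoints tying within 1e−9 in SSR are resolved toward the
smallest free-flux norm; all endpoints are retained in the result for
inspection. A start that fails is recorded, not fatal; only all starts
failing raises.

Measured MIDs must sum to 1 within ±0.02 and are renormalized to exactly
1; SDs are taken as given and never rescaled.

## Uncertainty

- **χ² quantiles** come from `scipy.stats.chi2.ppf`, never hardcoded.
- **Profile likelihood:** the target flux is stepped away from its
  best-fit value (initial step 1% of the value, doubled each step) while
  all other free fluxes are re-optimized warm-started from the previous
  profile point; once the profiled SSR crosses
  SSR_min + χ²(α, df=1) the crossing is located by bisection to 3
  significant figures. Reaching an optimizer bound first sets a flag on
  the interval instead of erroring — that is the signature of an
  unidentifiable flux.
- **Region rasters** evaluate the (re-optimized, if more than two free
  fluxes exist) SSR on a rectangular grid; membership uses the same
  df = 1 threshold by default so that a perfect fit's acceptance rule
  reduces to SSR ≤ 3.84 at 95%. The statistically conventional df = 2
  joint region is available via `df=2`. Profile endpoints agree with the
  raster boundary within one grid cell on the fixture, which is asserted
  in tests.
- **Monte Carlo:** a seeded random-walk Metropolis sampler with
  log-density −SSR/2 (step adapted during burn-in toward ~30%
  acceptance; a final acceptance rate outside [0.05, 0.8] warns), and a
  measurement-perturbation alternative that refits after adding Gaussian
  noise (the measurement SDs) to the fractions. Both are reproducible
  given a seed. The Metropolis 2.5–97.5% interval cross-checks the
  profile interval for identifiable fluxes; for flat-likelihood
  directions the posterior spread is sampler-dependent and no agreement
  is claimed.

## Non-stationary labeling

Concentration c and volume V appear only as the products c·V (pool
amount) and f·V (absolute flux), so the code tracks pool amounts in nmol
and never separates the factors. The EMU ODE
dm̄/dt = Σ fᵢ(mᵢ − m̄)/c is integrated with LSODA (rtol 1e−8,
atol 1e−10) from a fully unlabeled state (pre-labeled initial states are
accepted as an option), with tracer sources held at their post-switch
MIDs. Stored MIDs are checked for drift (< 1e−7 from sum 1), clipped
and renormalized. Properties asserted numerically: scaling all pools by
k maps the trajectory to m̄(t/k); the t → ∞ labeling is pool-independent
and equals the steady-state solve; a single pool fed fully labeled
substrate follows 1 − e^(−ft/c) exactly.

"t → ∞" is implemented by integrating in chunks of five upstream
turnover times until max |dm̄/dt| < 1e−9, capped at 50 turnover times.

With metabolic steady state dropped, each pool evolves as
d(cV)/dt = f_NetPro while the same labeling equation runs with the
time-varying pool; growth therefore dilutes incoming label. Integration
terminates with an error if any pool falls to a floor of 1e−6 of the
smallest initial pool (the labeling equation divides by the pool, so the
system is singular slightly before zero).

Time-course fitting reuses the multi-start least-squares contract with
the ODE solve inside the residual; pool amounts named in `free_pools`
join the parameter vector with bounds [1, 1e5] nmol. Default 5 starts
(each start costs one ODE solve per Jacobian column per iteration).

## Fixtures and synthetic data

The bundled steady-state network is upper glycolysis with reversible
aldolase and TPI, glucose uptake fixed at 100 nmol/h and reference free
fluxes f3 = 50, f5 = 150 under 1,2-¹³C₂-glucose — the configuration
whose FBP MID is 5.00% M+0 / 83.33% M+2 / 11.67% M+4. The TPI atom map
uses the chemically correct orientation (DHAP C1↔GAP C3, C2↔C2,
C3↔GAP C1); full-molecule MIDs are insensitive to the C1/C3 choice. The
non-stationary variant adds an explicit Glc6P node (Fruc6P lumped in)
with pools FBP = DHAP = GAP = 1000 nmol and Glc6P of 400 or 3000 nmol;
its absolute fluxes reuse the steady-state reference values, so the time
axis is conventional (nmol/h units) and kinetic assertions are ordering
properties, not absolute curves.

The synthetic measurement generator adds independent Gaussian noise per
MID fraction, clips at zero and renormalizes; the recorded SD column is
the nominal noise SD (matching the "1% error on all labeled fractions"
convention used for χ² thresholds), not the post-clip dispersion. Near
zero fractions the clip-and-renormalize step biases the mean upward by
design — the unbiasedness test therefore runs on a MID with no
near-zero fractions. What passing tests show: the estimator recovers
generating fluxes from data produced by the same forward model with
ideal independent Gaussian errors. What they do not show: robustness to
natural-abundance contamination, correlated MID errors, model
misspecification, or real MS noise structure.

## Known limitations

- Diagonal measurement covariance only; correlated MID errors are not
  supported.
- No natural-isotope-abundance correction or simulation.
- No isotopomer/bondomer-level measurement prediction (NMR fine
  structure); positional information is exposed only through weight-1
  cumomers (single-position enrichments).
- Local multi-start optimization only; no global optimizers. The
  bundled problems are comfortably solvable this way; large networks
  with many local minima may not be.
- Fluxes are constant within a simulation; no time-varying flux
  schedules, and pool dynamics are limited to constant net production.
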