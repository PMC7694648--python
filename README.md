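# emuflux

**¹³C metabolic flux analysis with elementary metabolite units (EMUs).**

Intracellular reaction rates (fluxes) cannot be measured directly.
Metabolic flux analysis (MFA) infers them from stable-isotope tracer
experiments: feed cells a ¹³C-labeled substrate, measure the mass
isotopomer distributions (MIDs) of intracellular metabolites by MS, and
find the fluxes whose predicted labeling best matches the observations.
`emuflux` implements this pipeline end to end for atom-mapped reaction
networks:

- **Forward simulation** — steady-state MIDs, positional (cumomer)
  enrichments and average enrichment from a flux vector and tracer, via
  EMU decomposition and size-layered linear solves; molecular symmetry by
  orientation averaging; a brute-force full-isotopomer oracle for
  validation.
- **Flux fitting** — multi-start bounded weighted least squares on the
  variance-weighted residuals (SSR), with a deterministic free-flux
  parameterization derived from stoichiometric balance.
- **Uncertainty** — χ² acceptance thresholds, profile-likelihood
  confidence intervals, 2-D confidence-region rasters for tracer
  evaluation, and Monte-Carlo sampling (Metropolis or
  measurement-perturbation refitting).
- **Non-stationary MFA / kinetic flux profiling** — EMU ODEs with
  metabolite pool sizes, optional evolving pools under non-zero net
  production, and fitting of fluxes *and* pool sizes to time-resolved
  MIDs.

## The model

At metabolic and isotopic steady state, a metabolite's labeling is the
flux-weighted average of its substrates' labeling. For production fluxes
$f_i$ delivering labeling patterns $m_i$ to a product with pattern
$\bar m$:

$$\sum_i f_i\,(m_i - \bar m) = 0$$

Condensation reactions combine fragment MIDs by convolution,
$(A \oplus B)_{M+k} = \sum_j A_{M+j} B_{M+k-j}$. Grouping EMUs by size
makes the balances linear within each size, so labeling is predicted by a
cascade of small dense solves. The fit minimizes

$$\mathrm{SSR} = \sum_j \left(\frac{m_j^{\text{meas}} - m_j^{\text{pred}}}{\sigma_j}\right)^2,$$

and a candidate flux vector is accepted at level $\alpha$ when its SSR
stays below $\mathrm{SSR}_{\min} + \chi^2(\alpha,\,\mathrm{df}{=}1)$.
Away from steady state, each EMU relaxes as
$d\bar m/dt = \sum_i f_i (m_i - \bar m)/c$ with pool amount $c$ — pool
sizes set labeling *speed*, never the endpoint, which is what makes
transient data informative about pools.

## Worked example

The bundled upper-glycolysis network (glucose → FBP → DHAP + GAP, with
reversible aldolase `f2`/`f3` and reversible TPI `f4`/`f5`, glucose
uptake `f1` fixed at 100 nmol/h) under 1,2-¹³C₂-glucose:

```python
import emuflux as ef

bundle = ef.build_upper_glycolysis()          # f3=50, f5=150 reference
net = ef.decompose(bundle.model, ["FBP[1-6]"])
mids = ef.solve_steady(net, bundle.fluxes, bundle.tracer)
```

prints (see `examples/01_forward_simulation.py`):

```
FBP[1-6]: M+0=0.0500, M+2=0.8333, M+4=0.1167
DHAP[1-3]: M+0=0.3000, M+2=0.7000
```

M+2 FBP comes straight from the intact tracer; M+0 and M+4 exist only
because aldolase and TPI run backwards, so those fractions *are* the
information about the exchange fluxes. Fitting the measured FBP MID
recovers f3 = 50, f5 = 150 from any starting point
(`examples/02_flux_fitting.py`), and profile likelihood puts the 95%
confidence intervals at f3 ∈ [43.2, 57.6] and f5 ∈ [73.8, 330.3] nmol/h
for 1% measurement SD (`examples/03_confidence_and_tracers.py`). The
same script shows that a 50% U-¹³C glucose mixture leaves f5 completely
unidentifiable — tracer choice decides what MFA can see.
`examples/04_nonstationary_labeling.py` simulates the tracer-switch
kinetics with an explicit Glc6P pool (400 vs 3000 nmol) and fits fluxes
plus the pool size from a time course.

A thin CLI mirrors the library:

```sh
emuflux fixtures-export --dir fixtures/
emuflux simulate --model fixtures/upper_glycolysis.model \
    --tracer fixtures/tracer_12_13C2_glucose.yaml \
    --flux f1=100 --flux f3=50 --flux f5=150 \
    --target "FBP[1-6]" --out mids.csv
emuflux fit --model fixtures/upper_glycolysis.model \
    --tracer fixtures/tracer_12_13C2_glucose.yaml \
    --measurements fixtures/fbp_reference_mids.csv \
    --fix f1=100 --starts 10 --seed 42 --out fit.json
```

## Layout

- `src/emuflux/model.py` — network/tracer/measurement types, model
  dialect parser, balance constraints, free-flux parameterization
- `src/emuflux/emu.py` — EMU decomposition and symmetry handling
- `src/emuflux/simulate.py` — steady-state EMU solver, convolution,
  enrichments, brute-force isotopomer oracle
- `src/emuflux/fit.py` — SSR and multi-start flux fitting
- `src/emuflux/uncertainty.py` — χ² cutoffs, profile CIs, region
  rasters, Monte-Carlo sampling
- `src/emuflux/inst.py` — non-stationary EMU ODEs, evolving pools,
  time-course fitting
- `src/emuflux/fixtures.py` — bundled networks and the synthetic
  measurement generator
- `docs/methods.md` — modeling assumptions, numerical choices, and
  limitations
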