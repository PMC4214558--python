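# Methods

## Model

`phosink` models a phosphate-sink two-component signaling motif: one
histidine kinase (HK) that phosphorylates two response regulators — a
*sink* RR (RR1) with fast forward and slow reverse phosphotransfer, and
an *output* RR (RR2) whose steady phospho-level is the system's
response. The reference parameterization describes the
*Sinorhizobium meliloti* chemotaxis proteins CheA (HK), CheY1 (sink)
and CheY2 (output).

### Basic (bimolecular) model

Mass-action reactions, concentrations in µM, time in seconds:

| reaction | rate constant | default |
|---|---|---|
| HK + ATP → HK·ATP | k1 | 1 µM⁻¹s⁻¹ |
| HK·ATP → HK + ATP | k2 | 100 s⁻¹ |
| HK·ATP → HK-p (signal) | ka | 1 s⁻¹ |
| HK-p + RR1 → HK + RR1-p | kS | 1 µM⁻¹s⁻¹ |
| RR1-p + HK → RR1 + HK-p | krS | 0.01 µM⁻¹s⁻¹ |
| HK-p + RR2 → HK + RR2-p | kM | 2 µM⁻¹s⁻¹ |
| RR2-p + HK → RR2 + HK-p | krM | 1 µM⁻¹s⁻¹ |
| RR1-p → RR1 | khS | 0.056 s⁻¹ |
| RR2-p → RR2 | khM | 0.066 s⁻¹ |

ATP is clamped (held constant): the cell's ATP pool is assumed large
and buffered relative to the signaling proteins. Three conservation
laws hold exactly (HK pool, RR1 pool, RR2 pool); the integrator and all
steady-state solvers are tested against them.

Reference totals are CheA:CheY1:CheY2 = 10:2.5:2.5 µM (in-vitro-style)
and 1.5:20:20 µM (in vivo stoichiometry).

**Clamped ATP default (10 µM).** The bundled fixtures clamp ATP at
10 µM, well below the binding constant K_d = k2/k1 = 100 µM, so the
HK+ATP⇌HK·ATP step stays quasi-equilibrated with low occupancy (~9%)
and autophosphorylation behaves as a first-order source in free HK.
This is the regime in which the motif's published sigmoidality numbers
are reproduced; at millimolar ATP most of the HK pool is sequestered as
HK·ATP, which suppresses reverse phosphotransfer and measurably shifts
the response curves.

### Extended model (phosphotransfer complexes)

Each transfer step can optionally proceed through an explicit
bimolecular complex, e.g. HK-p + RR1 ⇌ HK-p·RR1 → HK + RR1-p. The
extended parameters `kyS`, `kyM`, `kyrS`, `kyrM` set the inverse
Michaelis constant of the corresponding step (K_m = 1/ky), with
`complex_reversibility` fixing the unbinding/catalysis ratio; the
mapping preserves the effective bimolecular rate constant at low
substrate, so `ky → 0` recovers the basic model (verified by test).
Dead-end (non-productive) complexes such as HK:RR1 can be added.

## Signals

Three signal variables are supported:

- `ka` — the autophosphorylation rate of HK·ATP (the default; this is
  how an upstream stimulus enters the kinase);
- `ATP` — the clamped ATP concentration (used for in-vitro
  dose-response experiments);
- `source` — a lumped first-order HK → HK-p drive with the explicit
  ATP-binding step switched off.

**`source` vs `ka`.** The analytic necessary conditions for
sigmoidality (below) are statements about a first-order
phosphorylation source. Driving through the explicit binding step
(`ka`) reparametrizes the signal axis and adds an independent
curvature mechanism: rising ka drains the sequestered HK·ATP pool and
relieves HK sequestration, which can make the zero-signal curvature
positive even without a functioning sink. `check_conditions` therefore
classifies curves with `signal_kind="source"`; the `ka` variant remains
available and agrees in sign at low ATP occupancy.

## Numerical methods

- **Integration**: `scipy.integrate.solve_ivp` with LSODA
  (rtol 1e-8, atol 1e-10 defaults; Radau fallback when LSODA's
  stiffness switching fails at extreme clamped-ATP values).
- **Steady states**: integrate-then-refine. Long integration from the
  unphosphorylated state (extending 1e4 → 1e8 s as needed) followed by
  a Newton polish (`scipy.optimize.root`, hybr) in *reduced
  coordinates* (free HK, RR1, RR2 eliminated through the conservation
  laws). A state is accepted only if ‖rhs‖ < 1e-10 µM/s. Warm starts
  skip the integration when a nearby solution is supplied.
- **Signal-response curves**: numerical continuation along a log grid
  (warm-started Newton), with automatic plateau detection — the curve
  is extended until a 10-fold signal increase changes RR2-p by less
  than 0.1%.
- **Hill coefficient**: operational definition ln 81 / ln(S90/S10),
  where S10 and S90 are the signals at 10% and 90% of the curve's own
  plateau (not of the total RR2). The crossings are solved by
  bisection on the continuous steady-state map, never snapped to grid
  points.
- **Zero-signal curvature** (sigmoidality test): d²(RR2-p)/d(signal)²
  at zero signal, computed two independent ways: (a) implicit
  differentiation of the steady-state equations — the mass-action
  residual is quadratic in the state and linear in the signal, so
  every directional derivative involved is exact up to roundoff; (b)
  Richardson-extrapolated one-sided finite differences of the
  continued steady-state map, with a convergence criterion requiring
  two consecutive agreements (the quadratic regime of the response can
  begin several decades below the scale at which the response is first
  measurable, so a single agreement is not trusted). A positive value
  classifies the curve as sigmoidal.
- **Necessary conditions**: for the basic model, sigmoidality requires
  (i) kS·khS·RR1_tot ≠ 0 (the sink must exist and turn over) and (ii)
  kS > krS. With explicit transfer complexes (ii) relaxes to
  kS/krS > 1 *or* kS/krS > (kyM − kyS)/kyrS; the bundled
  `extended_complex_sink.yaml` fixture is sigmoidal at kS/krS = 0.83.
- **Termination half-time**: bisect the signal so that steady RR2-p is
  90% of total, equilibrate, set the signal to zero, and interpolate
  (dense output + bisection) the time at which RR2-p halves. The fold
  change is the ratio of half-times without/with the sink.
- **Multistationarity**: multistart Newton from random feasible states
  (Dirichlet-sampled within the conservation polytope), deduplication
  of converged roots, and stability classification via the eigenvalues
  of the steady-state Jacobian. The basic bimolecular motif shows a
  single steady state across all tested random draws.
- **Fitting**: global stage `scipy.optimize.differential_evolution`
  (seeded, log10 parameter space, Sobol initialization) followed by a
  Nelder-Mead polish. Residuals are weighted by per-point standard
  errors when present; SEs at or below float noise (e.g. the ~1e-16
  `np.std` of identical zero-noise replicates) are treated as
  unweighted to avoid assigning single points near-infinite weight.
  Candidates whose simulation fails receive a large penalty instead of
  aborting the search.

## Synthetic data

The generators mimic radiolabel/gel-quantification experiments:
fractional phosphorylation time courses and replicate-averaged steady
phospho-RR2 dose-response curves. Noise is multiplicative lognormal
(gel band errors scale with intensity) with an optional additive
background floor; `sigma=0` reproduces the model exactly. Every
dataset records its generating parameters and seed, so all synthetic
data are reproducible.

## Limitations

- ATP is clamped, never consumed; energy coupling is out of scope.
- The signal enters only through ka (or the lumped source); receptor
  and upstream dynamics are not modeled.
- The extended model's complex parameterization fixes the
  unbinding/catalysis ratio per step rather than exposing all on/off
  rates independently.
- The sigmoidality conditions are *necessary*, not sufficient: a draw
  can satisfy both and still be hyperbolic.
- Experimental gel datasets are not bundled; the fitting module is
  validated on synthetic data only.
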