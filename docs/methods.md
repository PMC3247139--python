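# Methods

`plateletsig` implements a time-resolved kinetic model of cyclic-nucleotide
signaling in human platelets and the statistical machinery used to calibrate
it, select between nested feedback hypotheses, and predict drug-combination
effects and downstream VASP phosphorylation. This note documents the model,
its assumptions, the numerical choices, the synthetic-study generator, and
the design decisions taken where the design was genuinely open.

## The kinetic model

Ten state variables: cAMP and cGMP (µM), active and inactive pools of PDE2,
PDE3 and PDE5 (mg/l), and the hydrolysis products AMP and GMP (µM). Basal
synthesis by adenylyl cyclase (AC) and guanylyl cyclase is constant
(k11 = 8, k12 = 1 µM/min). Degradation is enzymatic:

- PDE2 on cAMP follows a Hill form with coefficient h = 2
  (positively cooperative): `v = k1 · c^h · [PDE2] / (k2 + c^h)`, with k2
  compared against `c^h` exactly as the constants are tabulated (k1 = 120
  µmol·min⁻¹·mg⁻¹, k2 = 50 µM). Only under this literal form do the
  reported resting activities come out (1.45 µM/min at c = 4 µM with
  0.05 mg/l active enzyme).
- PDE3 on cAMP, and all cGMP branches, are Michaelis–Menten
  (`k3 = 3, k4 = 0.2; k5 = 120, k6 = 35; k7 = 0.3, k8 = 0.02;
  k9 = 5, k10 = 5`).
- Active/inactive PDE pools interconvert by mass action (k13–k18). All six
  rates default to zero — the resting model works with constant active
  pools, and the split exists to express that only a small fraction of the
  measured enzyme is catalytically active. The interconversion equations
  are written in the conservative form (the sum of active and inactive
  pool of each isoform is a strict invariant of the right-hand side).

Units: Vmax in µmol·min⁻¹·mg⁻¹ times an enzyme pool in mg/l gives µM/min;
"influx" constants are concentration-based rates (µM/min) referred to the
platelet volume of 5.2 fl, which also converts measured enzyme masses:
3.3 ng per 10⁷ platelets ↦ 63.46 mg/l.

### Drug action

- **Competitive PDE3 inhibition** (Milrinone, Cilostamide): the inhibitor
  dose u raises the apparent Km by `(1 + u / k_i)`. Multiple inhibitors
  add their `u/k_i` terms.
- **AC stimulation** (Iloprost via the prostacyclin receptor, Forskolin
  directly): each administered dose carries its own fitted influx rate
  `x` (µM/min), a *local* parameter, added to the basal influx.
- **AC inhibition** (e.g. a dideoxyadenosine-like compound): the basal
  influx is scaled by the saturating factor `K / (K + dose)` with a
  half-inhibition constant K (default 20 µM). The mechanism is a modeling
  choice; only the qualitative antagonism pattern is asserted.
- **Transient stimuli** decay exponentially after onset with a configurable
  half-life (default 5 min, the physiological prostacyclin scale); the
  local influx scales proportionally with the decaying dose.

### Feedback hypotheses H0–H3

Elevated cAMP activates PKA, which is not an explicit state; cAMP itself
serves as activity proxy in both loops:

- positive loop (kf1): the PDE3 Vmax becomes `k3 + kf1 · c(cAMP)`
  (floored at zero so a sign-free fitted kf1 cannot generate negative
  hydrolysis);
- negative loop (kf2): each drug-induced AC influx becomes
  `max(x − kf2 · c(cAMP), 0)`. The clamp keeps strong feedback from
  turning the cyclase into a sink; the basal influx is not touched by the
  loop (it models receptor/cyclase stimulation above baseline).

H0 disables both loops, H1 only kf1, H2 only kf2, H3 both. H3 with
kf1 = 0 is exactly H2, etc. (nesting is structural, verified by tests).

Whether the drug influx replaces or adds to the basal term is not
determined by the rate equations alone; it is implemented as additive,
which preserves the resting balance at zero dose.

### Resting state and the feedback proxy

The basal model (Table of constants, no feedback terms) holds cAMP at
4 µM and cGMP near 0.4 µM. Because the feedback loops use total cAMP as
PKA proxy, a variant with kf1 > 0 has a slightly lower resting level than
the basal model (the proxy overstates PKA activity at rest). Three
resolutions were examined:

1. re-balance the basal influx per variant (k11 compensates kf1 at rest);
2. fit k11 freely together with the feedback constants;
3. share the basal constants across variants and accept the small resting
   offset under feedback variants.

Options 1 and 2 make (kf1, kf2, k11) statistically near-unidentifiable:
on synthetic studies the maximum-likelihood point wanders far from the
generating values at indistinguishable χ² (the basal constraint or the
free influx absorbs exactly the component of the feedback signal that
separates the loops). This mirrors the classical pattern where each loop
is decisively supported on its own but the second addition is marginal.
Option 3 — the two-stage structure in which the basal model is calibrated
first and its constants enter the drug-response fits as known — keeps the
feedback constants identifiable and is the package default
(`build_default_specs`). The fuller parameter ledger (free basal influx
and active pools) remains available via `fit_basal_influx=True` /
`fit_pools=True`, with this caveat.

Under the default H3 ground truth the resting level of the *generating*
model is ≈3.4 µM rather than 4; every simulated experiment starts from the
resting steady state of its own variant, so generated series are
internally consistent.

### Basal cGMP

With the tabulated pools (active PDE5 = 1 mg/l) the cGMP steady state is
≈0.316 µM, about 21% below the nominal 0.4 µM. `calibrated_basal_state`
solves the active pools from the basal constraints instead (PDE2/PDE3 from
the cAMP balance with an 80% PDE3 share, PDE5 from the cGMP balance,
giving 0.055 / 2.24 / 0.77 mg/l) and then holds both nucleotides exactly.
Both parameterizations are exposed; the tabulated pools remain the default
state.

## Numerics

- **Full-system integration** (`integrate`): LSODA via
  `scipy.integrate.solve_ivp`, rtol 1e-8 / atol 1e-10 by default, with the
  timeline split at stimulus onsets so steps never fall inside an adaptive
  integrator step.
- **Fast reduced path** (`simulate_camp_batch`): with zero interconversion
  rates the cAMP equation is autonomous and scalar; all dose series of a
  study are advanced together as one numpy vector with a fixed-step
  classical Runge–Kutta scheme (default step 0.02 min; 0.05 min in the
  large simulation studies). Agreement with the adaptive full-system
  integrator is ~1e-4 relative (dominated by linear interpolation of the
  dense grid) and is covered by tests. The largest local rate constant in
  the admissible parameter region is ≈35 min⁻¹, well inside the stability
  region at these steps.
- **Steady states**: plateaus are defined as steady states, not fixed
  read-out times. The scalar cAMP plateau is bracketed and solved with
  Brent's method (xtol 1e-12); the full 8-dimensional state (excluding the
  product accumulators AMP/GMP, which grow without bound and carry no
  feedback) uses `scipy.optimize.root` with a long-integration fallback,
  residual tolerance 1e-6 µM/min.
- **VASP phospho-ODE**: linear two-state kinetics per site,
  `df/dt = k_site · A(c(t)) · (1 − f) − k_d · f` with
  `A(c) = c / (c + Ka)` (Hill coefficient 1, Ka = 10 µM default),
  `k157 = r · k239`, r = 15. The cAMP input is linearly interpolated;
  a fixed-step RK4 advances both sites (step 0.005 min). Initial fractions
  default to the stationary values at the first cAMP sample (resting
  platelets carry baseline phosphorylation). Defaults k239 = 0.05 min⁻¹,
  kd = 0.5 min⁻¹ give basal fractions ≈0.30 / 0.03 and minute-scale
  responses; only ordering and shape properties are asserted about them.
- **Synergy**: the constant `k_syn` multiplies the drug-induced AC influx
  whenever an AC stimulator is co-administered with a PDE inhibitor
  (`k_syn = 1.443` for the synergistic pair, 1 for non-synergistic
  pairs). Placing the factor on the stimulated influx preserves all
  single-drug limits exactly, which the zero-dose identities of the
  combination grids test.

## Fitting and model selection

The merit function is the standard chi-square with per-point sigmas,
`χ² = Σ ((y_i − y(t_i, p)) / σ_i)²` — the squared form, which is the
maximum-likelihood estimator under Gaussian errors. Measurement
uncertainty follows the error model `σ = 0.1·y + 0.05·max(y)` evaluated
per series, with a floor of 1e-6 to protect degenerate synthetic series.
Fits consume the per-time means of the triplicates; their σ is the error
model of the means divided by √(replicates) (SEM-style), which makes
χ²/N ≈ 1 the expected fit quality when the model is correct.

Optimization is bounded trust-region least squares
(`scipy.optimize.least_squares`, method `trf`) on transformed
coordinates: log scale for positive-constrained parameters (bounds span
decades), linear scale for the feedback constants. The shared/local
structure is declared to the solver as a jacobian sparsity pattern so
finite-difference columns of independent local parameters are grouped.
Optional restarts perturb the internal coordinates with Gaussian noise
(multiplicative lognormal on positive parameters, scale 0.2) and the best
restart is returned; results are deterministic given the seed, and the
returned χ² is never worse than at the initial guess.

**Sign-free feedback constants.** In hypothesis-testing fits kf1 and kf2
are bounded across zero. The likelihood-ratio statistic of a nested pair
is referred to χ²(df) with df the parameter-count difference; that
reference requires the null value to be interior to the parameter space —
with a kf ≥ 0 constraint the null deviance would follow a ½δ₀ + ½χ²₁
mixture and the test would be miscalibrated. Physical interpretation
(positive loop activates, negative loop inhibits) is imposed on the
defaults and ground truths, not on the test.

Forward selection runs the four nested tests (H1 vs H0, H2 vs H0,
H3 vs H1, H3 vs H2) at α = 0.05 and selects the most complex variant all
of whose additions are significant: if neither single loop improves on
H0, H0 stands; otherwise the better-fitting significant single-loop model
is the candidate and H3 replaces it only if the corresponding test is
significant. AIC is reported as `χ² + 2p`; absolute values differ from a
likelihood-based AIC by a data-dependent normalization constant, so only
differences between models fitted to the same data are meaningful (and
those match the χ²-based differences by construction). Comparisons verify
that both fits carry the same data fingerprint (SHA-256 over ids, times,
values, sigmas).

## The synthetic-study generator

No raw measurements are deposited, so `plateletsig.synth` emulates the
study design: dose series Cilostamide {0.5, 1, 5, 10, 50} µM, Milrinone
{1, 5, 10, 50, 100} µM, Iloprost {1, 5, 10, 50, 100} nM, Forskolin
{1, 3, 10, 30, 100, 200, 500} µM; triplicates at 7 time points
{0, 1, 2, 3, 5, 7, 10} min (the sampling grid is not published; this one
respects the observation that plateaus are approached within about five
minutes); Gaussian noise with the error model above, applied
independently per replicate, truncated at zero for concentrations (and
clipped to [0, 1] for phospho-fractions) with clip counts logged. The
default design yields 22 series × 7 points = 154 fitted points, matching
the scale of the original study (N = 155; the exact per-series breakdown
is not published).

Ground-truth parameters (the fitted values are not published; these were
chosen once to reproduce the reported qualitative behavior):

| parameter | value | anchor |
|---|---|---|
| k_i Milrinone | 2 µM | Milrinone acts more strongly than Cilostamide at comparable doses |
| k_i Cilostamide | 5 µM | hardly any effect at the lowest doses (0.5–1 µM) |
| Iloprost influx | Emax 10 µM/min, EC50 8 nM | saturating plateaus beyond 50 nM |
| Forskolin influx | Emax 247.5 µM/min, EC50 150 µM | ≈700 µM cAMP plateau at 500 µM |
| kf2 | 0.15 min⁻¹ | AC feedback dominant, decisive in selection |
| kf1 | 0.05 µmol·l·min⁻¹·mg⁻¹·µM⁻¹ | +7% PDE3 Vmax at basal cAMP |
| k_syn | 1.443 | synergistic Iloprost × Cilostamide combination |

kf1 deserves a remark: a considerably smaller value (~0.01) also
reproduces the qualitative sweep behavior but is statistically
unidentifiable at the study's noise level (its recovery error is of the
same order as the value itself — the positive loop is the marginal one in
model selection as well). The generator's role here is to define study
conditions under which calibration, recovery and selection are testable,
so the default sits in the identifiable regime while remaining a mild
perturbation at rest.

**What the generator does not emulate:** day/donor effects and batch
structure (replicates are iid), non-Gaussian assay error and detection
limits beyond zero-truncation, receptor desensitization, any
cGMP-stimulation arm, and digitized values from the published figures
(deliberately not reproduced). Passing recovery and selection tests on
these synthetic studies demonstrates the estimator and test machinery
under the stated noise model, not the biology of any particular platelet
preparation.

## Interfaces

Time series travel as long CSV (`experiment_id, drug, dose, dose_units,
time_min, replicate, observable, value`), parsed with exact float
round-trip; model configurations as YAML; fit results as JSON with seed
and data hash embedded. SBML Level 2 Version 4 export writes the ten
species, the constants and the thirteen reactions with exact kinetic-law
MathML (drug and feedback modifications are serialized inside the
affected laws; the kf2 clamp as an explicit piecewise). Import and
simulation are supported for the package's own exports — the MathML
subset the exporter emits — and round-trip within 1e-6. Export covers
step protocols at onset 0; transient profiles have time-dependent inputs
that SBML kinetic laws of this form cannot express.

The package is used from Python; the scripts in `examples/` cover the
workflows (budget calculations, fit + selection, combination surfaces,
VASP, sensitivity, SBML round trip) that a command-line front end would
otherwise wrap.

## Problem sizes used in the statistical test suites

Parameter recovery fits the both-feedback variant to 20 independent
synthetic studies at full design size (154 points, 16 free parameters);
model recovery runs the full four-variant selection on 50 studies
generated under the single-loop H2 truth; the LRT null calibration uses
250 studies from a 5-series AC-only sub-design (35 points) generated
under H0, testing H2 vs H0. These sizes give the medians and rates
asserted by the tests stable sampling error at interactive runtimes.

## Known limitations

- PKA/PKG are proxies, not states; saturation of kinase activity enters
  only through the VASP activity function, not the feedback loops.
- Molar PDE concentrations are not computed (molecular weights are not
  part of the parameterization); all enzyme kinetics run on mass
  concentrations.
- The AC-inhibitor dose-response is a one-parameter saturating
  reduction of basal synthesis — a placeholder mechanism constrained only
  by qualitative antagonism.
- The χ²(df) reference for the LRT is asymptotic; on heavily truncated
  series (strong noise near zero) mild anti-conservativeness of the
  H3-vs-H2 test is measurable (~7% at nominal 5% on the full design).
- Plateaus are true steady states; experimental "plateau at 5 minutes"
  read-outs can sit slightly below them for slowly relaxing doses.
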