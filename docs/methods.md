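# Methods

## The model

`ifndyn` implements a population-level ordinary-differential-equation model
of type-I interferon (IFNα) production by TLR-stimulated immune cells
(primarily plasmacytoid dendritic cells).  The population is partitioned
into three fates: a small fixed fraction *fr* of **first responders** that
activate directly upon stimulation, a pool of up to *sr* **second
responders** that activate only once paracrine IFNα signalling crosses a
threshold, and non-responders.  The states are the activated fractions f1
and f2 and the supernatant concentration [IFN]:

    df1/dt   = kon (fr − f1) − koff f1
    df2/dt   = kon · h([IFN]) (sr − f2) − koff f2
    d[IFN]/dt = kf (f1 + f2) − df [IFN]

with the Hill gate h(x) = x^H / (T^H + x^H).  The measured observables are
the percent IFNα-positive cells, 100·(f1+f2), and [IFN] itself (pg/mL,
identified with the ELISA readout with no scale factor; an explicit
calibration layer was considered and rejected as unidentifiable from the
available observables — the threshold T absorbs any common scale).

Model assumptions worth keeping in mind:

* Stimulus is implicit.  There is no stimulus state variable; stimulus
  identity and dose enter through the parameters (chiefly kon, and through
  the fitted dose dependence of T, koff, kf).
* Both responder types turn off at the same rate koff, and turned-off
  cells can re-activate (the equations relax toward an equilibrium rather
  than depleting an irreversible pool).
* Well-mixed supernatant: every cell sees the same [IFN]; no spatial or
  droplet topology, no TNFα compartment, no intracellular signalling
  detail (IFNAR/JAK/STAT are outside the model).

### Parameters, units, defaults

| parameter | meaning | units | population default |
|---|---|---|---|
| fr | first-responder fraction | – | 0.01 |
| sr | potential second-responder pool | – | 0.5 |
| kon | activation rate | 1/h | fitted (0.4 CpG-C, 1.5 R848) |
| koff | turn-off rate | 1/h | fitted, dose-dependent |
| kf | secretion rate per activated fraction | pg/mL/h | fitted (6600; 2000 at 50 µg/mL CpG-C) |
| df | IFNα consumption/degradation | 1/h | fitted (0.04) |
| T | activation threshold of second responders | pg/mL | fitted, dose-dependent |
| H | Hill coefficient | – | fitted (4) |

The four fitted regimes (`ifndyn.FITTED_REGIMES`) encode the dose-response
result this package reproduces: between CpG-C dosages only T and koff
change (440/0.2 → 230/0.33 → 20/2.0 going up in dose, with kf additionally
dropping to 2000 at the highest dose), while R848 shares the low threshold
of high-dose CpG-C but activates much faster (kon = 1.5/h, koff = 1/h).
The reading of kf as a secretion rate (it multiplies f1+f2 as a source)
and df as first-order loss follows directly from their positions in the
equations.

## Numerics

* **Initial condition** (0, 0, 0) at stimulus addition: the rest state is
  the only biologically sensible pre-stimulation state and makes the
  "first wave" narrative literal.
* **Integration**: adaptive LSODA (via `scipy.integrate.odeint`) at
  rtol 1e-8 / atol 1e-10 for reporting.  LSODA was chosen over an explicit
  adaptive Runge–Kutta after measuring a ~10× lower per-solve cost on this
  3-state system (≈1 ms per 0–26 h solve), which matters because recovery
  studies run ~10⁵ solves.  The system is non-stiff at all fitted regimes;
  integration failure raises, never degrades to NaN.  A fixed-step RK4
  reference (dt = 1e-3 h) serves as an independent oracle in the tests.
* **Invariant box**: 0 ≤ f1 ≤ fr, 0 ≤ f2 ≤ sr, [IFN] ≥ 0 is forward
  invariant in exact arithmetic (at f1 = fr the derivative is −koff·fr).
  After integration every reported state is checked against the box with
  slack proportional to the integration tolerance; sub-tolerance
  excursions are clipped, larger ones raise.
* **Hill gate at 0**: computed as exactly 0 (avoids 0^H/0 for non-integer
  H); H is a positive real ≥ 1, not restricted to integers, because
  fitting explores non-integer values.
* **Steady state**: f1* is closed-form; (f2*, [IFN]*) by bracketed Brent
  root finding on the scalar fixed-point equation, residual < 1e-9
  relative.  Used as a simulation oracle, not in fitting.

## Fitting

The published analysis minimised least squares with a spreadsheet GRG
solver.  Here the objective is the sum over conditions, time points and
both observables of squared residuals, with each observable divided by its
maximum observed value across the fitted conditions so that percentages
(≈0–40) and concentrations (≈0–10⁵ pg/mL) contribute comparably.  The
weighting scheme is pluggable (`unit` retains raw units) and recorded in
the result.  The paper does not state its weighting; this is the package's
own declared choice.

* **Censoring**: concentration points below the ELISA limit of
  quantification enter one-sidedly — zero residual while the model is
  below the LOQ, else (model − LOQ), scaled.  This is the standard
  treatment of left-censored assay data without introducing a likelihood.
* **Roles**: each parameter is Fixed(value), Shared(group) or Free
  (condition-specific); fr and sr default to Fixed(0.01)/Fixed(0.5).
* **Optimiser**: positive parameters spanning decades are optimised in
  log-space within generous bounds (kon, koff ∈ [1e-3, 1e2] 1/h;
  T ∈ [1e-1, 1e5] pg/mL; H ∈ [1, 8]; kf ∈ [1, 1e6] pg/mL/h;
  df ∈ [1e-4, 10] 1/h) by trust-region-reflective least squares with 16
  multistarts: start 0 at the log-midpoint of the bounds, the rest drawn
  log-uniformly from the spec's seed.  Ties between equal-objective
  restarts resolve to the lowest index; identical seed and spec give
  bit-identical results.
* **Finite differences and inner tolerance**: during optimisation the ODE
  runs at rtol 1e-6 and Jacobians use a relative step of 1e-4 in
  log-space, large enough that the differenced signal dominates
  integration error — without this the trust-region steps stall in the
  narrow kon/H/T valley of the joint fit.  The reported objective is
  re-evaluated at the reporting tolerance.
* **Parsimony**: nested families of specs (each freeing a superset of
  condition-specific parameters) are ranked by objective versus the number
  of condition-specific parameters; the smallest member within a factor
  1.05 of the fully-free member is flagged.  In the dose-response scenario
  later family members are warm-started from the previous member's
  optimum.
* **Profiles**: `profile_parameter` pins one free parameter on a grid and
  re-optimises the rest — the standard identifiability diagnostic.

## Synthetic data

The generator emulates the statistical structure of the assays, not their
biology:

* **Flow cytometry**: percent positive is 100·k/n with
  k ~ Binomial(n_cells, f1+f2); the default well of 25,000 cells makes
  counting error the irreducible floor (~0.09 percentage points SD at 2%
  positive).  No spillover/compensation or gating artefacts.
* **ELISA**: multiplicative lognormal noise with unit median and CV 5% by
  default; left-censoring at LOQ 12.5 pg/mL (IFNα).  The TNFα LOQ
  (7.8 pg/mL) is carried in the interface for completeness only — no TNFα
  model exists here.
* **Replicates**: 3 by default (the smallest replicate count the
  experimental legends report).  Replicates are averaged into one
  observation set per condition with SEM per point; a point is flagged
  below-LOQ iff *every* replicate fell below, in which case the reported
  mean is exactly the LOQ.  Partial censoring therefore biases the mean
  slightly upward, as it does in real reporting.
* **Donor effects**: real per-point error bars are spread across donors,
  not wells.  A lognormal donor effect on kon is stubbed
  (`donor_cv_kon`) but disabled by default; parameter recovery results do
  not cover donor heterogeneity.

Because the generator's truth is the model itself, passing recovery tests
demonstrates identifiability of the parameters from data of this shape and
noise level — not correctness of the model for real cells.

## Validation protocol and problem sizes

The headline validation is parameter recovery: generate noisy synthetic
data at a fitted regime (hourly 0–26 h, 3 replicates, default noise),
refit with the regime's free/shared structure, and take the median
recovered value over 20 independently seeded repetitions.  Recovery
studies derive per-repetition data and fit seeds from one base seed via
`numpy.random.SeedSequence`.  The dose-response parsimony scenario in the
test suite uses 8 multistarts per family member with warm-start chaining
(selection among nested structures needs basin identification, not final
polish); single-structure recovery fits use the default 16.

## Known limitations

* The model has no TNFα compartment and no crosstalk terms; priming
  effects appear only as the fold-change data transformations in the
  pipeline module (`fold_change`, `randomized_pairing_fold_change`, with
  random pairing done without replacement when replicate counts match).
* `replicate_spread` is the sample SD (n−1 denominator); published spread
  values from raw replicate data cannot be re-derived here and are not
  asserted anywhere.
* koff/kon can trade off when both are free in a single condition; T and
  kf are the best-identified parameters.  df is weakly informed within a
  26 h window (decay timescale 25 h) and is best recovered jointly across
  conditions.
* The objective treats replicate means as homoscedastic within an
  observable; per-point SEMs are carried through the containers but not
  used as weights (the published fit gives no indication of SEM
  weighting).
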