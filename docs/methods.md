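# Methods

## The model

`ironpbpk` implements a whole-body, perfusion-limited physiologically based
pharmacokinetic (PBPK) model of intravenous iron. The body is a single
plasma pool connected in parallel to twelve perfused organ compartments
(brain, bone, fat, gut, heart, kidney, liver, lung, muscle, skin, spleen,
and a lumped "remainder"), plus a circulating red-blood-cell (RBC) iron
pool. All fluxes are linear in the compartment amounts, so the state vector
A (µmol) obeys

    dA/dt = M · A,

with a constant generator matrix M assembled in `model_core.build_rate_matrix`.
The fluxes are:

| flux | rate |
|---|---|
| plasma → organ O | Q_O · C_P |
| organ O → plasma | (Q_O / KP_O) · C_O |
| gut, spleen → liver (portal) | (Q_O / KP_O) · C_O |
| bone → RBC pool (erythropoiesis) | Q_E · C_bone |
| RBC → spleen (erythrophagocytosis) | RBC / T_RBC |
| plasma → cumulative loss | CL_loss · C_P |
| FCM depot → spleen (FCM variant) | Q_spleen · A_depot / V_plasma |

where C_X = A_X / V_X, Q_O is the organ plasma flow (L/h), V_O the organ
volume (L), and KP_O the dimensionless tissue:plasma partition coefficient.
Perfusion limitation is the structural assumption: after an IV iron dose,
transferrin saturates and non-transferrin-bound iron is taken up
efficiently, so distribution is flow-limited rather than permeability-
limited. Transferrin speciation, hepcidin feedback, saturable uptake, and
oral absorption are deliberately outside the model.

Two readings of the plasma mass balance are possible: plasma outflow written
against the nominal cardiac output, or as the sum of the organ inflows. Only
the flux-graph reading (sum over organ flows) conserves mass, because each
organ receives exactly Q_O · C_P; the package therefore closes the balance
over the per-organ flows and carries cardiac output as metadata. Portal
organs (gut, spleen) drain into the liver only and are excluded from the
plasma-return sum, so no flux is counted twice. The lung is a parallel
perfused compartment with its tabulated flow, not an in-series pulmonary
compartment. The cumulative loss is an explicit sink state, which makes
every column of M sum to zero — conservation holds identically, and the
simulator verifies it at run time (tolerance 1e-6 relative).

A consequence of the portal topology worth noting: at stationarity of the
closed system (CL_loss = 0) every simple organ equilibrates at C_O/C_P =
KP_O, bone at Q_B·KP_B/(Q_B + KP_B·Q_E), but the liver sits *above* its KP
at KP_L·(Q_L + Q_G + Q_S + Q_E·C_B/C_P)/Q_L, because it must clear the
portal and erythrophagocytic return flux as well as its own arterial inflow.
`steady_state_ratios` returns these analytic ratios and is cross-checked
against long-horizon integration.

The RBC pool is carried as an amount (µmol), not a concentration — its
balance equation has no volume — and observed "RBC iron content" maps to
this amount; all other observations are concentrations. The iron-
carbohydrate complex (ferric carboxymaltose, FCM) is modelled as a depot
whose macrophage-mediated uptake is assigned the spleen blood flow: the
depot is referenced to plasma volume and drains into the spleen at rate
Q_spleen/V_plasma. A direct depot→plasma release path is deliberately
absent (its contribution is on the order of 0.1% of dose and is not
identifiable from the available data).

Endogenous baseline iron is not modelled: the mouse data the design
emulates are ⁵⁹Fe radiotracer measurements, so the initial state is zero.
For FCM serum datasets an optional additive serum baseline is available in
the error model (default off).

### Units and physiology

Canonical internal units are µmol, L, h; mg Fe ↔ µmol conversion uses the
iron molar mass 55.845 g/mol. Dose inputs accept µmol, mg, µmol/kg, mg/kg.
The mouse physiology preset (25 g, plasma 1.09 mL, per-organ volumes and
flows) is the study physiology. The rat (0.345 kg, CO 6.624 L/h) and human
(73 kg, CO 336 L/h) presets carry the study body weights and cardiac
outputs, but their organ volumes and flows are *reconstructed* from
standard reference compilations of fractional organ weights and fractional
cardiac output — they are clearly marked as such in the YAML headers and
are not measured values. A 70 kg human alternate is obtained by editing
`body_weight`.

### Numerics

The simulator (`simulate`) integrates the stiff linear system with LSODA
(analytic Jacobian, rtol 1e-8, atol 1e-12 µmol, generous step budget);
flow/volume ratios span more than four orders of magnitude, so a
stiff-capable method is required. Bolus doses are handled by restarting the
integration at each dose time; output times at a dose instant report the
post-dose state. An independent solution path (`simulate_matexp`) evaluates
the exact piecewise solution A(t) = expm(M Δt) A(t₀) and shares no numerics
with the ODE path; the two agree to ≲1e-8 of the dose over random
admissible parameter draws and serve as mutual cross-checks in the test
suite. One known limit: when a partition coefficient is within roundoff of
zero (the fitted remainder KP of ~1e-9 implies a return rate of ~1e10 h⁻¹),
the scaling-and-squaring matrix exponential loses accuracy (~1e-5); its
built-in mass-balance guard then raises rather than returning degraded
trajectories. The ODE path handles that regime correctly.

## Estimation

Observed group means are fitted by naive-pooled maximum likelihood: all
records are treated as one individual and the likelihood is a product of
Gaussian residual densities, proportional (variance σ₁²·Ŷ²) or additive
(variance σ₂²) per compartment. Proportional error everywhere is the
default; assignments are configurable per compartment. With no random
effects this pooled ML is exactly what conditional-estimation machinery
reduces to for mean data.

Fitting (`fit_naive_pooled`) minimizes −2 log L over log-transformed free
parameters (L-BFGS-B; positivity by construction). Residual variances are
not optimizer coordinates: they are profiled out in closed form per sigma
group (σ̂² is the mean squared (weighted) residual), which is equivalent at
the optimum and shrinks the search space. By default one sigma is shared by
plasma/serum/RBC ("blood") and one by all tissues, to keep the variance
count small; fully configurable. Fixed sigmas can be supplied instead —
this is what the noise-free recovery test uses, since the profiled variance
degenerates at zero residuals. A subtlety of the proportional model worth
knowing: with fixed σ the 2·log Ŷ term in the objective biases the optimum
O(σ²) below the data, so exact-data recovery checks use a small σ (1e-3).

Multi-start (default 5 log-normal jittered starts, seeded) guards against
local minima; the best start wins and the reported optimum is never worse
than the initial point. Convergence is declared on objective stagnation
(ftol 1e-11) or a small remaining gradient; a line-search stall at the
finite-difference noise floor of the ODE solver is treated as convergence,
not failure. The fit is deterministic given data, init, and seed, and
invariant to record order up to float summation order.

Standard errors (`compute_rse`) come from the inverse observed information:
a central-difference Hessian of half the (profile) −2 log L in log-parameter
space, computed in-package (small dense problem). By the delta method
SE(θ) = θ·SE(log θ) and RSE% = 100·SE(log θ). A singular or indefinite
information matrix yields "undefined" with a warning, never fabricated
numbers. `gof_table` emits observed/predicted/residual/weighted-residual
records for identity-line and residual diagnostics.

### Identifiability

The remainder compartment is never observed. At the iron-adequate and
iron-loaded presets its fitted KP is ~1e-9–1e-8 — effectively zero — and the
likelihood is flat in that coordinate: a compartment that holds no iron
leaves no signature in the observed compartments. KP_remainder is kept free
in every fit for faithfulness, but recovery guarantees apply to the
identifiable set (observed-tissue KPs, CL_loss, Q_E, T_RBC). In the
iron-deficient state KP_remainder ≈ 4.9 makes the remainder the largest
tissue store and fully identifiable.

## Interspecies scaling

The chain is mouse → rat → human (`interspecies`):

* cardiac output scales linearly with body weight, Q2 = BW2·Q1/BW1;
* Q_E scales with RBC lifespan, Q_E(target) = Q_E(source)·(T_RBC,target /
  T_RBC,source)^b with b fixed at 0.75; body-weight-based allometry of Q_E
  is intentionally not provided (the lifespan rule supersedes it);
* the rat model inherits every mouse KP and CL_loss, flags the six
  experimentally observed rat tissues (bone, liver, spleen, heart, muscle,
  kidney) for re-estimation, and uses the FCM depot route;
* the human model inherits KP and CL_loss rat-first with mouse fallback,
  fixes T_RBC at 2880 h (120 days), and takes Q_E from the *mouse* value via
  the lifespan rule. Nothing is estimated on human data.

Choices made where the design was open: the rat inherits the mouse
iron-deficient column (the rat study animals were iron-deficient); the Q_E
allometry anchors on the iron-adequate mouse column (the deficiency states
alter Q_E pathologically); the rat's own T_RBC, nowhere reported, defaults
to 1440 h (60 days, the standard rat RBC lifespan) with Q_E scaled
accordingly. All three are configurable.

## Synthetic studies

`synthetic_data` emulates the three study designs so the pipeline is
testable end to end: the mouse tracer study (0.2 µmol/kg bolus — the
figure caption's 0.02 µmol/kg variant is available through the dose
parameter — 3 diet states, 13 compartments, sampling at 0.25/12/24/96/168/
336/672 h), the rat FCM study (30 mg Fe/kg depot dose, serum + 6 tissues),
and the human single-ascending-dose FCM study (100/500/800/1000 mg, serum
only). Rat and human sampling grids are geometric reconstructions
(0.25–72 h and 0.25–168 h) — the real grids are not reported. Noise is
drawn from the residual model; σ = 0.05–0.15 is a testing convention, not a
reported value. Negative draws are redrawn rather than truncated (keeping
the error model honest) and the redraw rate is recorded in the manifest
(<1% for σ ≤ 0.2). Generators emit either per-time-point means (default,
mirroring digitized mean data) or every replicate. A fixed seed makes the
output byte-identical.

What the generator does *not* emulate: digitization error, inter-animal
variability collapsed into means, model misspecification, and sparse
terminal-phase sampling bias. Passing recovery tests therefore demonstrate
the correctness and stability of the estimation machinery under the model's
own assumptions — not that the model is right for real data.

## Recovery experiments and problem sizes

The headline validation (`workflows.run_recovery_experiment`, also driven
by `scripts/acceptance.py`) is seeded simulate-and-refit: per diet column,
10 derived seeds; per seed, 3 noisy replicates of the 13×7 observation grid
at 5% proportional noise (819 records), a log-normal jitter (sd 0.3) of the
generating values as the starting point, and a single-start fit of all 15
parameters with profiled variances. Medians across seeds recover the
generating RBC lifespan, Q_E, CL_loss, and liver/bone KPs to within a few
percent. These sizes (10 seeds, 3 replicates, single start) keep one full
experiment at roughly a minute per diet column on one CPU.

## Known limitations

* Single-dose designs only are emulated; nothing here validates multi-dose
  extrapolation.
* The remainder-KP flat direction (above) means full-vector recovery claims
  exclude that coordinate outside the iron-deficient state.
* The matrix-exponential path refuses (by raising) the near-zero-KP regime.
* Rat/human physiology presets are literature-style reconstructions; any
  quantitative use for those species should substitute measured physiology
  via the YAML schema.
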