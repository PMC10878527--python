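# Methods

## The model

The package implements a deterministic, well-mixed compartment model of the
unliganded VEGF receptor network on a human endothelial cell.  Three
receptors — VEGFR1 (the membrane-integral mFlt1 splice form), VEGFR2 and
the co-receptor Neuropilin-1 (NRP1) — are produced at constant zeroth-order
rates directly into the plasma membrane, couple reversibly into complexes,
and move between three live compartments: the cell surface, Rab4a/5a early
endosomes and Rab11a recycling endosomes.  A fourth, cumulative compartment
records degraded receptors and never feeds back.

Coupling follows two independent pairwise interactions: VEGFR1 and VEGFR2
homodimerize, and each VEGFR1 protomer binds NRP1.  VEGFR2 does not couple
to NRP1 or VEGFR1 without ligand.  This yields eight species (R1, R2, N1,
R1·R1, R2·R2, R1·N1, R1·R1·N1, R1·R1·N1·N1); with three live compartments
and eight degraded pools the state vector has 32 entries.  Rule expansion
produces 85 mass-action reactions: 3 production, 40 trafficking/degradation
(five first-order processes — internalization k_int, fast recycling k_rec4,
transfer k_4to11, slow recycling k_rec11, degradation k_deg — applied to
eight species), and 21 coupling plus 21 uncoupling reactions (seven rules in
three compartments).  Complexes containing VEGFR1 traffic with VEGFR1 rate
constants; the VEGFR2 dimer with VEGFR2 constants; free NRP1 with its own.

Two conventions matter downstream:

* **Homodimer rate law.** Dimer formation is kc·[M]², dissociation kd·[D],
  so K_d = kd/kc in per-cell units.  Statistical factors then follow from
  site counting *under this convention*: NRP1 binds the free dimer at 2·kc
  and the singly-occupied dimer at kc; both NRP1s of the full complex
  dissociate (2·kd); and the R1–R1 bond between two *distinguishable*
  partners (R1·N1 + R1) forms at 2·kc while two identical R1·N1 partners
  combine at kc·[R1N1]².  These are the unique factors for which every
  coupling cycle satisfies detailed balance, which the test suite verifies
  against the closed-form equilibrium.
* **Area scaling.** Coupling constants are given per unit membrane area
  ((molec/µm²)⁻¹s⁻¹) and divided by the compartment's area, so the same
  biophysical affinity is more potent in small endosomes.  Defaults: surface
  1000 µm², each endosome compartment 100 µm² (configurable; the surface
  value makes a base constant of 1e-4 correspond to 1e-7 (molec/cell)⁻¹s⁻¹).
  With kd = 0.01 s⁻¹ and kc_R1N1 = 8e-4, the effective surface K_d of the
  VEGFR1–NRP1 interaction is 12,500 molecules/cell.

Because every VEGFR1-containing species traffics at VEGFR1 rates, the
compartment totals of VEGFR1 (and of VEGFR2) obey a closed three-compartment
linear system even with coupling on; only NRP1 mixes rates through its
complexes.  This is exploited twice: the production rates of VEGFR1/VEGFR2
have a closed form (k_prod = S·k_int·k_deg/(k_rec4+k_4to11+k_deg) for a
surface target S), and the linear system provides an independent
matrix-exponential oracle for the integrator.

## Numerics

The 32 ODEs are integrated with LSODA and an analytic Jacobian (BDF for the
steady-state fallback); default tolerances rtol 1e-8 / atol 1e-6 molecules,
relaxed to rtol 1e-6 / atol 1e-3 inside the calibration loop.  Steady states
are found by a damped Newton solve (MINPACK hybr) on the 24 live states
starting from the closed-form monomer solution, with a staged long-time
integration fallback (10⁶–10⁸ s; slow modes arise when a degradation
constant approaches the 1e-6 s⁻¹ bound).  The residual is accepted when its
infinity norm is below 1e-9 of the total production flux.  A numba-compiled
right-hand side and Jacobian back both paths, with the pure-numpy
implementation retained as reference.

## Calibration

The dataset contains 24 observations — per receptor: absolute surface count
(1800 / 4900 / 68,000 receptors/cell), surface percentage (10 / 51 / 74%),
whole-cell fold change after an 80% Rab4a+Rab11a double knockdown (1.0,
read out at 18 h), and a five-point cycloheximide (CHX) chase at 1, 2, 4, 8,
24 h.  The CHX targets are exponential-decay values at the measured
half-lives: 45 min for VEGFR1, 82.5 min for VEGFR2 (midpoint of the reported
75–90 range), and flat 1.0 for NRP1.

Fifteen trafficking constants are free, bounded in [1e-6, 1e-1] s⁻¹.  The
three production rates are not free: an inner loop re-solves them for every
candidate so that steady-state surface counts match the surface-count
observations exactly (closed form for VEGFR1/VEGFR2; a bracketed monotone
1-D solve for NRP1, whose surface level is strongly superlinear in its
production once free NRP1 outruns the VEGFR1 coupling sink).

The outer problem is least squares on relative residuals
(prediction − observation)/max(observation, 0.05).  The 0.05 floor acts as a
densitometry detection limit: a fast receptor many half-lives into a CHX
chase has a true fold change near 1e-10, and a pure relative residual there
would dominate the cost with physically meaningless precision.  Counts and
percentages sit far above the floor and keep pure relative scaling.

Optimization is Levenberg–Marquardt in log10 parameter space (preserving the
named algorithm while honouring the bounds, which are enforced by clipping
plus a soft penalty residual).  Finite-difference steps are set to 1e-3 in
log10 space — well above the ODE-solver noise floor of ~1e-5 on the
residuals; with the scipy default step (~1e-8) the gradient estimates are
noise and LM stalls far from any optimum.  Each start is capped at 100 outer
residual evaluations (each LM iteration adds 15 finite-difference
evaluations); this is the main runtime knob at the default ensemble size and the dominant cost of
the pipeline (a 20-start fit takes a few minutes on one core).  A start
counts as a successful optimization only if its final RMS relative residual
is below 30%; starts stranded in pathological corners finish orders of
magnitude above this bar and are excluded from summaries.

The consensus parameter set takes the per-parameter median in log10 space
over successful starts (the geometric mean is also exposed), then re-solves
the production rates — so consensus surface counts always sit on the
calibration targets.

The median set is an *estimate to be tested against the data*, and the test
is part of the pipeline.  Several trafficking parameters (most notably the
recycling split of NRP1 and VEGFR2) are only weakly identified by the 24
observations: successful starts scatter along flat, curved ridges of the
cost surface, and a coordinate-wise median of points on a curved manifold
need not lie on the manifold.  At the default ensemble size of 20 starts
this can produce a median set whose predictions resemble no member of the
ensemble (for instance, an NRP1 surface percentage of 5% when every member
predicts 74%, because the median combination routes free NRP1 into a
Rab11a compartment with a near-zero exit constant that no single fit has).
``summarize_fits`` therefore validates the median set — it must fit the
data at least as well as the worst accepted member — and falls back to the
log-space medoid (the converged fit nearest the median) when the test
fails.  The medoid is a realized optimization, so its predictions are
always coherent; the per-parameter percentile table is reported from the
full ensemble either way.

## Perturbation protocols

Perturbations are declarative multiplicative parameter edits applied from
the protocol's t = 0, with the pre-perturbation steady state as the initial
condition (no drug pharmacokinetics):

* **CHX** zeroes all three production rates.
* **CHQ** multiplies every k_deg by (1 − f), f the inhibition fraction; the
  transport module estimates f from an observed whole-cell fold-change
  series by a bounded 1-D least-squares fit with all other parameters held
  fixed.
* **siRNA** scales the targeted recycling machinery to 0.2 (an 80%
  knockdown).  Rab4a knockdown scales both exits of the Rab4a endosome that
  the recycling machinery mediates — k_rec4 *and* k_4to11 — and Rab11a
  knockdown scales k_rec11.  This mapping was chosen over the alternative
  (k_4to11 unscaled) on model-consistency grounds: with k_4to11 unscaled, a
  double knockdown inflates the Rab11a pool of any receptor with
  substantial slow-route recycling roughly five-fold, predicting a large
  whole-cell increase that is incompatible with the observed flat response —
  which in turn forces any fit toward zero recycling.  With both Rab4a
  exits scaled, the Rab11a pool is invariant under the double knockdown and
  high-recycling parameter sets reproduce the observed "essentially
  unaffected" whole-cell levels.  The alternative mapping remains available
  (`PerturbationSpec.sirna(..., scale_transfer=False)`).

## Sensitivity analysis

Local sensitivities are one-at-a-time forward differences at +5%
(%Δ output / %Δ parameter) on the 18 fitted parameters, with outputs
(total, surface, internal, %surface per receptor) evaluated at the new
steady state and production treated as a free parameter (no inner
re-solve).  The global scan varies each parameter over 1e-2–1e2 times its
optimized value on a 9-point log grid (the grid always contains 1), holding
production at the scanned value, and records the cost and all 24
dataset-matched predictions, including the CHX and siRNA protocol
responses.  One-at-a-time variation is used throughout; parameters are
never varied jointly.

## Transport-rate analysis

Overall process rates are rate constant × stoichiometry-weighted pool
(receptors/cell/s); at steady state the per-compartment net rates vanish,
which is asserted to 1e-6 of the production flux.  Surface residence
half-life is ln 2/k_int.  The recycling:degradation ratio is reported
primarily as the rate-constant ratio (k_rec4 + k_4to11)/k_deg; because both
recycling routes and degradation drain the same Rab4a pool, the
flux-weighted variant coincides with it for VEGFR1 and VEGFR2 (whose
complexes all share their own constants) and legitimately differs for NRP1,
whose complexed fraction moves at VEGFR1 rates; both are exposed.  Coupling equilibria (trafficking off) have closed forms —
the homodimer quadratic, the 1:1 hetero-binding quadratic, and the full
detailed-balance system solved for the two free monomer concentrations —
used both as analysis operations and as oracles for the ODE path.  The
effective 2:2 NRP1–VEGFR1 affinity K_d,eff is computed numerically from the
clamped-NRP1 equilibrium occupancy rather than an assumed closed form.

## Synthetic data

The generator replaces the wet-lab inputs: a ground-truth parameter set
(trafficking log-uniform within the fit bounds; production solved for the
published surface densities) is pushed through the same simulation pipeline
as the calibration predictions, and multiplicative log-normal noise with
unit mean and fixed CV (default 0.15) emulates western-blot densitometry —
strictly positive, roughly constant relative error, applied per band.  The
surface/internal split emulates the biotin-labeling assay (eluate and
flow-through resuspended in equal volumes, so band intensities are
proportional to the pools).  Every table is reproducible bit-exactly from
(truth, seed).

What the generator does *not* emulate: replicate-level correlation
structure (same-blot bands share a loading-control error), antibody
nonlinearity and saturation, partial biotinylation efficiency, and any
receptor regulation feedback (e.g. production down-regulation under
accumulation).  Passing recovery tests therefore show the estimator is
consistent under the model's own assumptions, not that those assumptions
hold for real blots.

## Design choices and limitations

* The calibration targets idealize the reported summary statistics (exact
  exponential CHX decay, an exactly flat knockdown response).  The model's
  own CHX curves are not single exponentials (internal pools lag), so the
  optimizer prefers parameter regions that mimic the idealized shapes; in
  particular, because any VEGFR1 recycling slightly worsens both the
  knockdown and CHX fits of the idealized dataset, the fitted VEGFR1
  recycling:degradation ratio collapses toward zero rather than the ~5:1
  regime that real band data support.  Likewise the VEGFR2 internalization
  constant sits on a flat ridge (fast-cycling solutions with a large
  k_rec11 keep the Rab11a pool negligible and evade the knockdown datum),
  so the fitted VEGFR2 surface residence time is only loosely determined
  (~17–45 min across ensembles).  With the default 20 starts the recycling
  split (k_rec4 vs k_4to11 vs k_rec11) carries 5th–95th percentile bands of
  two or more decades.
* The published pool sizes are not mutually consistent to better than ~20%:
  1800 surface VEGFR1 at 10% surface implies a 16,200 intracellular pool
  (not the reported 18,000), and 68,000 surface NRP1 at 74% implies 23,900
  (not the reported 30,000).  The calibration uses the surface counts and
  percentages; derived pools land on the implied values.
* Degenerate inputs: zero degradation with nonzero production has no steady
  state and is reported as such; zero control values are rejected by
  normalization; CHQ series below 1.0 clip the inhibition estimate at 0 and
  are flagged.
* No ligand binding, phosphorylation, ER/Golgi transit, stochasticity or
  cell-to-cell variability; concentrations are well mixed within each
  compartment.
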