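# vegfr-trafficking

A mechanistic model of how human endothelial cells traffic their VEGF
receptors.  VEGFR1, VEGFR2 and the co-receptor Neuropilin-1 (NRP1) are not
static surface proteins: they are continuously produced, internalized into
Rab4a/5a early endosomes, recycled back to the surface directly or through
Rab11a recycling endosomes, and degraded.  Where a receptor sits determines
whether it can see extracellular ligand, so the steady-state split between
surface and intracellular pools — strikingly different for the three
receptors (~10% of VEGFR1 on the surface, ~51% of VEGFR2, ~74% of NRP1) —
is a quantity worth a quantitative model.

The package is for computational biologists who want to simulate, calibrate
or interrogate this trafficking network: it builds the reaction network from
rules, integrates it, fits its rate constants to measurement sets,
quantifies parameter sensitivity and identifiability, and analyses the
resulting transport fluxes.

## The model in brief

Eight molecular species (R1, R2, N1 monomers; R1·R1 and R2·R2 dimers;
R1·N1, R1·R1·N1, R1·R1·N1·N1 complexes — VEGFR2 does not couple to the
others without ligand) in three live compartments plus a cumulative
degraded pool give a 32-dimensional mass-action ODE system with 85
reactions.  Per receptor, five first-order trafficking constants
(k_int, k_rec4, k_4to11, k_rec11, k_deg, all s⁻¹) and a zeroth-order
production rate k_prod (molecules·cell⁻¹·s⁻¹) govern transport; reversible
coupling uses area-scaled rate constants (K_d = k_d/k_c).  Calibration fits
the 15 trafficking constants to 24 observations (surface counts, surface
percentages, Rab4a+Rab11a knockdown response, cycloheximide chase curves)
by multistart Levenberg–Marquardt in log space, with the 3 production rates
re-solved in an inner loop so steady-state surface counts always match the
measured densities (1,800 / 4,900 / 68,000 receptors per cell).  See
`docs/methods.md` for the full account.

## Worked example

Build the network and compute the calibrated baseline steady state:

```bash
python analysis/01_build_network.py
python analysis/02_baseline_steady_state.py
```

which prints

```
85 reactions over 32 state entries:
  production 3, trafficking+degradation 40, coupling 21, uncoupling 21
steady-state pools (receptors/cell):
          surface     rab4    rab11  internal     total  degraded
receptor
R1         1800.0   8096.9   8096.9   16193.8   17993.8       0.0
R2         4900.0   4271.3    427.1    4698.5    9598.5       0.0
N1        68000.0  21110.8  14571.4   35682.2  103682.2       0.0
  R1: 10.0% on the surface
  R2: 51.0% on the surface
  N1: 65.6% on the surface
```

The surface rows are pinned to the measured densities by the
production-rate solve; the internal pools and percentages are model
predictions from the reference rate constants (VEGFR1 overwhelmingly
intracellular, VEGFR2 evenly split, NRP1 surface-biased; NRP1's percentage
moves to ~74% once its trafficking constants are fitted rather than taken
from the reference table).  The same calculation from Python:

```python
from vegfr_trafficking import (
    expand_reactions, reference_parameters, solve_production_rates,
    steady_state, aggregate,
)

network = expand_reactions()
params = reference_parameters()
params = params.with_values(solve_production_rates(params, network))
report = aggregate(steady_state(params, network))
print(report.to_frame())
```

The remaining drivers run the calibration (`03_fit_trafficking.py`,
~8 min for 20 starts), sensitivity analyses (`04_sensitivity.py`),
transport-rate analysis (`05_transport_rates.py`) and the chloroquine
inhibition-fraction round trip (`06_chq_inhibition.py`); each writes tidy
CSV/JSON tables under `results/`.  A thin CLI wraps the same operations
(`vegfr-traffic simulate|fit|sensitivity|report|synth`).

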