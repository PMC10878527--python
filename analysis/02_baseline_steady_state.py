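"""Baseline steady state with the reference parameter set.

Solves production rates against the published surface densities
(1800/4900/68000 receptors per cell for VEGFR1/VEGFR2/NRP1), finds the
steady state, and writes the aggregate pools and resolved parameters to
results/baseline/.
"""

from pathlib import Path

from vegfr_trafficking import (
    aggregate,
    expand_reactions,
    reference_parameters,
    solve_production_rates,
    steady_state,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "baseline"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    network = expand_reactions()
    params = reference_parameters()
    production = solve_production_rates(params, network)
    params = params.with_values(production)
    params.to_yaml(OUT / "reference_parameters.yaml")
    rep = aggregate(steady_state(params, network))
    frame = rep.to_frame()
    frame.to_csv(OUT / "steady_state_pools.csv")
    print("steady-state pools (receptors/cell):")
    print(frame.round(1).to_string())
    for rec in ("R1", "R2", "N1"):
        print(f"  {rec}: {rep.surface_percent(rec):.1f}% on the surface")


if __name__ == "__main__":
    main()
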