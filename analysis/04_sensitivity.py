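"""Local (5% one-at-a-time) and global (1e-2..1e2 multiplier) sensitivity of
the calibrated model.

Reads the consensus parameters from results/fit/ (falls back to the
reference set if the fit has not been run) and writes tidy sensitivity
tables to results/sensitivity/.
"""

from pathlib import Path

from vegfr_trafficking import (
    CalibrationProblem,
    ParameterSet,
    build_huvec_dataset,
    expand_reactions,
    global_scan,
    local_sensitivity,
    reference_parameters,
    solve_production_rates,
)
from vegfr_trafficking.sensitivity import sensitivity_to_tidy

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "sensitivity"


def load_params():
    consensus = ROOT / "results" / "fit" / "consensus_parameters.yaml"
    if consensus.exists():
        print(f"using consensus parameters from {consensus}")
        return ParameterSet.from_yaml(consensus)
    print("no fit results found; using reference parameters")
    params = reference_parameters()
    network = expand_reactions()
    return params.with_values(solve_production_rates(params, network))


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    params = load_params()
    network = expand_reactions(params.compartments)
    matrix = local_sensitivity(params, network, delta=0.05)
    sensitivity_to_tidy(matrix).to_csv(OUT / "local_sensitivity.csv", index=False)
    print("local relative sensitivities (rows: parameters):")
    print(matrix.round(3).to_string())
    problem = CalibrationProblem(build_huvec_dataset())
    scan = global_scan(params, problem, grid_points_per_param=9)
    # compact export: the cost profile per parameter (the full per-prediction
    # table is available via GlobalScan.to_csv)
    scan.table[["parameter", "multiplier", "cost"]].to_csv(
        OUT / "global_scan_cost.csv", index=False
    )
    worst = (
        scan.table.groupby("parameter").cost.max().sort_values(ascending=False)
    )
    print("\nglobal scan: max cost over the 1e-2..1e2 multiplier grid")
    print(worst.round(2).to_string())


if __name__ == "__main__":
    main()
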