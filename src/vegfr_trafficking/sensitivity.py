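"""Local (one-at-a-time 5%) and global (1e-2 to 1e2 multiplier) sensitivity.

The local metric is the relative sensitivity: percent change in a
steady-state output divided by percent change in the parameter, computed by
forward difference.  The global scan varies each of the 18 fitted parameters
over four orders of magnitude around its optimized value and records the
goodness-of-fit cost and all 24 dataset-matched predictions per grid point,
including the CHX and siRNA protocol responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import CalibrationProblem
from .network import ReactionNetwork
from .parameters import PRODUCTION_NAMES, RECEPTORS, TRAFFICKING_NAMES, ParameterSet
from .simulate import SteadyStateError, aggregate, steady_state

FITTED_PARAMETERS = (*TRAFFICKING_NAMES, *PRODUCTION_NAMES)

OUTPUTS = ("total", "surface", "internal", "pct_surface")


def _outputs(state) -> dict[str, float]:
    rep = aggregate(state)
    out = {}
    for rec in RECEPTORS:
        p = rep[rec]
        out[f"total_{rec}"] = p["total"]
        out[f"surface_{rec}"] = p["surface"]
        out[f"internal_{rec}"] = p["internal"]
        out[f"pct_surface_{rec}"] = 100.0 * p["surface"] / p["total"]
    return out


def local_sensitivity(
    params: ParameterSet,
    network: ReactionNetwork,
    delta: float = 0.05,
    parameters: tuple[str, ...] = FITTED_PARAMETERS,
) -> pd.DataFrame:
    """Relative sensitivity matrix: rows = parameters, columns = per-receptor
    total/surface/internal/%surface at the perturbed steady state.

    Production rates are perturbed as free parameters (no inner re-solve),
    matching the definition of the fitted 18-parameter vector.  Entries for
    parameters whose perturbed steady state is infeasible are NaN.
    """
    base_state = steady_state(params, network)
    base = _outputs(base_state)
    rows = {}
    for name in parameters:
        perturbed = params.with_values({name: params[name] * (1.0 + delta)})
        try:
            state = steady_state(perturbed, network, x0=base_state)
            out = _outputs(state)
            rows[name] = {
                key: (out[key] - base[key]) / base[key] / delta if base[key] > 0
                else float("nan")
                for key in base
            }
        except SteadyStateError:
            rows[name] = {key: float("nan") for key in base}
    return pd.DataFrame(rows).T.rename_axis("parameter")


@dataclass
class GlobalScan:
    """Per-parameter multiplier grids with cost and matched predictions."""

    table: pd.DataFrame  # parameter, multiplier, cost, pred_<i> columns
    baseline_cost: float

    def costs(self, parameter: str) -> pd.DataFrame:
        return self.table[self.table.parameter == parameter][["multiplier", "cost"]]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def global_scan(
    params: ParameterSet,
    problem: CalibrationProblem,
    grid_points_per_param: int = 9,
    span_decades: float = 2.0,
    parameters: tuple[str, ...] = FITTED_PARAMETERS,
) -> GlobalScan:
    """One-at-a-time scan over log-spaced multipliers of each fitted
    parameter (default 1e-2 .. 1e2, grid always includes multiplier 1).

    ``params`` must carry the optimized production rates; production is held
    at the scanned value, not re-solved, so the surface-count residuals
    respond to the scan like every other prediction.
    """
    if grid_points_per_param < 3 or grid_points_per_param % 2 == 0:
        raise ValueError("grid_points_per_param must be odd and >= 3")
    multipliers = np.logspace(-span_decades, span_decades, grid_points_per_param)
    obs = problem.dataset.frame.value.to_numpy(dtype=float)

    def cost_and_preds(p: ParameterSet):
        try:
            preds = problem.predict_with_params(p)
        except (SteadyStateError, RuntimeError, ValueError):
            return float("nan"), np.full(len(obs), np.nan)
        r = (preds - obs) / obs
        return float(r @ r), preds

    baseline_cost, _ = cost_and_preds(params)
    records = []
    for name in parameters:
        for m in multipliers:
            if m == 1.0:
                c, preds = cost_and_preds(params)
            else:
                c, preds = cost_and_preds(
                    params.with_values({name: params[name] * m})
                )
            rec = {"parameter": name, "multiplier": m, "cost": c}
            rec.update({f"pred_{i}": v for i, v in enumerate(preds)})
            records.append(rec)
    return GlobalScan(pd.DataFrame(records), baseline_cost)


def sensitivity_to_tidy(matrix: pd.DataFrame) -> pd.DataFrame:
    """Long-format (parameter, output, value) table for heatmap plotting."""
    return (
        matrix.reset_index()
        .melt(id_vars="parameter", var_name="output", value_name="value")
    )
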