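"""Synthetic ground-truth parameter sets and pseudo-western measurements.

Replaces the wet-lab inputs for end-to-end testing: a ground-truth parameter
set is drawn (or supplied), the full measurement pipeline is simulated, and
multiplicative log-normal noise emulates densitometry variability of western
blot band quantification (strictly positive values, roughly constant CV).
Every table is reproducible bit-exactly from (truth, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationDataset,
    CalibrationProblem,
    DEFAULT_CHX_TIMES_H,
    DEFAULT_SIRNA_DURATION_H,
    build_huvec_dataset,
    solve_production_rates,
)
from .network import expand_reactions
from .parameters import (
    Compartments,
    DEFAULT_COUPLING,
    RECEPTORS,
    SURFACE_TARGETS,
    TRAFFICKING_BOUNDS,
    TRAFFICKING_NAMES,
    ParameterSet,
)
from .simulate import aggregate, steady_state


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal noise with a fixed coefficient of variation.

    CV = 0 reproduces model values exactly.  The log-normal is parameterized
    to have unit mean: sigma^2 = ln(1 + CV^2), mu = -sigma^2/2.
    """

    cv: float = 0.15
    seed: int | None = None

    def __post_init__(self):
        if self.cv < 0:
            raise ValueError("CV must be nonnegative")

    def sample_factors(self, n: int, rng: np.random.Generator | None = None):
        if self.cv == 0:
            return np.ones(n)
        rng = rng if rng is not None else np.random.default_rng(self.seed)
        sigma = np.sqrt(np.log1p(self.cv**2))
        return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


def draw_ground_truth(
    seed: int | None = None,
    surface_targets: Mapping[str, float] | None = None,
    coupling: Mapping[str, float] | None = None,
    compartments: Compartments | None = None,
    bounds=TRAFFICKING_BOUNDS,
) -> ParameterSet:
    """Ground-truth parameter set: trafficking constants log-uniform within
    the fit bounds, production solved so steady-state surface counts hit
    plausible targets (defaults 1800/4900/68000)."""
    rng = np.random.default_rng(seed)
    lo, hi = np.log10(bounds[0]), np.log10(bounds[1])
    trafficking = {
        n: float(10.0 ** rng.uniform(lo, hi)) for n in TRAFFICKING_NAMES
    }
    compartments = compartments or Compartments()
    values = dict(trafficking)
    values.update(DEFAULT_COUPLING, **(coupling or {}))
    values.update({f"k_prod_{r}": 0.0 for r in RECEPTORS})
    params = ParameterSet(values=values, compartments=compartments)
    network = expand_reactions(compartments)
    production = solve_production_rates(
        params, network, surface_targets or SURFACE_TARGETS
    )
    return params.with_values(production)


@dataclass
class SyntheticStudy:
    """A ground truth plus the tables generated from it."""

    truth: ParameterSet
    dataset: CalibrationDataset
    noise: NoiseModel
    seed: int | None = None
    extras: dict = field(default_factory=dict)


def generate_measurements(
    truth: ParameterSet,
    noise: NoiseModel | None = None,
    chx_times_h: Sequence[float] = DEFAULT_CHX_TIMES_H,
    sirna_duration_h: float = DEFAULT_SIRNA_DURATION_H,
) -> CalibrationDataset:
    """Simulate the full measurement pipeline under the truth and apply
    multiplicative noise; preserves the 24-row calibration structure.

    The truth must carry its production rates (see draw_ground_truth)."""
    noise = noise or NoiseModel(cv=0.0)
    template = build_huvec_dataset(chx_times_h, sirna_duration_h)
    problem = CalibrationProblem(
        template,
        coupling=truth.coupling(),
        compartments=truth.compartments,
    )
    preds = problem.predict_with_params(truth)
    frame = template.frame.copy()
    factors = noise.sample_factors(len(frame))
    frame["value"] = preds * factors
    ds = CalibrationDataset(frame)
    ds.validate_structure()
    return ds


def generate_biotin_split(
    truth: ParameterSet,
    noise: NoiseModel | None = None,
) -> pd.DataFrame:
    """Surface/internal partition per receptor at steady state, emulating the
    biotin-labeling assay (eluate and flow-through resuspended in the same
    volume, so band intensities are proportional to the pools).  Noise is
    applied per band; percentages are computed from the noisy bands."""
    noise = noise or NoiseModel(cv=0.0)
    network = expand_reactions(truth.compartments)
    rep = aggregate(steady_state(truth, network))
    rng = np.random.default_rng(noise.seed)
    rows = []
    for rec in RECEPTORS:
        surface, internal = rep[rec]["surface"], rep[rec]["internal"]
        f_s, f_i = noise.sample_factors(2, rng)
        s_meas, i_meas = surface * f_s, internal * f_i
        rows.append(
            {
                "receptor": rec,
                "surface": s_meas,
                "internal": i_meas,
                "total": s_meas + i_meas,
                "pct_surface": 100.0 * s_meas / (s_meas + i_meas),
            }
        )
    return pd.DataFrame(rows)


def make_study(
    seed: int | None = None,
    cv: float = 0.15,
    truth: ParameterSet | None = None,
) -> SyntheticStudy:
    """Convenience constructor: draw truth, generate the noisy dataset and
    the biotin split, all derived deterministically from the seed."""
    ss = np.random.SeedSequence(seed)
    truth_seed, meas_seed, biotin_seed = (int(s) % 2**31 for s in ss.generate_state(3))
    truth = truth or draw_ground_truth(truth_seed)
    dataset = generate_measurements(truth, NoiseModel(cv=cv, seed=meas_seed))
    biotin = generate_biotin_split(truth, NoiseModel(cv=cv, seed=biotin_seed))
    return SyntheticStudy(
        truth=truth,
        dataset=dataset,
        noise=NoiseModel(cv=cv, seed=meas_seed),
        seed=seed,
        extras={"biotin_split": biotin},
    )
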