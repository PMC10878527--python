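"""Transport-rate analysis: overall fluxes, residence half-lives,
recycling:degradation ratios, coupling equilibria, CHQ inhibition estimate.

The overall rate of a trafficking process is its rate constant multiplied by
the stoichiometry-weighted receptor pool it acts on (receptors/cell/s).  At
steady state the in- and out-fluxes of every live compartment balance, so net
rates are ~0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar, root

from .network import ReactionNetwork
from .parameters import RECEPTORS, ParameterSet
from .receptors import STOICHIOMETRY
from .simulate import (
    PerturbationSpec,
    steady_state,
    whole_cell_fold_change,
)

PROCESSES = (
    "production",
    "internalization",
    "recycle4",
    "transfer4to11",
    "recycle11",
    "degradation",
)

# compartment balance: process -> (source, destination); production has no source
_PROCESS_MOVES = {
    "production": (None, "surface"),
    "internalization": ("surface", "rab4"),
    "recycle4": ("rab4", "surface"),
    "transfer4to11": ("rab4", "rab11"),
    "recycle11": ("rab11", "surface"),
    "degradation": ("rab4", None),
}


@dataclass
class FluxTable:
    """Per-receptor process fluxes and per-compartment net rates."""

    fluxes: pd.DataFrame  # receptor, process, rate_per_s
    net: pd.DataFrame     # receptor, compartment, net_rate_per_s

    def rate(self, receptor: str, process: str) -> float:
        sel = self.fluxes[
            (self.fluxes.receptor == receptor) & (self.fluxes.process == process)
        ]
        return float(sel.rate_per_s.iloc[0])

    def to_csv(self, path) -> None:
        self.fluxes.to_csv(path, index=False)


def compute_fluxes(
    params: ParameterSet, network: ReactionNetwork, state: np.ndarray
) -> FluxTable:
    k = network.rate_constants(params)
    rates = network.reaction_rates(np.asarray(state, dtype=float), k)
    flux = {rec: {p: 0.0 for p in PROCESSES} for rec in RECEPTORS}
    for r in network.reactions:
        if r.klass == "production":
            rec = r.rate_name.removeprefix("k_prod_")
            flux[rec]["production"] += rates[r.rid]
        elif r.klass in _PROCESS_MOVES:
            moved = r.reactants[0] % 8  # complex index of the moved species
            for ri, rec in enumerate(RECEPTORS):
                w = STOICHIOMETRY[ri, moved]
                if w:
                    flux[rec][r.klass] += w * rates[r.rid]
    rows = [
        {"receptor": rec, "process": p, "rate_per_s": flux[rec][p]}
        for rec in RECEPTORS
        for p in PROCESSES
    ]
    net_rows = []
    for rec in RECEPTORS:
        net = {"surface": 0.0, "rab4": 0.0, "rab11": 0.0}
        for p, (src, dst) in _PROCESS_MOVES.items():
            if src:
                net[src] -= flux[rec][p]
            if dst:
                net[dst] += flux[rec][p]
        for comp, v in net.items():
            net_rows.append(
                {"receptor": rec, "compartment": comp, "net_rate_per_s": v}
            )
    return FluxTable(pd.DataFrame(rows), pd.DataFrame(net_rows))


def surface_residence_half_life(k_int: float) -> float:
    """ln(2)/k_int, seconds: the half-life of a receptor's residence on the
    cell surface before internalization."""
    if k_int <= 0:
        raise ValueError("k_int must be positive")
    return float(np.log(2.0) / k_int)


def recycling_degradation_ratio(
    params: ParameterSet, receptor: str, flux_weighted: bool = False,
    network: ReactionNetwork | None = None, state: np.ndarray | None = None,
) -> float:
    """(k_rec4 + k_4to11) / k_deg: recycled-per-degraded receptors leaving the
    early endosome.  The default is the pure rate-constant ratio; the
    flux-weighted variant divides the realized recycling flux (both routes)
    by the degradation flux at a given state."""
    if not flux_weighted:
        k_deg = params[f"k_deg_{receptor}"]
        if k_deg <= 0:
            raise ValueError("k_deg must be positive")
        return float(
            (params[f"k_rec4_{receptor}"] + params[f"k_4to11_{receptor}"]) / k_deg
        )
    if network is None or state is None:
        raise ValueError("flux-weighted ratio needs network and state")
    ft = compute_fluxes(params, network, state)
    deg = ft.rate(receptor, "degradation")
    if deg <= 0:
        raise ValueError("degradation flux must be positive")
    return (ft.rate(receptor, "recycle4") + ft.rate(receptor, "transfer4to11")) / deg


# --------------------------------------------------------------------------
# Coupling equilibria (trafficking off) — closed forms and full system
# --------------------------------------------------------------------------
def equilibrium_dimer_fraction(r_total: float, kc: float, kd: float) -> float:
    """Fraction of receptors in homodimers at equilibrium.

    Mass action with forward rate kc*[M]^2 and dissociation kd*[D]
    (K_d = kd/kc, per-cell units) under M + 2D = R_T gives
    2*kc*M^2 + kd*M - kd*R_T = 0.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    if r_total < 0 or kc < 0:
        raise ValueError("r_total and kc must be nonnegative")
    if kc == 0 or r_total == 0:
        return 0.0
    m = (-kd + np.sqrt(kd * kd + 8.0 * kc * kd * r_total)) / (4.0 * kc)
    return float(1.0 - m / r_total)


def equilibrium_hetero_fraction(
    r_total: float, n_total: float, kc: float, kd: float
) -> tuple[float, float]:
    """1:1 VEGFR1-NRP1 equilibrium: fractions of R and of N in complexes.

    [C] is the smaller root of C^2 - (R_T + N_T + K_d) C + R_T N_T = 0.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    if kc == 0 or r_total == 0 or n_total == 0:
        return 0.0, 0.0
    k_eq = kd / kc
    b = r_total + n_total + k_eq
    c = (b - np.sqrt(b * b - 4.0 * r_total * n_total)) / 2.0
    return float(c / r_total), float(c / n_total)


@dataclass
class EquilibriumResult:
    species: dict[str, float]
    r_total: float
    n_total: float

    @property
    def fraction_r1_dimerized(self) -> float:
        s = self.species
        dimer_r1 = 2 * (s["R1R1"] + s["R1R1N1"] + s["R1R1N1N1"])
        return dimer_r1 / self.r_total if self.r_total else 0.0

    @property
    def fraction_r1_with_n1(self) -> float:
        s = self.species
        bound = s["R1N1"] + 2 * s["R1R1N1"] + 2 * s["R1R1N1N1"]
        return bound / self.r_total if self.r_total else 0.0

    @property
    def fraction_n1_with_r1(self) -> float:
        s = self.species
        bound = s["R1N1"] + s["R1R1N1"] + 2 * s["R1R1N1N1"]
        return bound / self.n_total if self.n_total else 0.0


def equilibrium_coupled(
    r_total: float,
    n_total: float,
    kc_rr: float,
    kd_rr: float,
    kc_rn: float,
    kd_rn: float,
) -> EquilibriumResult:
    """Full VEGFR1/NRP1 coupling equilibrium (per-cell rate constants).

    Detailed balance gives, with K_RR = kc_rr/kd_rr and K_RN = kc_rn/kd_rn:
    [R1R1] = K_RR R^2, [R1N1] = K_RN R N, [R1R1N1] = 2 K_RR K_RN R^2 N,
    [R1R1N1N1] = K_RR K_RN^2 R^2 N^2; free (R, N) solve the two conservation
    equations.
    """
    if r_total < 0 or n_total < 0:
        raise ValueError("totals must be nonnegative")
    krr = kc_rr / kd_rr if kd_rr > 0 else 0.0
    krn = kc_rn / kd_rn if kd_rn > 0 else 0.0

    def species_from(r, n):
        return {
            "R1": r,
            "N1": n,
            "R1R1": krr * r * r,
            "R1N1": krn * r * n,
            "R1R1N1": 2.0 * krr * krn * r * r * n,
            "R1R1N1N1": krr * krn * krn * r * r * n * n,
        }

    scale = max(r_total, n_total, 1.0)

    def balance(logs):
        r, n = np.exp(logs)
        s = species_from(r, n)
        rt = s["R1"] + 2 * s["R1R1"] + s["R1N1"] + 2 * s["R1R1N1"] + 2 * s["R1R1N1N1"]
        nt = s["N1"] + s["R1N1"] + s["R1R1N1"] + 2 * s["R1R1N1N1"]
        return [(rt - r_total) / scale, (nt - n_total) / scale]

    if r_total == 0 and n_total == 0:
        return EquilibriumResult(species_from(0.0, 0.0), 0.0, 0.0)
    guess = np.log(np.maximum([r_total, n_total], 1e-9))
    sol = root(balance, guess, method="hybr")
    if np.max(np.abs(balance(sol.x))) > 1e-9:
        raise RuntimeError("equilibrium solve failed")
    r, n = np.exp(sol.x)
    return EquilibriumResult(species_from(r, n), r_total, n_total)


def effective_nrp1_affinity(
    r_total: float,
    n_free: float,
    kc_rr: float,
    kd_rr: float,
    kc_rn: float,
    kd_rn: float,
) -> float:
    """K_d,eff of NRP1 coupling to VEGFR1 under 2:2 binding, computed
    numerically from the full equilibrium with the free NRP1 level clamped:
    the NRP1 concentration at which the realized VEGFR1 occupancy would sit
    on a 1:1 binding curve, K_d,eff = N_free * (1 - f) / f."""
    krr = kc_rr / kd_rr if kd_rr > 0 else 0.0
    krn = kc_rn / kd_rn if kd_rn > 0 else 0.0
    n = n_free

    def r_conservation(log_r):
        r = np.exp(log_r)
        return (
            r
            + 2 * krr * r * r
            + krn * r * n
            + 4 * krr * krn * r * r * n
            + 2 * krr * krn * krn * r * r * n * n
            - r_total
        ) / max(r_total, 1.0)

    sol = root(r_conservation, np.log(max(r_total, 1e-9)))
    r = float(np.exp(sol.x[0]))
    bound = (
        krn * r * n + 4 * krr * krn * r * r * n + 2 * krr * krn * krn * r * r * n * n
    )
    f = bound / r_total
    if f <= 0 or f >= 1:
        raise ValueError("occupancy outside (0, 1); K_d,eff undefined")
    return float(n_free * (1.0 - f) / f)


# --------------------------------------------------------------------------
# Chloroquine inhibition fraction
# --------------------------------------------------------------------------
DEFAULT_CHQ_TIMES_H = (1.0, 2.0, 4.0, 8.0, 18.0)


def simulate_chq_series(
    params: ParameterSet,
    network: ReactionNetwork,
    inhibition_fraction: float,
    times_h=DEFAULT_CHQ_TIMES_H,
    receptor: str = "R1",
    initial: np.ndarray | None = None,
) -> np.ndarray:
    """Whole-cell fold-change series under CHQ at a given inhibition f."""
    fc = whole_cell_fold_change(
        params,
        network,
        PerturbationSpec.chq(inhibition_fraction),
        3600.0 * np.asarray(times_h, dtype=float),
        initial=initial,
    )
    return fc[receptor].to_numpy()


def estimate_chq_inhibition(
    times_h,
    fold_changes,
    params: ParameterSet,
    network: ReactionNetwork,
    receptor: str = "R1",
    full_output: bool = False,
):
    """Least-squares estimate of the CHQ degradation-inhibition fraction f.

    Fits only the scalar f in k_deg -> (1 - f) k_deg (all other parameters
    held fixed) to an observed whole-cell fold-change series.  A series that
    sits below 1.0 while accumulation is expected drives f to the boundary 0,
    which is returned flagged."""
    fold_changes = np.asarray(fold_changes, dtype=float)
    x0 = steady_state(params, network)

    def sse(f):
        sim = simulate_chq_series(
            params, network, f, times_h, receptor=receptor, initial=x0
        )
        d = sim - fold_changes
        return float(d @ d)

    res = minimize_scalar(sse, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-6})
    f_hat = float(res.x)
    # polish the boundary cases: bounded Brent never lands exactly on them
    for boundary in (0.0, 1.0):
        if sse(boundary) <= res.fun:
            f_hat, res_fun = boundary, sse(boundary)
            break
    else:
        res_fun = float(res.fun)
    flagged = f_hat == 0.0 and np.mean(fold_changes) < 1.0
    if full_output:
        return f_hat, {"sse": res_fun, "flagged_at_zero": flagged}
    return f_hat
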