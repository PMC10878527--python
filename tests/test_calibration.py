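"""Dataset construction, production solve, cost, and the multistart fit."""

import numpy as np
import pytest

from vegfr_trafficking import (
    CalibrationProblem,
    build_huvec_dataset,
    initial_final_correlation,
    multistart_fit,
    reference_parameters,
    solve_production_rates,
    summarize_fits,
)
from vegfr_trafficking.calibration import FitEnsemble, FitResult
from vegfr_trafficking.parameters import (
    REFERENCE_TRAFFICKING,
    SURFACE_TARGETS,
    TRAFFICKING_NAMES,
)
from vegfr_trafficking.synthetic import generate_measurements


@pytest.fixture(scope="module")
def dataset():
    return build_huvec_dataset()


@pytest.fixture(scope="module")
def problem(dataset):
    return CalibrationProblem(dataset)


class TestDataset:
    def test_24_rows_8_per_receptor(self, dataset):
        dataset.validate_structure()
        assert len(dataset.frame) == 24
        assert (dataset.frame.receptor.value_counts() == 8).all()

    def test_reported_measurement_values(self, dataset):
        df = dataset.frame
        surf = df[df.type == "surface_count"].set_index("receptor").value
        assert surf["R1"] == 1800 and surf["R2"] == 4900 and surf["N1"] == 68000
        pct = df[df.type == "surface_percent"].set_index("receptor").value
        assert (pct[["R1", "R2", "N1"]] == [10, 51, 74]).all()
        sirna = df[df.type == "sirna_double_foldchange"].value
        assert (sirna == 1.0).all()

    def test_chx_curves_follow_half_lives(self, dataset):
        df = dataset.frame
        r1 = df[(df.receptor == "R1") & (df.type == "chx_foldchange")]
        # 45-minute half-life: fold change 0.5 at t = 0.75 h; at 1 h
        # the curve gives 0.5^(60/45)
        v1h = r1[r1.time_h == 1.0].value.iloc[0]
        assert v1h == pytest.approx(0.5 ** (60 / 45.0))
        n1 = df[(df.receptor == "N1") & (df.type == "chx_foldchange")]
        assert (n1.value == 1.0).all()

    def test_csv_round_trip(self, dataset, tmp_path):
        path = tmp_path / "ds.csv"
        dataset.to_csv(path)
        from vegfr_trafficking import CalibrationDataset

        back = CalibrationDataset.from_csv(path)
        back.validate_structure()
        np.testing.assert_allclose(back.frame.value, dataset.frame.value)


class TestProductionSolve:
    def test_zero_targets_give_zero_production(self, network):
        params = reference_parameters()
        prod = solve_production_rates(
            params, network, {"R1": 0.0, "R2": 0.0, "N1": 0.0}
        )
        assert all(v == 0.0 for v in prod.values())

    def test_linear_formula_for_uncoupled_receptor(self, network):
        """Symbolic oracle: with coupling off the steady-state surface level
        is S = k_prod*(k_rec4+k_4to11+k_deg)/(k_int*k_deg), so
        k_prod = S*k_int*k_deg/(k_rec4+k_4to11+k_deg)."""
        from vegfr_trafficking import expand_reactions

        net = expand_reactions()
        params = reference_parameters(
            coupling={k: 0.0 for k in ("kc_R1R1", "kc_R2R2", "kc_R1N1")}
        )
        prod = solve_production_rates(params, net, SURFACE_TARGETS)
        for rec in ("R1", "R2", "N1"):
            kint = params[f"k_int_{rec}"]
            kdeg = params[f"k_deg_{rec}"]
            lam = params[f"k_rec4_{rec}"] + params[f"k_4to11_{rec}"] + kdeg
            expected = SURFACE_TARGETS[rec] * kint * kdeg / lam
            assert prod[f"k_prod_{rec}"] == pytest.approx(expected, rel=1e-9)

    def test_surface_targets_hit_within_tolerance(self, network, reference_params):
        from vegfr_trafficking import aggregate, steady_state

        rep = aggregate(steady_state(reference_params, network))
        for rec, target in SURFACE_TARGETS.items():
            assert rep[rec]["surface"] == pytest.approx(target, rel=1e-4)

    def test_nrp1_production_increases_with_coupling_rate(self, network):
        params_lo = reference_parameters(coupling={"kc_R1N1": 1e-4})
        params_hi = reference_parameters(coupling={"kc_R1N1": 8e-4})
        from vegfr_trafficking import expand_reactions

        net = expand_reactions()
        p_lo = solve_production_rates(params_lo, net)
        p_hi = solve_production_rates(params_hi, net)
        assert p_hi["k_prod_N1"] > p_lo["k_prod_N1"]
        assert p_hi["k_prod_R1"] == pytest.approx(p_lo["k_prod_R1"])

    def test_infeasible_target_reported(self, network):
        params = reference_parameters(trafficking={"k_int_R1": 0.0})
        from vegfr_trafficking.simulate import SteadyStateError

        with pytest.raises(SteadyStateError):
            solve_production_rates(params, network, SURFACE_TARGETS)


class TestCost:
    def test_cost_zero_when_predictions_equal_observations(self, problem):
        """Self-consistency: a noiseless dataset generated from known
        parameters has near-zero cost at the generating parameters."""
        truth = reference_parameters()
        from vegfr_trafficking import expand_reactions

        net = expand_reactions()
        production = solve_production_rates(truth, net)
        truth = truth.with_values(production)
        ds = generate_measurements(truth)  # CV = 0
        prob = CalibrationProblem(ds)
        assert prob.cost(truth.trafficking()) < 1e-6

    def test_cost_invariant_to_row_order(self, dataset):
        shuffled = dataset.frame.sample(frac=1.0, random_state=0)
        from vegfr_trafficking import CalibrationDataset

        prob_a = CalibrationProblem(dataset)
        prob_b = CalibrationProblem(CalibrationDataset(shuffled))
        traff = dict(REFERENCE_TRAFFICKING)
        assert prob_a.cost(traff) == pytest.approx(prob_b.cost(traff), rel=1e-6)

    def test_infeasible_parameters_get_finite_penalty(self, problem):
        traff = dict(REFERENCE_TRAFFICKING, k_deg_R1=0.0, k_rec4_R1=0.0,
                     k_4to11_R1=0.0)
        c = problem.cost(traff)
        assert np.isfinite(c) and c > 1e4


class TestMultistartFit:
    def test_start_at_truth_of_noiseless_dataset_stays_there(self):
        truth = reference_parameters()
        from vegfr_trafficking import expand_reactions

        net = expand_reactions()
        truth = truth.with_values(solve_production_rates(truth, net))
        ds = generate_measurements(truth)
        ens = multistart_fit(
            ds, n_starts=1, seed=0, initials=[truth.trafficking()]
        )
        res = ens.results[0]
        assert res.success
        assert res.cost < 1e-6

    def test_seeded_determinism_and_bounds(self, dataset):
        kw = dict(n_starts=2, seed=123, max_nfev=60)
        ens_a = multistart_fit(dataset, **kw)
        ens_b = multistart_fit(dataset, **kw)
        for ra, rb in zip(ens_a.results, ens_b.results):
            assert ra.trafficking == rb.trafficking
            assert ra.initial == rb.initial
        for res in ens_a.results:
            for v in res.trafficking.values():
                assert 1e-6 <= v <= 1e-1

    def test_jsonl_round_trip(self, dataset, tmp_path):
        ens = multistart_fit(dataset, n_starts=1, seed=5, max_nfev=30)
        path = tmp_path / "ens.jsonl"
        ens.to_jsonl(path)
        back = FitEnsemble.from_jsonl(path)
        assert back.results[0].trafficking == ens.results[0].trafficking


class TestSummaries:
    def _identical_ensemble(self, problem, n=4):
        traff = dict(REFERENCE_TRAFFICKING)
        production, _ = problem.solve_production(traff)
        res = FitResult(
            initial=traff, trafficking=traff, production=production,
            cost=1.0, success=True, nfev=1,
        )
        return FitEnsemble([res] * n, problem=problem)

    def test_consensus_of_identical_fits_is_unchanged(self, problem):
        ens = self._identical_ensemble(problem)
        params, summary = summarize_fits(ens)
        for name in TRAFFICKING_NAMES:
            assert params[name] == pytest.approx(REFERENCE_TRAFFICKING[name])
        assert set(summary.columns) >= {"consensus", "p5", "p95"}

    def test_consensus_reproduces_surface_targets(self, problem):
        """Inner-loop consistency: the consensus production re-solve puts
        steady-state surface counts back on the calibration targets."""
        from vegfr_trafficking import aggregate, steady_state

        ens = self._identical_ensemble(problem)
        params, _ = summarize_fits(ens)
        rep = aggregate(steady_state(params, problem.network))
        for rec, target in SURFACE_TARGETS.items():
            assert rep[rec]["surface"] == pytest.approx(target, rel=1e-4)

    def test_empty_ensemble_raises(self, problem):
        with pytest.raises(ValueError):
            summarize_fits(FitEnsemble([], problem=problem))

    def test_correlation_identity_and_degenerate_cases(self, problem):
        traff = dict(REFERENCE_TRAFFICKING)
        production, _ = problem.solve_production(traff)
        rng = np.random.default_rng(0)
        results = []
        for _ in range(5):
            init = {
                n: v * float(10 ** rng.uniform(-1, 1))
                for n, v in traff.items()
            }
            results.append(
                FitResult(initial=init, trafficking=init, production=production,
                          cost=1.0, success=True, nfev=1)
            )
        corr = initial_final_correlation(FitEnsemble(results, problem=problem))
        assert np.allclose(corr.to_numpy(), 1.0)
        # optimizer output constant across starts -> undefined correlation
        const = [
            FitResult(initial=r.initial, trafficking=traff, production=production,
                      cost=1.0, success=True, nfev=1)
            for r in results
        ]
        corr2 = initial_final_correlation(FitEnsemble(const, problem=problem))
        assert corr2.isna().all()
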