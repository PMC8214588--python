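"""Bootstrap and Monte Carlo PSA engines."""

import numpy as np
import pytest

from bootcua.markov import ModelConfig
from bootcua.pipeline import estimate_sativex_matrices, evaluate_point
from bootcua.psa import (
    BootstrapConfig,
    DispersionSpec,
    Replicate,
    _sample_matrix,
    ceac,
    draw_bootstrap_replicate,
    identity_resample,
    replicates_to_frame,
    run_bootstrap_psa,
    run_monte_carlo_psa,
    summarize_psa,
)
from bootcua.synthetic import GeneratorConfig, generate_delphi_panel, generate_trial
from bootcua.trial_data import (
    Stratum,
    TransitionEstimate,
    TrialDataset,
    estimate_utilities,
)


def _make_replicates(dc_dq_pairs):
    reps = []
    for i, (dc, dq) in enumerate(dc_dq_pairs):
        reps.append(
            Replicate(
                replicate_id=i,
                horizons=(1,),
                costs_treatment=np.array([float(dc)]),
                qalys_treatment=np.array([float(dq)]),
                costs_control=np.array([0.0]),
                qalys_control=np.array([0.0]),
            )
        )
    return reps


class TestResampling:
    def test_stratum_sizes_preserved(self, trial, panel_and_tariffs):
        panel, _ = panel_and_tariffs
        rng = np.random.default_rng(0)
        for _ in range(50):
            bt, bp = draw_bootstrap_replicate(trial, panel, rng)
            assert bt.counts_by_stratum == trial.counts_by_stratum
            assert bp.n_experts == panel.n_experts

    def test_single_patient_stratum_repeats_that_patient(self, panel_and_tariffs):
        panel, _ = panel_and_tariffs
        from bootcua.trial_data import PatientRecord

        pats = [
            PatientRecord("only", Stratum.SINGLE_BLIND_ONLY, {1: 5.0, 2: 5.0}),
            PatientRecord("s1", Stratum.DB_SATIVEX, {1: 5.0, 2: 5.0}),
            PatientRecord("s2", Stratum.DB_SATIVEX, {1: 8.0, 2: 8.0}),
            PatientRecord("p1", Stratum.DB_PLACEBO, {1: 5.0, 2: 5.0}),
        ]
        ds = TrialDataset.from_patients(pats)
        bt, _ = draw_bootstrap_replicate(ds, panel, np.random.default_rng(1))
        assert list(bt.patient_ids[bt.stratum == Stratum.SINGLE_BLIND_ONLY]) == ["only"]

    def test_empty_stratum_rejected(self, panel_and_tariffs):
        panel, _ = panel_and_tariffs
        from bootcua.trial_data import PatientRecord

        ds = TrialDataset.from_patients(
            [PatientRecord("a", Stratum.DB_SATIVEX, {1: 5.0})]
        )
        with pytest.raises(ValueError, match="empty"):
            draw_bootstrap_replicate(ds, panel, np.random.default_rng(0))


class TestBootstrapEngine:
    def test_fixed_seed_reproduces_replicates_bitwise(
        self, trial, panel_and_tariffs, model_config, soc_matrix
    ):
        panel, tariffs = panel_and_tariffs
        cfg = BootstrapConfig(n_replicates=25, seed=42, scenario="base")
        reps1, _ = run_bootstrap_psa(
            trial, panel, tariffs, model_config, cfg, soc_matrix=soc_matrix
        )
        reps2, _ = run_bootstrap_psa(
            trial, panel, tariffs, model_config, cfg, soc_matrix=soc_matrix
        )
        assert replicates_to_frame(reps1).to_csv() == replicates_to_frame(reps2).to_csv()
        reps3, _ = run_bootstrap_psa(
            trial, panel, tariffs, model_config,
            BootstrapConfig(25, 43, "base"), soc_matrix=soc_matrix,
        )
        assert replicates_to_frame(reps1).to_csv() != replicates_to_frame(reps3).to_csv()

    def test_identity_resample_single_replicate_equals_point_run(
        self, trial, panel_and_tariffs, model_config, soc_matrix
    ):
        panel, tariffs = panel_and_tariffs
        reps, _ = run_bootstrap_psa(
            trial, panel, tariffs, model_config,
            BootstrapConfig(1, 0, "base"),
            soc_matrix=soc_matrix, resample=identity_resample,
        )
        point = evaluate_point(
            trial, panel, tariffs, model_config, "base",
            soc_matrix=soc_matrix, warn=False,
        )
        for h in model_config.horizons:
            inc = reps[0].incremental(h)
            want = point.incrementals[h]
            assert inc.delta_costs == pytest.approx(want.delta_costs, abs=1e-9)
            assert inc.delta_qalys == pytest.approx(want.delta_qalys, abs=1e-12)

    def test_degenerate_inputs_collapse_all_intervals(
        self, degenerate_inputs, model_config, soc_matrix
    ):
        trial, panel, tariffs = degenerate_inputs
        reps, summ = run_bootstrap_psa(
            trial, panel, tariffs, model_config,
            BootstrapConfig(30, 9, "base"), soc_matrix=soc_matrix,
        )
        for h in model_config.horizons:
            s = summ[h]
            assert np.ptp(s.delta_costs) == 0.0
            assert np.ptp(s.delta_qalys) == 0.0
            assert s.ci_delta_costs[0] == pytest.approx(s.ci_delta_costs[1])
            assert s.ci_delta_qalys[0] == pytest.approx(s.ci_delta_qalys[1])
            assert s.dominance_probability in (0.0, 1.0)


class TestMonteCarloEngine:
    def test_degenerate_spec_reproduces_point_run(
        self, trial, panel_and_tariffs, model_config, soc_matrix
    ):
        panel, tariffs = panel_and_tariffs
        point = evaluate_point(
            trial, panel, tariffs, model_config, "base",
            soc_matrix=soc_matrix, warn=False,
        )
        sat = point.sat_estimates
        spec = DispersionSpec(
            sat_alphas=[np.zeros((3, 3))] * len(sat),  # no sampling: keep points
            sat_points=sat,
            utility_mean=point.utilities.as_array(),
            utility_se=np.zeros(3),
            cost_mean=point.state_costs.as_array(),
            cost_se=np.zeros(3),
        )
        reps, _ = run_monte_carlo_psa(
            point, spec, model_config, 5, seed=0, soc_matrix=soc_matrix
        )
        for r in reps:
            for h in model_config.horizons:
                assert r.incremental(h).delta_costs == pytest.approx(
                    point.incrementals[h].delta_costs, abs=1e-9
                )

    def test_sampled_rows_stay_on_simplex(self, trial):
        est = estimate_sativex_matrices(trial, warn=False)
        rng = np.random.default_rng(5)
        for e in est:
            alphas = e.row_counts[:, None] * e.matrix
            for _ in range(20):
                m = _sample_matrix(alphas, e.matrix, rng)
                np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
                assert np.all(m >= 0)
                # structural zeros are preserved
                assert np.all(m[e.matrix == 0] == 0)

    def test_fixed_seed_reproducible(self, trial, panel_and_tariffs, model_config, soc_matrix):
        panel, tariffs = panel_and_tariffs
        point = evaluate_point(
            trial, panel, tariffs, model_config, "base",
            soc_matrix=soc_matrix, warn=False,
        )
        spec = DispersionSpec.from_data(trial, panel, tariffs, "base")
        r1, _ = run_monte_carlo_psa(point, spec, model_config, 10, 3, soc_matrix=soc_matrix)
        r2, _ = run_monte_carlo_psa(point, spec, model_config, 10, 3, soc_matrix=soc_matrix)
        assert replicates_to_frame(r1).to_csv() == replicates_to_frame(r2).to_csv()


class TestCorrelationStructure:
    def test_bootstrap_preserves_parameter_coupling_monte_carlo_does_not(
        self, model_config, soc_matrix
    ):
        """Under strong utility-transition coupling in the source data, the
        bootstrap's replicate-level utility and improvement estimates
        correlate positively; independent Monte Carlo draws do not."""
        cfg = GeneratorConfig(rho=2.0)
        trial = generate_trial(cfg, 7)
        panel, tariffs = generate_delphi_panel(cfg, 8)
        n_rep = 400

        def improvement(mats):
            return np.mean([m[1, 0] + m[2, 0] + m[2, 1] for m in mats])

        u0 = estimate_utilities(trial)
        us, imps = [], []
        for ss in np.random.SeedSequence(21).spawn(n_rep):
            rng = np.random.default_rng(ss)
            bt, _ = draw_bootstrap_replicate(trial, panel, rng)
            us.append(np.mean(estimate_utilities(bt, fallback=u0).as_array()))
            imps.append(improvement([e.matrix for e in estimate_sativex_matrices(bt, warn=False)]))
        boot_corr = np.corrcoef(us, imps)[0, 1]

        spec = DispersionSpec.from_data(trial, panel, tariffs, "base")
        us, imps = [], []
        for ss in np.random.SeedSequence(22).spawn(n_rep):
            rng = np.random.default_rng(ss)
            mats = [
                _sample_matrix(a, e.matrix, rng)
                for e, a in zip(spec.sat_points, spec.sat_alphas)
            ]
            u = spec.utility_mean + spec.utility_se * rng.standard_normal(3)
            us.append(np.mean(u))
            imps.append(improvement(mats))
        mc_corr = np.corrcoef(us, imps)[0, 1]

        assert boot_corr > 0.1
        assert abs(mc_corr) < 0.1
        assert boot_corr > mc_corr


class TestCoverage:
    def test_bootstrap_interval_covers_generator_truth(self, model_config):
        """Scaled-down coverage check: across repeated synthetic trials the
        95% bootstrap interval for the 5-year QALY gain contains the
        generator-implied truth in at least 80% of experiments.  Run with
        coupling off, where the truth equals the estimators' limit."""
        from bootcua.synthetic import SYNTHETIC_SOC_MATRIX, true_point_result

        cfg = GeneratorConfig(rho=0.0)
        panel, tariffs = generate_delphi_panel(cfg, 999)
        truth = true_point_result(cfg).incrementals[5].delta_qalys
        n_exp, hits = 60, 0
        for s in range(n_exp):
            tr = generate_trial(cfg, 5_000 + s)
            _, summ = run_bootstrap_psa(
                tr, panel, tariffs, model_config,
                BootstrapConfig(200, s, "base"), soc_matrix=SYNTHETIC_SOC_MATRIX,
            )
            lo, hi = summ[5].ci_delta_qalys
            hits += lo <= truth <= hi
        assert hits / n_exp >= 0.8


class TestSummaries:
    def test_dominance_counting(self):
        reps = _make_replicates([(-1.0, 1.0)] * 4 + [(1.0, 1.0)] * 6)
        s = summarize_psa(reps, 1)
        assert s.dominance_probability == pytest.approx(0.4)
        assert s.quadrant_counts == {"NE": 6, "SE": 4, "SW": 0, "NW": 0}

    def test_all_dominant(self):
        s = summarize_psa(_make_replicates([(-5.0, 0.2)] * 10), 1)
        assert s.dominance_probability == 1.0
        assert s.prob_qaly_gain == 1.0

    def test_quadrant_counts_sum_to_n(self):
        rng = np.random.default_rng(0)
        reps = _make_replicates(zip(rng.normal(size=50), rng.normal(size=50)))
        s = summarize_psa(reps, 1)
        assert sum(s.quadrant_counts.values()) == 50

    def test_percentile_interval_interpolates(self):
        # delta-cost values 1..100: linear-interpolated 2.5/97.5 percentiles
        reps = _make_replicates([(float(i), 1.0) for i in range(1, 101)])
        s = summarize_psa(reps, 1)
        assert s.ci_delta_costs[0] == pytest.approx(1 + 0.025 * 99)
        assert s.ci_delta_costs[1] == pytest.approx(1 + 0.975 * 99)

    def test_zero_qaly_delta_excluded_from_icer_interval(self):
        reps = _make_replicates([(1.0, 0.0)] * 5 + [(1.0, 0.1)] * 5)
        s = summarize_psa(reps, 1)
        assert s.n_icer_defined == 5

    def test_empty_replicates_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_psa([], 1)

    def test_ceac_monotone_between_extremes(self):
        reps = _make_replicates([(100.0, 0.01), (-50.0, 0.02), (200.0, -0.01)])
        curve = ceac(reps, 1, np.array([0.0, 1e4, 1e9]))
        p = curve["probability_cost_effective"].to_numpy()
        assert p[0] == pytest.approx(1 / 3)  # only the cost-saving replicate
        assert p[-1] == pytest.approx(2 / 3)  # QALY-gaining replicates win
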