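import numpy as np
import pytest

from alnbrain.experiments import (FAMILY_RANGES, PerturbationSpec,
                                  VirtualCohort, apply_perturbation,
                                  compare_to_default, evolutionary_fit,
                                  run_condition)
from alnbrain.metrics import MetricsReport
from alnbrain.network import GlobalParams, PopulationParams
from alnbrain.stats import compare_groups


@pytest.fixture(scope="module")
def small_cohort(connectome16, partition16, tables_small):
    return VirtualCohort(
        connectome=connectome16, tables=tables_small, partition=partition16,
        glob=GlobalParams(duration=8.0, transient=2.0),
        seeds=(11, 12, 13))


def _fake_report(values):
    n = 4
    return MetricsReport(FC=np.eye(n), gbc_region=np.zeros(n),
                         gbc_global=values["gbc_global"],
                         gbc_per_network={},
                         gbc_association=values["gbc_association"],
                         gbc_sensory=values["gbc_sensory"],
                         mean_R=values["mean_R"],
                         metastability=values["metastability"])


def _fake_cohort_reports(rng, n, shift=0.0):
    reports = []
    for _ in range(n):
        base = {
            "gbc_global": rng.normal(0.4, 0.05) - shift,
            "gbc_association": rng.normal(0.4, 0.05) - shift,
            "gbc_sensory": rng.normal(0.45, 0.05) - shift,
            "mean_R": rng.normal(0.6, 0.04) - shift,
            "metastability": rng.normal(0.12, 0.02),
        }
        reports.append(_fake_report(base))
    return reports


class TestPerturbationSpec:
    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown family"):
            PerturbationSpec(family="dopamine")

    def test_reference_scale_required(self):
        with pytest.raises(ValueError, match="1.0"):
            PerturbationSpec(family="global_coupling", scales=(0.9, 0.8))

    @pytest.mark.parametrize("family,bad", [
        ("global_coupling", 0.5), ("gaba_weights", 1.2),
        ("noise_level", 0.9), ("glut_drive_to_I", 1.5)])
    def test_out_of_range_scales_rejected(self, family, bad):
        with pytest.raises(ValueError, match="outside"):
            PerturbationSpec(family=family, scales=(1.0, bad))
        PerturbationSpec(family=family, scales=(1.0, bad),
                         allow_out_of_range=True)  # override allowed

    def test_apply_perturbation_targets_right_parameters(self):
        pop, glob = PopulationParams(), GlobalParams()
        p2, g2 = apply_perturbation(pop, glob, "gaba_weights", 0.8)
        assert p2.J_EI == pytest.approx(pop.J_EI * 0.8)
        assert p2.J_II == pytest.approx(pop.J_II * 0.8)
        assert p2.J_IE == pop.J_IE and g2 is glob
        p2, g2 = apply_perturbation(pop, glob, "glut_drive_to_I", 0.7)
        assert p2.J_IE == pytest.approx(pop.J_IE * 0.7)
        p2, g2 = apply_perturbation(pop, glob, "global_coupling", 0.9)
        assert g2.K_gl == pytest.approx(glob.K_gl * 0.9) and p2 is pop
        p2, g2 = apply_perturbation(pop, glob, "noise_level", 1.3)
        assert g2.sigma_ou == pytest.approx(glob.sigma_ou * 1.3)


class TestRunCondition:
    def test_reference_scale_identical_to_default(self, small_cohort):
        spec = PerturbationSpec(family="noise_level", scales=(1.0, 1.2))
        default = run_condition(small_cohort, spec, 1.0)
        again = run_condition(small_cohort, spec, 1.0)
        for a, b in zip(default, again):
            np.testing.assert_array_equal(a.FC, b.FC)
            assert a.flat() == b.flat()

    def test_full_decoupling_kills_offdiagonal_fc(self, connectome16,
                                                  partition16, tables_small):
        cohort = VirtualCohort(
            connectome=connectome16, tables=tables_small,
            partition=partition16,
            glob=GlobalParams(duration=30.0, transient=2.0),
            seeds=(5,))
        spec = PerturbationSpec(family="global_coupling", scales=(1.0, 0.0),
                                allow_out_of_range=True)
        reports = run_condition(cohort, spec, 0.0)
        FC = reports[0].FC
        off = FC[np.triu_indices(FC.shape[0], k=1)]
        assert abs(off.mean()) < 0.15

    def test_undeclared_scale_rejected(self, small_cohort):
        spec = PerturbationSpec(family="noise_level", scales=(1.0, 1.2))
        with pytest.raises(ValueError, match="not declared"):
            run_condition(small_cohort, spec, 1.3)


class TestCompareToDefault:
    def test_self_comparison_is_null(self):
        rng = np.random.default_rng(0)
        reports = _fake_cohort_reports(rng, 8)
        df = compare_to_default(reports, reports, n_perm=200)
        assert np.allclose(df["mean_default_minus_perturbed"], 0.0)
        assert np.allclose(df["hedges_g"], 0.0)

    def test_sign_convention_fixture(self):
        rng = np.random.default_rng(1)
        default = _fake_cohort_reports(rng, 10)
        c = 0.07
        shifted = []
        for r in default:
            shifted.append(_fake_report({**r.flat(),
                                         "gbc_global": r.gbc_global - c}))
        df = compare_to_default(default, shifted, n_perm=200).set_index("measure")
        assert df.loc["gbc_global", "mean_default_minus_perturbed"] == \
            pytest.approx(c, abs=1e-12)
        assert df.loc["gbc_global", "mean_perturbed_minus_default"] == \
            pytest.approx(-c, abs=1e-12)

    def test_rows_match_direct_stats_calls(self):
        rng = np.random.default_rng(2)
        default = _fake_cohort_reports(rng, 9)
        cond = _fake_cohort_reports(rng, 9, shift=0.04)
        df = compare_to_default(default, cond, n_perm=300, seed=5)
        for _, row in df.iterrows():
            x = np.array([r.flat()[row["measure"]] for r in default])
            y = np.array([r.flat()[row["measure"]] for r in cond])
            ref = compare_groups(x, y, row["measure"], n_perm=300, seed=5)
            assert row["hedges_g"] == pytest.approx(ref.hedges_g, abs=1e-12)
            assert row["p_perm"] == pytest.approx(ref.p_value, abs=1e-12)


class TestEvolutionaryFit:
    def test_recovers_sphere_optimum(self):
        target = np.array([0.3, -1.2])

        def objective(x):
            return -float(((x - target) ** 2).sum())

        res = evolutionary_fit(objective, bounds=[(-2, 2), (-2, 2)],
                               n_init=30, n_pop=15, n_gen=25, seed=1)
        span = 4.0
        assert np.all(np.abs(res["best_params"] - target) < 0.01 * span)

    def test_trace_monotone_best_so_far(self):
        def objective(x):
            return -float((x ** 2).sum())

        res = evolutionary_fit(objective, bounds=[(-1, 1)] * 3,
                               n_init=20, n_pop=10, n_gen=10, seed=2)
        assert np.all(np.diff(res["trace"]) >= -1e-15)

    def test_deterministic_under_seed(self):
        def objective(x):
            return float(np.sin(x).sum())

        a = evolutionary_fit(objective, bounds=[(0, 3)] * 2, n_init=12,
                             n_pop=6, n_gen=8, seed=7)
        b = evolutionary_fit(objective, bounds=[(0, 3)] * 2, n_init=12,
                             n_pop=6, n_gen=8, seed=7)
        np.testing.assert_array_equal(a["trace"], b["trace"])
        np.testing.assert_array_equal(a["best_params"], b["best_params"])

    def test_failing_individuals_discarded_not_fatal(self):
        calls = {"n": 0}

        def objective(x):
            calls["n"] += 1
            if x[0] > 0.5:
                raise RuntimeError("simulation blew up")
            return -float(x[0] ** 2)

        res = evolutionary_fit(objective, bounds=[(0, 1)], n_init=20,
                               n_pop=8, n_gen=5, seed=3)
        assert res["best_params"][0] <= 0.5
        assert calls["n"] > 20
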