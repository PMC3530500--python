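import numpy as np
import pytest
from scipy import stats

from ardiscan.simulate import (
    LogisticModel,
    PenetranceModel,
    SimStudySpec,
    add_imputation_noise,
    max_ld_r2,
    simulate_case_control,
    simulate_consortium,
    simulate_genotypes,
    simulate_ld_pair,
)


class TestSimulateGenotypes:
    def test_hwe_frequencies_at_maf_half(self):
        g = simulate_genotypes(100_000, 0.5, 0)
        freqs = np.bincount(g.astype(int), minlength=3) / g.size
        np.testing.assert_allclose(freqs, [0.25, 0.5, 0.25], atol=0.01)

    def test_empirical_maf_close_to_target(self):
        g = simulate_genotypes(100_000, 0.3, 1)
        assert abs(g.mean() / 2 - 0.3) < 0.005

    def test_same_seed_reproduces(self):
        np.testing.assert_array_equal(simulate_genotypes(1000, 0.3, 5),
                                      simulate_genotypes(1000, 0.3, 5))

    def test_hwe_exact_test_rejects_at_nominal_rate(self):
        rejections = 0
        for seed in range(200):
            g = simulate_genotypes(500, 0.3, seed)
            n = np.bincount(g.astype(int), minlength=3)
            q = (n[1] + 2 * n[2]) / (2 * g.size)
            expected = g.size * np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
            chi2 = np.sum((n - expected) ** 2 / expected)
            rejections += stats.chi2.sf(chi2, 1) < 0.05
        assert rejections <= 25  # ~5% nominal over 200 draws


class TestSimulateLdPair:
    def test_perfect_ld_duplicates_vector(self):
        a, b = simulate_ld_pair(5000, 0.3, 0.3, 1.0, 0)
        np.testing.assert_array_equal(a, b)

    def test_zero_target_independent(self):
        a, b = simulate_ld_pair(10_000, 0.3, 0.25, 0.0, 1)
        assert np.corrcoef(a, b)[0, 1] ** 2 < 0.01

    def test_intermediate_target_achieved(self):
        a, b = simulate_ld_pair(10_000, 0.3, 0.3, 0.8, 2)
        assert 0.75 <= np.corrcoef(a, b)[0, 1] ** 2 <= 0.85

    def test_infeasible_target_errors_with_max(self):
        with pytest.raises(ValueError, match="maximum achievable"):
            simulate_ld_pair(100, 0.05, 0.5, 0.9, 0)
        assert max_ld_r2(0.05, 0.5) < 0.9


class TestPenetranceModel:
    def test_presets_have_unit_baseline_cell(self):
        for model in (PenetranceModel.null(),
                      PenetranceModel.multiplicative(0.3),
                      PenetranceModel.ardi_carrier(-0.3),
                      PenetranceModel.dominant_dominant(0.4),
                      PenetranceModel.recessive_recessive(0.5),
                      PenetranceModel.threshold(0.3),
                      PenetranceModel.checkerboard(0.2)):
            assert model.rr[0, 0] == 1.0
            assert (model.rr > 0).all()

    def test_ardi_carrier_preset_shares_one_deviation(self):
        m = PenetranceModel.ardi_carrier(-0.3, b1=0.1, b2=0.2)
        g = np.arange(3)
        mains = np.exp(0.1 * g[:, None] + 0.2 * g[None, :])
        dev = np.log(m.rr / mains)
        np.testing.assert_allclose(dev[1:, 1:], -0.3, atol=1e-12)
        np.testing.assert_allclose(dev[0, :], 0.0, atol=1e-12)

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            PenetranceModel(np.full((3, 3), 2.0))  # R[0][0] != 1


class TestSimulateCaseControl:
    def test_quotas_met_exactly(self):
        spec = SimStudySpec(n_case=300, n_control=450, seed=0)
        data = simulate_case_control(spec, PenetranceModel.null())
        assert data.n_cases == 300
        assert data.n_controls == 450

    def test_null_model_leaves_genotypes_independent_of_status(self):
        spec = SimStudySpec(n_case=4000, n_control=4000, seed=1)
        data = simulate_case_control(spec, PenetranceModel.null())
        cases = data.dosages[data.phenotype == 1, 0]
        controls = data.dosages[data.phenotype == 0, 0]
        assert stats.ttest_ind(cases, controls).pvalue > 0.001

    def test_zero_covariate_effects_leave_covariates_balanced(self):
        spec = SimStudySpec(n_case=4000, n_control=4000, seed=2)
        data = simulate_case_control(spec, PenetranceModel.null())
        age = data.covariates[:, 0]
        assert abs(np.corrcoef(age, data.phenotype)[0, 1]) < 0.05

    def test_infeasible_quota_raises(self):
        spec = SimStudySpec(n_case=5000, n_control=100, seed=3)
        with pytest.raises(RuntimeError, match="quotas"):
            simulate_case_control(spec, PenetranceModel.null(baseline=1e-4))

    def test_reproducible_for_fixed_seed(self):
        spec = SimStudySpec(n_case=200, n_control=200, seed=4)
        a = simulate_case_control(spec, PenetranceModel.null())
        b = simulate_case_control(spec, PenetranceModel.null())
        np.testing.assert_array_equal(a.dosages, b.dosages)
        np.testing.assert_array_equal(a.phenotype, b.phenotype)


class TestImputationNoise:
    def test_target_one_is_identity(self):
        d = simulate_genotypes(1000, 0.3, 0)
        noisy, achieved = add_imputation_noise(d, 1.0, 1)
        np.testing.assert_array_equal(noisy, d)
        assert achieved == 1.0

    def test_target_half_achieved(self):
        d = simulate_genotypes(10_000, 0.3, 0)
        noisy, achieved = add_imputation_noise(d, 0.5, 1)
        assert 0.45 <= achieved <= 0.55
        assert noisy.min() >= 0 and noisy.max() <= 2

    def test_noisier_dosage_inflates_marginal_se(self):
        from ardiscan.interaction import test_marginal

        model = LogisticModel(intercept=-1.0, beta1=0.2)
        clean = simulate_case_control(
            SimStudySpec(n_case=2000, n_control=2000, seed=5), model)
        noisy = simulate_case_control(
            SimStudySpec(n_case=2000, n_control=2000, seed=5,
                         imputation_r2=(0.4, 1.0)), model)
        assert (test_marginal(noisy, "snp1").se
                > test_marginal(clean, "snp1").se)


class TestSimulateConsortium:
    def test_single_spec_equals_direct_simulation(self):
        spec = SimStudySpec(n_case=200, n_control=200, seed=9)
        direct = simulate_case_control(spec, PenetranceModel.null())
        [via] = simulate_consortium([spec], PenetranceModel.null())
        np.testing.assert_array_equal(direct.dosages, via.dosages)

    def test_homogeneous_studies_show_no_heterogeneity_enrichment(self):
        from ardiscan.interaction import test_ardi
        from ardiscan.meta import cochran_q

        model = LogisticModel(intercept=-1.0, interaction=np.log(0.8))
        phets = []
        for rep in range(30):
            specs = [SimStudySpec(n_case=800, n_control=800,
                                  seed=1000 + rep * 10 + i,
                                  study_id=f"s{i}") for i in range(4)]
            studies = simulate_consortium(specs, model)
            ests = [test_ardi(s, "snp1", "snp2") for s in studies]
            _, p_het = cochran_q([e for e in ests if e.converged])
            phets.append(p_het)
        assert np.mean(np.array(phets) < 0.05) < 0.25

    def test_heterogeneous_interaction_enriches_low_p_het(self):
        from ardiscan.interaction import test_ardi
        from ardiscan.meta import cochran_q

        low = 0
        for rep in range(12):
            studies = []
            for i, gamma in enumerate((np.log(0.4), np.log(0.4),
                                       np.log(2.5), np.log(2.5))):
                model = LogisticModel(intercept=-1.0, interaction=gamma)
                spec = SimStudySpec(n_case=1500, n_control=1500,
                                    seed=2000 + rep * 10 + i,
                                    study_id=f"s{i}")
                studies.append(simulate_case_control(spec, model))
            ests = [test_ardi(s, "snp1", "snp2") for s in studies]
            _, p_het = cochran_q([e for e in ests if e.converged])
            low += p_het < 0.05
        assert low >= 9

    def test_child_seeds_derived_from_master_are_reproducible(self):
        specs = [SimStudySpec(n_case=100, n_control=100) for _ in range(2)]
        a = simulate_consortium(
            [SimStudySpec(n_case=100, n_control=100) for _ in range(2)],
            PenetranceModel.null(), master_seed=3)
        b = simulate_consortium(
            [SimStudySpec(n_case=100, n_control=100) for _ in range(2)],
            PenetranceModel.null(), master_seed=3)
        np.testing.assert_array_equal(a[0].dosages, b[0].dosages)
        np.testing.assert_array_equal(a[1].dosages, b[1].dosages)
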