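import numpy as np
import pytest
from scipy import optimize, stats

# imported under aliases: pytest must not collect the package's test_* API
from ardiscan.interaction import carrier_score
from ardiscan.interaction import test_ardi as ardi_test
from ardiscan.interaction import test_ardi_unrestricted_main as ardi_umain_test
from ardiscan.interaction import test_marginal as marginal_test
from ardiscan.interaction import test_multiplicative as multiplicative_test
from ardiscan.interaction import test_unrestricted as unrestricted_test
from ardiscan.logistic import fit_logistic
from ardiscan.simulate import LogisticModel, SimStudySpec, simulate_case_control

from conftest import make_dataset


class TestCarrierScore:
    @pytest.mark.parametrize("dosage, expected", [
        (2.0, 1.0), (1.0, 1.0), (0.0, 0.0), (0.4, 0.4), (1.7, 1.0),
    ])
    def test_dosage_only(self, dosage, expected):
        assert carrier_score(np.array([dosage]))[0] == pytest.approx(expected)

    def test_probability_triple(self):
        probs = np.array([[0.2, 0.5, 0.3]])
        assert carrier_score(np.array([1.1]), probs)[0] == pytest.approx(0.8)


class TestArdiOracle:
    def test_matches_direct_likelihood_maximization(self, small_pair_dataset):
        """The IRLS ARDI estimate equals a derivative-free maximization of
        the 4-parameter log-likelihood written out independently."""
        data = small_pair_dataset
        g1, g2 = data.dosages[:, 0], data.dosages[:, 1]
        c12 = np.minimum(g1, 1) * np.minimum(g2, 1)
        y = data.phenotype.astype(float)

        def nll(theta):
            eta = theta[0] + theta[1] * g1 + theta[2] * g2 + theta[3] * c12
            return -np.sum(y * eta - np.log1p(np.exp(eta)))

        res = optimize.minimize(nll, np.zeros(4), method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10,
                                         "maxiter": 20000})
        est = ardi_test(data, "snp1", "snp2")
        assert est.converged
        assert est.beta == pytest.approx(res.x[3], abs=1e-4)

    def test_umain_variant_matches_its_own_likelihood(self, small_pair_dataset):
        data = small_pair_dataset
        g1, g2 = data.dosages[:, 0], data.dosages[:, 1]
        h1, m1 = (g1 == 1).astype(float), (g1 == 2).astype(float)
        h2, m2 = (g2 == 1).astype(float), (g2 == 2).astype(float)
        c12 = np.minimum(g1, 1) * np.minimum(g2, 1)
        y = data.phenotype.astype(float)

        def nll(theta):
            eta = (theta[0] + theta[1] * h1 + theta[2] * m1
                   + theta[3] * h2 + theta[4] * m2 + theta[5] * c12)
            return -np.sum(y * eta - np.log1p(np.exp(eta)))

        res = optimize.minimize(nll, np.zeros(6), method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10,
                                         "maxiter": 40000})
        est = ardi_umain_test(data, "snp1", "snp2")
        assert est.converged
        assert est.beta == pytest.approx(res.x[5], abs=1e-4)


class TestUnrestricted:
    def test_empty_double_homozygote_cell_reduces_df(self):
        rng = np.random.default_rng(5)
        g1 = rng.binomial(2, 0.3, 400).astype(float)
        g2 = rng.binomial(2, 0.3, 400).astype(float)
        g2[(g1 == 2) & (g2 == 2)] = 1.0  # empty the (2,2) cell
        y = rng.binomial(1, 0.4, 400)
        est = unrestricted_test(make_dataset(g1, g2, y), "snp1", "snp2")
        assert est.df == 3
        assert "df reduced" in est.message

    def test_lrt_p_uniform_under_null(self):
        rng = np.random.default_rng(6)
        pvals = []
        for _ in range(200):
            g1 = rng.binomial(2, 0.3, 1200).astype(float)
            g2 = rng.binomial(2, 0.3, 1200).astype(float)
            y = rng.binomial(1, 0.5, 1200)
            est = unrestricted_test(make_dataset(g1, g2, y), "snp1", "snp2")
            if est.converged:
                pvals.append(est.p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestDegenerateContracts:
    def test_multiplicative_with_identical_snp_does_not_crash(self):
        rng = np.random.default_rng(8)
        g = rng.binomial(2, 0.3, 300).astype(float)
        y = rng.binomial(1, 0.4, 300)
        est = multiplicative_test(make_dataset(g, g.copy(), y), "snp1", "snp2")
        assert est.converged in (True, False)  # result or flagged failure

    def test_marginal_on_constant_genotype_flagged(self):
        g1 = np.ones(100)
        g2 = np.random.default_rng(9).binomial(2, 0.3, 100).astype(float)
        y = np.random.default_rng(10).binomial(1, 0.4, 100)
        est = marginal_test(make_dataset(g1, g2, y), "snp1")
        assert not est.converged


class TestRecoveryAndConsistency:
    def test_marginal_recovers_known_log_or(self):
        model = LogisticModel(intercept=-1.5, beta1=0.2, beta2=0.0)
        spec = SimStudySpec(n_case=8000, n_control=12000, seed=21)
        data = simulate_case_control(spec, model)
        est = marginal_test(data, "snp1")
        assert est.converged
        assert abs(est.beta - 0.2) < 3 * est.se

    def test_ardi_and_umain_agree_on_additive_main_data(self):
        model = LogisticModel(intercept=-1.0, beta1=np.log(1.2),
                              beta2=np.log(1.1), interaction=np.log(0.7))
        spec = SimStudySpec(n_case=4000, n_control=4000, seed=22)
        data = simulate_case_control(spec, model)
        e1 = ardi_test(data, "snp1", "snp2")
        e2 = ardi_umain_test(data, "snp1", "snp2")
        assert abs(e1.beta - e2.beta) < 2 * max(e1.se, e2.se)

    def test_wald_and_lrt_agree_for_the_1df_interaction(self):
        model = LogisticModel(intercept=-1.0, beta1=np.log(1.2),
                              beta2=np.log(1.1), interaction=np.log(0.9))
        spec = SimStudySpec(n_case=10000, n_control=10000, seed=23)
        data = simulate_case_control(spec, model)
        est = ardi_test(data, "snp1", "snp2")
        g1, g2 = data.dosages[:, 0], data.dosages[:, 1]
        c12 = np.minimum(g1, 1) * np.minimum(g2, 1)
        X_full = np.column_stack([np.ones(len(g1)), g1, g2, c12,
                                  data.covariates])
        X_red = np.column_stack([np.ones(len(g1)), g1, g2, data.covariates])
        y = data.phenotype.astype(float)
        lrt = 2 * (fit_logistic(X_full, y).loglik - fit_logistic(X_red, y).loglik)
        p_lrt = stats.chi2.sf(lrt, 1)
        assert est.z**2 == pytest.approx(lrt, rel=0.05)
        assert abs(est.p - p_lrt) < 0.02


@pytest.fixture(scope="module")
def flip_data():
    rng = np.random.default_rng(30)
    g1 = rng.binomial(2, 0.35, 3000).astype(float)
    g2 = rng.binomial(2, 0.25, 3000).astype(float)
    eta = -0.5 + 0.2 * g1 + 0.1 * g2 + 0.15 * g1 * g2
    y = (rng.random(3000) < 1 / (1 + np.exp(-eta))).astype(int)
    return (make_dataset(g1, g2, y), make_dataset(2 - g1, g2, y))


class TestAlleleFlipInvariance:
    """Flipping which allele a SNP counts (d -> 2-d) leaves the marginal
    and multiplicative tests invariant (the design spans are identical);
    ARDI is intentionally not invariant because the carrier indicator is
    asymmetric in the two alleles."""

    def test_marginal_p_invariant(self, flip_data):
        orig, flipped = flip_data
        a = marginal_test(orig, "snp1")
        b = marginal_test(flipped, "snp1")
        assert a.p == pytest.approx(b.p, rel=1e-6)
        assert a.beta == pytest.approx(-b.beta, abs=1e-6)

    def test_multiplicative_p_invariant(self, flip_data):
        orig, flipped = flip_data
        a = multiplicative_test(orig, "snp1", "snp2")
        b = multiplicative_test(flipped, "snp1", "snp2")
        assert a.p == pytest.approx(b.p, rel=1e-5)
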