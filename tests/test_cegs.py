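import math

import numpy as np
import pytest
from scipy import integrate
from scipy.special import exp1, sici

import sadkit as sk
from sadkit import CEGSParams

GRID = [(g, l) for g in (0.0, 0.5, 1.0, 2.0, 4.0) for l in (0.25, 1.0, 4.0)]


def quad_pmf(x, gamma, lam, convention="stopping"):
    """Independent adaptive-quadrature oracle for the marginal PMF."""

    def integrand(E):
        w = E**gamma / lam
        p = 1.0 / (w + 1.0) if convention == "stopping" else w / (w + 1.0)
        return math.exp(-E) * (1.0 - p) ** x * p

    val, _ = integrate.quad(integrand, 0, np.inf, limit=400)
    return val


class TestStopProb:
    def test_values(self):
        assert sk.cegs_stop_prob(1.0, CEGSParams(2, 1)) == pytest.approx(0.5)
        assert sk.cegs_stop_prob(17.3, CEGSParams(0, 1)) == pytest.approx(0.5)
        assert sk.cegs_stop_prob(2.0, CEGSParams(2, 4)) == pytest.approx(0.5)

    def test_conventions_are_complementary(self):
        E = np.array([0.2, 1.0, 5.0])
        p_stop = sk.cegs_stop_prob(E, CEGSParams(2, 1), convention="stopping")
        p_cont = sk.cegs_stop_prob(E, CEGSParams(2, 1), convention="continuation")
        assert np.allclose(p_stop + p_cont, 1.0)

    def test_domain(self):
        with pytest.raises(ValueError):
            sk.cegs_stop_prob(0.0, CEGSParams(2, 1))
        with pytest.raises(ValueError):
            sk.cegs_stop_prob(1.0, CEGSParams(2, 1), convention="bogus")
        with pytest.raises(ValueError):
            CEGSParams(-1, 1)
        with pytest.raises(ValueError):
            CEGSParams(1, 0)


class TestZeroClass:
    def test_geometric_limit(self):
        assert sk.cegs_p0(CEGSParams(0, 1)) == pytest.approx(0.5, abs=1e-12)
        assert sk.cegs_p0(CEGSParams(0, 3)) == pytest.approx(0.75, abs=1e-12)

    def test_closed_forms(self):
        # gamma=1: e * E1(1); gamma=2: Ci(1) sin(1) + (pi/2 - Si(1)) cos(1)
        assert sk.cegs_p0(CEGSParams(1, 1)) == pytest.approx(math.e * exp1(1.0), abs=1e-10)
        si, ci = sici(1.0)
        expected = ci * math.sin(1.0) + (math.pi / 2 - si) * math.cos(1.0)
        assert sk.cegs_p0(CEGSParams(2, 1)) == pytest.approx(expected, abs=1e-10)

    def test_increasing_in_lam(self):
        for gamma in (0.5, 1.0, 2.0, 4.0):
            p0s = [sk.cegs_p0(CEGSParams(gamma, lam)) for lam in (0.25, 0.5, 1, 2, 4, 16)]
            assert np.all(np.diff(p0s) > 0)

    def test_equals_pmf_at_zero(self):
        for conv in sk.CONVENTIONS:
            params = CEGSParams(2, 1)
            assert sk.cegs_p0(params, convention=conv) == pytest.approx(
                sk.cegs_pmf(0, params, convention=conv), abs=1e-15
            )


class TestPMF:
    @pytest.mark.parametrize("lam", [0.25, 1.0, 4.0])
    def test_gamma_zero_is_geometric(self, lam):
        # constant latent abundance 1/lam: pure geometric, p = lam/(1+lam)
        p = lam / (1.0 + lam)
        x = np.arange(51)
        got = sk.cegs_pmf(x, CEGSParams(0, lam))
        assert np.allclose(got, (1 - p) ** x * p, atol=1e-8, rtol=1e-8)

    @pytest.mark.parametrize("x", [0, 1, 2, 5, 20, 200])
    @pytest.mark.parametrize("conv", ["stopping", "continuation"])
    def test_against_quadrature_oracle(self, x, conv):
        # the continuation mixture concentrates near E=0 at large x and
        # needs a much denser rule there; the default suffices for the rest
        dense = conv == "continuation" and x >= 20
        n_quad = 800 if dense else 120
        got = sk.cegs_pmf(x, CEGSParams(2, 1), n_quad=n_quad, convention=conv)
        assert got == pytest.approx(quad_pmf(x, 2, 1, conv), rel=1e-6 if dense else 1e-7)

    def test_worked_first_class(self):
        # P(1; gamma=2, lam=1) = integral e^-E E^2/(1+E^2)^2 dE
        val, _ = integrate.quad(
            lambda E: math.exp(-E) * E**2 / (1 + E**2) ** 2, 0, np.inf, limit=200
        )
        assert sk.cegs_pmf(1, CEGSParams(2, 1)) == pytest.approx(val, rel=1e-8)

    @pytest.mark.parametrize("gamma,lam", GRID)
    @pytest.mark.parametrize("conv", ["stopping", "continuation"])
    def test_truncation_corrected_normalization(self, gamma, lam, conv):
        params = CEGSParams(gamma, lam)
        total = sk.cegs_pmf(np.arange(301), params, convention=conv).sum()
        total += sk.cegs_survival(300, params, convention=conv)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_survival_vanishes(self):
        # stopping convention, gamma=2, lam=1: the tail past ~2000 is negligible
        assert sk.cegs_survival(2000, CEGSParams(2, 1)) < 1e-6

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sk.cegs_pmf(-1, CEGSParams(2, 1))
        with pytest.raises(ValueError):
            sk.cegs_pmf(0.5, CEGSParams(2, 1))
        with pytest.raises(ValueError):
            sk.cegs_pmf(1, CEGSParams(2, 1), n_quad=10)


class TestCompression:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((1, 1, 3, 5, 7), (1, 1, 3, 3, 3)),
            ((1, 2, 3, 4, 5), (1, 2, 2, 2, 3)),
            ((1, 1, 2, 2, 3), (1, 1, 2, 2, 2)),
            ((7, 5, 3, 1, 1), (1, 1, 3, 3, 3)),  # order-free
        ],
    )
    def test_examples(self, counts, expected):
        assert tuple(sk.compress_counts(counts)) == expected

    def test_preserves_length(self, rng):
        for _ in range(20):
            c = rng.integers(1, 50, size=rng.integers(5, 30))
            if len(np.unique(c)) < 3:
                continue
            assert len(sk.compress_counts(c)) == len(c)

    @pytest.mark.parametrize("counts", [(1, 1, 2, 2), (1, 2, 3, 4), (1, 1, 1, 2, 2)])
    def test_preconditions(self, counts):
        with pytest.raises(ValueError):
            sk.compress_counts(counts)


class TestSampler:
    def test_seed_reproducibility(self):
        a = sk.cegs_sample(300, CEGSParams(2, 1), seed=4)
        b = sk.cegs_sample(300, CEGSParams(2, 1), seed=4)
        assert np.array_equal(a, b)

    def test_gamma_zero_mean(self):
        x = sk.cegs_sample(200000, CEGSParams(0, 1), seed=1)
        assert x.mean() == pytest.approx(1.0, abs=0.02)

    @pytest.mark.parametrize("gamma,lam", GRID)
    def test_tv_against_pmf(self, gamma, lam):
        # tail counts past 300 are lumped into one class: the heavy-tailed
        # corners of the grid scatter a few thousand singleton counts over
        # an enormous support, and that sampling noise alone would dominate
        # an unlumped total-variation distance at 10^6 draws
        params = CEGSParams(gamma, lam)
        K = 300
        x = sk.cegs_sample(10**6, params, seed=8)
        emp = np.bincount(np.minimum(x, K), minlength=K + 1) / len(x)
        model = np.empty(K + 1)
        model[:K] = sk.cegs_pmf(np.arange(K), params)
        model[K] = sk.cegs_survival(K - 1, params)
        assert 0.5 * np.abs(emp - model).sum() < 0.005


class TestFit:
    def test_recovers_parameters(self):
        x = sk.cegs_sample(5000, CEGSParams(2, 1), seed=21)
        fit = sk.cegs_fit(x[x > 0])
        assert fit.model == "cegs" and fit.converged
        assert fit.params.gamma == pytest.approx(2.0, rel=0.25)
        assert fit.params.lam == pytest.approx(1.0, rel=0.4)
        assert fit.R_hat == pytest.approx(5000, rel=0.12)
        assert fit.R_hat >= fit.S_obs

    def test_precondition_errors(self):
        with pytest.raises(ValueError, match="5 species"):
            sk.cegs_fit([1, 2, 3, 4])
        with pytest.raises(ValueError, match="distinct"):
            sk.cegs_fit([1, 1, 2, 2, 1, 2])

    def test_raw_fit_debug_path(self):
        x = sk.cegs_sample(2000, CEGSParams(2, 1), seed=22)
        fit = sk.cegs_fit(x[x > 0], compress=False)
        assert fit.R_hat >= fit.S_obs
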