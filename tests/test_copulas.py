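"""Archimedean kernel: CDF/density identities, domains and sampling."""

import numpy as np
import pytest
from scipy.stats import kendalltau, kstest

from copulaclust.copulas import (
    CLAYTON,
    FRANK,
    GUMBEL,
    CopulaDomainError,
    CopulaModel,
    get_family,
)

ALL = [GUMBEL, CLAYTON, FRANK]


def interior_points(rng, n, d):
    return rng.uniform(0.05, 0.95, size=(n, d))


def mixed_partial_fd(model, u, h=1e-3):
    """Central-difference d-th mixed partial of the CDF at u."""
    d = model.dim
    total = 0.0
    for mask in range(1 << d):
        signs = np.array([1.0 if mask >> i & 1 else -1.0 for i in range(d)])
        total += (-1.0) ** (d - bin(mask).count("1")) * model.cdf(u + 0.5 * h * signs)
    return total / h**d


class TestCdf:
    def test_independence_product(self):
        assert CopulaModel(GUMBEL, 1.0, 2).cdf([0.3, 0.7]) == pytest.approx(0.21)

    def test_clayton_closed_form(self):
        expected = (0.5**-2 + 0.5**-2 - 1) ** -0.5
        assert CopulaModel(CLAYTON, 2.0, 2).cdf([0.5, 0.5]) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("family,theta", [(GUMBEL, 2.5), (CLAYTON, 1.5), (FRANK, 4.0)])
    @pytest.mark.parametrize("d", [2, 3, 4])
    def test_grounded_and_margins(self, family, theta, d, rng):
        model = CopulaModel(family, theta, d)
        for _ in range(20):
            u = interior_points(rng, 1, d)[0]
            i = rng.integers(d)
            u0 = u.copy()
            u0[i] = 0.0
            assert model.cdf(u0) == 0.0
            u1 = np.ones(d)
            u1[i] = u[i]
            assert model.cdf(u1) == pytest.approx(u[i], abs=1e-9)

    @pytest.mark.parametrize("family,theta", [(GUMBEL, 3.0), (CLAYTON, 2.0), (FRANK, 5.0)])
    @pytest.mark.parametrize("d", [2, 3])
    def test_d_increasing_on_random_boxes(self, family, theta, d, rng):
        model = CopulaModel(family, theta, d)
        for _ in range(50):
            a = rng.uniform(0, 1, size=d)
            b = rng.uniform(a, 1)
            total = 0.0
            for mask in range(1 << d):
                corner = np.where([mask >> i & 1 for i in range(d)], b, a)
                total += (-1.0) ** (d - bin(mask).count("1")) * model.cdf(corner)
            assert total >= -1e-12


class TestLogDensity:
    def test_independence_is_zero(self):
        assert CopulaModel(GUMBEL, 1.0, 2).log_density([0.3, 0.7]) == pytest.approx(0.0, abs=1e-12)

    def test_clayton_closed_form(self):
        theta, u = 2.0, np.array([0.5, 0.5])
        expected = np.log(
            (1 + theta) * (u[0] * u[1]) ** -(1 + theta)
            * (u[0] ** -theta + u[1] ** -theta - 1) ** -(2 + 1 / theta)
        )
        got = CopulaModel(CLAYTON, theta, 2).log_density(u)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.3926, abs=5e-4)

    @pytest.mark.parametrize("family,theta", [(GUMBEL, 2.0), (CLAYTON, 1.5), (FRANK, 4.0)])
    @pytest.mark.parametrize("d", [2, 3])
    def test_matches_finite_difference_of_cdf(self, family, theta, d, rng):
        model = CopulaModel(family, theta, d)
        for u in interior_points(rng, 25, d):
            fd = mixed_partial_fd(model, u)
            assert np.exp(model.log_density(u)) == pytest.approx(fd, rel=1e-4)

    @pytest.mark.parametrize(
        "family,theta", [(GUMBEL, 1.0), (CLAYTON, 1e-6), (FRANK, 1e-6)]
    )
    def test_independence_limit(self, family, theta, rng):
        model = CopulaModel(family, theta, 3)
        u = interior_points(rng, 50, 3)
        assert np.max(np.abs(model.log_density(u))) < 1e-3

    @pytest.mark.parametrize("family,theta", [(GUMBEL, 3.0), (CLAYTON, 2.0), (FRANK, 6.0)])
    def test_exchangeable(self, family, theta, rng):
        model = CopulaModel(family, theta, 4)
        u = interior_points(rng, 30, 4)
        base = model.log_density(u)
        for _ in range(5):
            perm = rng.permutation(4)
            # symmetric up to summation-order rounding (last few ulps)
            assert np.allclose(model.log_density(u[:, perm]), base, rtol=1e-12, atol=1e-13)

    @pytest.mark.parametrize("family,theta", [(GUMBEL, 2.5), (CLAYTON, 3.0), (FRANK, 5.0)])
    @pytest.mark.parametrize("d", [2, 3])
    def test_monte_carlo_normalisation(self, family, theta, d, rng):
        # mean of the density under uniform draws is 1 (it integrates to 1)
        model = CopulaModel(family, theta, d)
        u = rng.uniform(1e-6, 1 - 1e-6, size=(100_000, d))
        w = np.exp(model.log_density(u))
        se = w.std() / np.sqrt(len(w))
        assert abs(w.mean() - 1.0) < 3 * se


class TestDomains:
    @pytest.mark.parametrize(
        "family,bad",
        [(GUMBEL, 0.8), (GUMBEL, 51.0), (CLAYTON, 0.0), (CLAYTON, -1.0),
         (CLAYTON, 60.0), (FRANK, -2.0), (FRANK, 101.0)],
    )
    def test_theta_rejected(self, family, bad):
        with pytest.raises(CopulaDomainError):
            CopulaModel(family, bad, 2)

    def test_dimension_and_shape_errors(self):
        with pytest.raises(CopulaDomainError):
            CopulaModel(CLAYTON, 2.0, 1)
        model = CopulaModel(CLAYTON, 2.0, 3)
        with pytest.raises(CopulaDomainError):
            model.cdf([0.5, 0.5])
        with pytest.raises(CopulaDomainError):
            model.log_density([0.5, 0.5, 1.0])  # boundary coordinate

    def test_family_lookup(self):
        assert get_family("Gumbel") is GUMBEL
        with pytest.raises(CopulaDomainError):
            get_family("gaussian")


class TestSampling:
    def test_clayton_kendall_tau(self):
        u = CopulaModel(CLAYTON, 4.0, 2).sample(20_000, 42)
        tau = kendalltau(u[:, 0], u[:, 1]).statistic
        assert tau == pytest.approx(4.0 / 6.0, abs=0.02)

    def test_gumbel_independence(self):
        u = CopulaModel(GUMBEL, 1.0, 3).sample(5_000, 7)
        corr = np.corrcoef(u.T)
        off = corr[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.03)

    @pytest.mark.parametrize(
        "family,theta,seed", [(GUMBEL, 3.0, 11), (CLAYTON, 2.0, 12), (FRANK, 4.0, 13)]
    )
    def test_uniform_margins(self, family, theta, seed):
        u = CopulaModel(family, theta, 2).sample(20_000, seed)
        for j in range(2):
            assert kstest(u[:, j], "uniform").pvalue > 0.01

    def test_seed_determinism(self):
        a = CopulaModel(FRANK, 4.0, 3).sample(100, 5)
        b = CopulaModel(FRANK, 4.0, 3).sample(100, 5)
        assert np.array_equal(a, b)
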