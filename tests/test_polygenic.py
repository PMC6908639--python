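"""Polygenic variance decomposition: oracle equivalence, invariants and
hypothesis tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from telodyn import (
    PolygenicModelSpec,
    compute_kinship,
    covariate_association,
    fit_polygenic,
    lrt_covariate,
    lrt_heritability,
    naive_association,
)
from telodyn.pedigree import KinshipMatrix
from telodyn.polygenic import _fit, _prepare


@pytest.fixture(scope="module")
def family_data(three_generation):
    """Six related individuals with a known-covariance phenotype."""
    km = compute_kinship(three_generation)
    rng = np.random.default_rng(21)
    ids = km.ids
    A = km.additive_relationship()
    L = np.linalg.cholesky(A + 1e-10 * np.eye(len(ids)))
    female = np.array([0, 1, 1, 0, 1, 1], dtype=float)
    y = (0.4 * female + np.sqrt(0.5) * (L @ rng.standard_normal(len(ids)))
         + np.sqrt(0.5) * rng.standard_normal(len(ids)))
    data = pd.DataFrame({"y": y, "female": female}, index=ids)
    return km, data


@pytest.fixture(scope="module")
def cohort_data():
    """A 120-animal cohort drawn from a generated colony pedigree."""
    import telodyn
    from telodyn.simulate import generation_depths

    ped = telodyn.generate_pedigree(seed=77)
    depth = generation_depths(ped)
    top = max(depth.values())
    pool = [i for i in ped.ids if depth[i] >= top - 1]
    rng = np.random.default_rng(4)
    ids = list(rng.choice(pool, size=120, replace=False))
    km = compute_kinship(ped).submatrix(ids)
    A = km.additive_relationship()
    L = np.linalg.cholesky(A + 1e-10 * np.eye(120))
    female = rng.integers(0, 2, 120).astype(float)
    age = rng.uniform(6, 17, 120)
    y = (0.5 * female - 0.08 * (age - age.mean())
         + np.sqrt(0.35) * (L @ rng.standard_normal(120))
         + np.sqrt(0.65) * rng.standard_normal(120))
    data = pd.DataFrame({"y": y, "female": female, "age": age}, index=ids)
    return km, data


class TestLikelihoodOracle:
    def test_profile_matches_dense_mvn(self, family_data):
        """At 20 grid points of h2 the profiled ML objective equals the
        dense multivariate-normal log-density at the profiled MLEs."""
        km, data = family_data
        spec = PolygenicModelSpec("y", ("female",), km)
        model = _prepare(spec, data, min_rows=4)
        A = km.additive_relationship()
        X = np.column_stack([np.ones(len(data)),
                             data["female"].to_numpy()])
        y = data["y"].to_numpy()
        for h2 in np.linspace(0.0, 0.95, 20):
            ll, beta, sigma2, _ = model.profile(h2, "ml")
            V = sigma2 * (h2 * A + (1 - h2) * np.eye(len(y)))
            dense = multivariate_normal.logpdf(y, mean=X @ beta, cov=V)
            assert ll == pytest.approx(dense, abs=1e-8)

    def test_fit_not_beaten_by_grid(self, cohort_data):
        km, data = cohort_data
        spec = PolygenicModelSpec("y", ("female", "age"), km)
        fit = fit_polygenic(spec, data, method="ml")
        model = _prepare(spec, data)
        best_grid = max(model.loglik(h, "ml")
                        for h in np.linspace(0, 0.999999, 2001))
        assert fit.loglik >= best_grid - 1e-9


class TestFitInvariants:
    def test_nesting_and_variance_signs(self, cohort_data):
        km, data = cohort_data
        spec = PolygenicModelSpec("y", ("female", "age"), km)
        model = _prepare(spec, data)
        full = _fit(model, "ml")
        null = _fit(model.drop("female"), "ml")
        assert full.loglik >= null.loglik
        assert full.sigma2_g >= 0 and full.sigma2_e >= 0
        assert full.h2 == pytest.approx(
            full.sigma2_g / (full.sigma2_g + full.sigma2_e))

    @pytest.mark.parametrize("method", ["ml", "reml"])
    def test_scale_equivariance(self, cohort_data, method):
        km, data = cohort_data
        spec = PolygenicModelSpec("y", ("female", "age"), km)
        base = fit_polygenic(spec, data, method=method)
        scaled = data.copy()
        c = 3.7
        scaled["y"] = c * scaled["y"]
        other = fit_polygenic(spec, scaled, method=method)
        assert other.h2 == pytest.approx(base.h2, abs=1e-6)
        assert other.sigma2_g == pytest.approx(c * c * base.sigma2_g,
                                               rel=1e-6)
        assert other.sigma2_e == pytest.approx(c * c * base.sigma2_e,
                                               rel=1e-6)
        p0 = lrt_covariate(spec, data, "female")
        p1 = lrt_covariate(spec, scaled, "female")
        assert p0 == pytest.approx(p1, abs=1e-6)

    def test_unrelated_individuals_flat_ridge(self):
        """With 2*Phi = I the likelihood cannot separate genetic from
        environmental variance; the fit resolves to h2 = 0 flagged."""
        ids = [f"u{k}" for k in range(40)]
        km = KinshipMatrix(ids, 0.5 * np.eye(40))
        rng = np.random.default_rng(0)
        data = pd.DataFrame({"y": rng.standard_normal(40),
                             "female": rng.integers(0, 2, 40)}, index=ids)
        fit = fit_polygenic(PolygenicModelSpec("y", ("female",), km), data)
        assert fit.h2 == 0.0
        assert "unidentifiable" in fit.flags and fit.boundary

    def test_constant_trait_rejected(self, cohort_data):
        km, data = cohort_data
        flat = data.copy()
        flat["y"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_polygenic(PolygenicModelSpec("y", ("female",), km), flat)


class TestLrt:
    def test_zero_covariate_gives_p_one(self, cohort_data):
        """Constraining an identically-zero covariate changes nothing:
        the LRT statistic is 0 and p = 1."""
        km, data = cohort_data
        data = data.copy()
        data["zero"] = 0.0
        spec = PolygenicModelSpec("y", ("female", "age", "zero"), km)
        assert lrt_covariate(spec, data, "zero") == 1.0
        # an informative covariate still tests normally alongside it
        p = lrt_covariate(PolygenicModelSpec("y", ("female", "age"), km),
                          data, "female")
        assert 0.0 < p <= 1.0

    def test_boundary_zero_statistic(self):
        ids = [f"u{k}" for k in range(30)]
        km = KinshipMatrix(ids, 0.5 * np.eye(30))
        rng = np.random.default_rng(1)
        data = pd.DataFrame({"y": rng.standard_normal(30),
                             "female": rng.integers(0, 2, 30)}, index=ids)
        p = lrt_heritability(PolygenicModelSpec("y", ("female",), km), data)
        assert p == 0.5


class TestAssociation:
    def test_r2_is_r_squared_and_sign_matches_beta(self, cohort_data):
        km, data = cohort_data
        rng = np.random.default_rng(9)
        data = data.copy()
        data["marker"] = (0.3 * (data["y"] - data["y"].mean())
                          + rng.standard_normal(len(data)))
        spec = PolygenicModelSpec("y", ("female", "age"), km)
        row = covariate_association(spec, data, "marker")
        assert row.r2 == pytest.approx(row.r ** 2, abs=1e-12)
        assert np.sign(row.r) == np.sign(row.beta)
        assert row.r > 0

    def test_independent_predictor_near_zero(self, cohort_data):
        km, data = cohort_data
        rng = np.random.default_rng(12)
        data = data.copy()
        data["noise"] = rng.standard_normal(len(data))
        spec = PolygenicModelSpec("y", ("female", "age"), km)
        row = covariate_association(spec, data, "noise")
        assert abs(row.r) < 0.25
        assert row.p > 0.01

    def test_naive_route_agrees_in_direction(self, cohort_data):
        km, data = cohort_data
        rng = np.random.default_rng(11)
        data = data.copy()
        data["marker"] = (0.5 * (data["y"] - data["y"].mean())
                          + rng.standard_normal(len(data)))
        spec = PolygenicModelSpec("y", ("female", "age"), km)
        model_row = covariate_association(spec, data, "marker")
        plain_row = naive_association(data, "y", "marker")
        assert np.sign(model_row.r) == np.sign(plain_row.r)
        assert abs(model_row.r - plain_row.r) < 0.15
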