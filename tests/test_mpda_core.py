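import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phenoscreen.mpda_core import (
    ControlModel,
    DegenerateSeparationError,
    NoSeparatingFeaturesError,
    SingularCovarianceError,
    fit_control_model,
    mahalanobis_score,
    per_feature_zprime,
    score_plate,
    select_features,
    zprime,
)
from phenoscreen.synthetic_screen import ScreenSimConfig, simulate_feature_table


def values_with(mean, sd):
    """Three values with exactly the requested sample mean and SD (ddof=1)."""
    return mean + sd * np.array([-1.0, 0.0, 1.0])


def control_frame(ac: np.ndarray, nc: np.ndarray, names=None):
    X = np.vstack([ac, nc])
    names = names or [f"f{i}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=names)
    roles = pd.Series(["active_control"] * len(ac) + ["negative_control"] * len(nc))
    return df, roles


class TestZPrime:
    def test_textbook_separation(self):
        res = zprime(values_with(100, 6), values_with(10, 6))
        assert res.zprime == pytest.approx(0.6, abs=1e-12)
        assert (res.n_plus, res.n_minus) == (3, 3)

    def test_noiseless_limit_is_one(self):
        assert zprime([5.0, 5.0], [1.0, 1.0]).zprime == 1.0

    def test_equal_means_degenerate(self):
        with pytest.raises(DegenerateSeparationError):
            zprime([1.0, 3.0], [3.0, 1.0])

    def test_too_few_values(self):
        with pytest.raises(ValueError, match=">= 2"):
            zprime([1.0], [0.0, 1.0])

    @given(
        mu=st.floats(-50, 50),
        gap=st.floats(0.5, 100),
        sd1=st.floats(0, 10),
        sd2=st.floats(0, 10),
    )
    def test_symmetric_and_bounded(self, mu, gap, sd1, sd2):
        a, b = values_with(mu, sd1), values_with(mu + gap, sd2)
        z_ab, z_ba = zprime(a, b).zprime, zprime(b, a).zprime
        assert z_ab == z_ba
        assert z_ab <= 1.0


class TestFeatureSelection:
    def test_single_separating_feature_wins(self, rng):
        n = 12
        perfect = np.concatenate([np.ones(n), np.zeros(n)])  # Z' = 1
        noise = rng.normal(0, 1, (2 * n, 10))
        df = pd.DataFrame(
            np.column_stack([perfect, noise]),
            columns=["sep"] + [f"noise{i}" for i in range(10)],
        )
        roles = pd.Series(["active_control"] * n + ["negative_control"] * n)
        subset = select_features(df, roles, zprime_floor=0.0)
        assert subset.names == ("sep",)
        assert subset.per_feature_zprime["sep"] == 1.0

    def test_constant_feature_excluded_as_degenerate(self):
        ac = np.column_stack([np.ones(4) * 5, np.arange(4) + 10.0])
        nc = np.column_stack([np.ones(4) * 5, np.arange(4) - 10.0])
        df, roles = control_frame(ac, nc, names=["const", "good"])
        zp = per_feature_zprime(df, roles)
        assert "const" not in zp
        subset = select_features(df, roles)
        assert subset.names == ("good",)

    def test_ties_broken_by_catalog_order_and_capped(self):
        ac = np.tile(values_with(10, 1).reshape(-1, 1), (1, 5))
        nc = np.tile(values_with(0, 1).reshape(-1, 1), (1, 5))
        df, roles = control_frame(ac, nc, names=list("abcde"))
        subset = select_features(df, roles, max_features=3)
        assert subset.names == ("a", "b", "c")

    def test_no_feature_clears_floor(self, rng):
        noise = rng.normal(0, 1, (20, 4))
        df = pd.DataFrame(noise, columns=list("wxyz"))
        roles = pd.Series(["active_control"] * 10 + ["negative_control"] * 10)
        with pytest.raises(NoSeparatingFeaturesError):
            select_features(df, roles, zprime_floor=0.9)


class TestControlModel:
    def test_full_shrinkage_gives_scaled_identity(self, rng):
        X = rng.normal(0, 1, (20, 4))
        model = fit_control_model(X, lam=1.0)
        S = np.cov(X, rowvar=False, ddof=1)
        np.testing.assert_allclose(
            model.sigma, np.trace(S) / 4 * np.eye(4), atol=1e-12
        )

    def test_zero_shrinkage_gives_sample_covariance(self, rng):
        X = rng.normal(0, 2, (50, 3))
        model = fit_control_model(X, lam=0.0)
        np.testing.assert_allclose(model.sigma, np.cov(X, rowvar=False, ddof=1))

    def test_shrinkage_rescues_n_below_d(self, rng):
        X = rng.normal(0, 1, (3, 10))
        model = fit_control_model(X, lam=0.1)
        eigvals = np.linalg.eigvalsh(model.sigma)
        S = np.cov(X, rowvar=False, ddof=1)
        assert eigvals.min() > 0
        assert eigvals.min() >= 0.1 * np.trace(S) / 10 - 1e-10

    def test_singular_without_shrinkage(self, rng):
        X = rng.normal(0, 1, (3, 10))
        with pytest.raises(SingularCovarianceError):
            fit_control_model(X, lam=0.0)

    def test_nan_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="non-finite"):
            fit_control_model(X)


class TestMahalanobis:
    def test_distance_to_mean_is_zero(self, rng):
        X = rng.normal(0, 1, (30, 4))
        model = fit_control_model(X, lam=0.1)
        assert mahalanobis_score(model.mu, model) == 0.0

    def test_one_dimensional_reduces_to_standardized_distance(self):
        X = np.array([[-2.0], [0.0], [2.0]])  # mean 0, variance 4
        model = fit_control_model(X, lam=0.0)
        assert mahalanobis_score(np.array([4.0]), model) == pytest.approx(2.0)

    def test_matches_explicit_inverse(self, rng):
        for _ in range(100):
            d = int(rng.integers(1, 6))
            A = rng.normal(0, 1, (d + 3, d))
            sigma = A.T @ A / (d + 3) + 0.1 * np.eye(d)
            mu = rng.normal(0, 1, d)
            model = ControlModel(
                mu=mu, sigma=sigma, lam=0.0, n=d + 3,
                feature_names=tuple(f"f{i}" for i in range(d)),
            )
            x = rng.normal(0, 2, d)
            expected = np.sqrt((x - mu) @ np.linalg.inv(sigma) @ (x - mu))
            assert mahalanobis_score(x, model) == pytest.approx(expected, abs=1e-8)

    def test_affine_invariance_without_shrinkage(self, rng):
        n, d = 40, 4
        X = rng.normal(0, 1, (n, d))
        x = rng.normal(0, 1, d)
        base = mahalanobis_score(x, fit_control_model(X, lam=0.0))
        for _ in range(10):
            A = rng.normal(0, 1, (d, d)) + 2 * np.eye(d)
            b = rng.normal(0, 5, d)
            mapped = mahalanobis_score(x @ A.T + b, fit_control_model(X @ A.T + b, lam=0.0))
            assert mapped == pytest.approx(base, abs=1e-8)

    def test_dimension_mismatch_raises(self, rng):
        model = fit_control_model(rng.normal(0, 1, (10, 3)), lam=0.1)
        with pytest.raises(ValueError, match="dimension"):
            mahalanobis_score(np.zeros(4), model)


class TestScorePlate:
    def test_controls_separate_on_calibrated_plate(self):
        df, _ = simulate_feature_table(ScreenSimConfig(), seed=3)
        result = score_plate(df)
        s = result.scores
        ac = s.loc[s["role"] == "active_control", "mhd_ac"]
        nc = s.loc[s["role"] == "negative_control", "mhd_ac"]
        assert ac.median() < nc.median()
        assert len(s) == 384
        assert result.qc.zprime <= 1.0
        assert (s["mhd_ac"] >= 0).all() and (s["mhd_nc"] >= 0).all()

    def test_controls_only_plate_is_scoreable(self):
        df, _ = simulate_feature_table(ScreenSimConfig(), n_compound=0, seed=5)
        result = score_plate(df)
        assert len(result.scores) == 64
        assert np.isfinite(result.qc.zprime)

    def test_per_column_affine_invariance(self, rng):
        df, _ = simulate_feature_table(ScreenSimConfig(), seed=9)
        base = score_plate(df, lam=0.0)
        feat_cols = [c for c in df.columns if c not in ("well", "role", "compound_id")]
        mapped = df.copy()
        scales = rng.uniform(0.5, 3.0, len(feat_cols))
        shifts = rng.normal(0, 10, len(feat_cols))
        mapped[feat_cols] = mapped[feat_cols] * scales + shifts
        res = score_plate(mapped, lam=0.0)
        np.testing.assert_allclose(
            res.scores["mhd_ac"], base.scores["mhd_ac"], atol=1e-8
        )
        np.testing.assert_allclose(
            res.scores["mhd_nc"], base.scores["mhd_nc"], atol=1e-8
        )

    def test_per_feature_zprime_monotone_in_separation(self):
        zs = []
        for sep in (7.0, 12.0, 18.0):
            cfg = dataclasses.replace(ScreenSimConfig(), control_separation=sep)
            df, _ = simulate_feature_table(
                cfg, n_ac=300, n_nc=300, n_compound=0, feature_dim=3, seed=11
            )
            zp = per_feature_zprime(
                df[["f000", "f001", "f002"]], df["role"]
            )
            zs.append(zp["f000"])
        assert zs[0] < zs[1] < zs[2]
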