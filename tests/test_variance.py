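"""Variance-component engine: ANOVA decomposition, profiled REML/ML, metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isoniche import (
    Isotope,
    anova_trophic_metrics,
    fit_random_intercept,
    lmm_trophic_metrics,
    two_way_anova_ss,
)
from isoniche.variance import RandomInterceptModel, trophic_metrics_table

from conftest import balanced_scute


# ---------------------------------------------------------------------------
# ANOVA sums of squares
# ---------------------------------------------------------------------------

def _projection_oracle(y, X_blocks):
    """Sequential SS by explicit nested least-squares RSS differences."""
    y = np.asarray(y, float)
    X = np.ones((y.size, 1))
    rss = [float(np.sum((y - y.mean()) ** 2))]
    for blk in X_blocks:
        X = np.hstack([X, blk])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss.append(float(np.sum((y - X @ beta) ** 2)))
    return [rss[i] - rss[i + 1] for i in range(len(X_blocks))] + [rss[-1]]


class TestAnova:
    def test_constant_response_all_ss_zero(self):
        y = np.full(12, 3.3)
        tab = two_way_anova_ss(y, np.tile([1, 2, 3, 4], 3), np.repeat(list("abc"), 4))
        for term in ("layer", "turtle", "residual"):
            assert tab[term][0] == pytest.approx(0.0, abs=1e-18)

    def test_matches_projection_oracle(self, rng):
        # 3 animals x 4 layers, arbitrary values
        turtle = np.repeat(list("abc"), 4)
        layer = np.tile([1.0, 2.0, 3.0, 4.0], 3)
        y = rng.normal(size=12)
        tab = two_way_anova_ss(y, layer, turtle)
        lay_blk = (layer - layer.mean())[:, None]
        tur_blk = np.zeros((12, 2))
        tur_blk[4:8, 0] = 1
        tur_blk[8:, 1] = 1
        ss = _projection_oracle(y, [lay_blk, tur_blk])
        assert tab["layer"][0] == pytest.approx(ss[0], abs=1e-10)
        assert tab["turtle"][0] == pytest.approx(ss[1], abs=1e-10)
        assert tab["residual"][0] == pytest.approx(ss[2], abs=1e-10)

    def test_sequential_ss_sum_to_total(self, scute, rng):
        y = scute["d13C"].to_numpy()
        tab = two_way_anova_ss(y, scute["layer"].to_numpy(), scute["turtle_id"].to_numpy())
        total = sum(tab[t][0] for t in ("layer", "turtle", "residual"))
        assert total == pytest.approx(tab.ss_total, rel=1e-8)

    def test_pure_group_effect_matches_one_way_closed_form(self, rng):
        # no layer trend: turtle term reduces to one-way between-group MS
        g, k = 5, 6
        b = rng.normal(0, 2, g)
        y = np.repeat(b, k) + rng.normal(0, 0.5, g * k)
        turtle = np.repeat(np.arange(g), k)
        tab = two_way_anova_ss(y, None, turtle)
        gm = y.reshape(g, k).mean(axis=1)
        ms_between = k * np.sum((gm - y.mean()) ** 2) / (g - 1)
        assert tab.mean_square("turtle") == pytest.approx(ms_between, rel=1e-10)

    def test_layer_as_factor_option(self, rng):
        turtle = np.repeat(list("abcd"), 5)
        layer = np.tile(np.arange(1.0, 6.0), 4)
        y = rng.normal(size=20) + 0.3 * layer**2
        tab = two_way_anova_ss(y, layer, turtle, layer_as_factor=True)
        assert tab["layer"][1] == 4  # 5 levels -> 4 df

    def test_single_turtle_rejected(self):
        with pytest.raises(ValueError, match="individuals"):
            two_way_anova_ss(np.arange(4.0), None, np.repeat("a", 4))


# ---------------------------------------------------------------------------
# Profiled REML / ML engine
# ---------------------------------------------------------------------------

def _em_reml_oracle(y, codes, g, tol=1e-12, max_iter=20_000):
    """EM algorithm for REML variance components (dense, small n).

    Classical update  σ_k² ← σ_k² + σ_k⁴/q_k·(yᵀPZ_kZ_kᵀPy − tr(Z_kᵀPZ_k))
    with P the REML projection; fixed point = REML estimating equations.
    """
    n = y.size
    X = np.ones((n, 1))
    Z = np.zeros((n, g))
    Z[np.arange(n), codes] = 1.0
    s2b, s2w = np.var(y) / 2 + 0.1, np.var(y) / 2 + 0.1
    for _ in range(max_iter):
        V = s2w * np.eye(n) + s2b * (Z @ Z.T)
        Vi = np.linalg.inv(V)
        P = Vi - Vi @ X @ np.linalg.solve(X.T @ Vi @ X, X.T @ Vi)
        Py = P @ y
        new_b = s2b + (s2b**2 / g) * (Py @ Z @ Z.T @ Py - np.trace(Z.T @ P @ Z))
        new_w = s2w + (s2w**2 / n) * (Py @ Py - np.trace(P))
        if abs(new_b - s2b) + abs(new_w - s2w) < tol:
            s2b, s2w = new_b, new_w
            break
        s2b, s2w = max(new_b, 1e-12), max(new_w, 1e-12)
    return s2b, s2w


class TestRandomIntercept:
    def test_balanced_reml_equals_moments_closed_form(self, rng):
        # balanced one-way layout: REML σ̂²_b = (MS_between − MS_within)/k
        g, k = 8, 5
        y = np.repeat(rng.normal(0, 1.5, g), k) + rng.normal(0, 0.7, g * k)
        tid = np.repeat(np.arange(g), k)
        tab = two_way_anova_ss(y, None, tid)
        mom = (tab.mean_square("turtle") - tab.mean_square("residual")) / k
        fit = fit_random_intercept(y, None, tid, method="reml")
        assert fit.sigma2_between == pytest.approx(max(mom, 0.0), abs=1e-6)
        assert fit.sigma2_within == pytest.approx(tab.mean_square("residual"), rel=1e-6)

    def test_matches_em_oracle_on_random_balanced_datasets(self):
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(50):
            g, k = int(rng.integers(5, 9)), int(rng.integers(3, 6))
            y = np.repeat(rng.normal(0, 1.4, g), k) + rng.normal(0, 1.0, g * k)
            tid = np.repeat(np.arange(g), k)
            fit = fit_random_intercept(y, None, tid, method="reml")
            if fit.boundary:
                continue  # EM cannot reach an exact zero boundary
            s2b, s2w = _em_reml_oracle(y, tid, g)
            assert fit.sigma2_between == pytest.approx(s2b, rel=1e-5)
            assert fit.sigma2_within == pytest.approx(s2w, rel=1e-5)
            checked += 1
        assert checked >= 30

    def test_matches_statsmodels_mixedlm_unbalanced(self, scute):
        sm = pytest.importorskip("statsmodels.api")
        df = scute
        m = sm.MixedLM(
            df["d15N"].to_numpy(),
            np.column_stack([np.ones(len(df)), df["layer"].to_numpy()]),
            groups=df["turtle_id"].to_numpy(),
        ).fit(reml=True)
        ours = fit_random_intercept(
            df["d15N"].to_numpy(), df["layer"].to_numpy(), df["turtle_id"].to_numpy(),
            method="reml",
        )
        assert ours.sigma2_within == pytest.approx(m.scale, rel=1e-4)
        assert ours.sigma2_between == pytest.approx(float(np.asarray(m.cov_re)[0, 0]), rel=1e-3)
        assert ours.params == pytest.approx(np.asarray(m.fe_params), rel=1e-4)

    def test_recovery_200x10(self):
        rng = np.random.default_rng(42)
        g, k = 200, 10
        b = rng.normal(0, np.sqrt(2.0), g)
        y = np.repeat(b, k) + rng.normal(0, 1.0, g * k)
        tid = np.repeat(np.arange(g), k)
        fit = fit_random_intercept(y, None, tid)
        assert fit.sigma2_between == pytest.approx(np.var(b, ddof=1), rel=0.10)
        assert fit.sigma2_within == pytest.approx(1.0, rel=0.10)

    def test_pure_noise_hits_zero_boundary(self, rng):
        y = rng.normal(0, 1, 60)
        tid = np.repeat(np.arange(10), 6)
        fit = fit_random_intercept(y, None, tid)
        assert fit.sigma2_between <= 0.05
        if fit.sigma2_between == 0.0:
            assert fit.boundary

    def test_ml_llf_increases_with_extra_covariate(self, scute):
        y = scute["d13C"].to_numpy()
        lay = scute["layer"].to_numpy()
        tid = scute["turtle_id"].to_numpy()
        full = fit_random_intercept(y, lay, tid, method="ml")
        null = fit_random_intercept(y, None, tid, method="ml")
        assert full.llf >= null.llf - 1e-8

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            RandomInterceptModel(
                np.arange(6.0), np.repeat([0, 1], 3), exog=np.ones((6, 1))
            )

    def test_summary_mentions_components(self, scute):
        fit = fit_random_intercept(
            scute["d13C"].to_numpy(), scute["layer"].to_numpy(),
            scute["turtle_id"].to_numpy(),
        )
        s = fit.summary()
        assert "sigma2_b" in s and "REML" in s


# ---------------------------------------------------------------------------
# Trophic metrics
# ---------------------------------------------------------------------------

class TestTrophicMetrics:
    def test_tnw_identity_both_estimators(self, scute):
        for fn in (anova_trophic_metrics, lmm_trophic_metrics):
            for iso in (Isotope.C13, Isotope.N15):
                m = fn(scute, iso)
                assert m.TNW == m.WIC + m.BIC  # exact by construction
                assert 0.0 <= m.ratio <= 1.0

    def test_specialists_have_ratio_near_zero(self, rng):
        t = balanced_scute(rng, n_turtles=12, n_layers=6, sigma_b=3.0, sigma_w=0.05)
        m = lmm_trophic_metrics(t, Isotope.C13)
        assert m.ratio < 0.05

    def test_generalists_have_ratio_near_one(self, rng):
        t = balanced_scute(rng, n_turtles=12, n_layers=6, sigma_b=0.0, sigma_w=1.0)
        m = lmm_trophic_metrics(t, Isotope.C13)
        assert m.ratio > 0.9

    def test_noise_free_data_gives_zero_wic(self, rng):
        t = balanced_scute(rng, n_turtles=6, n_layers=4, sigma_b=2.0, sigma_w=0.0)
        m = anova_trophic_metrics(t, Isotope.C13, include_layer=False)
        assert m.WIC == pytest.approx(0.0, abs=1e-18)
        assert m.ratio == pytest.approx(0.0, abs=1e-12)

    @given(shift=st.floats(-50, 50), scale=st.floats(0.1, 5.0))
    @settings(max_examples=15, deadline=None)
    def test_translation_invariance_and_quadratic_scaling(self, scute, shift, scale):
        base = anova_trophic_metrics(scute, Isotope.C13)
        mod = scute.copy()
        mod["d13C"] = scale * mod["d13C"] + shift
        m = anova_trophic_metrics(mod, Isotope.C13)
        assert m.WIC == pytest.approx(scale**2 * base.WIC, rel=1e-8)
        assert m.TNW == pytest.approx(scale**2 * base.TNW, rel=1e-8)
        assert m.ratio == pytest.approx(base.ratio, rel=1e-8)

    def test_estimators_agree_on_lifestage_ordering(self):
        # lifestage-specific between-individual variance (subadult > adult):
        # both estimators should rank the lifestages identically in >= 90%
        # of replicates
        rng = np.random.default_rng(606)
        agree = 0
        reps = 200
        for _ in range(reps):
            adult = balanced_scute(rng, n_turtles=15, n_layers=6, sigma_b=1.0, sigma_w=1.0)
            sub = balanced_scute(rng, n_turtles=12, n_layers=6, sigma_b=1.6, sigma_w=1.0)
            sub["turtle_id"] = "S" + sub["turtle_id"]
            orderings = []
            for fn in (anova_trophic_metrics, lmm_trophic_metrics):
                bic_a = fn(adult, Isotope.C13).BIC
                bic_s = fn(sub, Isotope.C13).BIC
                orderings.append(bic_s > bic_a)
            agree += orderings[0] == orderings[1]
        assert agree / reps >= 0.9

    def test_summary_table_shape(self, scute):
        tab = trophic_metrics_table(scute)
        assert set(tab["estimator"]) == {"anova", "lmm"}
        assert list(tab["group"].unique()) == ["all", "adults", "subadults"]
        for tag in ("C", "N"):
            assert np.allclose(
                tab[f"TNW_{tag}"], tab[f"WIC_{tag}"] + tab[f"BIC_{tag}"]
            )
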