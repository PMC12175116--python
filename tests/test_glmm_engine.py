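"""Mixed logit engine: degenerate reductions, quadrature oracle, recovery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from seatrend.glmm_engine import (
    GlmmSpec,
    fit_glmm,
    laplace_loglik,
    predict_state_probabilities,
    select_polynomial,
)


def binomial_frame(rng, n_groups=20, n_years=20, b0=-0.5, b1=0.15, sigma=0.0):
    year = np.tile(np.arange(n_years, dtype=float), n_groups)
    grp = np.repeat([f"g{i}" for i in range(n_groups)], n_years)
    u = dict(zip(set(grp), rng.normal(0, sigma, n_groups)))
    eta = b0 + b1 * (year - year.mean()) + np.array([u[g] for g in grp])
    y = rng.random(len(year)) < 1.0 / (1.0 + np.exp(-eta))
    return pd.DataFrame(
        {
            "state": np.where(y, "positive", "neutral"),
            "year": year - year.mean(),
            "species": grp,
            "station": "st0",
        }
    )


def gh_binomial_loglik(data, beta, sigma2, nodes=64):
    """Independent-groups Gauss–Hermite oracle for the marginal likelihood."""
    z, w = np.polynomial.hermite.hermgauss(nodes)
    total = 0.0
    for _, sub in data.groupby("species"):
        y = (sub["state"] == "positive").to_numpy(float)
        x = sub["year"].to_numpy()
        vals = []
        for zi in z:
            eta = beta[0] + beta[1] * x + np.sqrt(2.0 * sigma2) * zi
            vals.append(np.exp(np.sum(y * eta - np.log1p(np.exp(eta)))))
        total += np.log(np.sum(w * np.array(vals)) / np.sqrt(np.pi))
    return total


class TestDegenerateReductions:
    def test_binomial_matches_plain_logit_when_variance_vanishes(self, rng):
        data = binomial_frame(rng, sigma=0.0)
        fit = fit_glmm(
            GlmmSpec(response_kind="binomial"), data, compute_year_p=False
        )
        X = sm.add_constant(data["year"].to_numpy())
        ref = sm.Logit((data["state"] == "positive").astype(float), X).fit(disp=0)
        assert fit.sigma2["species"] == pytest.approx(0.0, abs=1e-3)
        np.testing.assert_allclose(
            fit.coef_original_scale().ravel(), np.asarray(ref.params), atol=1e-4
        )

    def test_multinomial_matches_mnlogit_when_variance_vanishes(self, rng):
        n = 600
        year = rng.uniform(-1, 1, n)
        eta_pos, eta_neg = 0.4 + 0.8 * year, -0.2 - 0.5 * year
        denom = 1.0 + np.exp(eta_pos) + np.exp(eta_neg)
        u = rng.random(n)
        state = np.where(
            u < np.exp(eta_pos) / denom,
            "positive",
            np.where(u < (np.exp(eta_pos) + np.exp(eta_neg)) / denom, "negative", "neutral"),
        )
        data = pd.DataFrame(
            {"state": state, "year": year, "species": "sp", "station": "st"}
        )
        fit = fit_glmm(GlmmSpec(), data, compute_year_p=False)
        # statsmodels MNLogit uses the alphabetically first state (negative)
        # as baseline; convert to neutral-baseline logits
        codes = pd.Categorical(state, categories=["negative", "neutral", "positive"])
        ref = sm.MNLogit(codes.codes, sm.add_constant(year)).fit(disp=0)
        P = np.asarray(ref.params)  # columns: neutral|neg, positive|neg
        b_neg = -P[:, 0]
        b_pos = P[:, 1] - P[:, 0]
        ours = fit.coef_original_scale()
        got = {s: ours[:, j] for j, s in enumerate(fit.states)}
        np.testing.assert_allclose(got["negative"], b_neg, atol=2e-3)
        np.testing.assert_allclose(got["positive"], b_pos, atol=2e-3)


class TestLaplaceAgainstQuadrature:
    def test_tiny_binomial_instance(self, rng):
        year = np.tile(np.arange(4.0), 3)
        grp = np.repeat(["a", "b", "c"], 4)
        y = rng.random(12) < 0.5
        data = pd.DataFrame(
            {"state": np.where(y, "positive", "neutral"), "year": year, "species": grp}
        )
        spec = GlmmSpec(response_kind="binomial", random_groups=("species",))
        beta = np.array([[0.3], [-0.2]])
        sigma2 = 0.0625
        ll = laplace_loglik(spec, data, beta, {"species": sigma2})
        oracle = gh_binomial_loglik(data, beta.ravel(), sigma2)
        assert ll == pytest.approx(oracle, abs=1e-3)

    def test_laplace_error_shrinks_with_variance(self, rng):
        year = np.tile(np.arange(4.0), 3)
        grp = np.repeat(["a", "b", "c"], 4)
        y = rng.random(12) < 0.5
        data = pd.DataFrame(
            {"state": np.where(y, "positive", "neutral"), "year": year, "species": grp}
        )
        spec = GlmmSpec(response_kind="binomial", random_groups=("species",))
        beta = np.array([[0.3], [-0.2]])
        errs = [
            abs(
                laplace_loglik(spec, data, beta, {"species": s2})
                - gh_binomial_loglik(data, beta.ravel(), s2)
            )
            for s2 in (0.01, 0.09, 0.5)
        ]
        assert errs[0] < errs[1] < errs[2]


class TestRecoveryAndSelection:
    def test_multinomial_year_slope_recovered_within_2se(self, rng):
        hits, n_rep = 0, 120
        warm = None
        for _ in range(n_rep):
            n_groups, n_years = 50, 20
            year = np.tile(np.arange(n_years, dtype=float), n_groups)
            grp = np.repeat([f"g{i}" for i in range(n_groups)], n_years)
            u = np.repeat(rng.normal(0, 0.3, n_groups), n_years)
            x = (year - year.mean()) / 10.0
            eta_pos = 0.2 * (year - year.mean()) + u
            eta_neg = -0.3 + u
            denom = 1.0 + np.exp(eta_pos) + np.exp(eta_neg)
            r = rng.random(len(year))
            state = np.where(
                r < np.exp(eta_pos) / denom,
                "positive",
                np.where(
                    r < (np.exp(eta_pos) + np.exp(eta_neg)) / denom,
                    "negative",
                    "neutral",
                ),
            )
            data = pd.DataFrame(
                {"state": state, "year": year, "species": grp, "station": "st"}
            )
            fit = fit_glmm(GlmmSpec(), data, compute_year_p=False, warm_start=warm)
            warm = fit
            j = fit.states.index("positive")
            slope = fit.coef_original_scale()[1, j]
            se = fit.coef_se[1, j] / fit.x_scale
            if abs(slope - 0.2) <= 2.0 * se:
                hits += 1
        assert hits / n_rep >= 0.90

    def test_select_polynomial_prefers_generating_shape(self, rng):
        lin_wins = quad_wins = 0
        n_rep = 40
        for i in range(n_rep):
            n_groups, n_years = 30, 15
            year = np.tile(np.arange(n_years, dtype=float), n_groups)
            grp = np.repeat([f"g{i}" for i in range(n_groups)], n_years)
            xc = year - year.mean()
            for quad in (False, True):
                eta = 0.3 * xc if not quad else 1.2 - 0.12 * xc**2
                y = rng.random(len(year)) < 1.0 / (1.0 + np.exp(-eta))
                data = pd.DataFrame(
                    {
                        "state": np.where(y, "positive", "neutral"),
                        "year": year,
                        "species": grp,
                        "station": "st",
                    }
                )
                spec, _ = select_polynomial(
                    GlmmSpec(response_kind="binomial"), data
                )
                if quad:
                    quad_wins += spec.quadratic
                else:
                    lin_wins += not spec.quadratic
        assert lin_wins / n_rep >= 0.85
        assert quad_wins / n_rep >= 0.85

    def test_loglik_reported_is_best_over_outer_iterations(self, rng):
        data = binomial_frame(rng, n_groups=10, n_years=12, sigma=0.4)
        fit = fit_glmm(
            GlmmSpec(response_kind="binomial"), data, compute_year_p=False
        )
        assert fit.loglik == pytest.approx(max(fit.monitor), abs=1e-9)


class TestPrediction:
    def test_zero_coefficients_give_uniform_probabilities(self):
        from seatrend.glmm_engine import GlmmFit

        fit = GlmmFit(
            spec=GlmmSpec(),
            states=("negative", "positive"),
            reference="neutral",
            coef=np.zeros((2, 2)),
            coef_se=np.ones((2, 2)),
            sigma2={},
            loglik=0.0,
            aic=0.0,
            converged=True,
            separation=False,
            x_center=0.0,
            x_scale=1.0,
        )
        pred = predict_state_probabilities(fit, np.arange(3))
        for col in ("pi_negative", "pi_neutral", "pi_positive"):
            np.testing.assert_allclose(pred[col], 1.0 / 3.0)

    def test_probabilities_match_hand_softmax_and_sum_to_one(self):
        from seatrend.glmm_engine import GlmmFit

        coef = np.array([[-1.0, 1.0], [0.0, 0.0]])  # eta_neg=-1, eta_pos=+1
        fit = GlmmFit(
            spec=GlmmSpec(),
            states=("negative", "positive"),
            reference="neutral",
            coef=coef,
            coef_se=np.ones((2, 2)),
            sigma2={},
            loglik=0.0,
            aic=0.0,
            converged=True,
            separation=False,
            x_center=0.0,
            x_scale=1.0,
        )
        pred = predict_state_probabilities(fit, np.array([5.0]))
        denom = 1.0 + np.exp(1.0) + np.exp(-1.0)
        assert pred["pi_positive"][0] == pytest.approx(np.exp(1.0) / denom, abs=1e-12)
        assert pred["pi_negative"][0] == pytest.approx(np.exp(-1.0) / denom, abs=1e-12)
        total = pred[["pi_negative", "pi_neutral", "pi_positive"]].sum(axis=1)
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_binomial_coefficients_zero_give_half(self):
        from seatrend.glmm_engine import GlmmFit

        fit = GlmmFit(
            spec=GlmmSpec(response_kind="binomial"),
            states=("positive",),
            reference="neutral",
            coef=np.zeros((2, 1)),
            coef_se=np.ones((2, 1)),
            sigma2={},
            loglik=0.0,
            aic=0.0,
            converged=True,
            separation=False,
            x_center=0.0,
            x_scale=1.0,
        )
        pred = predict_state_probabilities(fit, np.arange(2))
        np.testing.assert_allclose(pred["pi_positive"], 0.5)
        np.testing.assert_allclose(pred["pi_neutral"], 0.5)
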