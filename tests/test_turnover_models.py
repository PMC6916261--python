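import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from papyrusnet import (
    ModelSpec,
    aicc,
    all_subsets,
    fit_logistic,
    model_average,
    predict_probability,
    rank_models,
    screen_quadratic_terms,
    top_model_set,
)
from papyrusnet.patch_io import TurnoverDataset
from papyrusnet.turnover_models import (
    AveragedModel,
    FittedModel,
    SeparationWarning,
    averaged_table,
    conditional_average,
    design_matrix,
    fit_model,
)


def make_dataset(df, kind="colonization"):
    return TurnoverDataset(kind=kind, species="sp", data=df)


class TestFitLogistic:
    def test_intercept_only_symmetry(self):
        y = np.array([1] * 5 + [0] * 5, dtype=float)
        X = np.ones((10, 1))
        coef, cov, ll = fit_logistic(y, X)
        assert coef[0] == pytest.approx(0.0, abs=1e-8)

    def test_matches_grid_oracle(self):
        """Six-row fixture: the IRLS optimum agrees with brute-force grid
        maximization of the Bernoulli log-likelihood."""
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0, 3.0])
        y = np.array([0.0, 0.0, 1.0, 0.0, 1.0, 1.0])
        X = np.column_stack([np.ones(6), x])
        coef, _, ll = fit_logistic(y, X)

        def loglik(b0, b1):
            p = expit(b0 + b1 * x)
            return np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))

        grid = np.linspace(-4, 4, 801)
        best = max(((loglik(b0, b1), b0, b1) for b0 in grid for b1 in grid))
        assert coef[0] == pytest.approx(best[1], abs=1e-2)
        assert coef[1] == pytest.approx(best[2], abs=1e-2)
        assert ll >= best[0] - 1e-6

    def test_all_zero_response_warns_separation(self):
        y = np.zeros(8)
        X = np.ones((8, 1))
        with pytest.warns(SeparationWarning):
            fit_logistic(y, X)

    def test_rank_deficiency_rejected(self):
        y = np.array([0.0, 1.0, 0.0, 1.0])
        X = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(ValueError):
            fit_logistic(y, X)


class TestAicc:
    def test_direct_arithmetic(self):
        assert aicc(-10.0, 2, 20) == pytest.approx(24 + 12 / 17)

    def test_large_n_limit_is_aic(self):
        assert aicc(-10.0, 2, 10**7) == pytest.approx(24.0, abs=1e-4)

    def test_saturated_model_rejected(self):
        with pytest.raises(ValueError, match="too rich"):
            aicc(-1.0, 19, 20)


class TestAllSubsets:
    def test_plain_terms_power_set(self):
        specs = all_subsets(ModelSpec(("a", "b", "c")))
        assert len(specs) == 8
        assert ModelSpec(()) in specs

    def test_marginality_prunes_quadratics(self):
        specs = all_subsets(ModelSpec(("v", "v^2")))
        terms = {s.terms for s in specs}
        assert terms == {(), ("v",), ("v", "v^2")}

    def test_intercept_only_global(self):
        assert all_subsets(ModelSpec(())) == [ModelSpec(())]

    def test_combinatorial_guard(self):
        with pytest.raises(ValueError):
            all_subsets(ModelSpec(tuple(f"t{i}" for i in range(13))))

    def test_squared_without_linear_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(("v^2",))


class TestQuadraticScreening:
    def make_humped(self, seed=0, n=500, quadratic=True):
        rng = np.random.default_rng(seed)
        v = rng.uniform(0, 1, n)
        if quadratic:  # hump at intermediate proportion
            lp = -2 + 10 * v - 10 * v**2
        else:
            lp = np.zeros(n)
        y = (rng.random(n) < expit(lp)).astype(float)
        df = pd.DataFrame({"veg_mixed": v, "veg_disturbed": rng.uniform(0, 1, n),
                           "veg_undisturbed": rng.uniform(0, 1, n), "y": y})
        return make_dataset(df)

    def test_hump_retains_squared_term(self):
        ds = self.make_humped(seed=3, quadratic=True)
        retained = screen_quadratic_terms(ds, ("veg_mixed",))
        assert retained == ["veg_mixed^2"]

    def test_flat_response_drops_squared_term(self):
        """Under a response independent of the proportion the squared term
        should usually not pay its AIC cost."""
        kept = sum(
            bool(screen_quadratic_terms(self.make_humped(seed=s, quadratic=False),
                                        ("veg_mixed",)))
            for s in range(10)
        )
        assert kept <= 3  # retention is chance-level, far below certainty


class TestTopSetAndWeights:
    def mk(self, aicc_value, terms=(), n=50):
        k = len(terms) + 1
        return FittedModel(
            spec=ModelSpec(tuple(terms)),
            coef=np.zeros(k),
            cov=np.eye(k),
            loglik=0.0,
            k=k,
            n=n,
            aicc=aicc_value,
        )

    def test_inclusive_threshold(self):
        top = top_model_set([self.mk(100.0), self.mk(101.9, ("a",)), self.mk(102.1, ("b",))])
        assert len(top) == 2
        top2 = top_model_set([self.mk(100.0), self.mk(102.0, ("a",))])
        assert len(top2) == 2  # boundary is inclusive

    def test_single_model_weight_one(self):
        top = top_model_set([self.mk(10.0)])
        assert top[0].weight == pytest.approx(1.0)

    def test_equal_aicc_splits_weights(self):
        top = top_model_set([self.mk(100.0), self.mk(100.0, ("a",))])
        assert [m.weight for m in top] == pytest.approx([0.5, 0.5])

    def test_weights_sum_to_one(self):
        top = top_model_set([self.mk(100.0 + d, (t,)) for d, t in
                             zip((0, 0.3, 1.1, 1.9), "abcd")])
        assert sum(m.weight for m in top) == pytest.approx(1.0, abs=1e-12)


class TestModelAverage:
    def two_tied_models(self, beta=1.0, var=0.04):
        m1 = FittedModel(
            spec=ModelSpec(()), coef=np.array([0.0]), cov=np.array([[var]]),
            loglik=-10.0, k=1, n=50, aicc=100.0,
        )
        m2 = FittedModel(
            spec=ModelSpec(("x",)), coef=np.array([0.0, beta]),
            cov=np.diag([var, var]), loglik=-9.0, k=2, n=50, aicc=100.0,
        )
        return top_model_set([m1, m2])

    def test_zero_substitution_average_and_ri(self):
        top = self.two_tied_models(beta=1.0)
        avg = model_average(top)
        assert avg.coef["x"] == pytest.approx(0.5)
        assert avg.ri["x"] == pytest.approx(0.5)
        assert avg.ri["intercept"] == 1.0

    def test_unconditional_se_exceeds_conditional(self):
        top = self.two_tied_models(beta=1.0, var=0.04)
        avg = model_average(top)
        # half the mass sits at 0, half at 1: spread must enter the SE
        expected = 0.5 * math.sqrt(0.0 + 0.25) + 0.5 * math.sqrt(0.04 + 0.25)
        assert avg.se["x"] == pytest.approx(expected, rel=1e-12)

    def test_single_model_identity(self):
        m = FittedModel(
            spec=ModelSpec(("x",)), coef=np.array([0.3, -1.2]),
            cov=np.diag([0.01, 0.02]), loglik=-5.0, k=2, n=40, aicc=50.0,
        )
        avg = model_average(top_model_set([m]))
        assert avg.coef["x"] == pytest.approx(-1.2)
        assert avg.ri["x"] == 1.0
        assert avg.se["x"] == pytest.approx(math.sqrt(0.02))

    def test_ri_bounds(self):
        top = self.two_tied_models()
        avg = model_average(top)
        assert all(0.0 <= r <= 1.0 for r in avg.ri.values())

    def test_conditional_average_rescales(self):
        top = self.two_tied_models(beta=1.0)
        cond = conditional_average(top)
        assert cond.coef["x"] == pytest.approx(1.0)  # renormalized over presence


class TestPrediction:
    def make_avg(self, coef):
        terms = tuple(coef)
        return AveragedModel(
            terms=terms,
            coef=dict(coef),
            se={t: 0.1 for t in terms},
            ci_lower={t: coef[t] - 0.2 for t in terms},
            ci_upper={t: coef[t] + 0.2 for t in terms},
            ri={t: 1.0 for t in terms},
            significant={t: False for t in terms},
        )

    def test_zero_intercept_gives_half(self):
        avg = self.make_avg({"intercept": 0.0})
        probs = predict_probability(avg, pd.DataFrame({"area": [1.0, 5.0]},
                                                      index=["a", "b"]))
        assert (probs == 0.5).all()

    def test_hand_computed_linear_predictor(self):
        avg = self.make_avg({"intercept": -1.0, "area": 0.5, "veg_mixed^2": 2.0,
                             "veg_mixed": 0.0})
        cov = pd.DataFrame({"area": [2.0], "veg_mixed": [0.3]}, index=["p"])
        lp = -1.0 + 0.5 * 2.0 + 2.0 * 0.09
        assert predict_probability(avg, cov).loc["p"] == pytest.approx(
            expit(lp), abs=1e-12
        )

    def test_missing_covariate_names_patch_and_term(self):
        avg = self.make_avg({"intercept": 0.0, "area": 1.0})
        with pytest.raises(KeyError, match="p7"):
            predict_probability(avg, pd.DataFrame({"circ": [1.0]}, index=["p7"]))


class TestEndToEndRanking:
    def test_never_selected_covariate_leaves_predictions_unchanged(self):
        """Across several draws, whenever the noise covariate stays out of
        the top set, dropping it from the global model must not move the
        averaged predictions; at least one draw must exercise the case."""
        exercised = 0
        # draws chosen so the noise term falls outside the top set (a
        # zero-gain term costs just over the inclusive delta-AICc bound,
        # so most draws keep it; the invariant is conditional on exclusion)
        for seed in (9, 13, 27):
            rng = np.random.default_rng(seed)
            n = 400
            x = rng.normal(size=n)
            junk = rng.normal(size=n)
            y = (rng.random(n) < expit(-0.5 + 1.5 * x)).astype(float)
            df = pd.DataFrame({"x": x, "junk": junk, "y": y})
            ds = make_dataset(df)
            cov = df.drop(columns="y")

            top_w = top_model_set(rank_models(ds, all_subsets(ModelSpec(("x", "junk")))))
            if any("junk" in m.spec.terms for m in top_w):
                continue
            exercised += 1
            avg_w = model_average(top_w)
            avg_wo = model_average(
                top_model_set(rank_models(ds, all_subsets(ModelSpec(("x",)))))
            )
            p_w = predict_probability(avg_w, cov)
            p_wo = predict_probability(avg_wo, cov)
            pd.testing.assert_series_equal(p_w, p_wo)
        assert exercised == 3

    def test_ranking_is_sorted_with_nonnegative_delta(self):
        rng = np.random.default_rng(7)
        n = 200
        df = pd.DataFrame(
            {
                "a": rng.normal(size=n),
                "b": rng.normal(size=n),
                "y": (rng.random(n) < 0.3).astype(float),
            }
        )
        fitted = rank_models(make_dataset(df), all_subsets(ModelSpec(("a", "b"))))
        aiccs = [m.aicc for m in fitted]
        assert aiccs == sorted(aiccs)
        assert fitted[0].delta == 0.0
        assert all(m.delta >= 0 for m in fitted)
        tab = averaged_table(model_average(top_model_set(fitted)))
        assert set(tab.columns) == {
            "term", "estimate", "se", "ci_lower", "ci_upper", "RI", "significant",
        }
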