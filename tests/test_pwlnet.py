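"""Point-wise linear net: decomposition, logistic equivalence, importance."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from decliner import (
    PWLNetConfig,
    contributions,
    fit_pwl_net,
    importance_from_contributions,
    importance_scores,
    predict_proba,
    select_features,
)
from decliner.errors import DomainError, SchemaError
from decliner.pwlnet import load_model, predict_logit, save_model


def _toy_separable(rng, n=60):
    y = (rng.random(n) < 0.5).astype(int)
    X = np.column_stack([y * 4.0 - 2.0 + rng.normal(0, 0.2, n), rng.standard_normal(n)])
    return X, y


def _logistic_data(rng, n=80, d=4):
    X = rng.standard_normal((n, d))
    beta = np.array([1.5, -1.0, 0.5, 0.0])[:d]
    y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta + 0.3)))).astype(int)
    return X, y


class TestFit:
    def test_depth0_separable_training_auc_one(self, rng):
        from decliner.pairsearch import rank_auc

        X, y = _toy_separable(rng)
        cfg = PWLNetConfig(hidden_layers=0, max_epochs=300, validation_fraction=0.0)
        m = fit_pwl_net(X, y, cfg, seed=0)
        assert rank_auc(predict_proba(m, X), y.astype(bool)) == 1.0

    def test_depth0_matches_penalized_logistic(self, rng):
        # oracle: sklearn L2 logistic at C = 1/weight_decay
        X, y = _logistic_data(rng)
        lam = 1.0
        cfg = PWLNetConfig(
            hidden_layers=0, weight_decay=lam, learning_rate=0.02, max_epochs=20000,
            validation_fraction=0.0, class_weight=None,
        )
        m = fit_pwl_net(X, y, cfg, seed=0)
        sk = LogisticRegression(C=1 / lam, max_iter=10000, tol=1e-12).fit(X, y)
        ref = np.append(sk.coef_[0], sk.intercept_[0])
        got = np.append(m.params["w0"], m.params["b0"][0])
        assert np.max(np.abs(got - ref) / np.maximum(np.abs(ref), 1e-6)) < 1e-3

    def test_same_seed_identical_parameters(self, rng):
        X, y = _logistic_data(rng)
        cfg = PWLNetConfig(hidden_layers=2, width=8, max_epochs=50)
        m1 = fit_pwl_net(X, y, cfg, seed=7)
        m2 = fit_pwl_net(X, y, cfg, seed=7)
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k])

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(DomainError):
            fit_pwl_net(X, np.zeros(10), PWLNetConfig(max_epochs=5))

    def test_nonfinite_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        X[0, 0] = np.nan
        with pytest.raises(DomainError):
            fit_pwl_net(X, np.r_[np.ones(5), np.zeros(5)], PWLNetConfig(max_epochs=5))


@pytest.fixture(scope="module")
def model_and_data():
    rng = np.random.default_rng(5)
    X, y = _logistic_data(rng, n=60)
    cfg = PWLNetConfig(hidden_layers=2, width=8, max_epochs=120)
    return fit_pwl_net(X, y, cfg, seed=1), X, y


class TestPredictAndContributions:
    def test_logit_reconstruction_exact(self, model_and_data):
        m, X, _ = model_and_data
        c, bias = contributions(m, X)
        logit = predict_logit(m, X)
        assert np.max(np.abs(c.sum(axis=1) + bias - logit)) < 1e-8

    def test_zero_input_zero_contribution(self, model_and_data):
        m, X, _ = model_and_data
        X0 = X.copy()
        X0[:, 1] = 0.0
        c, _ = contributions(m, X0)
        assert np.all(c[:, 1] == 0.0)

    def test_row_wise_function(self, model_and_data):
        m, X, _ = model_and_data
        p = predict_proba(m, X)
        p_dup = predict_proba(m, np.vstack([X, X[:1]]))
        assert p_dup[-1] == p[0]
        assert np.allclose(p_dup[:-1], p)

    def test_zero_feature_equals_deleted_term(self, model_and_data):
        # a 0-valued input must not change the inference
        m, X, _ = model_and_data
        X0 = X.copy()
        X0[:, 2] = 0.0
        c, bias = contributions(m, X0)
        manual = c[:, [0, 1, 3]].sum(axis=1) + bias  # term j=2 deleted
        assert np.allclose(predict_logit(m, X0), manual, atol=1e-10)

    def test_column_mismatch_rejected(self, model_and_data):
        m, X, _ = model_and_data
        with pytest.raises(SchemaError):
            predict_proba(m, X[:, :2])

    def test_depth0_contributions_match_logistic_terms(self, rng):
        X, y = _logistic_data(rng)
        cfg = PWLNetConfig(hidden_layers=0, weight_decay=1.0, learning_rate=0.02,
                           max_epochs=20000, validation_fraction=0.0, class_weight=None)
        m = fit_pwl_net(X, y, cfg, seed=0)
        sk = LogisticRegression(C=1.0, max_iter=10000, tol=1e-12).fit(X, y)
        c, _ = contributions(m, X)
        assert np.allclose(c, sk.coef_[0][None, :] * X, atol=1e-3)

    def test_save_load_round_trip(self, model_and_data, tmp_path):
        m, X, _ = model_and_data
        save_model(m, tmp_path / "model.json")
        back = load_model(tmp_path / "model.json")
        assert np.allclose(predict_proba(back, X), predict_proba(m, X))


class TestImportance:
    def _boundary_contributions(self):
        """Feature 0 is top-decile for exactly half of the rapid class and
        for no non-rapid sample."""
        rng = np.random.default_rng(0)
        n_rapid, n_non, d = 10, 20, 30
        c = rng.uniform(0.1, 1.0, size=(n_rapid + n_non, d))
        c[:, 0] = 0.0  # never top-decile by default
        c[:5, 0] = 100.0  # half the rapid samples: clearly top-decile
        y = np.r_[np.ones(n_rapid), np.zeros(n_non)].astype(bool)
        return c, y

    def test_boundary_score_is_quarter_exactly(self):
        c, y = self._boundary_contributions()
        rep = importance_from_contributions(c, y)
        row = rep.table.set_index("feature").loc["x0"]
        assert row["unsigned"] == 0.25
        assert row["f_rapid"] == 0.5 and row["f_non"] == 0.0

    def test_always_top_decile_scores_one(self):
        c, y = self._boundary_contributions()
        c[:, 1] = -1000.0  # top-decile in every sample, negative direction
        rep = importance_from_contributions(c, y)
        row = rep.table.set_index("feature").loc["x1"]
        assert row["unsigned"] == 1.0
        assert row["score"] == -1.0

    def test_signs_follow_mean_contribution(self):
        c, y = self._boundary_contributions()
        rep = importance_from_contributions(c, y)
        tab = rep.table.set_index("feature")
        assert tab.loc["x0", "score"] > 0  # large positive contributions

    def test_both_classes_required(self):
        c, _ = self._boundary_contributions()
        with pytest.raises(DomainError):
            importance_from_contributions(c, np.ones(c.shape[0], dtype=bool))

    def test_model_pathway_shapes(self, rng):
        X, y = _logistic_data(rng, n=50)
        m = fit_pwl_net(X, y, PWLNetConfig(hidden_layers=1, width=8, max_epochs=60), seed=0)
        rep = importance_scores(m, X, y)
        assert len(rep.table) == X.shape[1]
        assert (rep.table["score"].abs() <= 1.0).all()
        assert np.allclose(rep.table["unsigned"], rep.table["score"].abs())


class TestSelectFeatures:
    def _report(self, scores):
        import pandas as pd

        from decliner.pwlnet import ImportanceReport

        tab = pd.DataFrame(
            {"feature": list(scores), "score": list(scores.values()),
             "unsigned": [abs(v) for v in scores.values()],
             "f_rapid": 0.0, "f_non": 0.0, "sign_rapid": 1.0, "sign_non": 1.0}
        )
        return ImportanceReport(tab)

    def test_auto_plus_curated(self):
        rep = self._report({"A": 0.3, "B": 0.1, "C": 0.05})
        sel = select_features(rep, curated=["B"])
        assert dict(zip(sel["feature"], sel["origin"])) == {"A": "auto", "B": "curated"}

    def test_curated_below_006_excluded(self):
        rep = self._report({"A": 0.3, "C": 0.05})
        sel = select_features(rep, curated=["C"])
        assert list(sel["feature"]) == ["A"]

    def test_cap_keeps_largest_scores(self):
        scores = {f"F{i}": 0.26 + i * 0.01 for i in range(60)}
        sel = select_features(self._report(scores), cap=50)
        assert len(sel) == 50
        assert sel["score"].abs().min() > 0.35

    def test_unknown_curated_name(self):
        with pytest.raises(SchemaError):
            select_features(self._report({"A": 0.3}), curated=["Z"])
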