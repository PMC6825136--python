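import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import paleotf as pt
from paleotf.data import DataError
from paleotf.methods import DEFAULT_PARAMS, MethodSpec


def _percent(rng, n, m):
    v = rng.uniform(0.01, 10.0, size=(n, m))
    return 100.0 * v / v.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# squared chord distance
# ---------------------------------------------------------------------------


class TestSqChord:
    def test_identical_is_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert pt.sq_chord(p, p) == 0.0

    def test_disjoint_is_maximal(self):
        assert pt.sq_chord([1.0, 0.0], [0.0, 1.0]) == pytest.approx(2.0)

    def test_direct_formula_value(self):
        assert pt.sq_chord([0.5, 0.5], [1.0, 0.0]) == \
            pytest.approx(2.0 - np.sqrt(2.0), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            pt.sq_chord([1.0], [0.5, 0.5])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_nonnegative_bounded(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(6))
        q = rng.dirichlet(np.ones(6))
        d = pt.sq_chord(p, q)
        assert 0.0 <= d <= 2.0 + 1e-12
        assert d == pytest.approx(pt.sq_chord(q, p), abs=1e-12)
        assert pt.sq_chord(p, p) < 1e-15

    def test_matrix_matches_scalar(self):
        rng = np.random.default_rng(3)
        P = rng.dirichlet(np.ones(5), size=4)
        Q = rng.dirichlet(np.ones(5), size=3)
        D = pt.sq_chord_matrix(P, Q)
        for i in range(4):
            for j in range(3):
                assert D[i, j] == pytest.approx(pt.sq_chord(P[i], Q[j]), abs=1e-12)


# ---------------------------------------------------------------------------
# MAT
# ---------------------------------------------------------------------------


def _mat_oracle(Xtr, ytr, Xte, k):
    """Exhaustive-sort inverse-distance oracle, written independently."""
    Ptr = Xtr / Xtr.sum(axis=1, keepdims=True)
    Pte = Xte / Xte.sum(axis=1, keepdims=True)
    preds = []
    for p in Pte:
        d = [sum((np.sqrt(p[t]) - np.sqrt(q[t])) ** 2 for t in range(len(p)))
             for q in Ptr]
        order = sorted(range(len(d)), key=lambda j: (d[j], j))[:k]
        if any(d[j] < 1e-12 for j in order):
            zero = [ytr[j] for j in order if d[j] < 1e-12]
            preds.append(sum(zero) / len(zero))
        else:
            w = [1.0 / d[j] for j in order]
            preds.append(sum(wi * ytr[j] for wi, j in zip(w, order)) / sum(w))
    return np.array(preds)


class TestMAT:
    def test_train_range_recorded(self):
        rng = np.random.default_rng(0)
        X, y = _percent(rng, 10, 4), rng.uniform(5.0, 15.0, 10)
        m = pt.fit_mat(X, y, k=3)
        assert m.train_range == (y.min(), y.max())

    def test_k_zero_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(DataError):
            pt.fit_mat(_percent(rng, 5, 3), np.arange(5.0), k=0)

    def test_k_exceeding_n_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(DataError):
            pt.fit_mat(_percent(rng, 5, 3), np.arange(5.0), k=6)

    def test_stored_matrix_is_proportions(self):
        rng = np.random.default_rng(1)
        X = _percent(rng, 6, 4)
        m = pt.fit_mat(X, np.arange(6.0))
        np.testing.assert_allclose(m.P_train, X / 100.0, rtol=1e-12)

    def test_identical_sample_k1(self):
        rng = np.random.default_rng(2)
        X, y = _percent(rng, 8, 5), rng.uniform(0, 20, 8)
        m = pt.fit_mat(X, y, k=1)
        assert m.predict(X[3][None, :])[0] == pytest.approx(y[3])

    def test_equidistant_pair_averages(self):
        X = np.array([[60.0, 40.0], [40.0, 60.0]])
        y = np.array([10.0, 20.0])
        m = pt.fit_mat(X, y, k=2)
        assert m.predict(np.array([[50.0, 50.0]]))[0] == pytest.approx(15.0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        Xtr, ytr = _percent(rng, 8, 5), rng.uniform(0, 30, 8)
        Xte = _percent(rng, 6, 5)
        m = pt.fit_mat(Xtr, ytr, k=3)
        np.testing.assert_allclose(m.predict(Xte),
                                   _mat_oracle(Xtr, ytr, Xte, 3), atol=1e-12)

    def test_predictions_within_analogue_range(self):
        rng = np.random.default_rng(8)
        Xtr, ytr = _percent(rng, 40, 6), rng.uniform(0, 30, 40)
        m = pt.fit_mat(Xtr, ytr, k=5)
        pred = m.predict(_percent(rng, 20, 6))
        assert np.all(pred >= ytr.min() - 1e-12)
        assert np.all(pred <= ytr.max() + 1e-12)


# ---------------------------------------------------------------------------
# WA
# ---------------------------------------------------------------------------


class TestWA:
    def test_single_taxon_optimum_is_mean(self):
        X = np.array([[100.0], [100.0]])
        y = np.array([10.0, 20.0])
        with pytest.warns(UserWarning):
            # a single taxon cannot be deshrunk meaningfully; use inverse
            m = pt.fit_wa(np.hstack([X, np.zeros((2, 1))]), y,
                          deshrinking="inverse")
        assert m.optima[0] == pytest.approx(15.0)

    def test_single_occurrence_tolerance_floored(self):
        X = np.array([[50.0, 50.0, 0.0],
                      [50.0, 0.0, 50.0],
                      [60.0, 0.0, 40.0]])
        y = np.array([5.0, 10.0, 15.0])
        m = pt.fit_wa(X, y, deshrinking="inverse")
        # taxon 1 occurs at one site: raw tolerance 0, floored to a positive value
        assert m.tolerances[1] > 0
        assert np.all(m.tolerances >= m.tolerances.min())

    def test_optima_match_hand_computed_weighted_means(self):
        rng = np.random.default_rng(4)
        X, y = _percent(rng, 5, 3), rng.uniform(0, 10, 5)
        m = pt.fit_wa(X, y, deshrinking="inverse")
        Y = np.sqrt(X)
        for k in range(3):
            u = sum(Y[i, k] * y[i] for i in range(5)) / sum(Y[:, k])
            assert m.optima[k] == pytest.approx(u, abs=1e-10)

    def test_all_zero_site_rejected(self):
        X = np.array([[50.0, 50.0], [0.0, 0.0]])
        with pytest.raises(DataError, match="s1"):
            pt.fit_wa(X, np.array([1.0, 2.0]), site_ids=["s0", "s1"])

    def test_noiseless_self_prediction(self, cal100):
        cal, truth = cal100
        config = pt.default_preset(n_sites=100, count_depth=None)
        cal_nl, truth_nl = pt.gen_calibration(config, seed=1)
        y = truth_nl["x1_true"]
        m = pt.fit_wa(cal_nl.taxa.values, y)
        pred = m.predict(cal_nl.taxa.values)
        assert pt.r_squared(y, pred) > 0.99

    def test_inverse_deshrinking_preserves_mean(self):
        rng = np.random.default_rng(6)
        X, y = _percent(rng, 30, 8), rng.uniform(5, 25, 30)
        m = pt.fit_wa(X, y, deshrinking="inverse")
        assert np.mean(m.predict(X)) == pytest.approx(np.mean(y), abs=1e-8)

    def test_monotonic_deshrinking_is_monotone(self):
        rng = np.random.default_rng(9)
        X, y = _percent(rng, 40, 6), rng.uniform(5, 25, 40)
        m = pt.fit_wa(X, y, deshrinking="monotonic")
        grid = np.linspace(y.min() - 5, y.max() + 5, 200)
        out = m._deshrink(grid)
        assert np.all(np.diff(out) >= -1e-10)

    def test_raw_scores_within_present_taxon_optima(self):
        rng = np.random.default_rng(10)
        X, y = _percent(rng, 25, 5), rng.uniform(0, 10, 25)
        m = pt.fit_wa(X, y)
        r = m.raw_scores(X)
        assert np.all(r >= m.optima.min() - 1e-9)
        assert np.all(r <= m.optima.max() + 1e-9)

    def test_disjoint_sample_yields_missing(self):
        X = np.array([[50.0, 50.0, 0.0], [60.0, 40.0, 0.0], [30.0, 70.0, 0.0]])
        y = np.array([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning):
            m = pt.fit_wa(X, y, deshrinking="inverse")
            out = m.predict(np.array([[0.0, 0.0, 100.0]]))
        assert np.isnan(out[0])


# ---------------------------------------------------------------------------
# WAPLS
# ---------------------------------------------------------------------------


class TestWAPLS:
    def test_one_component_equals_wa_inverse(self):
        rng = np.random.default_rng(11)
        X, y = _percent(rng, 40, 8), rng.uniform(5, 25, 40)
        Xnew = _percent(rng, 15, 8)
        wa = pt.fit_wa(X, y, deshrinking="inverse", tolerance_dw=False)
        wp = pt.fit_wapls(X, y, n_components=1)
        np.testing.assert_allclose(wp.predict(Xnew), wa.predict(Xnew), atol=1e-8)

    def test_training_rmse_nonincreasing_in_components(self, cal100):
        cal, _ = cal100
        X, y = cal.taxa.values, cal.response("T_jul")
        rmse = []
        for nc in range(1, 5):
            m = pt.fit_wapls(X, y, n_components=nc)
            rmse.append(float(np.sqrt(np.mean((m.predict(X) - y) ** 2))))
        assert all(b <= a + 1e-10 for a, b in zip(rmse, rmse[1:]))

    def test_zero_components_rejected(self):
        rng = np.random.default_rng(12)
        with pytest.raises(DataError):
            pt.fit_wapls(_percent(rng, 10, 4), np.arange(10.0), n_components=0)


# ---------------------------------------------------------------------------
# machine-learning adapters
# ---------------------------------------------------------------------------


ML_SPECS = [
    MethodSpec("RF", seed=1),
    MethodSpec("ETREES", seed=1),
    MethodSpec("BRT", {"max_trees": 60, "cv_folds": 3}, seed=1),
    MethodSpec("NNET", {"n_hidden": 4}, seed=1),
    MethodSpec("ELM", {"n_hidden": 20}, seed=1),
]


class TestMLAdapters:
    @pytest.mark.parametrize("spec", ML_SPECS, ids=lambda s: s.code)
    def test_constant_response_reproduced(self, spec):
        rng = np.random.default_rng(13)
        X = _percent(rng, 40, 6)
        y = np.full(40, 7.25)
        m = pt.fit_ml(spec, X, y)
        np.testing.assert_allclose(m.predict(X), 7.25, atol=1e-6)

    @pytest.mark.parametrize("spec", ML_SPECS, ids=lambda s: s.code)
    def test_same_seed_bit_identical(self, spec):
        rng = np.random.default_rng(14)
        X, y = _percent(rng, 50, 8), rng.uniform(0, 20, 50)
        Xnew = _percent(rng, 10, 8)
        a = pt.fit_ml(spec, X, y).predict(Xnew)
        b = pt.fit_ml(spec, X, y).predict(Xnew)
        np.testing.assert_array_equal(a, b)

    def test_unknown_code_rejected(self):
        with pytest.raises(DataError):
            MethodSpec("GAM")

    def test_missing_hidden_units_demand_config(self):
        rng = np.random.default_rng(15)
        X, y = _percent(rng, 20, 4), np.arange(20.0)
        for code in ("NNET", "ELM"):
            with pytest.raises(DataError, match="hidden"):
                pt.fit_ml(MethodSpec(code, seed=0), X, y)

    def test_brt_tuning_beats_tiny_ensemble(self, cal100):
        cal, _ = cal100
        X, y = cal.taxa.values, cal.response("T_jul")
        tr, te = np.arange(0, 80), np.arange(80, 100)
        tuned = pt.fit_ml(MethodSpec("BRT", {"max_trees": 500}, seed=2),
                          X[tr], y[tr])
        tiny = pt.fit_ml(MethodSpec("BRT", {"max_trees": 10, "cv_folds": 0},
                                    seed=2), X[tr], y[tr])
        assert tuned.backend.n_estimators <= 500
        rmse = lambda m: np.sqrt(np.mean((m.predict(X[te]) - y[te]) ** 2))
        assert rmse(tuned) < rmse(tiny)


class TestRelativeInfluence:
    def test_contributions_sum_to_100(self, cal100):
        cal, _ = cal100
        m = pt.fit_ml(MethodSpec("BRT", {"max_trees": 60, "cv_folds": 0}, seed=3),
                      cal.taxa.values, cal.response("T_jul"),
                      taxon_names=cal.taxa.taxon_names)
        ri = pt.relative_influence(m)
        assert ri.sum() == pytest.approx(100.0, abs=1e-6)
        assert list(ri.index[:1])  # sorted descending
        assert ri.iloc[0] >= ri.iloc[-1]

    def test_non_brt_rejected(self):
        rng = np.random.default_rng(16)
        m = pt.fit_mat(_percent(rng, 10, 4), np.arange(10.0))
        with pytest.raises(DataError):
            pt.relative_influence(m)


def test_table2_default_parameterization_exposed():
    """The canonical defaults: MAT k=5, WAPLS 3 components, RF 100 trees,
    BRT lr 0.025 depth 4 bag 0.5 max 3000, ELM mean of 5 networks."""
    assert DEFAULT_PARAMS["MAT"]["k"] == 5
    assert DEFAULT_PARAMS["WAPLS"]["n_components"] == 3
    assert DEFAULT_PARAMS["RF"]["n_trees"] == 100
    brt = DEFAULT_PARAMS["BRT"]
    assert (brt["learning_rate"], brt["tree_depth"], brt["bag_fraction"],
            brt["max_trees"]) == (0.025, 4, 0.5, 3000)
    assert DEFAULT_PARAMS["ELM"]["n_networks"] == 5
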