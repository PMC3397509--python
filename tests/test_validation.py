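"""Validation statistics, the benchmark-table reproduction, Y-randomization."""

import numpy as np
import pytest

from qsar_garf.datasets import fixture_dataset
from qsar_garf.forest import fit_forest
from qsar_garf.synthetic import SyntheticSpec, generate_qsar
from qsar_garf.validation import (PredictionSet, origin_stats, r2_m,
                                  r2_pearson, r2_pred, r2_press,
                                  report_from_fixture, rmse, tropsha_check,
                                  y_randomization)

from conftest import make_dataset


def fixture_sets(model="garf"):
    y, yhat, is_test = fixture_dataset(model)
    ybar = float(y[~is_test].mean())
    return (PredictionSet(y[~is_test], yhat[~is_test], ybar),
            PredictionSet(y[is_test], yhat[is_test], ybar))


class TestElementaryStatistics:
    def test_rmse_trivial_cases(self):
        ps = PredictionSet(np.arange(4.0), np.arange(4.0))
        assert rmse(ps) == 0.0
        ps2 = PredictionSet(np.arange(4.0), np.arange(4.0) + 0.3)
        assert rmse(ps2) == pytest.approx(0.3)

    def test_r2_pearson_affine_invariance(self):
        y = np.random.default_rng(0).normal(size=50)
        assert r2_pearson(PredictionSet(y, 2 * y + 3)) == pytest.approx(1.0)

    def test_r2_pearson_independent_vectors_near_zero(self):
        g = np.random.default_rng(1)
        ps = PredictionSet(g.normal(size=4000), g.normal(size=4000))
        assert r2_pearson(ps) < 0.01

    def test_r2_press_reference_behaviour(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        assert r2_press(PredictionSet(y, np.full(4, y.mean()))) == 0.0
        assert r2_press(PredictionSet(y, y)) == 1.0
        assert r2_press(PredictionSet(y, -y)) < 0.0

    def test_origin_stats_exact_on_proportional_data(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        k, r2o = origin_stats(PredictionSet(y, y))
        assert (k, r2o) == (pytest.approx(1.0), pytest.approx(1.0))
        k2, r2o2 = origin_stats(PredictionSet(2 * y, y))
        assert (k2, r2o2) == (pytest.approx(2.0), pytest.approx(1.0))

    def test_r2_m_identity_sweep_and_worst_case(self):
        for v in np.linspace(0.0, 1.0, 21):
            assert r2_m(v, v) == pytest.approx(v)
        assert r2_m(1.0, 0.0) == 0.0

    def test_r2_m_clamps_negative_difference(self):
        with pytest.warns(UserWarning, match="clamping"):
            assert r2_m(0.80, 0.81) == pytest.approx(0.80)


class TestFixtureReproduction:
    def test_garf_test_statistics_match_printed_values(self):
        _, test_ps = fixture_sets("garf")
        assert rmse(test_ps) == pytest.approx(0.34, abs=0.005)
        assert r2_pearson(test_ps) == pytest.approx(0.91, abs=0.005)
        assert r2_pred(test_ps) == pytest.approx(0.90, abs=0.005)
        k, r2o = origin_stats(test_ps)
        assert k == pytest.approx(1.01, abs=0.005)
        assert r2o == pytest.approx(0.90, abs=0.005)

    def test_rf_test_statistics_match_printed_values(self):
        _, test_ps = fixture_sets("rf")
        assert rmse(test_ps) == pytest.approx(0.42, abs=0.005)
        assert r2_pearson(test_ps) == pytest.approx(0.87, abs=0.005)
        assert r2_pred(test_ps) == pytest.approx(0.85, abs=0.005)

    def test_training_statistics_match_printed_values(self):
        train_ps, _ = fixture_sets("garf")
        assert r2_pearson(train_ps) == pytest.approx(0.96, abs=0.005)
        assert rmse(train_ps) == pytest.approx(0.25, abs=0.005)

    def test_r2_m_matches_printed_values(self):
        rep_g = report_from_fixture("garf")
        rep_r = report_from_fixture("rf")
        assert rep_g.r2_m == pytest.approx(0.83, abs=0.02)
        assert rep_r.r2_m == pytest.approx(0.76, abs=0.02)

    def test_full_report_perfect_predictions(self):
        y = np.linspace(3.0, 8.0, 10)
        from qsar_garf.validation import full_report
        rep = full_report(PredictionSet(y, y), PredictionSet(y, y),
                          PredictionSet(y, y, float(y.mean())))
        assert rep.r2_ncv == pytest.approx(1.0)
        assert rep.r2_ts == pytest.approx(1.0)
        assert rep.rmse_test == 0.0 and rep.k == pytest.approx(1.0)
        assert rep.r2_m == pytest.approx(1.0)
        assert rep.tropsha_pass


class TestTropsha:
    def test_fixture_reports_pass(self):
        assert report_from_fixture("garf").tropsha_pass
        assert report_from_fixture("rf").tropsha_pass

    def test_slope_out_of_band_fails(self):
        rep = report_from_fixture("garf")
        rep.k = 1.20
        flags, ok = tropsha_check(rep)
        assert not flags["k_in_0.85_1.15"] and not ok

    def test_boundary_is_strict(self):
        rep = report_from_fixture("garf")
        rep.r2_pred = 0.5
        flags, ok = tropsha_check(rep)
        assert not flags["r2_pred_gt_0.5"] and not ok


class TestPermutationBehaviour:
    def test_r2_press_near_zero_under_label_permutation(self):
        g = np.random.default_rng(8)
        vals = []
        y = g.normal(size=60)
        for _ in range(60):
            vals.append(r2_press(PredictionSet(g.permutation(y),
                                               np.full(60, y.mean()),
                                               float(y.mean()))))
        assert np.mean(vals) <= 0.05

    def test_identity_permutation_matches_direct_report(self):
        spec = SyntheticSpec(n_compounds=60, n_descriptors=10, n_informative=3,
                             n_sparse_columns=0, n_correlated_pairs=0,
                             n_constant_columns=0, seed=13)
        data, _ = generate_qsar(spec)
        split = ["train"] * 40 + ["test"] * 20
        ds = data.with_split(split)

        def proc(Xa, ya, Xb, s):
            f = fit_forest(Xa, ya, ntree=50, seed=s)
            return f.predict(Xa), f.oob_prediction, f.predict(Xb)

        res = y_randomization(ds, proc, rounds=1, seed=5, shuffle=False)
        round_seed = int(np.random.default_rng(5).integers(0, 2**31 - 1))
        X_tr, y_tr = ds.training_xy()
        X_ts, y_ts = ds.test_xy()
        yhat_tr, yhat_oob, yhat_ts = proc(X_tr, y_tr, X_ts, round_seed)
        from qsar_garf.validation import full_report
        ybar = float(y_tr.mean())
        direct = full_report(PredictionSet(y_tr, yhat_tr, ybar),
                             PredictionSet(y_tr, yhat_oob, ybar),
                             PredictionSet(y_ts, yhat_ts, ybar))
        assert res.reports[0].to_dict() == direct.to_dict()

    def test_permutation_inflates_training_rmse(self):
        spec = SyntheticSpec(n_compounds=80, n_descriptors=12, n_informative=4,
                             n_sparse_columns=0, n_correlated_pairs=0,
                             n_constant_columns=0, seed=17)
        data, _ = generate_qsar(spec)
        ds = data.with_split(["train"] * 60 + ["test"] * 20)

        def proc(Xa, ya, Xb, s):
            f = fit_forest(Xa, ya, ntree=60, seed=s)
            return f.predict(Xa), f.oob_prediction, f.predict(Xb)

        baseline = y_randomization(ds, proc, rounds=1, seed=3,
                                   shuffle=False).reports[0]
        permuted = y_randomization(ds, proc, rounds=8, seed=3)
        assert permuted.mean_statistics()["rmse_train"] > baseline.rmse_train


class TestPredictionSetGuards:
    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            PredictionSet(np.ones(3), np.ones(4))

    def test_non_finite(self):
        with pytest.raises(ValueError):
            PredictionSet(np.array([1.0, np.inf]), np.ones(2))

    def test_all_zero_predictions_origin_error(self):
        with pytest.raises(ValueError):
            origin_stats(PredictionSet(np.array([1.0, 2.0]), np.zeros(2)))


def test_fixture_report_is_fast_and_deterministic():
    import time
    t0 = time.perf_counter()
    a = report_from_fixture("garf")
    b = report_from_fixture("garf")
    assert time.perf_counter() - t0 < 1.0
    da, db = a.to_dict(), b.to_dict()
    assert da.keys() == db.keys()
    for key in da:
        assert da[key] == db[key] or (da[key] != da[key]
                                      and db[key] != db[key])  # NaN == NaN
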