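import numpy as np
import pytest

from invade import maxent, synth
from invade.maxent import (
    FeatureSet,
    OccurrenceSet,
    auc,
    auc_scores,
    fit_maxent,
    jackknife_gains,
    percent_contribution,
    permutation_importance,
    predict,
    predict_surface,
    response_curve,
    sample_background,
    spearman_screen,
    split_train_test,
    tune_model,
)


@pytest.fixture(scope="module")
def fitted(occurrences_and_background):
    d = occurrences_and_background
    fs = FeatureSet.build(
        d["bg_env"], names=list(_names()), categorical={"landcover"},
        classes=("linear", "quadratic"),
    )
    model = fit_maxent(fs, d["pres_env"], d["bg_env"], reg_multiplier=1.0)
    return {"model": model, **d}


def _names():
    return synth.DEFAULT_LAYERS


class TestFeatures:
    def test_scaled_to_unit_interval_over_background(self, occurrences_and_background):
        bg = occurrences_and_background["bg_env"]
        fs = FeatureSet.build(bg, list(_names()), categorical={"landcover"})
        F = fs.transform(bg)
        assert F.min() >= 0.0 and F.max() <= 1.0 + 1e-12

    def test_hinge_knots_inside_range(self, occurrences_and_background):
        bg = occurrences_and_background["bg_env"]
        fs = FeatureSet.build(bg, list(_names()), categorical={"landcover"})
        names = list(_names())
        for f in fs.features:
            if f.kind in ("hinge", "hinge_rev"):
                col = bg[:, names.index(f.variable)]
                assert col.min() <= f.param <= col.max()

    def test_nonfinite_rejected(self, occurrences_and_background):
        bg = occurrences_and_background["bg_env"]
        fs = FeatureSet.build(bg, list(_names()), categorical={"landcover"})
        bad = bg.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fs.transform(bad)

    def test_serialization_roundtrip(self, fitted, tmp_path):
        path = tmp_path / "model.json"
        fitted["model"].to_json(str(path))
        back = maxent.MaxentModel.from_json(str(path))
        env = fitted["bg_env"][:50]
        np.testing.assert_allclose(predict(back, env), predict(fitted["model"], env))


class TestBackground:
    def test_exhaustion(self, masked_landscape):
        n_valid = int(masked_landscape.valid_mask.sum())
        env, xy = sample_background(masked_landscape, n=n_valid + 500, seed=0)
        assert len(env) == n_valid

    def test_deterministic(self, landscape):
        a, _ = sample_background(landscape, n=200, seed=9)
        b, _ = sample_background(landscape, n=200, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_never_samples_nodata(self, masked_landscape):
        env, xy = sample_background(masked_landscape, n=400, seed=1)
        assert not np.isnan(env).any()
        assert masked_landscape.in_extent(xy[:, 0], xy[:, 1]).all()


class TestSpearmanScreen:
    def test_duplicate_layer_dropped(self, occurrences_and_background):
        d = occurrences_and_background
        names = ["bio6", "bio6_copy", "bio8"]
        pres = np.column_stack([d["pres_env"][:, 5], d["pres_env"][:, 5], d["pres_env"][:, 7]])
        bg = np.column_stack([d["bg_env"][:, 5], d["bg_env"][:, 5], d["bg_env"][:, 7]])
        res = spearman_screen(pres, background_env=bg, names=names, threshold=0.75)
        assert len([n for n in res["retained"] if n.startswith("bio6")]) == 1

    def test_independent_layers_retained(self):
        rng = np.random.default_rng(3)
        pres = rng.uniform(size=(100, 2))
        bg = rng.uniform(size=(500, 2))
        res = spearman_screen(pres, background_env=bg, names=["u", "v"], threshold=0.75)
        assert sorted(res["retained"]) == ["u", "v"]

    def test_planted_correlated_pair(self, landscape, occurrences_and_background):
        """The generator plants rho ~ 0.9 between bio16 and bio12; exactly
        one of the pair survives the 0.75 screen."""
        d = occurrences_and_background
        names = list(_names())
        res = spearman_screen(
            d["pres_env"], background_env=d["bg_env"], names=names,
            threshold=0.75, categorical={"landcover"},
        )
        assert ("bio16" in res["retained"]) != ("bio12" in res["retained"])
        pair_vars = {v for p in res["correlated_pairs"] for v in p[:2]}
        assert {"bio16", "bio12"} <= pair_vars

    def test_constant_layer_flagged(self):
        rng = np.random.default_rng(4)
        pres = np.column_stack([np.ones(50), rng.uniform(size=50)])
        bg = np.column_stack([np.ones(300), rng.uniform(size=300)])
        res = spearman_screen(pres, background_env=bg, names=["const", "x"])
        assert res["constant"] == ["const"]
        assert res["retained"] == ["x"]


class TestFit:
    def test_zero_features_gives_uniform(self, occurrences_and_background):
        d = occurrences_and_background
        fs = FeatureSet(names=list(_names()), features=[], categorical={"landcover"})
        model = fit_maxent(fs, d["pres_env"], d["bg_env"])
        raw = model.raw(d["bg_env"])
        np.testing.assert_allclose(raw, raw[0])  # all equal
        assert raw.sum() == pytest.approx(1.0, abs=1e-6)

    def test_raw_probabilities_sum_to_one(self, fitted):
        assert fitted["model"].raw(fitted["bg_env"]).sum() == pytest.approx(1.0, abs=1e-6)

    def test_gibbs_parameter_recovery(self):
        """Presences simulated from a known 2-feature Gibbs model are
        recovered within 15% relative error at n = 2000."""
        st = synth.gen_landscape(
            synth.LandscapeSpec(n_rows=60, n_cols=60, seed=7, correlation_plan=())
        )
        truth = synth.TruthModel(coef_linear={"bio16": 0.3, "bio6": -0.8})
        occ = synth.gen_occurrences(st, truth, n=2000, seed=8)
        bg_env, _ = sample_background(st, n=10000, seed=9)
        names = ["bio16", "bio6"]
        cols = [st.names.index(n) for n in names]
        pres = st.sample(occ.points[:, 0], occ.points[:, 1])[:, cols]
        fs = FeatureSet.build(bg_env[:, cols], names, classes=("linear",))
        model = fit_maxent(fs, pres, bg_env[:, cols], reg_multiplier=0.1)
        rec = model.raw_coefficients()["linear"]
        for var, true_coef in truth.coef_linear.items():
            assert rec[var] == pytest.approx(true_coef, rel=0.15)

    def test_doubling_one_feature_penalty_shrinks_it(self, occurrences_and_background):
        d = occurrences_and_background
        names = ["bio16", "bio6"]
        cols = [list(_names()).index(n) for n in names]
        fs = FeatureSet.build(d["bg_env"][:, cols], names, classes=("linear", "quadratic"))
        m1 = fit_maxent(fs, d["pres_env"][:, cols], d["bg_env"][:, cols], reg_multiplier=1.0)
        j = int(np.argmax(np.abs(m1.weights)))
        scale = np.ones(len(fs))
        scale[j] = 2.0
        m2 = fit_maxent(fs, d["pres_env"][:, cols], d["bg_env"][:, cols],
                        reg_multiplier=1.0, beta_scale=scale)
        assert abs(m2.weights[j]) <= abs(m1.weights[j]) + 1e-6

    def test_huge_penalty_gives_uniform(self, occurrences_and_background):
        d = occurrences_and_background
        names = ["bio16", "bio6"]
        cols = [list(_names()).index(n) for n in names]
        fs = FeatureSet.build(d["bg_env"][:, cols], names, classes=("linear", "quadratic"))
        m = fit_maxent(fs, d["pres_env"][:, cols], d["bg_env"][:, cols], reg_multiplier=1e6)
        assert np.all(m.weights == 0.0)
        s = predict(m, d["bg_env"][:, cols])
        np.testing.assert_allclose(s, s[0])

    def test_too_few_presences(self, occurrences_and_background):
        d = occurrences_and_background
        fs = FeatureSet.build(d["bg_env"], list(_names()), categorical={"landcover"})
        with pytest.raises(ValueError, match="presence"):
            fit_maxent(fs, d["pres_env"][:3], d["bg_env"])


class TestPredict:
    def test_bounded(self, fitted):
        s = predict(fitted["model"], fitted["bg_env"])
        assert s.min() >= 0.0 and s.max() <= 1.0

    def test_monotone_single_linear_feature(self, occurrences_and_background):
        d = occurrences_and_background
        cols = [list(_names()).index("bio16")]
        fs = FeatureSet.build(d["bg_env"][:, cols], ["bio16"], classes=("linear",))
        m = fit_maxent(fs, d["pres_env"][:, cols], d["bg_env"][:, cols], reg_multiplier=0.5)
        assert m.weights[0] > 0  # truth loads positively on bio16
        xs = np.linspace(d["bg_env"][:, cols].min(), d["bg_env"][:, cols].max(), 50)
        s = predict(m, xs[:, None])
        assert np.all(np.diff(s) >= -1e-12)

    def test_surface_preserves_nodata(self, masked_landscape):
        truth = synth.TruthModel(coef_linear={"bio16": 0.3})
        occ = synth.gen_occurrences(masked_landscape, truth, n=100, seed=5)
        bg_env, _ = sample_background(masked_landscape, n=500, seed=6)
        pres = masked_landscape.sample(occ.points[:, 0], occ.points[:, 1])
        fs = FeatureSet.build(bg_env, masked_landscape.names,
                              categorical={"landcover"}, classes=("linear",))
        m = fit_maxent(fs, pres, bg_env)
        surf = predict_surface(m, masked_landscape)
        assert np.isnan(surf[masked_landscape.mask]).all()
        assert not np.isnan(surf[masked_landscape.valid_mask]).any()


class TestSplit:
    def test_75_25(self):
        train, test = split_train_test(np.arange(100), seed=1)
        assert (len(train), len(test)) == (75, 25)

    def test_four_points(self):
        train, test = split_train_test(np.arange(4), seed=1)
        assert (len(train), len(test)) == (3, 1)

    def test_partition(self):
        pts = np.arange(37)
        train, test = split_train_test(pts, seed=2)
        assert sorted(np.concatenate([train, test]).tolist()) == pts.tolist()
        assert set(train.tolist()).isdisjoint(test.tolist())


class TestAUC:
    def test_perfect_separation(self):
        assert auc_scores([0.9, 0.8], [0.1, 0.2, 0.3]) == 1.0

    def test_shuffled_labels_near_half(self):
        rng = np.random.default_rng(14)
        scores = rng.uniform(size=4000)
        assert auc_scores(scores[:2000], scores[2000:]) == pytest.approx(0.5, abs=0.03)

    def test_single_presence_rank(self):
        rng = np.random.default_rng(15)
        bg = rng.uniform(size=500)
        p = 0.73
        expected = ((bg < p).sum() + 0.5 * (bg == p).sum()) / 500
        assert auc_scores([p], bg) == pytest.approx(expected)

    def test_matches_sklearn(self, fitted):
        from sklearn.metrics import roc_auc_score

        pres = predict(fitted["model"], fitted["pres_env"])
        bg = predict(fitted["model"], fitted["bg_env"])
        ours = auc_scores(pres, bg)
        ref = roc_auc_score(
            np.r_[np.ones(len(pres)), np.zeros(len(bg))], np.r_[pres, bg]
        )
        assert ours == pytest.approx(ref, abs=1e-12)


class TestImportance:
    def test_contribution_single_variable(self, occurrences_and_background):
        d = occurrences_and_background
        cols = [list(_names()).index("bio16")]
        fs = FeatureSet.build(d["bg_env"][:, cols], ["bio16"], classes=("linear", "quadratic"))
        m = fit_maxent(fs, d["pres_env"][:, cols], d["bg_env"][:, cols])
        contrib = percent_contribution(m)
        assert contrib["bio16"] == pytest.approx(100.0)

    def test_contribution_symmetric_signal(self):
        """Two identical copies of the signal split the credit about 50/50."""
        rng = np.random.default_rng(31)
        n_bg = 4000
        v = rng.normal(size=n_bg)
        bg = np.column_stack([v, v + rng.normal(scale=1e-3, size=n_bg)])
        eta = 1.2 * v
        p = np.exp(eta - eta.max())
        p /= p.sum()
        idx = rng.choice(n_bg, size=1500, p=p)
        pres = bg[idx]
        fs = FeatureSet.build(bg, ["a", "b"], classes=("linear",))
        m = fit_maxent(fs, pres, bg, reg_multiplier=0.5)
        contrib = percent_contribution(m)
        assert contrib["a"] == pytest.approx(50.0, abs=5.0)
        assert sum(contrib.values()) == pytest.approx(100.0, abs=0.1)

    def test_contribution_sums_to_100(self, fitted):
        contrib = percent_contribution(fitted["model"])
        assert sum(contrib.values()) == pytest.approx(100.0, abs=0.1)
        assert all(v >= 0 for v in contrib.values())

    def test_permutation_unused_variable_zero(self, fitted):
        model = fitted["model"]
        unused = [
            n for n in model.feature_set.names
            if all(w == 0 for f, w in zip(model.feature_set.features, model.weights)
                   if f.variable == n)
        ]
        imp = permutation_importance(model, fitted["pres_env"], fitted["bg_env"], seed=1)
        for n in unused:
            assert imp[n] == 0.0
        assert sum(imp.values()) == pytest.approx(100.0, abs=0.1)

    def test_permutation_dominant_variable(self, occurrences_and_background):
        d = occurrences_and_background
        names = ["bio6", "bio3", "bio15"]  # truth loads only on bio6 here
        cols = [list(_names()).index(n) for n in names]
        fs = FeatureSet.build(d["bg_env"][:, cols], names, classes=("linear", "quadratic"))
        m = fit_maxent(fs, d["pres_env"][:, cols], d["bg_env"][:, cols])
        imp = permutation_importance(m, d["pres_env"][:, cols], d["bg_env"][:, cols], seed=2)
        assert imp["bio6"] == max(imp.values())

    def test_jackknife(self, occurrences_and_background):
        d = occurrences_and_background
        rng = np.random.default_rng(8)
        names = ["bio16", "bio16_dup", "noise"]
        bg = np.column_stack([
            d["bg_env"][:, list(_names()).index("bio16")],
            d["bg_env"][:, list(_names()).index("bio16")],
            rng.normal(size=len(d["bg_env"])),
        ])
        pres = np.column_stack([
            d["pres_env"][:, list(_names()).index("bio16")],
            d["pres_env"][:, list(_names()).index("bio16")],
            rng.normal(size=len(d["pres_env"])),
        ])
        fs = FeatureSet.build(bg, names, classes=("linear", "quadratic"))
        full = fit_maxent(fs, pres, bg)
        gains = jackknife_gains(fs, pres, bg)
        assert all(g["with_only"] >= 0 and g["without"] >= 0 for g in gains.values())
        # pure-noise layer carries almost no single-variable gain
        assert gains["noise"]["with_only"] <= 0.05
        # removing a duplicated variable costs (almost) nothing
        assert gains["bio16_dup"]["without"] == pytest.approx(full.gain(), rel=0.1)


class TestResponseCurve:
    def test_monotone_for_positive_linear(self, occurrences_and_background):
        d = occurrences_and_background
        cols = [list(_names()).index("bio16")]
        fs = FeatureSet.build(d["bg_env"][:, cols], ["bio16"], classes=("linear",))
        m = fit_maxent(fs, d["pres_env"][:, cols], d["bg_env"][:, cols], reg_multiplier=0.5)
        xs, ys = response_curve(m, "bio16", d["bg_env"][:, cols])
        assert np.all(np.diff(ys) >= -1e-12)

    def test_flat_for_absent_variable(self, fitted):
        model = fitted["model"]
        zeroed = [
            n for n in model.feature_set.names
            if all(w == 0 for f, w in zip(model.feature_set.features, model.weights)
                   if f.variable == n)
        ]
        if not zeroed:
            pytest.skip("every variable carries weight in this fit")
        xs, ys = response_curve(model, zeroed[0], fitted["bg_env"])
        np.testing.assert_allclose(ys, ys[0])

    def test_negative_quadratic_unimodal(self, occurrences_and_background):
        d = occurrences_and_background
        cols = [list(_names()).index("bio8")]
        bg = d["bg_env"][:, cols]
        fs = FeatureSet.build(bg, ["bio8"], classes=("linear", "quadratic"))
        # hand-build a concave model: peak at an interior bio8 value
        lin = next(f for f in fs.features if f.kind == "linear")
        quad = next(f for f in fs.features if f.kind == "quadratic")
        m = maxent.MaxentModel(
            feature_set=fs, weights=np.zeros(len(fs)), betas=np.zeros(len(fs)),
            reg_multiplier=1.0, log_z=0.0, entropy=0.0,
            n_presence=10, n_background=len(bg),
        )
        mid = (bg.min() + bg.max()) / 2
        # eta = 2*a*mid*v - a*v^2 peaks at v = mid (a > 0, raw scale)
        a = 0.5
        m.weights[fs.features.index(lin)] = 2 * a * mid * (lin.hi - lin.lo)
        m.weights[fs.features.index(quad)] = -a * (quad.hi - quad.lo)
        eta_bg = m.linear_predictor(bg)
        from scipy.special import logsumexp
        m.log_z = float(logsumexp(eta_bg))
        xs, ys = response_curve(m, "bio8", bg)
        peak = np.argmax(ys)
        assert 0 < peak < len(ys) - 1
        assert xs[peak] == pytest.approx(mid, abs=(xs[1] - xs[0]) * 2)


class TestObjective:
    def test_monotone_decrease(self, fitted):
        trace = np.asarray(fitted["model"].objective_trace)
        assert np.all(np.diff(trace) <= 1e-10)

    def test_oracle_dominance(self, occurrences_and_background):
        """The true generating suitability ranks presences at least as well
        as any fitted model (up to stochastic slack)."""
        d = occurrences_and_background
        names = list(_names())
        truth = d["truth"]
        eta_p = truth.predictor_env(d["pres_env"], names)
        eta_b = truth.predictor_env(d["bg_env"], names)
        auc_truth = auc_scores(eta_p, eta_b)
        fs = FeatureSet.build(d["bg_env"], names, categorical={"landcover"})
        m = fit_maxent(fs, d["pres_env"], d["bg_env"])
        assert auc_truth >= auc(m, d["pres_env"], d["bg_env"]) - 0.02


class TestTune:
    def test_single_candidate(self, occurrences_and_background):
        d = occurrences_and_background
        names = ["bio16", "bio6"]
        cols = [list(_names()).index(n) for n in names]
        res = tune_model(
            d["pres_env"][:, cols], d["bg_env"][:, cols], names,
            reg_multipliers=(1.0,), feature_class_sets=(("linear", "quadratic"),),
        )
        assert res["best"]["reg_multiplier"] == 1.0
        assert len(res["table"]) == 1

    def test_regularized_beats_overfit_on_small_n(self):
        """With few presences, AICc prefers a regularized sparse model to a
        near-unregularized hinge-rich one."""
        rng = np.random.default_rng(44)
        bg = rng.normal(size=(2000, 2))
        eta = 0.8 * bg[:, 0]
        p = np.exp(eta - eta.max())
        p /= p.sum()
        pres = bg[rng.choice(2000, size=12, p=p)]
        res = tune_model(
            pres, bg, ["a", "b"],
            reg_multipliers=(0.001, 2.0),
            feature_class_sets=(("linear", "quadratic", "hinge"),),
            criterion="aicc",
        )
        assert res["best"]["reg_multiplier"] == 2.0
        assert len(res["table"]) == 2

    def test_table_covers_grid(self, occurrences_and_background):
        d = occurrences_and_background
        names = ["bio16", "bio6"]
        cols = [list(_names()).index(n) for n in names]
        res = tune_model(
            d["pres_env"][:, cols], d["bg_env"][:, cols], names,
            reg_multipliers=(0.5, 1.0, 2.0),
            feature_class_sets=(("linear",), ("linear", "quadratic")),
        )
        assert len(res["table"]) == 6


class TestOccurrenceSet:
    def test_csv_roundtrip(self, tmp_path, occurrences_and_background):
        occ = occurrences_and_background["occ"]
        path = tmp_path / "occ.csv"
        occ.to_csv(str(path))
        back = OccurrenceSet.from_csv(str(path))
        np.testing.assert_allclose(back.points, occ.points)
        assert back.species == occ.species

    def test_thin_to_cells(self, landscape, occurrences_and_background):
        occ = occurrences_and_background["occ"]
        thinned = occ.thin_to_cells(landscape)
        rows, cols = landscape.xy_to_rowcol(thinned.points[:, 0], thinned.points[:, 1])
        assert len(np.unique(np.stack([rows, cols]), axis=1).T) == len(thinned)

    def test_filter_valid(self, masked_landscape):
        pts = np.array([[-50.0, -50.0], [1.0, 1.0]])
        occ = OccurrenceSet(pts).filter_valid(masked_landscape)
        assert len(occ) <= 2
        if len(occ):
            assert masked_landscape.in_extent(occ.points[:, 0], occ.points[:, 1]).all()
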