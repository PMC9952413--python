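import numpy as np
import pandas as pd
import pytest

from prosfold import statpipe, synthetic
from prosfold.errors import ProsfoldError
from prosfold.statpipe import (
    FeatureGroups, assign_groups, classify, cluster_features, fit_regression,
    mann_whitney, optimize_boundaries, select_features,
)

from _oracles import mwu_exact_p

BLOCK1 = [f"a{i}" for i in range(5)]
BLOCK2 = [f"b{i}" for i in range(6)]


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_p_near_one(self):
        x = np.arange(30, dtype=float)
        _, p = mann_whitney(x, x + 0.0)
        assert p > 0.9

    def test_extreme_separation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 2000)
        y = rng.normal(10, 1, 2000)
        _, p = mann_whitney(x, y)
        assert p < 1e-10

    def test_empty_sample_rejected(self):
        with pytest.raises(ProsfoldError):
            mann_whitney([], [1.0])

    def test_exact_p_matches_enumeration_up_to_8_8(self):
        """For every sample-size pair up to (8,8) without ties, the exact
        p equals full enumeration over label placements."""
        rng = np.random.default_rng(1)
        for n in range(1, 9):
            for m in range(n, 9):
                pooled = rng.permutation(np.arange(n + m, dtype=float) * 1.37)
                x, y = pooled[:n], pooled[n:]
                _, p = mann_whitney(x, y)
                assert p == pytest.approx(mwu_exact_p(x, y), abs=1e-12), (n, m)


class TestClassify:
    @pytest.mark.parametrize("rmsd,expect", [
        (1.00, "excellent"),   # the long-helix worked example
        (1.76, "excellent"),   # boundary inclusive
        (2.95, "average"),
        (4.13, "poor"),        # boundary inclusive
        (5.19, "poor"),        # the extended-segment worked example
    ])
    def test_published_boundaries(self, rmsd, expect):
        assert classify(rmsd) == expect

    def test_invalid_boundaries(self):
        with pytest.raises(ProsfoldError):
            classify(1.0, b1=4.0, b2=2.0)


class TestOptimizeBoundaries:
    def test_planted_two_cluster_data(self):
        """Boundaries recovered on bimodal RMSDs keep the low cluster out
        of the poor class and the high cluster out of the excellent class."""
        rng = np.random.default_rng(5)
        low = rng.normal(1.5, 0.3, 30)
        high = rng.normal(5.0, 0.5, 30)
        rmsds = np.concatenate([low, high])
        feats = pd.DataFrame({
            f"f{i}": np.concatenate([rng.normal(0, 1, 30), rng.normal(2, 1, 30)])
            for i in range(5)})
        b1, b2 = optimize_boundaries(rmsds, feats)
        assert low.max() < b2 and high.min() > b1
        labels = statpipe.classify_all(rmsds, b1, b2)
        assert not np.any(labels[:30] == "poor")
        assert not np.any(labels[30:] == "excellent")

    def test_null_features_deterministic_tiebreak(self):
        rng = np.random.default_rng(6)
        rmsds = rng.uniform(0.5, 6.0, 40)
        feats = pd.DataFrame({f"f{i}": rng.normal(size=40) for i in range(3)})
        pair1 = optimize_boundaries(rmsds, feats)
        pair2 = optimize_boundaries(rmsds, feats)
        assert pair1 == pair2

    def test_too_few_segments(self):
        with pytest.raises(ProsfoldError):
            optimize_boundaries(np.ones(10), pd.DataFrame({"f": np.ones(10)}))


class TestSelectFeatures:
    def test_constant_feature_not_selected_rmsd_feature_minimal(self):
        rng = np.random.default_rng(2)
        n = 40
        rmsds = np.concatenate([rng.uniform(0.3, 1.5, n), rng.uniform(4.5, 7, n)])
        labels = np.array(["excellent"] * n + ["poor"] * n)
        df = pd.DataFrame({"constant": np.ones(2 * n),
                           "noise": rng.normal(size=2 * n),
                           "rmsd_copy": rmsds})
        result = select_features(df, labels)
        assert "constant" not in result.selected
        assert "rmsd_copy" in result.selected
        assert result.p_excellent_vs_poor["rmsd_copy"] == min(
            result.p_excellent_vs_poor.values())

    def test_planted_shifted_features_recovered(self):
        """Five features shifted by 1.5 SD between classes are selected and
        six null features are not, in nearly all seeds."""
        shifted = [f"s{i}" for i in range(5)]
        null = [f"n{i}" for i in range(6)]
        exact = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 60
            cols = {f: np.concatenate([rng.normal(0, 1, n),
                                       rng.normal(1.5 if f in shifted else 0.0, 1, n)])
                    for f in shifted + null}
            labels = np.array(["excellent"] * n + ["poor"] * n)
            result = select_features(pd.DataFrame(cols), labels)
            exact += set(result.selected) == set(shifted)
        assert exact >= 95

    def test_empty_class_rejected(self):
        df = pd.DataFrame({"f": np.arange(4.0)})
        with pytest.raises(ProsfoldError):
            select_features(df, np.array(["excellent"] * 4))


class TestRegression:
    def test_noiseless_model_recovered_exactly(self):
        rng = np.random.default_rng(3)
        x1 = rng.normal(size=50)
        df = pd.DataFrame({"x1": x1})
        model = fit_regression(df, 2.0 * x1 + 1.0, outlier_threshold=np.inf)
        assert model.coefficients[0] == pytest.approx(2.0, abs=1e-9)
        assert model.intercept == pytest.approx(1.0, abs=1e-9)
        assert model.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_planted_coefficients_within_3se(self):
        coefs = {f"f{i}": c for i, c in enumerate(
            [0.05, 0.5, -3.9, 2.3, 1.3, 2.3, 1.8, -0.4, 0.5, -0.2, 0.4])}
        df, _ = synthetic.gen_feature_table(150, coefs, noise_sd=1.0, seed=9)
        model = fit_regression(df.drop(columns=["rmsd"]), df["rmsd"],
                               outlier_threshold=np.inf)
        import statsmodels.api as sm
        design = sm.add_constant(df[list(coefs)].to_numpy())
        se = sm.OLS(df["rmsd"].to_numpy(), design).fit().bse[1:]
        for i, name in enumerate(coefs):
            assert abs(model.coefficients[i] - coefs[name]) <= 3 * se[i]

    def test_outliers_excluded_by_true_rmsd(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=60)
        y = 1.0 + x.copy()
        y[:5] += 20.0  # rows beyond the threshold
        model = fit_regression(pd.DataFrame({"x": x}), y, outlier_threshold=7.0)
        assert model.outlier_mask.sum() == 5
        assert model.n_used == 55
        assert model.coefficients[0] == pytest.approx(1.0, abs=1e-9)

    def test_t_value_sign_matches_coefficient(self):
        coefs = {"up": 2.0, "down": -2.0, "weak": 0.3}
        df, _ = synthetic.gen_feature_table(120, coefs, noise_sd=0.5, seed=10)
        model = fit_regression(df.drop(columns=["rmsd"]), df["rmsd"],
                               outlier_threshold=np.inf)
        for i, name in enumerate(coefs):
            assert np.sign(model.t_values[name]) == np.sign(model.coefficients[i])

    def test_collinear_design_rejected_with_names(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        df = pd.DataFrame({"x": x, "x_twice": 2.0 * x})
        with pytest.raises(ProsfoldError, match="x_twice"):
            fit_regression(df, x + 1.0, outlier_threshold=np.inf)


class TestClusterFeatures:
    def _planted(self, seed=0):
        coefs = {f: 1.0 for f in BLOCK1 + BLOCK2}
        df, _ = synthetic.gen_feature_table(150, coefs, blocks=[BLOCK1, BLOCK2],
                                            within_r=0.8, seed=seed)
        return df

    def test_two_planted_blocks_recovered(self):
        df = self._planted()
        groups = cluster_features(df.drop(columns=["rmsd"]), df["rmsd"])
        assert {frozenset(groups.group1), frozenset(groups.group2)} == \
            {frozenset(BLOCK1), frozenset(BLOCK2)}

    def test_feature_and_negation_land_together(self):
        rng = np.random.default_rng(7)
        f = rng.normal(size=100)
        g = rng.normal(size=100)
        h = rng.normal(size=100)
        y = f + g + h + rng.normal(scale=0.1, size=100)
        df = pd.DataFrame({"f": f, "neg_f": -f, "g": g, "h": h})
        groups = cluster_features(df, y)
        side = groups.group1 if "f" in groups.group1 else groups.group2
        assert "neg_f" in side
        assert groups.sign_flips["neg_f"] == -1

    def test_invariant_to_column_order_and_negation(self):
        df = self._planted(seed=3)
        x = df.drop(columns=["rmsd"])
        base = cluster_features(x, df["rmsd"])
        shuffled = x[list(reversed(x.columns))]
        alt = cluster_features(shuffled, df["rmsd"])
        assert {frozenset(base.group1), frozenset(base.group2)} == \
            {frozenset(alt.group1), frozenset(alt.group2)}
        flipped = x.copy()
        flipped["a0"] = -flipped["a0"]
        alt2 = cluster_features(flipped, df["rmsd"])
        assert {frozenset(base.group1), frozenset(base.group2)} == \
            {frozenset(alt2.group1), frozenset(alt2.group2)}

    def test_constant_feature_rejected_by_name(self):
        df = pd.DataFrame({"ok": np.arange(10.0), "flat": np.ones(10),
                           "ok2": np.arange(10.0) ** 2})
        with pytest.raises(ProsfoldError, match="flat"):
            cluster_features(df, np.arange(10.0))


class TestAssignGroups:
    def _model(self, names, coefs, intercept=0.0):
        return statpipe.RegressionModel(
            feature_names=list(names), coefficients=np.asarray(coefs, float),
            intercept=intercept, t_values={}, r_squared=1.0, pearson_r=1.0,
            outlier_mask=np.zeros(1, dtype=bool), n_used=1)

    def test_zero_group2_coefficients_forces_group1(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"a": rng.normal(size=20), "b": rng.normal(size=20)})
        model = self._model(["a", "b"], [1.5, 0.0])
        groups = FeatureGroups(linkage=np.zeros((0, 4)), group1=["a"], group2=["b"])
        out = assign_groups(model, groups, df)
        assert (out["d1"] == 0.0).all()
        assert (out.loc[out["d2"] > 0, "group"] == 1).all()

    def test_exact_tie_goes_to_group2(self):
        df = pd.DataFrame({"a": [1.0, -2.0], "b": [1.0, -2.0]})
        model = self._model(["a", "b"], [1.0, 1.0])
        groups = FeatureGroups(linkage=np.zeros((0, 4)), group1=["a"], group2=["b"])
        out = assign_groups(model, groups, df)
        assert (out["group"] == 2).all()

    def test_planted_groups_recovered(self):
        """Items whose RMSD depends on only one feature block are assigned
        to that block's group in nearly every case."""
        accs = []
        for seed in range(20):
            df, truth = synthetic.gen_grouped_feature_table(100, BLOCK1, BLOCK2,
                                                            seed=seed)
            x = df.drop(columns=["rmsd"])
            model = fit_regression(x, df["rmsd"], outlier_threshold=np.inf)
            groups = FeatureGroups(linkage=np.zeros((0, 4)),
                                   group1=BLOCK1, group2=BLOCK2)
            out = assign_groups(model, groups, x)
            accs.append(np.mean(out["group"].to_numpy() ==
                                np.array(truth["groups"])))
        assert min(accs) >= 0.90

    def test_scale_invariance_of_group_counts(self):
        df, _ = synthetic.gen_grouped_feature_table(80, BLOCK1, BLOCK2, seed=4)
        x = df.drop(columns=["rmsd"])
        model = fit_regression(x, df["rmsd"], outlier_threshold=np.inf)
        groups = FeatureGroups(linkage=np.zeros((0, 4)),
                               group1=BLOCK1, group2=BLOCK2)
        base = assign_groups(model, groups, x)["group"]
        scaled = x.copy()
        scaled["a0"] = scaled["a0"] * 37.0
        model2 = fit_regression(scaled, df["rmsd"], outlier_threshold=np.inf)
        alt = assign_groups(model2, groups, scaled)["group"]
        assert (base.to_numpy() == alt.to_numpy()).all()

    def test_missing_feature_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        model = self._model(["a", "b"], [1.0, 1.0])
        groups = FeatureGroups(linkage=np.zeros((0, 4)), group1=["a"], group2=["b"])
        with pytest.raises(ProsfoldError):
            assign_groups(model, groups, df)
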