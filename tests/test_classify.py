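"""Screening, kernels, SVM training and leave-one-out validation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from barogeo import classify as clf


def enum_mann_whitney(x, y):
    """Full-enumeration two-sided Mann–Whitney oracle (no ties)."""
    pooled = np.concatenate([x, y])
    nx, n = len(x), len(pooled)

    def ustat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = ustat(x, y)
    mn = nx * (n - nx)
    u_max = max(u_obs, mn - u_obs)
    cnt = tot = 0
    for comb in itertools.combinations(range(n), nx):
        mask = np.zeros(n, bool)
        mask[list(comb)] = True
        if ustat(pooled[mask], pooled[~mask]) >= u_max:
            cnt += 1
        tot += 1
    return min(1.0, 2 * cnt / tot)


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        assert clf.mann_whitney([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_constant_samples(self):
        assert clf.mann_whitney([2.0, 2.0], [2.0, 2.0]) == 1.0

    def test_exact_path_matches_enumeration(self, rng):
        for _ in range(15):
            nx = int(rng.integers(2, 7))
            ny = int(rng.integers(2, 13 - nx))
            pooled = rng.normal(size=nx + ny)
            x, y = pooled[:nx], pooled[nx:]
            assert clf.mann_whitney(x, y) == pytest.approx(
                enum_mann_whitney(x, y), abs=1e-12
            )

    def test_large_shifted_normals(self):
        r = np.random.default_rng(1)
        x = r.normal(size=200)
        y = r.normal(loc=1.0, size=200)
        assert clf.mann_whitney(x, y) < 1e-3

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            clf.mann_whitney([], [1.0])


class TestCorrelationFilter:
    def test_identical_columns_excluded(self, rng):
        a = rng.normal(size=100)
        df = pd.DataFrame({"f1": a, "f2": a, "f3": rng.normal(size=100)})
        pairs = clf.correlation_filter(df, ["f1", "f2", "f3"], rho_max=0.7)
        assert ("f1", "f2") not in pairs
        assert ("f1", "f3") in pairs and ("f2", "f3") in pairs

    def test_independent_noise_admitted(self, rng):
        df = pd.DataFrame({"f1": rng.normal(size=100), "f2": rng.normal(size=100)})
        # oracle: direct rank correlation is far below the cut
        from scipy.stats import spearmanr
        assert abs(spearmanr(df["f1"], df["f2"]).statistic) < 0.3
        assert clf.correlation_filter(df, ["f1", "f2"]) == [("f1", "f2")]

    def test_single_index_errors(self, rng):
        df = pd.DataFrame({"f1": rng.normal(size=10)})
        with pytest.raises(ValueError):
            clf.correlation_filter(df, ["f1"])

    def test_no_admissible_pair_reports_matrix(self, rng):
        a = rng.normal(size=50)
        df = pd.DataFrame({"f1": a, "f2": 2 * a + 1})
        with pytest.raises(ValueError, match="Spearman"):
            clf.correlation_filter(df, ["f1", "f2"])


class TestKernels:
    def test_self_similarity(self):
        x = np.array([[0.3, -1.2]])
        assert clf.kernel_matrix(x, x, "gaussian", 1.0)[0, 0] == pytest.approx(1.0)
        assert clf.kernel_matrix(x, x, "laplace", 1.0)[0, 0] == pytest.approx(1.0)
        for d in (1, 2, 3):
            assert clf.kernel_matrix(x, x, "anova", 1.0, d)[0, 0] == pytest.approx(2.0**d)

    def test_gaussian_at_one_sigma(self):
        x, y = np.array([[0.0, 0.0]]), np.array([[1.0, 0.0]])
        k = clf.kernel_matrix(x, y, "gaussian", sigma=1.0)
        assert k[0, 0] == pytest.approx(np.exp(-0.5))

    @pytest.mark.parametrize("kernel", clf.KERNELS)
    def test_gram_positive_semidefinite(self, kernel, rng):
        X = rng.normal(size=(10, 2))
        g = clf.kernel_matrix(X, None, kernel, sigma=1.0, d=2)
        np.testing.assert_allclose(g, g.T, atol=1e-12)
        assert np.linalg.eigvalsh(g).min() >= -1e-8

    def test_bad_sigma_errors(self):
        with pytest.raises(ValueError):
            clf.kernel_matrix(np.zeros((2, 2)), kernel="gaussian", sigma=0.0)


class TestTrainSvm:
    def test_separable_points(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        fit = clf.train_svm(X, y, C=10.0, kernel="gaussian", sigma=1.0)
        assert np.all(fit.predict(X) == y)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            clf.train_svm(np.zeros((3, 1)), np.array([1, 1, 1]))

    def test_xor_pattern_solved_by_rbf(self):
        X = np.array([[0.0, 0], [1, 1], [0, 1], [1, 0]])
        y = np.array([0, 0, 1, 1])
        fit = clf.train_svm(X, y, C=10.0, kernel="gaussian", sigma=0.5)
        assert np.all(fit.predict(X) == y)
        # decision function sign agrees with predictions at the 4 points
        f = fit.decision_function(X)
        assert np.all((f > 0) == (y == fit.classes[1]))


class TestMetrics:
    def test_reference_confusion_triple(self):
        acc, sn, sp = clf.classification_metrics(tp=16, fn=1, tn=22, fp=2)
        assert round(acc, 1) == 92.7
        assert round(sn, 1) == 94.1
        assert round(sp, 1) == 91.7

    def test_perfect_predictor(self):
        assert clf.classification_metrics(10, 0, 10, 0) == (100.0, 100.0, 100.0)

    def test_all_positive_predictor(self):
        acc, sn, sp = clf.classification_metrics(10, 0, 0, 10)
        assert sn == 100.0 and sp == 0.0

    def test_identities_hold(self, rng):
        for _ in range(20):
            tp, fn, tn, fp = rng.integers(0, 30, size=4)
            if tp + fn == 0 or tn + fp == 0:
                continue
            acc, sn, sp = clf.classification_metrics(tp, fn, tn, fp)
            n = tp + fn + tn + fp
            assert acc == pytest.approx(100 * (tp + tn) / n)
            assert sn == pytest.approx(100 * tp / (tp + fn))
            assert sp == pytest.approx(100 * tn / (tn + fp))


def _planted_table(seed=7, n_per=12, shift=2.5, n_noise=6):
    """Feature table with one strongly separating low-correlation pair."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per
    data = {f"noise{i}": rng.normal(size=n) for i in range(n_noise)}
    y = np.array(["A"] * n_per + ["B"] * n_per)
    data["sigA"] = rng.normal(size=n) + shift * (y == "B")
    data["sigB"] = rng.normal(size=n) + shift * (y == "B")
    idx = [f"S{i:02d}" for i in range(n)]
    return pd.DataFrame(data, index=idx), pd.Series(y, index=idx, name="group")


class TestLoocv:
    def test_separable_pair_high_accuracy(self):
        feats, groups = _planted_table()
        X = feats[["sigA", "sigB"]].to_numpy()
        acc, sn, sp, preds = clf.loocv_evaluate(
            X, groups.to_numpy(), positive="B", C=1.0, kernel="gaussian", sigma=1.0
        )
        assert acc >= 90.0
        assert preds.shape == (24,)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            clf.loocv_evaluate(np.zeros((4, 2)), np.array(["A"] * 4), "A")


class TestModelSearch:
    def test_selects_planted_pair(self):
        feats, groups = _planted_table()
        res = clf.model_search(
            feats, groups, ("A", "B"), mode="paper",
            grid={"C": (1.0,), "sigma": (1.0,)}, kernels=("gaussian",),
        )
        assert set(res.feature_pair) == {"sigA", "sigB"}
        assert res.acc >= 90.0
        assert res.positive == "B"

    def test_minimal_grid_single_candidate(self):
        feats, groups = _planted_table(n_noise=0)
        res = clf.model_search(
            feats, groups, ("A", "B"), mode="paper",
            grid={"C": (1.0,), "sigma": (1.0,)}, kernels=("gaussian",),
        )
        assert res.n_candidates == 1
        assert res.kernel == "gaussian" and res.C == 1.0 and res.sigma == 1.0

    def test_determinism(self):
        feats, groups = _planted_table()
        kw = dict(grid={"C": (1.0, 5.0), "sigma": (0.5, 1.0)}, kernels=("gaussian", "laplace"))
        r1 = clf.model_search(feats, groups, ("A", "B"), mode="honest", **kw)
        r2 = clf.model_search(feats, groups, ("A", "B"), mode="honest", **kw)
        assert r1.to_dict() == r2.to_dict()

    def test_missing_values_excluded_not_imputed(self):
        feats, groups = _planted_table()
        feats.loc["S00", "sigA"] = np.nan
        res = clf.model_search(
            feats, groups, ("A", "B"), mode="paper",
            grid={"C": (1.0,), "sigma": (1.0,)}, kernels=("gaussian",),
        )
        if set(res.feature_pair) == {"sigA", "sigB"}:
            assert res.n_excluded == 1
            assert "S00" not in res.predictions.index

    def test_positive_class_convention(self):
        feats, groups = _planted_table()
        groups = groups.replace({"A": "CON", "B": "ICM"})
        model = clf.SubspaceClassifier(feats, groups, ("ICM", "CON"))
        assert model.positive == "ICM"  # patient group, even when first-listed
        model2 = clf.SubspaceClassifier(feats, groups, ("CON", "ICM"))
        assert model2.positive == "ICM"

    def test_honest_mode_screening_inside_folds_blocks_leakage(self):
        """Label shuffles: honest LOOCV stays near chance (no screening leak)."""
        rng = np.random.default_rng(55)
        n_per = 8
        n = 2 * n_per
        idx = [f"S{i:02d}" for i in range(n)]
        feats = pd.DataFrame(
            {f"f{i}": rng.normal(size=n) for i in range(20)}, index=idx
        )
        base = np.array(["A"] * n_per + ["B"] * n_per)
        accs = []
        for _ in range(100):
            y = pd.Series(rng.permutation(base), index=idx)
            res = clf.model_search(
                feats, y, ("A", "B"), mode="honest",
                grid={"C": (1.0,), "sigma": (1.0, 2.0)}, kernels=("gaussian",),
            )
            accs.append(res.acc)
        assert abs(np.median(accs) - 50.0) <= 15.0
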