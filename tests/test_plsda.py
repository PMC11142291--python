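"""NIPALS PLS-DA: identities, recovery, pruning, loading selection."""

import numpy as np
import pandas as pd
import pytest

from ogttmet.plsda import (
    PLSDAModel,
    fit_plsda,
    loo_accuracy,
    lv_repeated_measures,
    prune_by_vip,
    select_by_loading,
    vip_scores,
)


def two_class_data(n=30, p=10, sep=2.0, seed=0):
    rng = np.random.default_rng(seed)
    shift = np.zeros(p)
    shift[:2] = sep
    X = np.vstack([rng.normal(0, 1, (n, p)) + shift, rng.normal(0, 1, (n, p))])
    return X, ["a"] * n + ["b"] * n


def test_separable_classes_full_loo_accuracy():
    X, labels = two_class_data(sep=4.0)
    model = fit_plsda(X, labels, max_components=2)
    assert model.cv["loo_accuracy"].max() == 1.0
    t1 = model.T[:, 0]
    within_sd = np.sqrt((t1[:30].var(ddof=1) + t1[30:].var(ddof=1)) / 2)
    assert t1[:30].mean() > t1[30:].mean() + 2 * within_sd


def test_weight_recovers_informative_direction():
    rng = np.random.default_rng(3)
    direction = np.zeros(8)
    direction[3] = 1.0
    y = np.repeat([1.0, -1.0], 500)
    # noise in every column so autoscaling leaves the geometry intact
    X = np.outer(y, direction) + rng.normal(0, 0.3, (1000, 8))
    model = fit_plsda(X, ["a" if v > 0 else "b" for v in y], max_components=1, cv=False)
    w = model.W[:, 0]
    cos = abs(w @ direction) / np.linalg.norm(w)
    assert cos > 0.99


def test_rank_one_noise_free_matches_svd():
    rng = np.random.default_rng(5)
    u = rng.normal(size=20)
    v = rng.normal(size=6)
    X = np.outer(u, v)
    X = X + rng.normal(0, 1e-9, X.shape)  # break exact degeneracy only
    labels = ["a" if s > 0 else "b" for s in u]
    model = fit_plsda(X, labels, max_components=1, cv=False)
    Xc = (X - X.mean(0)) / X.std(0, ddof=1)
    _, _, vt = np.linalg.svd(Xc)
    cos = abs(model.W[:, 0] @ vt[0]) / np.linalg.norm(model.W[:, 0])
    assert cos > 1 - 1e-6


def test_score_orthogonality_and_vip_identity():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(40, 12))
    X[:20, :3] += 1.0
    model = fit_plsda(X, ["a"] * 20 + ["b"] * 20, max_components=3, cv=False)
    G = model.T.T @ model.T
    off = G - np.diag(np.diag(G))
    assert np.abs(off).max() < 1e-8
    assert np.mean(model.vip**2) == pytest.approx(1.0, abs=1e-8)


def test_vip_toy_hand_case():
    w = np.array([[0.8], [0.6], [0.0]])
    model = PLSDAModel(
        variables=["a", "b", "c"], classes=["x", "y"],
        W=w, P=w.copy(), Q=np.array([[1.0], [-1.0]]), T=np.zeros((4, 1)),
        A=1, ssy=np.array([2.0]),
        x_mean=np.zeros(3), x_std=np.ones(3), y_mean=np.zeros(2),
    )
    vip = vip_scores(model)
    assert vip == pytest.approx([1.3856, 1.0392, 0.0], abs=1e-3)


def test_cross_check_against_sklearn_pls():
    from sklearn.cross_decomposition import PLSRegression

    X, labels = two_class_data(n=25, p=6, sep=1.5, seed=11)
    model = fit_plsda(X, labels, max_components=2, cv=False)
    Y = np.array([[1.0, 0.0] if l == "a" else [0.0, 1.0] for l in labels])
    sk = PLSRegression(n_components=2, scale=True).fit(X, Y)
    for a in range(2):
        cos = abs(model.W[:, a] @ sk.x_weights_[:, a]) / (
            np.linalg.norm(model.W[:, a]) * np.linalg.norm(sk.x_weights_[:, a])
        )
        assert cos > 1 - 1e-6


class TestPrune:
    def test_zero_threshold_is_plain_fit(self):
        X, labels = two_class_data(seed=1)
        pruned = prune_by_vip(X, labels, threshold=0.0, max_components=2)
        assert len(pruned.variables) == X.shape[1]

    def test_symmetric_informative_fixed_point(self):
        rng = np.random.default_rng(0)
        y = np.repeat([1.0, -1.0], 20)
        X = np.outer(y, np.ones(4)) + rng.normal(0, 0.3, (40, 4))
        pruned = prune_by_vip(X, ["a" if v > 0 else "b" for v in y], max_components=1)
        assert pruned.history["round"].max() == 0  # all VIP ~ 1 > 0.8
        assert len(pruned.variables) == 4

    def test_recovers_informative_variables(self):
        kept_frac = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n, p_inf, p_noise = 30, 5, 25
            y = np.repeat([1.0, -1.0], n // 2)
            X = np.hstack(
                [np.outer(y, np.ones(p_inf)) + rng.normal(0, 0.6, (n, p_inf)),
                 rng.normal(0, 1, (n, p_noise))]
            )
            names = [f"inf{j}" for j in range(p_inf)] + [f"noise{j}" for j in range(p_noise)]
            pruned = prune_by_vip(
                X, ["a" if v > 0 else "b" for v in y], max_components=2, variables=names
            )
            kept_frac.append(
                sum(v.startswith("inf") for v in pruned.variables) / p_inf
            )
        assert np.mean(kept_frac) >= 0.8


class TestSelectByLoading:
    def _model_with_loadings(self, loadings):
        P = np.asarray(loadings, float)[:, None]
        return PLSDAModel(
            variables=[f"v{j}" for j in range(len(loadings))], classes=["a", "b"],
            W=P.copy(), P=P, Q=np.ones((2, 1)), T=np.zeros((3, 1)), A=1,
            ssy=np.ones(1), x_mean=np.zeros(len(loadings)),
            x_std=np.ones(len(loadings)), y_mean=np.zeros(2),
        )

    def test_outlier_selected(self):
        model = self._model_with_loadings([0, 0, 0, 0, 10])
        assert select_by_loading(model, 1.5) == ["v4"]

    def test_infinite_k_empty(self):
        model = self._model_with_loadings([0.5, -1, 2, 0.1, 1])
        assert select_by_loading(model, np.inf) == []

    def test_normal_tail_fraction(self):
        rng = np.random.default_rng(0)
        fracs = []
        for _ in range(200):
            model = self._model_with_loadings(rng.standard_normal(200))
            fracs.append(len(select_by_loading(model, 1.5)) / 200)
        from scipy.stats import norm

        assert np.mean(fracs) == pytest.approx(2 * norm.sf(1.5), abs=0.02)

    def test_degenerate_loadings_warn_empty(self):
        model = self._model_with_loadings([1.0, 1.0, 1.0])
        with pytest.warns(UserWarning, match="degenerate"):
            assert select_by_loading(model) == []


class TestLvRepeatedMeasures:
    def test_no_time_structure_p_one_region(self):
        subj = np.repeat([f"s{i}" for i in range(8)], 5)
        time = np.tile([0, 15, 30, 60, 120], 8)
        scores = np.repeat(np.arange(8.0), 5)  # subject offsets only
        res = lv_repeated_measures(scores, subj, time)
        assert res["F"] == 0.0 and res["p"] == 1.0

    def test_monotone_drift_detected_and_pairwise_count(self):
        rng = np.random.default_rng(0)
        n = 40
        subj = np.repeat([f"s{i}" for i in range(n)], 5)
        time = np.tile([0, 15, 30, 60, 120], n)
        drift = np.tile(np.linspace(0, 1.0, 5), n)
        scores = drift + rng.normal(0, 1, n * 5) + np.repeat(rng.normal(0, 1, n), 5)
        res = lv_repeated_measures(scores, subj, time)
        assert res["p"] < 0.05
        assert len(res["pairwise_p"]) == 10

    def test_incomplete_subject_dropped_with_warning(self):
        subj = np.array(["s0"] * 5 + ["s1"] * 5 + ["s2"] * 3)
        time = np.array([0, 15, 30, 60, 120] * 2 + [0, 15, 30])
        scores = np.arange(13.0)
        with pytest.warns(UserWarning, match="incomplete"):
            res = lv_repeated_measures(scores, subj, time)
        assert res["n_subjects"] == 2


def test_permuted_labels_loo_near_majority_rate():
    X, labels = two_class_data(n=20, p=8, sep=0.0, seed=21)
    rng = np.random.default_rng(0)
    accs = []
    for _ in range(20):
        perm = list(rng.permutation(labels))
        accs.append(loo_accuracy(X, perm, A=1))
    assert abs(np.mean(accs) - 0.5) < 0.12
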