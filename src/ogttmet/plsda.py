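"""NIPALS PLS-DA with leave-one-out cross-validation and VIP pruning.

Partial least squares discriminant analysis regresses a one-hot class
indicator matrix on the (autoscaled) predictor matrix via the nonlinear
iterative partial least squares (NIPALS) algorithm. The number of
components is chosen by leave-one-out classification accuracy with a
one-standard-error parsimony tie-break. Variable importance in projection
(VIP) scores summarize each variable's contribution (mean-square 1 by
construction); the pruning loop iteratively refits on variables with
VIP above a threshold until the set is stable or cross-validated accuracy
degrades. Loading-based selection (the "1.5 SD" rule) and a
repeated-measures analysis of latent-variable scores across oGTT
timepoints round out the module.

Sign convention: each weight vector is flipped so its largest-magnitude
element is positive, making fits reproducible (NIPALS signs are otherwise
arbitrary).
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats


@dataclasses.dataclass
class PLSDAModel:
    """A fitted PLS-DA model.

    Attributes follow the standard PLS notation: predictor weights ``W``
    (variable x component), predictor loadings ``P``, response weights
    ``Q`` (class x component), scores ``T`` (sample x component), number of
    components ``A``, per-component explained response sum of squares
    ``ssy``, per-variable ``vip``, and the leave-one-out record ``cv``
    (accuracy per candidate component count).
    """

    variables: list[str]
    classes: list[str]
    W: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    T: np.ndarray
    A: int
    ssy: np.ndarray
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    cv: pd.DataFrame | None = None
    vip: np.ndarray | None = None

    @property
    def loadings(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.P, index=self.variables, columns=[f"LV{a+1}" for a in range(self.A)]
        )

    @property
    def scores(self) -> np.ndarray:
        return self.T

    def coefficients(self) -> np.ndarray:
        """Regression matrix B with y_hat = x_centered @ B + y_mean."""
        pw = self.P.T @ self.W
        return self.W @ np.linalg.solve(pw, self.Q.T)

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        Xc = (np.asarray(X, float) - self.x_mean) / self.x_std
        scores = np.empty((Xc.shape[0], self.A))
        E = Xc.copy()
        for a in range(self.A):
            t = E @ self.W[:, a]
            scores[:, a] = t
            E = E - np.outer(t, self.P[:, a])
        return scores

    def predict(self, X: np.ndarray) -> list[str]:
        """Class prediction: argmax over the continuous class columns."""
        Xc = (np.asarray(X, float) - self.x_mean) / self.x_std
        yhat = Xc @ self.coefficients() + self.y_mean
        return [self.classes[k] for k in np.argmax(yhat, axis=1)]


def _nipals(
    Xc: np.ndarray, Yc: np.ndarray, n_components: int, tol: float = 1e-12, max_iter: int = 1000
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Core NIPALS PLS2 loop on centered matrices; returns W, P, Q, T, ssy."""
    n, p = Xc.shape
    k = Yc.shape[1]
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((k, n_components))
    T = np.zeros((n, n_components))
    ssy = np.zeros(n_components)
    E, F = Xc.copy(), Yc.copy()
    for a in range(n_components):
        u = F[:, int(np.argmax(F.var(axis=0)))].copy()
        t_old = np.zeros(n)
        for _ in range(max_iter):
            w = E.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            t = E @ w
            q = F.T @ t / (t @ t)
            nq = np.linalg.norm(q)
            u = F @ q / (q @ q) if nq > 0 else t
            if np.linalg.norm(t - t_old) < tol * max(1.0, np.linalg.norm(t)):
                break
            t_old = t
        # deterministic sign: largest-|w| element positive
        jmax = int(np.argmax(np.abs(w)))
        if w[jmax] < 0:
            w, t, q = -w, -t, -q
        tt = t @ t
        if tt == 0:
            break
        p_load = E.T @ t / tt
        E = E - np.outer(t, p_load)
        ssy[a] = tt * (q @ q)
        F = F - np.outer(t, q)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_load, q, t
    return W, P, Q, T, ssy


def _one_hot(labels: list[str]) -> tuple[np.ndarray, list[str]]:
    classes = sorted(set(labels))
    Y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        Y[i, classes.index(lab)] = 1.0
    return Y, classes


def _fit_raw(X: np.ndarray, labels: list[str], A: int, variables: list[str]) -> PLSDAModel:
    X = np.asarray(X, dtype=float)
    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0, ddof=1)
    if np.any(x_std == 0):
        j = int(np.where(x_std == 0)[0][0])
        raise ValueError(f"constant predictor column {variables[j]!r}; autoscale first")
    Xc = (X - x_mean) / x_std
    Y, classes = _one_hot(labels)
    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean
    A = min(A, X.shape[1], X.shape[0] - 1)
    W, P, Q, T, ssy = _nipals(Xc, Yc, A)
    return PLSDAModel(
        variables=list(variables),
        classes=classes,
        W=W, P=P, Q=Q, T=T, A=A, ssy=ssy,
        x_mean=x_mean, x_std=x_std, y_mean=y_mean,
    )


def loo_accuracy(X: np.ndarray, labels: list[str], A: int) -> float:
    """Leave-one-out classification accuracy of an A-component PLS-DA."""
    X = np.asarray(X, dtype=float)
    n = len(labels)
    hits = 0
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        train_labels = [labels[j] for j in idx[mask]]
        if len(set(train_labels)) < 2:
            continue
        model = _fit_raw(X[mask], train_labels, A, [str(j) for j in range(X.shape[1])])
        pred = model.predict(X[i : i + 1])[0]
        hits += pred == labels[i]
    return hits / n


def fit_plsda(
    X,
    labels,
    max_components: int = 3,
    variables=None,
    cv: bool = True,
) -> PLSDAModel:
    """Fit a PLS-DA model, choosing the component count by LOO accuracy.

    ``X`` should already be autoscaled (a constant column is an error); the
    fit internally re-centers/scales so leave-one-out folds are honest.
    With ``cv=False`` the model uses ``max_components`` outright. The
    one-standard-error rule picks the smallest A whose LOO accuracy is
    within one binomial SE of the best.
    """
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    if len(set(labels)) < 2:
        raise ValueError("PLS-DA needs >= 2 classes")
    if variables is None:
        variables = [f"x{j}" for j in range(X.shape[1])]
    max_components = max(1, min(max_components, X.shape[1], X.shape[0] - 2))
    cv_record = None
    A = max_components
    if cv:
        accs = [loo_accuracy(X, labels, a) for a in range(1, max_components + 1)]
        best = int(np.argmax(accs))
        se = np.sqrt(max(accs[best] * (1 - accs[best]), 1e-12) / len(labels))
        A = 1 + min(a for a in range(max_components) if accs[a] >= accs[best] - se)
        cv_record = pd.DataFrame(
            {"n_components": np.arange(1, max_components + 1), "loo_accuracy": accs}
        )
    model = _fit_raw(X, labels, A, variables)
    model.cv = cv_record
    model.vip = vip_scores(model)
    return model


def vip_scores(model: PLSDAModel) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt(p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a), where
    SSY_a is the response sum of squares explained by component a. The
    scores satisfy mean(VIP^2) = 1.
    """
    ssy = model.ssy[: model.A]
    total = ssy.sum()
    if total <= 0:
        raise ValueError("zero explained response variance; VIP undefined")
    W = model.W[:, : model.A]
    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    Wn2 = (W / norms) ** 2
    p = W.shape[0]
    return np.sqrt(p * (Wn2 @ ssy) / total)


def prune_by_vip(
    X,
    labels,
    threshold: float = 0.8,
    max_components: int = 3,
    variables=None,
    max_rounds: int = 30,
) -> PLSDAModel:
    """Iterative VIP pruning: fit, drop variables with VIP <= threshold, refit.

    Stops when every variable clears the threshold or when LOO accuracy
    degrades versus the previous round (the previous model is returned).
    The per-round history (variable count, accuracy) is attached as
    ``model.history``.
    """
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    if variables is None:
        variables = [f"x{j}" for j in range(X.shape[1])]
    variables = list(variables)
    keep = np.arange(X.shape[1])
    history = []
    prev_model = None
    prev_acc = -np.inf
    for round_no in range(max_rounds):
        model = fit_plsda(X[:, keep], labels, max_components, [variables[j] for j in keep])
        acc = float(model.cv["loo_accuracy"].iloc[model.A - 1]) if model.cv is not None else np.nan
        history.append(
            {"round": round_no, "n_variables": len(keep), "loo_accuracy": acc,
             "n_components": model.A}
        )
        if prev_model is not None and acc < prev_acc:
            model = prev_model
            break
        vip = model.vip
        low = vip <= threshold
        if not low.any():
            break
        if low.all():
            warnings.warn("pruning would empty the variable set; keeping last model")
            break
        prev_model, prev_acc = model, acc
        keep = keep[~low]
    model.history = pd.DataFrame(history)  # type: ignore[attr-defined]
    return model


def select_by_loading(model: PLSDAModel, k_sd: float = 1.5) -> list[str]:
    """Variables whose LV1 loading lies outside mean +/- k_sd * SD of loadings."""
    load = model.P[:, 0]
    sd = load.std(ddof=1)
    if sd == 0:
        warnings.warn("degenerate loadings (all equal); empty selection")
        return []
    mask = np.abs(load - load.mean()) >= k_sd * sd
    return [v for v, m in zip(model.variables, mask) if m]


def lv_repeated_measures(
    scores, subject, timepoint, pairwise: bool = True
) -> dict:
    """Within-subject ANOVA of latent-variable scores across oGTT timepoints.

    Subjects lacking a score at every timepoint are dropped with a warning.
    Returns the overall repeated-measures F and p plus unadjusted paired
    t-tests for every timepoint pair (the exploratory reporting style used
    for latent-variable trajectories).
    """
    from statsmodels.stats.anova import AnovaRM

    df = pd.DataFrame(
        {"score": np.asarray(scores, float), "subject": subject, "time": timepoint}
    )
    counts = df.groupby("subject")["time"].nunique()
    n_times = df["time"].nunique()
    complete = counts[counts == n_times].index
    if len(complete) < len(counts):
        warnings.warn(
            f"dropping {len(counts) - len(complete)} subject(s) with incomplete timepoints"
        )
    df = df[df["subject"].isin(complete)]
    if df["subject"].nunique() < 2 or n_times < 2:
        raise ValueError("repeated-measures analysis needs >= 2 subjects and timepoints")
    time_means = df.groupby("time")["score"].mean()
    if np.ptp(time_means.to_numpy()) < 1e-12 * max(1.0, np.abs(time_means).max()):
        out = {"F": 0.0, "p": 1.0, "n_subjects": int(df["subject"].nunique())}
    else:
        res = AnovaRM(df, depvar="score", subject="subject", within=["time"]).fit()
        out = {
            "F": float(res.anova_table["F Value"].iloc[0]),
            "p": float(res.anova_table["Pr > F"].iloc[0]),
            "n_subjects": int(df["subject"].nunique()),
        }
    if pairwise:
        wide = df.pivot(index="subject", columns="time", values="score")
        pairs = {}
        for a, b in itertools.combinations(sorted(wide.columns), 2):
            t, p = stats.ttest_rel(wide[a], wide[b])
            pairs[f"{a:g} vs {b:g}" if isinstance(a, float) else f"{a} vs {b}"] = float(p)
        out["pairwise_p"] = pairs
    return out
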