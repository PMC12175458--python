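"""From-scratch multivariate models for metabolomics fingerprints.

Implements the standard chemometric toolbox used to compare crude-extract
LC-MS (or binned NMR) profiles:

* Pareto scaling — centre each feature and divide by the square root of its
  standard deviation, a compromise between unit-variance scaling (which
  inflates noise) and no scaling (which lets the most abundant ions dominate).
* PCA with per-component R²X and the 95% Hotelling T² ellipse for outlier
  screening in score space.
* PLS-DA / OPLS-DA fitted by NIPALS with deflation, cross-validated Q²
  (venetian-blind folds), VIP scores and the OPLS S-plot (covariance p vs
  correlation pcorr of each feature with the predictive score).
* A random-forest importance ranking as an orthogonal, non-linear feature
  selector.

Conventions: scores/loadings carry a deterministic sign (the largest-loading
coordinate of each component is positive), class membership is one-hot
encoded, and Q² is reported as 1 − PRESS/SS(Y) with PRESS pooled over folds.

Model quality symbols follow field usage: R²X / R²Y are the fractions of X-
and Y-variance explained; Q² is the cross-validated counterpart of R²Y and
values above ~0.5 indicate useful predictivity, while values near or below
zero indicate a model no better than the Y mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .exceptions import ConfigurationError, StratificationError

__all__ = [
    "ScaledMatrix",
    "LatentModel",
    "SPlot",
    "HotellingResult",
    "pareto_scale",
    "fit_pca",
    "hotelling_ellipse",
    "fit_plsda",
    "fit_oplsda",
    "vip_scores",
    "rank_features_rf",
    "permutation_q2",
]

_CONV_TOL = 1e-10
_MAX_ITER = 500


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------


@dataclass
class ScaledMatrix:
    """A samples × features matrix after centring/scaling.

    ``dropped_features`` lists zero-variance columns excluded from modelling.
    """

    X: np.ndarray
    sample_names: list[str]
    feature_names: list[str]
    column_means: np.ndarray
    column_sds: np.ndarray
    scaling: str
    dropped_features: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.sample_names, columns=self.feature_names)


def pareto_scale(X, scaling: str = "pareto") -> ScaledMatrix:
    """Centre columns and scale them; Pareto scaling divides by sqrt(sd).

    Accepts a samples × features DataFrame (or array). ``scaling`` is one of
    ``"pareto"``, ``"uv"`` (unit variance) or ``"none"`` (centre only).
    Constant columns cannot be scaled and are dropped with a warning.
    """
    if isinstance(X, pd.DataFrame):
        samples = [str(s) for s in X.index]
        features = [str(f) for f in X.columns]
        mat = X.to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        samples = [f"s{i}" for i in range(mat.shape[0])]
        features = [f"f{j}" for j in range(mat.shape[1])]
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ConfigurationError("scaling requires a 2-D matrix with >= 2 samples")
    if scaling not in ("pareto", "uv", "none"):
        raise ConfigurationError(f"unknown scaling {scaling!r}")
    means = mat.mean(axis=0)
    sds = mat.std(axis=0, ddof=1)
    keep = sds > 0
    dropped = [f for f, k in zip(features, keep) if not k]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} zero-variance feature(s) before modelling",
            stacklevel=2,
        )
    mat = mat[:, keep] - means[keep]
    if scaling == "pareto":
        mat = mat / np.sqrt(sds[keep])
    elif scaling == "uv":
        mat = mat / sds[keep]
    return ScaledMatrix(
        X=mat,
        sample_names=samples,
        feature_names=[f for f, k in zip(features, keep) if k],
        column_means=means[keep],
        column_sds=sds[keep],
        scaling=scaling,
        dropped_features=dropped,
    )


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class LatentModel:
    """Scores/loadings of a PCA, PLS-DA or OPLS-DA fit.

    ``T``/``P`` hold scores and loadings column-per-component; supervised
    models add weights ``W``, Y-loadings ``C`` and fit statistics R²Y/Q²;
    OPLS-DA additionally carries the orthogonal block ``T_orth``/``P_orth``/
    ``W_orth`` (its single predictive component lives in ``T``/``P``/``W``).
    """

    kind: str
    T: np.ndarray
    P: np.ndarray
    r2x_per_comp: np.ndarray
    R2X_cum: float
    n_components: int
    feature_names: list[str]
    sample_names: list[str]
    W: np.ndarray | None = None
    C: np.ndarray | None = None
    classes: list | None = None
    labels: list | None = None
    Y: np.ndarray | None = None
    y_means: np.ndarray | None = None
    r2y_per_comp: np.ndarray | None = None
    R2Y_cum: float | None = None
    Q2_cum: float | None = None
    ssy_per_comp: np.ndarray | None = None
    T_orth: np.ndarray | None = None
    P_orth: np.ndarray | None = None
    W_orth: np.ndarray | None = None

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"t{i + 1}" for i in range(self.T.shape[1])]
        frame = pd.DataFrame(self.T, index=self.sample_names, columns=cols)
        if self.T_orth is not None and self.T_orth.shape[1]:
            for i in range(self.T_orth.shape[1]):
                frame[f"t_orth{i + 1}"] = self.T_orth[:, i]
        if self.labels is not None:
            frame.insert(0, "label", self.labels)
        return frame

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"p{i + 1}" for i in range(self.P.shape[1])]
        return pd.DataFrame(self.P, index=self.feature_names, columns=cols)


@dataclass
class SPlot:
    """Per-feature covariance (p) and correlation (pcorr) with t_pred."""

    feature_names: list[str]
    p: np.ndarray
    pcorr: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"p": self.p, "pcorr": self.pcorr}, index=self.feature_names
        )

    def top_decile(self) -> list[str]:
        """Features whose |pcorr| falls in the top 10%."""
        k = max(1, int(np.ceil(len(self.pcorr) / 10)))
        order = np.argsort(-np.abs(self.pcorr), kind="stable")[:k]
        return [self.feature_names[i] for i in order]


@dataclass
class HotellingResult:
    t2: np.ndarray
    crit: float
    radii: tuple[float, ...]
    outliers: np.ndarray  # boolean per sample
    comps: tuple[int, ...]
    alpha: float

    def outlier_samples(self, sample_names) -> list[str]:
        return [s for s, o in zip(sample_names, self.outliers) if o]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def _fix_signs(P: np.ndarray, *blocks: np.ndarray) -> None:
    """In place: make the largest-|loading| coordinate of each comp positive."""
    for a in range(P.shape[1]):
        j = int(np.argmax(np.abs(P[:, a])))
        if P[j, a] < 0:
            P[:, a] *= -1
            for b in blocks:
                b[:, a] *= -1


def fit_pca(Xs: ScaledMatrix, n_comp: int = 2) -> LatentModel:
    """PCA via singular value decomposition of the scaled matrix.

    Components maximize residual variance in order; ``r2x_per_comp[a]`` is
    the fraction of total (scaled) sum of squares carried by component a.
    """
    n, p = Xs.X.shape
    max_comp = min(n - 1, p)
    if not 1 <= n_comp <= max_comp:
        raise ConfigurationError(
            f"n_comp must be in [1, {max_comp}] for a {n}x{p} matrix"
        )
    U, s, Vt = np.linalg.svd(Xs.X, full_matrices=False)
    ss_total = float(np.sum(Xs.X**2))
    T = U[:, :n_comp] * s[:n_comp]
    P = Vt[:n_comp].T.copy()
    _fix_signs(P, T)
    r2x = (s[:n_comp] ** 2) / ss_total if ss_total > 0 else np.zeros(n_comp)
    return LatentModel(
        kind="PCA",
        T=T,
        P=P,
        r2x_per_comp=r2x,
        R2X_cum=float(r2x.sum()),
        n_components=n_comp,
        feature_names=Xs.feature_names,
        sample_names=Xs.sample_names,
    )


def hotelling_ellipse(
    model: LatentModel, alpha: float = 0.05, comps: tuple[int, int] = (1, 2)
) -> HotellingResult:
    """Hotelling T² confidence region in score space (components 1-based).

    The critical value is ``A(n²-1)/(n(n-A))`` times the F(1-alpha; A, n-A)
    quantile; a sample is an outlier when its T² exceeds it. Ellipse
    half-axes are ``sqrt(crit * var(t_a))``.
    """
    if model.T.shape[1] < max(comps):
        raise ConfigurationError("model has fewer components than requested")
    A = len(comps)
    n = model.T.shape[0]
    if n <= A:
        raise ConfigurationError("need more samples than components for T²")
    idx = [c - 1 for c in comps]
    t = model.T[:, idx]
    s2 = t.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(s2 > 0, t**2 / np.where(s2 > 0, s2, 1.0), 0.0)
    t2 = contrib.sum(axis=1)
    crit = A * (n**2 - 1) / (n * (n - A)) * stats.f.ppf(1 - alpha, A, n - A)
    radii = tuple(float(np.sqrt(crit * v)) for v in s2)
    return HotellingResult(
        t2=t2, crit=float(crit), radii=radii, outliers=t2 > crit,
        comps=tuple(comps), alpha=alpha,
    )


# ---------------------------------------------------------------------------
# PLS machinery
# ---------------------------------------------------------------------------


def _one_hot(labels) -> tuple[np.ndarray, np.ndarray, list]:
    labels = [str(l) for l in labels]
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ConfigurationError("supervised models require >= 2 classes")
    Y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        Y[i, classes.index(lab)] = 1.0
    means = Y.mean(axis=0)
    return Y - means, means, classes


def _nipals_component(X: np.ndarray, Y: np.ndarray):
    """One PLS component by NIPALS; returns (w, t, p, c)."""
    u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
    if not np.any(u):
        u = Y[:, 0].copy()
    t_old = None
    for _ in range(_MAX_ITER):
        w = X.T @ u
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ConfigurationError("X carries no covariance with Y")
        w /= norm
        t = X @ w
        tt = float(t @ t)
        if tt == 0:
            raise ConfigurationError("degenerate component (zero score)")
        c = Y.T @ t / tt
        cc = float(c @ c)
        if cc == 0:
            raise ConfigurationError("Y residual exhausted")
        u = Y @ c / cc
        if t_old is not None and np.linalg.norm(t - t_old) < _CONV_TOL * np.linalg.norm(t):
            break
        t_old = t
    p = X.T @ t / tt
    return w, t, p, c


def _pls_fit_core(X: np.ndarray, Y: np.ndarray, n_comp: int):
    """NIPALS PLS2 with deflation of X and Y; returns stacked blocks."""
    Xd, Yd = X.copy(), Y.copy()
    W, T, P, C = [], [], [], []
    for _ in range(n_comp):
        w, t, p, c = _nipals_component(Xd, Yd)
        tt = float(t @ t)
        Xd = Xd - np.outer(t, p)
        Yd = Yd - np.outer(t, c)
        W.append(w)
        T.append(t)
        P.append(p)
        C.append(c)
    return (
        np.column_stack(W),
        np.column_stack(T),
        np.column_stack(P),
        np.column_stack(C),
        Xd,
        Yd,
    )


def _pls_regression_matrix(W, P, C) -> np.ndarray:
    """B such that Yhat = X @ B for a fitted PLS model."""
    A = W.shape[1]
    M = P.T @ W  # A x A, upper triangular-ish
    return W @ np.linalg.solve(M, np.eye(A)) @ C.T


def _venetian_folds(n: int, cv_folds: int, fold_groups=None) -> np.ndarray:
    """Fold assignment: every cv_folds-th observation (or group block)."""
    if fold_groups is None:
        return np.arange(n) % cv_folds
    fold_groups = [str(g) for g in fold_groups]
    if len(fold_groups) != n:
        raise ConfigurationError("fold_groups length must match sample count")
    order: dict[str, int] = {}
    for g in fold_groups:
        if g not in order:
            order[g] = len(order)
    return np.array([order[g] % cv_folds for g in fold_groups])


def _check_stratification(folds: np.ndarray, labels) -> None:
    labels = np.asarray([str(l) for l in labels])
    classes = set(labels)
    for f in np.unique(folds):
        if set(labels[folds != f]) != classes:
            raise StratificationError(
                f"fold {f} would remove an entire class from training; "
                "use fewer folds or different fold_groups"
            )


def _q2_from_cv(X, Y, labels, n_comp, cv_folds, fold_groups, refit_predict) -> float:
    n = X.shape[0]
    if not 2 <= cv_folds <= n:
        raise ConfigurationError("cv_folds must be between 2 and n samples")
    folds = _venetian_folds(n, cv_folds, fold_groups)
    _check_stratification(folds, labels)
    press = 0.0
    for f in np.unique(folds):
        train, test = folds != f, folds == f
        Ytr = Y[train]
        ymean = Ytr.mean(axis=0)
        yhat = refit_predict(X[train], Ytr - ymean, X[test], n_comp) + ymean
        press += float(np.sum((Y[test] - yhat) ** 2))
    ssy = float(np.sum(Y**2))
    return 1.0 - press / ssy


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------


def fit_plsda(
    Xs: ScaledMatrix,
    labels,
    n_comp: int | str = 2,
    cv_folds: int = 7,
    compute_q2: bool = True,
    fold_groups=None,
    max_auto_comp: int = 15,
) -> LatentModel:
    """Multi-class PLS-DA on a scaled matrix.

    Class labels are one-hot encoded and centred; components are extracted
    by NIPALS with deflation of both blocks. ``n_comp="auto"`` keeps adding
    components while cross-validated Q² improves by more than 0.01.

    Q² uses venetian-blind folds over the sample order (``fold_groups`` may
    group replicate injections into shared folds when class structure allows
    it); every training fold must retain every class.
    """
    if len(labels) != Xs.n_samples:
        raise ConfigurationError("labels length must match sample count")
    Y, y_means, classes = _one_hot(labels)

    def _predict(Xtr, Ytr, Xte, A):
        W, _, P, C, _, _ = _pls_fit_core(Xtr, Ytr, A)
        return Xte @ _pls_regression_matrix(W, P, C)

    if n_comp == "auto":
        best = None
        prev_q2 = -np.inf
        limit = min(max_auto_comp, Xs.n_samples - 1, Xs.n_features)
        for a in range(1, limit + 1):
            q2 = _q2_from_cv(Xs.X, Y, labels, a, cv_folds, fold_groups, _predict)
            if q2 - prev_q2 <= 0.01 and best is not None:
                break
            best, prev_q2 = a, q2
        n_comp = best or 1
    n_comp = int(n_comp)
    max_comp = min(Xs.n_samples - 1, Xs.n_features)
    if not 1 <= n_comp <= max_comp:
        raise ConfigurationError(f"n_comp must be in [1, {max_comp}]")

    X0 = Xs.X
    W, T, P, C, Xres, Yres = _pls_fit_core(X0, Y, n_comp)
    ssx0 = float(np.sum(X0**2))
    ssy0 = float(np.sum(Y**2))
    tt = np.sum(T**2, axis=0)
    r2x = tt * np.sum(P**2, axis=0) / ssx0
    ssy_per_comp = tt * np.sum(C**2, axis=0)
    r2y = ssy_per_comp / ssy0
    _fix_signs(P, T, W, C)
    q2 = None
    if compute_q2:
        q2 = _q2_from_cv(X0, Y, labels, n_comp, cv_folds, fold_groups, _predict)
    return LatentModel(
        kind="PLS-DA",
        T=T,
        P=P,
        W=W,
        C=C,
        r2x_per_comp=r2x,
        R2X_cum=float(r2x.sum()),
        r2y_per_comp=r2y,
        R2Y_cum=1.0 - float(np.sum(Yres**2)) / ssy0,
        Q2_cum=q2,
        ssy_per_comp=ssy_per_comp,
        n_components=n_comp,
        feature_names=Xs.feature_names,
        sample_names=Xs.sample_names,
        classes=classes,
        labels=[str(l) for l in labels],
        Y=Y,
        y_means=y_means,
    )


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------


def _opls_fit_core(X: np.ndarray, Y: np.ndarray, n_orth: int):
    """O-PLS: strip n_orth Y-orthogonal components, then one predictive one."""
    w, _, _, _ = _nipals_component(X, Y)
    Xd = X.copy()
    W_o, T_o, P_o = [], [], []
    for _ in range(n_orth):
        t = Xd @ w
        p = Xd.T @ t / float(t @ t)
        w_o = p - float(w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            raise ConfigurationError(
                "no Y-orthogonal variation left; reduce n_orth"
            )
        w_o /= norm
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / float(t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        W_o.append(w_o)
        T_o.append(t_o)
        P_o.append(p_o)
    t = Xd @ w
    tt = float(t @ t)
    p = Xd.T @ t / tt
    c = Y.T @ t / tt
    stack = lambda cols: (np.column_stack(cols) if cols else np.zeros((X.shape[0], 0)))
    W_o_m = np.column_stack(W_o) if W_o else np.zeros((X.shape[1], 0))
    P_o_m = np.column_stack(P_o) if P_o else np.zeros((X.shape[1], 0))
    return w, t, p, c, W_o_m, stack(T_o), P_o_m


def fit_oplsda(
    Xs: ScaledMatrix,
    labels,
    n_orth: int = 1,
    cv_folds: int = 7,
    compute_q2: bool = True,
    fold_groups=None,
) -> tuple[LatentModel, SPlot]:
    """OPLS-DA: orthogonal-variation filtering before one predictive component.

    Variation in X uncorrelated with class membership is peeled off into
    ``n_orth`` orthogonal components; the remaining predictive score carries
    the between-class separation. With ``n_orth=0`` the model coincides with
    a one-component PLS-DA.

    Returns the model together with its S-plot (p = cov(t_pred, x_j),
    pcorr = corr(t_pred, x_j), both against the original scaled data).
    """
    if len(labels) != Xs.n_samples:
        raise ConfigurationError("labels length must match sample count")
    if n_orth < 0:
        raise ConfigurationError("n_orth must be >= 0")
    rank_bound = min(Xs.n_samples - 1, Xs.n_features)
    if n_orth >= rank_bound:
        raise ConfigurationError(
            f"n_orth must be < rank bound {rank_bound} of the data matrix"
        )
    Y, y_means, classes = _one_hot(labels)
    X0 = Xs.X
    w, t, p, c, W_o, T_o, P_o = _opls_fit_core(X0, Y, n_orth)

    ssx0 = float(np.sum(X0**2))
    ssy0 = float(np.sum(Y**2))
    tt = float(t @ t)
    r2x_pred = tt * float(p @ p) / ssx0
    r2x_orth = [
        float(T_o[:, k] @ T_o[:, k]) * float(P_o[:, k] @ P_o[:, k]) / ssx0
        for k in range(T_o.shape[1])
    ]
    ssy_pred = tt * float(c @ c)
    yres = Y - np.outer(t, c)
    r2y_cum = 1.0 - float(np.sum(yres**2)) / ssy0

    def _predict(Xtr, Ytr, Xte, _A):
        w_, t_, p_, c_, Wo_, To_, Po_ = _opls_fit_core(Xtr, Ytr, n_orth)
        Xte = Xte.copy()
        for k in range(To_.shape[1]):
            t_o_te = Xte @ Wo_[:, k]
            Xte = Xte - np.outer(t_o_te, Po_[:, k])
        return np.outer(Xte @ w_, c_)

    q2 = None
    if compute_q2:
        q2 = _q2_from_cv(X0, Y, labels, 1, cv_folds, fold_groups, _predict)

    T = t[:, None]
    P = p[:, None]
    Wm = w[:, None]
    Cm = c[:, None]
    _fix_signs(P, T, Wm, Cm)
    t_signed = T[:, 0]

    # S-plot against the original scaled matrix
    n = X0.shape[0]
    tc = t_signed - t_signed.mean()
    cov = tc @ (X0 - X0.mean(axis=0)) / (n - 1)
    sd_t = tc.std(ddof=1)
    sd_x = X0.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pcorr = np.where(sd_x > 0, cov / (sd_t * sd_x), 0.0)
    splot = SPlot(feature_names=list(Xs.feature_names), p=cov, pcorr=pcorr)

    model = LatentModel(
        kind="OPLS-DA",
        T=T,
        P=P,
        W=Wm,
        C=Cm,
        r2x_per_comp=np.array([r2x_pred] + r2x_orth),
        R2X_cum=float(r2x_pred + sum(r2x_orth)),
        r2y_per_comp=np.array([ssy_pred / ssy0]),
        R2Y_cum=r2y_cum,
        Q2_cum=q2,
        ssy_per_comp=np.array([ssy_pred]),
        n_components=1,
        feature_names=Xs.feature_names,
        sample_names=Xs.sample_names,
        classes=classes,
        labels=[str(l) for l in labels],
        Y=Y,
        y_means=y_means,
        T_orth=T_o,
        P_orth=P_o,
        W_orth=W_o,
    )
    return model, splot


# ---------------------------------------------------------------------------
# VIP, random forest, permutation null
# ---------------------------------------------------------------------------


def vip_scores(model: LatentModel) -> pd.Series:
    """Variable importance in projection for a supervised model.

    VIP_j = sqrt( p * Σ_a SSY_a (w_aj / ||w_a||)² / Σ_a SSY_a ) with p the
    number of modelled features, so that mean(VIP²) = 1; features above 1
    contribute more than average to the class separation.
    """
    if model.W is None or model.ssy_per_comp is None:
        raise ConfigurationError("VIP requires a supervised (PLS/OPLS) model")
    W = model.W
    p = W.shape[0]
    ssy = model.ssy_per_comp
    wnorm2 = np.sum(W**2, axis=0)
    weights = (W**2 / wnorm2) @ ssy
    vip = np.sqrt(p * weights / ssy.sum())
    return pd.Series(vip, index=model.feature_names, name="VIP")


def rank_features_rf(
    Xs: ScaledMatrix, labels, k: int = 15, seed: int = 0, n_estimators: int = 300
) -> pd.DataFrame:
    """Top-k features by random-forest impurity-decrease importance."""
    labels = [str(l) for l in labels]
    if len(set(labels)) < 2:
        raise ConfigurationError("random-forest ranking requires >= 2 classes")
    if k > Xs.n_features:
        warnings.warn("k exceeds feature count; returning all features", stacklevel=2)
        k = Xs.n_features
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=int(seed), n_jobs=1
    )
    forest.fit(Xs.X, labels)
    imp = forest.feature_importances_
    order = np.argsort(-imp, kind="stable")[:k]
    return pd.DataFrame(
        {
            "feature_id": [Xs.feature_names[i] for i in order],
            "importance": imp[order],
            "rank": np.arange(1, len(order) + 1),
        }
    )


def permutation_q2(
    Xs: ScaledMatrix,
    labels,
    n_comp: int = 2,
    n_perm: int = 20,
    seed: int = 0,
    cv_folds: int = 7,
) -> np.ndarray:
    """Q² under random label permutations (the permutation null of PLS-DA).

    A sound model should collapse to Q² ≤ 0 when class labels are shuffled.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray([str(l) for l in labels])
    out = []
    for _ in range(n_perm):
        perm = rng.permutation(len(labels))
        model = fit_plsda(
            Xs, labels[perm], n_comp=n_comp, cv_folds=cv_folds, compute_q2=True
        )
        out.append(model.Q2_cum)
    return np.asarray(out)
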