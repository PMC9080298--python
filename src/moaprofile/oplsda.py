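"""Multi-class OPLS-DA on a NIPALS PLS2 backbone.

The discriminant model regresses a column-centered class-indicator (dummy)
matrix Y (n x K) on the scaled feature matrix X.  Orthogonal variation is
removed first, in the Trygg-Wold sense: for each orthogonal component a PLS
round supplies a loading p whose part lying outside the span of the
Y-predictive weight basis is taken as the orthogonal weight w_o; X is
deflated by the corresponding score/loading pair.  A K-1 component PLS2
model on the filtered matrix yields the predictive scores, Y-loadings and
regression coefficients.

Model quality is summarized by R2X / R2Y (explained variation of X and Y)
and Q2 = 1 - PRESS/SSY from stratified sevenfold cross-validation with the
scaling refit inside each training fold.  Per-feature influence is the VIP
(variable importance in projection) over the predictive components; mean
VIP^2 is exactly 1, so VIP > 1 flags above-average contributors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .preprocess import ScaledMatrix, pareto_scale


class NotFittedError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Dummy response coding
# ---------------------------------------------------------------------------

@dataclass
class DummyY:
    """Class-indicator coding of a label vector (one column per class)."""

    levels: list[str]
    indicator: np.ndarray  # n x K, exactly one 1 per row
    labels: np.ndarray  # original label per row

    @classmethod
    def from_labels(cls, labels, levels: list[str] | None = None) -> "DummyY":
        labels = np.asarray(labels)
        if levels is None:
            levels = sorted(set(labels.tolist()))
        levels = list(levels)
        if len(levels) < 2:
            raise ValueError("need at least 2 class levels")
        pos = {lv: k for k, lv in enumerate(levels)}
        unknown = [l for l in labels.tolist() if l not in pos]
        if unknown:
            raise ValueError(f"labels outside levels: {sorted(set(unknown))}")
        ind = np.zeros((len(labels), len(levels)))
        for i, l in enumerate(labels.tolist()):
            ind[i, pos[l]] = 1.0
        return cls(levels, ind, labels)

    @property
    def n_classes(self) -> int:
        return len(self.levels)

    @property
    def mean(self) -> np.ndarray:
        return self.indicator.mean(axis=0)

    @property
    def centered(self) -> np.ndarray:
        return self.indicator - self.mean


# ---------------------------------------------------------------------------
# NIPALS PLS2
# ---------------------------------------------------------------------------

@dataclass
class PlsFactors:
    W: np.ndarray  # p x A, unit-norm weight columns
    T: np.ndarray  # n x A scores
    P: np.ndarray  # p x A X-loadings
    C: np.ndarray  # K x A Y-loadings
    ssy_explained: np.ndarray  # per-component explained Y sum of squares

    @property
    def B(self) -> np.ndarray:
        """Regression coefficients for undeflated X: B = W (P'W)^-1 C'."""
        return self.W @ np.linalg.solve(self.P.T @ self.W, self.C.T)


def _nipals_component(X: np.ndarray, Y: np.ndarray, tol: float, max_iter: int):
    # Warm start at the NIPALS fixed point (dominant left singular vector of
    # X'Y): the alternating updates converge linearly at rate lambda2/lambda1,
    # which is painfully slow for near-degenerate balanced multi-class
    # designs; the cheap p x K SVD start cuts that to a few polishing steps.
    cov = X.T @ Y
    if not np.any(cov):
        raise ValueError("X and Y are uncorrelated (zero covariance)")
    w0 = np.linalg.svd(cov, full_matrices=False)[0][:, 0]
    t0 = X @ w0
    c0 = Y.T @ t0 / (t0 @ t0)
    if not np.any(c0):
        u = Y[:, np.argmax(Y.var(axis=0))].copy()
    else:
        u = Y @ c0 / (c0 @ c0)
    t_old = np.zeros(X.shape[0])
    for _ in range(max_iter):
        w = X.T @ u
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError("zero-variance X (cannot extract component)")
        w /= norm
        t = X @ w
        c = Y.T @ t / (t @ t)
        u = Y @ c / (c @ c)
        if np.linalg.norm(t - t_old) < tol * max(1.0, np.linalg.norm(t)):
            break
        t_old = t
    else:
        raise RuntimeError(f"NIPALS did not converge in {max_iter} iterations")
    p = X.T @ t / (t @ t)
    return w, t, p, c


def fit_pls2_nipals(
    X: np.ndarray,
    Yc: np.ndarray,
    n_components: int,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> PlsFactors:
    """Extract ``n_components`` PLS2 factors from centered X and Yc by NIPALS.

    Per component: iterate u -> w = X'u/||X'u||, t = Xw, c = Y't/(t't),
    u = Yc c/(c'c) to convergence of t, then deflate X := X - tp' and
    Y := Y - tc'.
    """
    X = np.array(X, dtype=float, copy=True)
    Y = np.array(Yc, dtype=float, copy=True)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    A = n_components
    W = np.empty((p, A))
    T = np.empty((n, A))
    P = np.empty((p, A))
    C = np.empty((Y.shape[1], A))
    ssy = np.empty(A)
    for a in range(A):
        w, t, pl, c = _nipals_component(X, Y, tol, max_iter)
        W[:, a], T[:, a], P[:, a], C[:, a] = w, t, pl, c
        ssy[a] = (t @ t) * (c @ c)
        X -= np.outer(t, pl)
        Y -= np.outer(t, c)
    return PlsFactors(W, T, P, C, ssy)


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------

@dataclass
class OplsModel:
    """Fitted multi-class OPLS-DA model (predictive + orthogonal parts)."""

    levels: list[str]
    n_pred: int
    n_orth: int
    W: np.ndarray  # p x A_p predictive weights (unit norm)
    P: np.ndarray
    T: np.ndarray
    C: np.ndarray  # K x A_p
    W_o: np.ndarray  # p x A_o
    P_o: np.ndarray
    T_o: np.ndarray
    B: np.ndarray  # p x K regression coefficients (filtered X space)
    y_mean: np.ndarray  # K
    ssy_explained: np.ndarray
    r2x: float
    r2y: float
    feature_ids: list[str] | None = None
    x_center: np.ndarray | None = None
    x_scale: np.ndarray | None = None
    train_labels: np.ndarray | None = None
    q2: float | None = None
    vip_: np.ndarray | None = None

    @property
    def n_classes(self) -> int:
        return len(self.levels)

    # -- persistence --------------------------------------------------------
    def to_json(self, path) -> None:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        payload = {
            "levels": self.levels, "n_pred": self.n_pred, "n_orth": self.n_orth,
            "W": arr(self.W), "P": arr(self.P), "T": arr(self.T), "C": arr(self.C),
            "W_o": arr(self.W_o), "P_o": arr(self.P_o), "T_o": arr(self.T_o),
            "B": arr(self.B), "y_mean": arr(self.y_mean),
            "ssy_explained": arr(self.ssy_explained),
            "r2x": self.r2x, "r2y": self.r2y, "q2": self.q2,
            "feature_ids": self.feature_ids,
            "x_center": arr(self.x_center), "x_scale": arr(self.x_scale),
            "train_labels": arr(self.train_labels), "vip": arr(self.vip_),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "OplsModel":
        d = json.loads(Path(path).read_text())

        def arr(key, none_ok=False):
            v = d[key]
            if v is None:
                return None
            return np.asarray(v, dtype=float)

        labels = d["train_labels"]
        return cls(
            levels=d["levels"], n_pred=d["n_pred"], n_orth=d["n_orth"],
            W=arr("W"), P=arr("P"), T=arr("T"), C=arr("C"),
            W_o=arr("W_o"), P_o=arr("P_o"), T_o=arr("T_o"),
            B=arr("B"), y_mean=arr("y_mean"), ssy_explained=arr("ssy_explained"),
            r2x=d["r2x"], r2y=d["r2y"], q2=d["q2"],
            feature_ids=d["feature_ids"],
            x_center=arr("x_center"), x_scale=arr("x_scale"),
            train_labels=None if labels is None else np.asarray(labels),
            vip_=arr("vip"),
        )


def _orthogonal_filter(X: np.ndarray, Yc: np.ndarray, n_orth: int,
                       tol: float, max_iter: int):
    """Extract ``n_orth`` Y-orthogonal components, returning the filtered X."""
    X = np.array(X, dtype=float, copy=True)
    p = X.shape[1]
    W_o = np.empty((p, n_orth))
    P_o = np.empty((p, n_orth))
    T_o = np.empty((X.shape[0], n_orth))
    # Y-predictive weight basis: orthonormalized X'y_k per dummy column
    for a in range(n_orth):
        raw = X.T @ Yc
        basis, r = np.linalg.qr(raw)
        # drop numerically dependent directions (dummy columns sum to zero)
        diag = np.abs(np.diag(r))
        keep = diag > 1e-10 * max(diag.max(), 1e-300)
        basis = basis[:, keep]
        w, t, pl, c = _nipals_component(X, Yc, tol, max_iter)
        w_o = pl - basis @ (basis.T @ pl)
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            raise ValueError("no orthogonal variation left to extract")
        w_o /= norm
        t_o = X @ w_o
        p_o = X.T @ t_o / (t_o @ t_o)
        X -= np.outer(t_o, p_o)
        W_o[:, a], P_o[:, a], T_o[:, a] = w_o, p_o, t_o
    return X, W_o, P_o, T_o


def fit_oplsda(
    X,
    y,
    n_orth: int | str = 0,
    n_pred: int | None = None,
    tol: float = 1e-10,
    max_iter: int = 500,
    feature_ids: list[str] | None = None,
    x_center: np.ndarray | None = None,
    x_scale: np.ndarray | None = None,
    auto_folds: int = 7,
    auto_seed: int = 0,
    auto_cap: int = 5,
    auto_delta: float = 0.01,
) -> OplsModel:
    """Fit a multi-class OPLS-DA model on an already scaled matrix ``X``.

    ``y`` is a label vector or a :class:`DummyY`.  ``n_pred`` defaults to
    K - 1.  ``n_orth="auto"`` adds orthogonal components while the
    cross-validated Q2 improves by more than ``auto_delta`` (capped at
    ``auto_cap``).
    """
    if isinstance(X, pd.DataFrame):
        feature_ids = feature_ids or list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    dummy = y if isinstance(y, DummyY) else DummyY.from_labels(y)
    counts = dummy.indicator.sum(axis=0)
    if (counts < 2).any():
        small = [lv for lv, c in zip(dummy.levels, counts) if c < 2]
        raise ValueError(f"class(es) with fewer than 2 samples: {small}")
    K = dummy.n_classes
    if n_pred is None:
        n_pred = max(K - 1, 1)
    if n_pred < 1:
        raise ValueError("n_pred must be >= 1")

    if n_orth == "auto":
        n_orth = _auto_n_orth(X, dummy, n_pred, folds=auto_folds,
                              seed=auto_seed, cap=auto_cap, delta=auto_delta,
                              tol=tol, max_iter=max_iter)
    n_orth = int(n_orth)

    Yc = dummy.centered
    if n_orth > 0:
        Xf, W_o, P_o, T_o = _orthogonal_filter(X, Yc, n_orth, tol, max_iter)
    else:
        p = X.shape[1]
        Xf = X
        W_o = np.empty((p, 0))
        P_o = np.empty((p, 0))
        T_o = np.empty((X.shape[0], 0))

    pls = fit_pls2_nipals(Xf, Yc, n_pred, tol=tol, max_iter=max_iter)

    ssx_total = float((X ** 2).sum())
    ssx_model = float((pls.T ** 2).sum(axis=0) @ (pls.P ** 2).sum(axis=0))
    y_hat = Xf @ pls.B + dummy.mean
    ssy_total = float((Yc ** 2).sum())
    r2y = 1.0 - float(((dummy.indicator - y_hat) ** 2).sum()) / ssy_total
    r2x = ssx_model / ssx_total if ssx_total > 0 else 0.0

    model = OplsModel(
        levels=dummy.levels, n_pred=n_pred, n_orth=n_orth,
        W=pls.W, P=pls.P, T=pls.T, C=pls.C,
        W_o=W_o, P_o=P_o, T_o=T_o, B=pls.B,
        y_mean=dummy.mean, ssy_explained=pls.ssy_explained,
        r2x=r2x, r2y=r2y, feature_ids=feature_ids,
        x_center=None if x_center is None else np.asarray(x_center, float),
        x_scale=None if x_scale is None else np.asarray(x_scale, float),
        train_labels=dummy.labels,
    )
    model.vip_ = vip(model)
    return model


def fit_oplsda_scaled(scaled: ScaledMatrix, labels, **kwargs) -> OplsModel:
    """Fit on a :class:`ScaledMatrix`, storing its center/scale for projection
    of raw (log-scale) new samples."""
    return fit_oplsda(
        scaled.X, labels,
        feature_ids=scaled.feature_ids,
        x_center=scaled.center.to_numpy(dtype=float),
        x_scale=scaled.scale.to_numpy(dtype=float),
        **kwargs,
    )


def vip(model: OplsModel) -> np.ndarray:
    """Variable importance in projection over the predictive components.

    VIP_j = sqrt( p * sum_a SSY_a w_ja^2 / sum_a SSY_a ); with unit-norm
    weight columns the mean of VIP^2 is exactly 1.
    """
    if model.W is None or model.W.size == 0:
        raise NotFittedError("model has no predictive components")
    p = model.W.shape[0]
    ssy = model.ssy_explained
    contrib = (model.W ** 2) @ ssy
    return np.sqrt(p * contrib / ssy.sum())


def predict(model: OplsModel, X_new, return_frame: bool = True):
    """Project new samples through the frozen model.

    ``X_new`` may be raw log-scale data (if the model stores its training
    center/scale) or an already scaled matrix.  Orthogonal variation is
    stripped with the model's W_o/P_o before the predictive scores and
    Y-hat are computed.

    Returns ``(t_pred, t_orth, y_hat)``; as DataFrames when ``X_new`` is one.
    """
    index = None
    if isinstance(X_new, pd.DataFrame):
        index = X_new.index
        if model.feature_ids is not None:
            missing = [f for f in model.feature_ids if f not in X_new.columns]
            extra = [f for f in X_new.columns if f not in set(model.feature_ids)]
            if missing or extra:
                raise ValueError(
                    f"feature mismatch: {len(missing)} missing "
                    f"(e.g. {missing[:3]}), {len(extra)} extra (e.g. {extra[:3]})"
                )
            X_new = X_new.loc[:, model.feature_ids]
        X_new = X_new.to_numpy(dtype=float)
    X = np.array(X_new, dtype=float, copy=True)
    if model.x_center is not None:
        X = (X - model.x_center) / model.x_scale
    # strip orthogonal components sequentially
    n = X.shape[0]
    T_o = np.empty((n, model.n_orth))
    for a in range(model.n_orth):
        t_o = X @ model.W_o[:, a]
        X -= np.outer(t_o, model.P_o[:, a])
        T_o[:, a] = t_o
    # predictive scores with sequential deflation (training-equivalent)
    T = np.empty((n, model.n_pred))
    Xd = X.copy()
    for a in range(model.n_pred):
        t = Xd @ model.W[:, a]
        Xd -= np.outer(t, model.P[:, a])
        T[:, a] = t
    y_hat = X @ model.B + model.y_mean
    if return_frame and index is not None:
        T = pd.DataFrame(T, index=index,
                         columns=[f"t{a + 1}" for a in range(model.n_pred)])
        T_o = pd.DataFrame(T_o, index=index,
                           columns=[f"to{a + 1}" for a in range(model.n_orth)])
        y_hat = pd.DataFrame(y_hat, index=index, columns=model.levels)
    return T, T_o, y_hat


def assign_classes(model: OplsModel, y_hat) -> np.ndarray:
    """Argmax class per row of Y-hat; exact ties go to the smallest class
    index (documented tie-break)."""
    arr = np.asarray(y_hat)
    idx = np.argmax(arr, axis=1)  # np.argmax takes the first maximum
    return np.asarray(model.levels, dtype=object)[idx]


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvResult:
    q2: float
    press: float
    ssy: float
    press_per_fold: list[float]
    y_pred_cv: np.ndarray  # n x K out-of-fold predictions
    dummy: DummyY
    n_pred: int
    n_orth: int
    folds: int

    @property
    def residuals(self) -> np.ndarray:
        return self.dummy.indicator - self.y_pred_cv


def cross_validate(
    X,
    labels,
    n_pred: int | None = None,
    n_orth: int = 0,
    folds: int = 7,
    stratified: bool = True,
    seed: int = 0,
    scale: bool = True,
    levels: list[str] | None = None,
) -> CvResult:
    """Stratified k-fold cross-validated Q2 for the OPLS-DA pipeline.

    ``X`` is the *unscaled* (log-transformed) samples x features matrix when
    ``scale=True`` (the default): Pareto scaling is refit inside each
    training fold and applied to the held-out part, so the held-out samples
    never leak into the scaling.  Pass ``scale=False`` for an already scaled
    matrix.  Q2 = 1 - PRESS/SSY over the centered dummy matrix.
    """
    if isinstance(X, pd.DataFrame):
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    dummy = DummyY.from_labels(labels, levels=levels)
    n = len(labels)
    _, counts = np.unique(labels, return_counts=True)
    if folds > counts.min():
        raise ValueError(
            f"folds ({folds}) exceeds the smallest class size ({counts.min()}); "
            "a fold would miss a class"
        )
    if stratified:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split = splitter.split(Xv, labels)
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        split = ((np.setdiff1d(perm, fold), fold)
                 for fold in np.array_split(perm, folds))

    y_pred = np.full((n, dummy.n_classes), np.nan)
    press_folds = []
    for train_idx, test_idx in split:
        Xtr, Xte = Xv[train_idx], Xv[test_idx]
        if scale:
            center = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0, ddof=1)
            sc = np.sqrt(sd)
            sc[sc == 0] = 1.0
            Xtr = (Xtr - center) / sc
            Xte = (Xte - center) / sc
        sub = DummyY.from_labels(labels[train_idx], levels=dummy.levels)
        model = fit_oplsda(Xtr, sub, n_orth=n_orth, n_pred=n_pred)
        _, _, y_hat = predict(model, Xte, return_frame=False)
        y_pred[test_idx] = y_hat
        press_folds.append(float(((dummy.indicator[test_idx] - y_hat) ** 2).sum()))
    press = float(np.nansum((dummy.indicator - y_pred) ** 2))
    ssy = float((dummy.centered ** 2).sum())
    q2 = 1.0 - press / ssy
    model0 = n_pred if n_pred is not None else max(dummy.n_classes - 1, 1)
    return CvResult(q2, press, ssy, press_folds, y_pred, dummy,
                    model0, n_orth, folds)


def _auto_n_orth(X: np.ndarray, dummy: DummyY, n_pred: int, folds: int,
                 seed: int, cap: int, delta: float, tol: float,
                 max_iter: int) -> int:
    """Grow the orthogonal part while CV Q2 improves by more than ``delta``.

    Architecture search runs on the already scaled matrix (no per-fold
    rescaling) — it only picks the component count; the reported Q2 comes
    from :func:`cross_validate`.
    """
    counts = dummy.indicator.sum(axis=0)
    max_folds = int(min(folds, counts.min()))
    if max_folds < 2:
        return 0
    best_q2 = -np.inf
    best = 0
    for a_o in range(cap + 1):
        try:
            cv = cross_validate(X, dummy.labels, n_pred=n_pred, n_orth=a_o,
                                folds=max_folds, seed=seed, scale=False,
                                levels=dummy.levels)
        except (ValueError, RuntimeError):
            break
        if cv.q2 > best_q2 + delta:
            best_q2 = cv.q2
            best = a_o
        else:
            break
    return best
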