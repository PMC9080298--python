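"""Projection-based mechanism-of-action classification of new treatment sets.

New compound sample sets are projected onto the frozen class-discriminant
model: per-sample class = argmax of the predicted class-membership vector
(raw Y-hat, no renormalization), set call = majority vote.  A set whose two
largest mean memberships differ by less than ``margin_threshold`` is flagged
as mixed-mechanism — the projection falls in the region between two training
classes, the signature of a compound acting through two mechanisms at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .oplsda import OplsModel, assign_classes, predict as _project

WEAK_MEMBERSHIP = 0.4


@dataclass
class PredictionResult:
    set_label: str
    scores: pd.DataFrame  # predictive scores per sample
    scores_orth: pd.DataFrame
    y_hat: pd.DataFrame  # raw membership vectors, one column per class
    sample_class: pd.Series
    margins: pd.Series  # per-sample gap between top-2 memberships (>= 0)
    majority_class: str  # "unresolved" on an exact tie
    fraction_concordant: float  # fraction of samples voting the majority
    mean_membership: pd.Series
    top2: tuple[str, str]
    mixed_flag: bool
    weak_signal: bool
    r2_pred: float
    q2_ext: float


def classify_set(
    model: OplsModel,
    X_new: pd.DataFrame,
    set_label: str,
    margin_threshold: float = 0.2,
    folds: int = 7,
    refit_with: tuple[pd.DataFrame, "np.ndarray"] | None = None,
) -> PredictionResult:
    """Classify one treatment set by projection onto the frozen model.

    ``X_new`` is the set's log10 matrix (samples x training features); the
    model's stored center/scale bring it into the training space.  R2_pred
    measures how well the projected memberships match the called class;
    Q2_ext accumulates the same residuals over a sevenfold re-blocking of
    the set (the model stays frozen throughout).

    ``refit_with=(X_train_log, train_labels)`` switches R2_pred/Q2_ext to
    refit mode: the model is refit on training plus the new set (under its
    called class) and the metrics come from that refit — the alternative
    reading of per-drug R2/Q2 reporting.  The class call itself always comes
    from the frozen projection.
    """
    if len(X_new) == 0:
        raise ValueError("empty sample set")
    t_pred, t_orth, y_hat = _project(model, X_new)
    sample_cls = pd.Series(assign_classes(model, y_hat), index=X_new.index)

    sorted_members = np.sort(y_hat.to_numpy(), axis=1)
    margins = pd.Series(sorted_members[:, -1] - sorted_members[:, -2],
                        index=X_new.index)

    counts = sample_cls.value_counts()
    if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
        majority = "unresolved"
        concord = float(counts.iloc[0] / len(sample_cls))
    else:
        majority = str(counts.index[0])
        concord = float(counts.iloc[0] / len(sample_cls))

    mean_mem = y_hat.mean(axis=0).sort_values(ascending=False)
    top2 = (str(mean_mem.index[0]),
            str(mean_mem.index[1]) if len(mean_mem) > 1 else "")
    gap = float(mean_mem.iloc[0] - mean_mem.iloc[1]) if len(mean_mem) > 1 else np.inf
    mixed = bool(gap < margin_threshold)
    weak = bool(mean_mem.iloc[0] < WEAK_MEMBERSHIP)
    if weak:
        warnings.warn(
            f"set {set_label!r}: low class memberships everywhere "
            f"(max mean membership {mean_mem.iloc[0]:.2f}) — weak signal",
            stacklevel=2,
        )

    call = majority if majority != "unresolved" else top2[0]
    y_call = np.zeros_like(y_hat.to_numpy())
    call_idx = model.levels.index(call)
    y_call[:, call_idx] = 1.0
    ss_res = float(((y_hat.to_numpy() - y_call) ** 2).sum())
    ss_tot = float(((y_call - model.y_mean) ** 2).sum())
    r2_pred = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    # external Q2: same frozen-model residuals accumulated over 7 blocks
    n = len(X_new)
    block_ids = np.arange(n) % min(folds, n)
    press = 0.0
    for b in np.unique(block_ids):
        sel = block_ids == b
        press += float(((y_hat.to_numpy()[sel] - y_call[sel]) ** 2).sum())
    q2_ext = 1.0 - press / ss_tot if ss_tot > 0 else 0.0

    if refit_with is not None:
        r2_pred, q2_ext = _refit_metrics(model, X_new, call, refit_with, folds)

    return PredictionResult(
        set_label=set_label, scores=t_pred, scores_orth=t_orth, y_hat=y_hat,
        sample_class=sample_cls, margins=margins,
        majority_class=majority, fraction_concordant=concord,
        mean_membership=mean_mem, top2=top2, mixed_flag=mixed,
        weak_signal=weak, r2_pred=r2_pred, q2_ext=q2_ext,
    )


def _refit_metrics(model, X_new, call, refit_with, folds):
    """R2Y/Q2 of a model refit on training + the new set under its call."""
    from .oplsda import cross_validate, fit_oplsda
    from .preprocess import pareto_scale

    X_train, train_labels = refit_with
    X_all = pd.concat([X_train.loc[:, list(X_new.columns)], X_new])
    labels_all = np.concatenate([np.asarray(train_labels),
                                 np.full(len(X_new), call, dtype=object)])
    scaled = pareto_scale(X_all)
    refit = fit_oplsda(scaled.X, labels_all, n_orth=model.n_orth,
                       n_pred=model.n_pred)
    cv = cross_validate(X_all, labels_all, n_orth=model.n_orth,
                        n_pred=model.n_pred, folds=folds, seed=0)
    return refit.r2y, cv.q2


# ---------------------------------------------------------------------------
# Score-space region report
# ---------------------------------------------------------------------------

def _hull_contains(hull_points: np.ndarray, queries: np.ndarray) -> np.ndarray:
    from scipy.spatial import Delaunay

    tri = Delaunay(hull_points)
    return tri.find_simplex(queries) >= 0


@dataclass
class RegionReport:
    class_hulls: dict  # class -> hull vertex coordinates (h x 2)
    inside_fractions: pd.DataFrame  # sets x classes
    plot_path: str | None = None


def region_report(
    model: OplsModel,
    results: list[PredictionResult],
    plot_path=None,
) -> RegionReport:
    """Convex hulls of the training classes in the first two predictive score
    dimensions, and the fraction of each new set's points falling inside
    each hull (a mixed-mechanism set shows nonzero fractions in two hulls).
    """
    if not results:
        raise ValueError("no prediction results supplied")
    if model.train_labels is None:
        raise ValueError("model carries no training labels")
    if model.n_pred < 2:
        raise ValueError("need at least 2 predictive score dimensions")
    from scipy.spatial import ConvexHull

    T = np.asarray(model.T)[:, :2]
    labels = np.asarray(model.train_labels)
    hulls = {}
    for cls in model.levels:
        pts = T[labels == cls]
        if len(pts) < 3:
            raise ValueError(f"class {cls!r} has < 3 training samples (degenerate hull)")
        hull = ConvexHull(pts)
        hulls[cls] = pts[hull.vertices]
    frac = {}
    for res in results:
        q = res.scores.to_numpy()[:, :2]
        frac[res.set_label] = {
            cls: float(np.mean(_hull_contains(np.asarray(pts), q)))
            for cls, pts in hulls.items()
        }
    table = pd.DataFrame(frac).T.loc[:, list(model.levels)]
    out = RegionReport(class_hulls=hulls, inside_fractions=table)
    if plot_path is not None:
        _plot_regions(model, results, hulls, plot_path)
        out.plot_path = str(plot_path)
    return out


def _plot_regions(model, results, hulls, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_panels = len(results)
    ncol = min(3, n_panels)
    nrow = int(np.ceil(n_panels / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3.2 * nrow),
                             squeeze=False)
    colors = plt.get_cmap("tab10")
    T = np.asarray(model.T)[:, :2]
    labels = np.asarray(model.train_labels)
    for ax, res in zip(axes.ravel(), results):
        for k, cls in enumerate(model.levels):
            pts = T[labels == cls]
            ax.scatter(pts[:, 0], pts[:, 1], s=6, alpha=0.35,
                       color=colors(k), label=cls)
            hull_pts = np.vstack([hulls[cls], hulls[cls][:1]])
            ax.plot(hull_pts[:, 0], hull_pts[:, 1], color=colors(k), lw=0.8)
        q = res.scores.to_numpy()[:, :2]
        ax.scatter(q[:, 0], q[:, 1], s=18, color="black", marker="x",
                   label=res.set_label)
        ax.set_title(res.set_label, fontsize=9)
        ax.set_xlabel("t1")
        ax.set_ylabel("t2")
    for ax in axes.ravel()[n_panels:]:
        ax.axis("off")
    axes[0, 0].legend(frameon=False, fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
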