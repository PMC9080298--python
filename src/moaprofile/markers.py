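"""Differential-metabolite (marker) selection and heat-map clustering.

The selection cascade mirrors the study workflow: features with VIP > 1 in
the fitted class-discriminant model are candidates; each candidate is tested
treated-vs-control within the drug class by one-way ANOVA with a Bonferroni
correction over the candidate family; survivors are ranked by the oriented
ROC AUC and retained when the adjusted p is below alpha and the AUC exceeds
0.50.  Fold change is computed on the cell-count-normalized, pre-log
intensity scale: FC = mean(treated)/mean(control), trend "up" iff FC > 1
(strict; FC exactly 1 counts as "down" by the boundary policy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import dendrogram, fcluster, linkage

from .io import PeakTable
from .oplsda import NotFittedError, OplsModel
from .preprocess import ScaledMatrix

P_FLOOR = 1e-300


@dataclass
class MarkerCandidate:
    feature_id: str
    moa_class: str
    vip: float
    p_raw: float
    p_adj: float
    auc: float  # oriented (>= 0.5 reports discriminative power)
    auc_raw: float  # treated-as-positive AUC
    fc: float
    trend: str
    passes: bool


def anova_bonferroni(groups: list[np.ndarray], m: int) -> tuple[float, float, float]:
    """Classic one-way ANOVA with Bonferroni-adjusted p over ``m`` tests.

    F = (SSB/(k-1)) / (SSW/(N-k)).  Degenerate inputs: zero within-group
    variance with equal means gives F = 0, p = 1; with unequal means the
    difference is infinitely significant and p is floored at 1e-300.
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if m < 1:
        raise ValueError("number of tests m must be >= 1")
    groups = [np.asarray(g, dtype=float) for g in groups]
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    k = len(groups)
    n = len(all_vals)
    if ssw == 0:
        if ssb == 0:
            return 0.0, 1.0, 1.0
        return float("inf"), P_FLOOR, min(1.0, P_FLOOR * m)
    F = (ssb / (k - 1)) / (ssw / (n - k))
    p_raw = float(stats.f.sf(F, k - 1, n - k))
    p_raw = max(p_raw, P_FLOOR)
    p_adj = min(1.0, p_raw * m)
    return float(F), p_raw, p_adj


def fold_change(treated: np.ndarray, control: np.ndarray) -> tuple[float, str]:
    """FC = mean(treated)/mean(control) on the intensity scale; trend "up"
    iff FC > 1 (strict)."""
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.size == 0 or control.size == 0:
        raise ValueError("both groups must be non-empty")
    cmean = control.mean()
    if cmean == 0:
        raise ZeroDivisionError("control mean is 0: fold change undefined")
    fc = float(treated.mean() / cmean)
    return fc, ("up" if fc > 1 else "down")


def roc_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC of ``values`` for the positive group (labels truthy).

    AUC = U / (n1 * n0) with midranks, so ties count 0.5.  Equals the
    exhaustive pair-counting probability P(value_pos > value_neg) + 0.5
    P(tie).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both label groups must be non-empty")
    ranks = stats.rankdata(values)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def oriented_auc(auc_raw: float) -> float:
    return max(auc_raw, 1.0 - auc_raw)


def select_markers(
    model: OplsModel,
    scaled: ScaledMatrix,
    table_pre_log: dict[str, PeakTable] | PeakTable,
    meta: pd.DataFrame,
    moa_class: str,
    vip_threshold: float = 1.0,
    alpha: float = 0.05,
    min_auc: float = 0.50,
    grouping: str = "treated_control",
) -> list[MarkerCandidate]:
    """Run the VIP -> ANOVA/Bonferroni -> AUC cascade for one drug class.

    ``scaled`` holds the log/Pareto matrix over *all* biological samples
    (treated and control); ``table_pre_log`` the cell-count-normalized
    intensity table(s) for fold changes (one table or a dict per block).
    Returns every VIP-passing candidate with its statistics and a ``passes``
    flag, sorted by oriented AUC descending; downstream selection keeps the
    passing ones.

    ``grouping`` picks the ANOVA family: ``"treated_control"`` (default,
    matching the per-class marker tables) tests treated vs control within
    the class; ``"classes"`` tests the treated samples across all classes.
    AUC and fold change always contrast treated vs control of the class.
    """
    if grouping not in ("treated_control", "classes"):
        raise ValueError(f"unknown grouping {grouping!r}")
    if model.vip_ is None:
        raise NotFittedError("model carries no VIP scores")
    if moa_class not in set(meta["moa_class"].dropna()):
        raise ValueError(f"class {moa_class!r} not present in metadata")
    vip = pd.Series(model.vip_, index=model.feature_ids)
    candidates = vip.index[vip > vip_threshold]
    if len(candidates) == 0:
        return []
    m = len(candidates)

    sub = meta[(meta["moa_class"] == moa_class)
               & meta["condition"].isin(["treated", "control"])]
    treated_ids = sub.loc[sub["condition"] == "treated", "sample_id"].tolist()
    control_ids = sub.loc[sub["condition"] == "control", "sample_id"].tolist()
    treated_ids = [s for s in treated_ids if s in scaled.X.index]
    control_ids = [s for s in control_ids if s in scaled.X.index]
    if len(treated_ids) < 2 or len(control_ids) < 2:
        raise ValueError("need >= 2 treated and >= 2 control samples")

    if isinstance(table_pre_log, PeakTable):
        intens = table_pre_log.intensities
    else:
        intens = pd.concat([t.intensities for t in table_pre_log.values()])

    if grouping == "classes":
        treated_all = meta[meta["condition"] == "treated"]
        class_groups = [
            [s for s in treated_all.loc[treated_all["moa_class"] == cls,
                                        "sample_id"] if s in scaled.X.index]
            for cls in sorted(set(treated_all["moa_class"].dropna()))
        ]

    out: list[MarkerCandidate] = []
    for fid in candidates:
        tvals = scaled.X.loc[treated_ids, fid].to_numpy()
        cvals = scaled.X.loc[control_ids, fid].to_numpy()
        if grouping == "classes":
            groups = [scaled.X.loc[ids, fid].to_numpy() for ids in class_groups]
        else:
            groups = [tvals, cvals]
        _, p_raw, p_adj = anova_bonferroni(groups, m=m)
        auc_raw = roc_auc(
            np.concatenate([tvals, cvals]),
            np.concatenate([np.ones(len(tvals)), np.zeros(len(cvals))]),
        )
        try:
            fc, trend = fold_change(
                intens.loc[fid, treated_ids].to_numpy(),
                intens.loc[fid, control_ids].to_numpy(),
            )
        except ZeroDivisionError:
            warnings.warn(f"dropping {fid}: control mean is 0", stacklevel=2)
            continue
        auc_o = oriented_auc(auc_raw)
        out.append(
            MarkerCandidate(
                feature_id=fid, moa_class=moa_class, vip=float(vip[fid]),
                p_raw=p_raw, p_adj=p_adj, auc=auc_o, auc_raw=auc_raw,
                fc=fc, trend=trend,
                passes=bool(p_adj < alpha and auc_o > min_auc),
            )
        )
    out.sort(key=lambda c: (-c.auc, c.feature_id))
    return out


def candidates_frame(cands: list[MarkerCandidate]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in cands])


@dataclass
class HeatmapClustering:
    row_order: list
    col_order: list
    row_clusters: pd.Series  # cluster label per row, in input order


def cluster_heatmap(fc_matrix: pd.DataFrame, n_clusters: int = 4,
                    plot_path=None) -> HeatmapClustering:
    """Agglomerative clustering (Euclidean, average linkage) of the marker x
    class fold-change matrix, cut into ``n_clusters`` row clusters.

    Ordering is the deterministic dendrogram leaf order.  A constant matrix
    carries no structure: everything merges at height 0 and a single cluster
    is returned with a warning.
    """
    if len(fc_matrix) < 2:
        raise ValueError("need at least 2 rows to cluster")
    vals = fc_matrix.to_numpy(dtype=float)
    if np.ptp(vals) == 0:
        warnings.warn("constant fold-change matrix: single cluster", stacklevel=2)
        return HeatmapClustering(
            row_order=list(fc_matrix.index),
            col_order=list(fc_matrix.columns),
            row_clusters=pd.Series(1, index=fc_matrix.index),
        )
    Z = linkage(vals, method="average", metric="euclidean")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    leaves = dendrogram(Z, no_plot=True)["leaves"]
    row_order = [fc_matrix.index[i] for i in leaves]
    if fc_matrix.shape[1] >= 3 and np.ptp(vals.T) > 0:
        Zc = linkage(vals.T, method="average", metric="euclidean")
        col_leaves = dendrogram(Zc, no_plot=True)["leaves"]
        col_order = [fc_matrix.columns[i] for i in col_leaves]
    else:
        col_order = list(fc_matrix.columns)
    result = HeatmapClustering(
        row_order=row_order, col_order=col_order,
        row_clusters=pd.Series(labels, index=fc_matrix.index),
    )
    if plot_path is not None:
        _plot_heatmap(fc_matrix, result, plot_path)
    return result


def _plot_heatmap(fc_matrix: pd.DataFrame, clust: HeatmapClustering, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = fc_matrix.loc[clust.row_order, clust.col_order]
    fig, ax = plt.subplots(figsize=(4, max(3, 0.18 * len(ordered))))
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(ordered.shape[1]), ordered.columns, rotation=45,
                  ha="right", fontsize=7)
    ax.set_yticks(range(ordered.shape[0]), ordered.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="fold change")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
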