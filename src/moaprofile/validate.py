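"""Model validation: label-permutation test and CV-ANOVA.

The permutation test refits the whole pipeline on class labels shuffled at
random many times.  For each permutation i the similarity of the permuted
dummy matrix to the original one is summarized as r_i (mean absolute
column-wise correlation), and (r_i, R2_i) / (r_i, Q2_i) points — including
the unpermuted model at r = 1 — are fit with least-squares lines whose
intercepts at r = 0 are the reported permutation intercepts.  A valid model
shows all permuted metrics below the originals and a negative Q2 intercept.

CV-ANOVA compares the cross-validated predictive residual sum of squares
(PRESS) against the total response variation with an F test, giving a
p-value for model significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .oplsda import CvResult, DummyY, cross_validate, fit_oplsda


@dataclass
class PermutationResult:
    n_perm: int
    r: np.ndarray  # per permutation (plus the original at r = 1, last)
    r2: np.ndarray
    q2: np.ndarray
    r2_intercept: float
    q2_intercept: float
    r2_original: float
    q2_original: float
    exceedance_r2: float  # fraction of permuted R2 >= original
    exceedance_q2: float

    def summary(self) -> str:
        return (
            f"permutation test ({self.n_perm} permutations): intercepts "
            f"R2 = {self.r2_intercept:.4f} and Q2 = {self.q2_intercept:.4f}; "
            f"original R2 = {self.r2_original:.3f}, Q2 = {self.q2_original:.3f}"
        )


@dataclass
class CvAnovaResult:
    F: float
    df_reg: int
    df_res: int
    p_value: float


def _mean_abs_corr(perm_dummy: np.ndarray, orig_dummy: np.ndarray) -> float:
    """Mean |Pearson r| between paired dummy columns (permuted vs original)."""
    rs = []
    for k in range(orig_dummy.shape[1]):
        a = perm_dummy[:, k]
        b = orig_dummy[:, k]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            rs.append(1.0 if sa == sb else 0.0)
        else:
            rs.append(abs(np.corrcoef(a, b)[0, 1]))
    return float(np.mean(rs))


def permutation_test(
    X,
    labels,
    n_perm: int = 999,
    folds: int = 7,
    seed: int = 0,
    n_pred: int | None = None,
    n_orth: int = 0,
    scale: bool = True,
) -> PermutationResult:
    """Label-permutation validation of the OPLS-DA pipeline.

    Rows of Y are shuffled jointly (class labels permuted; never within a
    dummy column), the model is refit with the fixed architecture
    ``(n_pred, n_orth)``, and R2Y / cross-validated Q2 are recorded.
    Deterministic under ``seed``.
    """
    if n_perm == 0:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 20:
        warnings.warn("fewer than 20 permutations: intercepts will be unstable",
                      stacklevel=2)
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    labels = np.asarray(labels)
    dummy = DummyY.from_labels(labels)
    rng = np.random.default_rng(seed)

    def _metrics(lbl, cv_seed):
        cv = cross_validate(X, lbl, n_pred=n_pred, n_orth=n_orth, folds=folds,
                            seed=cv_seed, scale=scale, levels=dummy.levels)
        if scale:
            center = X.mean(axis=0)
            sd = X.std(axis=0, ddof=1)
            sc = np.sqrt(sd)
            sc[sc == 0] = 1.0
            Xs = (X - center) / sc
        else:
            Xs = X
        model = fit_oplsda(Xs, DummyY.from_labels(lbl, levels=dummy.levels),
                           n_orth=n_orth, n_pred=n_pred)
        return model.r2y, cv.q2

    r_vals, r2_vals, q2_vals = [], [], []
    for _ in range(n_perm):
        perm = rng.permutation(len(labels))
        lbl = labels[perm]
        r2, q2 = _metrics(lbl, cv_seed=int(rng.integers(2 ** 31)))
        r_vals.append(_mean_abs_corr(dummy.indicator[perm], dummy.indicator))
        r2_vals.append(r2)
        q2_vals.append(q2)
    r2_orig, q2_orig = _metrics(labels, cv_seed=seed)
    r = np.array(r_vals + [1.0])
    r2 = np.array(r2_vals + [r2_orig])
    q2 = np.array(q2_vals + [q2_orig])

    def intercept(metric):
        # degenerate spread: fall back to the mean of the permuted metrics
        if np.ptp(r) < 1e-12:
            return float(metric[:-1].mean())
        slope, icpt = np.polyfit(r, metric, 1)
        return float(icpt)

    return PermutationResult(
        n_perm=n_perm, r=r, r2=r2, q2=q2,
        r2_intercept=intercept(r2), q2_intercept=intercept(q2),
        r2_original=r2_orig, q2_original=q2_orig,
        exceedance_r2=float(np.mean(np.asarray(r2_vals) >= r2_orig)),
        exceedance_q2=float(np.mean(np.asarray(q2_vals) >= q2_orig)),
    )


def cv_anova(cv: CvResult) -> CvAnovaResult:
    """F test of cross-validated residuals against total response variation.

    SS_total = SSY with df = N*K - K (one mean per dummy column);
    SS_reg = SSY - PRESS with df = total fitted components;
    SS_res = PRESS with df = N*K - K - A_total.  PRESS >= SSY (a model worse
    than the mean) floors F at 0 with p = 1.
    """
    n, k = cv.y_pred_cv.shape
    a_total = cv.n_pred + cv.n_orth
    df_total = n * k - k
    df_reg = a_total
    df_res = df_total - a_total
    if df_res <= 0:
        raise ValueError("not enough residual degrees of freedom")
    ss_reg = cv.ssy - cv.press
    if ss_reg <= 0:
        return CvAnovaResult(0.0, df_reg, df_res, 1.0)
    F = (ss_reg / df_reg) / (cv.press / df_res)
    p = float(stats.f.sf(F, df_reg, df_res))
    return CvAnovaResult(float(F), df_reg, df_res, max(p, 1e-300))


def permutation_plot(result: PermutationResult, path) -> None:
    """Scatter of (r, R2) and (r, Q2) with the intercept regression lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.r[:-1], result.r2[:-1], s=12, c="tab:green", label="R2 (perm)")
    ax.scatter(result.r[:-1], result.q2[:-1], s=12, c="tab:blue", label="Q2 (perm)")
    ax.scatter([1], [result.r2_original], c="tab:green", marker="s")
    ax.scatter([1], [result.q2_original], c="tab:blue", marker="s")
    xs = np.array([0.0, 1.0])
    for metric, icpt, color in (
        (result.r2, result.r2_intercept, "tab:green"),
        (result.q2, result.q2_intercept, "tab:blue"),
    ):
        slope, b = np.polyfit(result.r, metric, 1)
        ax.plot(xs, slope * xs + b, color=color, lw=1)
    ax.set_xlabel("correlation with original Y")
    ax.set_ylabel("R2 / Q2")
    ax.legend(frameon=False, fontsize=8)
    ax.set_title(
        f"intercepts: R2 = {result.r2_intercept:.4f}, Q2 = {result.q2_intercept:.4f}",
        fontsize=9,
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
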