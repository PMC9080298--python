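"""Unsupervised QC: PCA of the scaled matrix and pooled-QC drift flagging."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ScaledMatrix


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x A
    loadings: pd.DataFrame  # features x A
    explained_variance_fraction: np.ndarray
    provenance: dict


def fit_pca(scaled: ScaledMatrix | pd.DataFrame, n_components: int) -> PcaResult:
    """PCA by SVD of the (already centered/scaled) matrix.

    Explained fraction of component a is sigma_a^2 / sum sigma^2.  The SVD
    sign ambiguity is fixed by making the largest-magnitude loading of each
    component positive.
    """
    if isinstance(scaled, ScaledMatrix):
        X = scaled.X
        prov = dict(scaled.provenance)
    else:
        X = scaled
        prov = {}
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components must be in [1, {min(n - 1, p)}], got {n_components}"
        )
    U, s, Vt = np.linalg.svd(X.to_numpy(dtype=float), full_matrices=False)
    explained = (s ** 2) / (s ** 2).sum()
    U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    # sign convention: dominant loading positive
    for a in range(n_components):
        j = np.argmax(np.abs(Vt[a]))
        if Vt[a, j] < 0:
            Vt[a] *= -1.0
            U[:, a] *= -1.0
    cols = [f"PC{a + 1}" for a in range(n_components)]
    scores = pd.DataFrame(U * s, index=X.index, columns=cols)
    loadings = pd.DataFrame(Vt.T, index=X.columns, columns=cols)
    return PcaResult(scores, loadings, explained[:n_components], prov)


def qc_drift_check(pca: PcaResult, meta: pd.DataFrame, k: float = 2.0) -> pd.DataFrame:
    """Flag pooled-QC samples drifting in the first two PCA components.

    A QC sample passes iff each of its PC1/PC2 scores lies within ``k``
    standard deviations of that component's score distribution over all
    samples (the instrument-stability rule: QCs should shift only a small
    extent within 2 SD).  Returns one row per QC with per-component flags,
    an overall ``pass`` column, and a ``verdict`` attribute in ``.attrs``.
    """
    qc_ids = meta.loc[meta["condition"] == "qc", "sample_id"]
    qc_ids = [s for s in qc_ids if s in pca.scores.index]
    if len(qc_ids) < 2:
        raise ValueError("need at least 2 QC samples in the score space")
    use = pca.scores.columns[: min(2, pca.scores.shape[1])]
    sd = pca.scores[use].std(axis=0, ddof=1)
    rows = {}
    for sid in qc_ids:
        within = (pca.scores.loc[sid, use].abs() <= k * sd)
        rows[sid] = {f"{c}_within": bool(within[c]) for c in use}
        rows[sid]["pass"] = bool(within.all())
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    out.attrs["verdict"] = bool(out["pass"].all())
    out.attrs["k"] = k
    return out
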