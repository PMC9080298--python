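"""From raw peak lists to the fused, filtered, normalized, scaled model matrix.

Fixed stage order (asserted by :func:`run_preprocess`):

    align -> filter (missing > 20% removed) -> cell-count normalize
          -> log10 (half-minimum zero fill) -> Pareto scale -> fuse blocks

Log10 transform plus Pareto scaling (centering and dividing by the square
root of the standard deviation) is the standard metabolomics compromise
between no scaling and unit-variance scaling: it shrinks the dominance of
high-abundance features without blowing up pure-noise ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PeakTable, feature_id


@dataclass
class ScaledMatrix:
    """Samples x features matrix with the centering/scaling state attached.

    ``center``/``scale`` are per-feature and allow exact projection of new
    samples into the training space (``(x - center) / scale``) and exact
    back-transformation.
    """

    X: pd.DataFrame  # samples x features
    center: pd.Series
    scale: pd.Series
    blocks: pd.Series  # per-feature block label
    provenance: dict = field(default_factory=dict)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.X.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.X.index)

    def transform(self, X_new: pd.DataFrame) -> pd.DataFrame:
        """Project new (log-scale) samples with the stored center/scale."""
        missing = [c for c in self.X.columns if c not in X_new.columns]
        extra = [c for c in X_new.columns if c not in self.X.columns]
        if missing or extra:
            raise ValueError(
                f"feature mismatch: missing {missing[:5]}..., extra {extra[:5]}..."
                if len(missing) > 5 or len(extra) > 5
                else f"feature mismatch: missing {missing}, extra {extra}"
            )
        aligned = X_new.loc[:, self.X.columns]
        return (aligned - self.center) / self.scale

    def back_transform(self, X_scaled: pd.DataFrame | None = None) -> pd.DataFrame:
        X_scaled = self.X if X_scaled is None else X_scaled
        return X_scaled * self.scale + self.center


# ---------------------------------------------------------------------------
# Peak-list alignment (MarkerLynx-style binning)
# ---------------------------------------------------------------------------

def align_features(
    peak_lists: dict[str, pd.DataFrame],
    mass_window: float = 0.05,
    rt_tolerance: float = 0.5,
    min_intensity_frac: float = 0.05,
    block: str = "RP",
) -> PeakTable:
    """Greedily bin per-sample (rt, mz, intensity) peak lists into features.

    Peaks below ``min_intensity_frac`` of their own sample's base-peak
    intensity are discarded.  Remaining peaks are processed in order of
    descending intensity; a peak joins the first existing feature within
    ``mass_window`` Da and ``rt_tolerance`` min that has no peak from its
    sample yet, otherwise it seeds a new feature (whose RT/mz are the seeding
    peak's).  Unmatched samples get intensity 0 for that feature.
    """
    if not peak_lists:
        raise ValueError("no peak lists supplied")
    rows = []
    for sid, df in peak_lists.items():
        if len(df) == 0:
            continue
        base = df["intensity"].max()
        keep = df[df["intensity"] >= min_intensity_frac * base]
        for rt, mz, inten in keep[["rt", "mz", "intensity"]].itertuples(index=False):
            rows.append((sid, float(rt), float(mz), float(inten)))
    if not rows:
        raise ValueError("all peaks fell below the intensity floor")
    pooled = pd.DataFrame(rows, columns=["sample", "rt", "mz", "intensity"])
    pooled = pooled.sort_values("intensity", ascending=False, kind="stable",
                                ignore_index=True)

    feat_rt: list[float] = []
    feat_mz: list[float] = []
    members: list[dict[str, float]] = []
    rt_arr = np.empty(0)
    mz_arr = np.empty(0)
    for sid, rt, mz, inten in pooled.itertuples(index=False):
        assigned = False
        if len(feat_rt):
            close = np.flatnonzero(
                (np.abs(mz_arr - mz) <= mass_window)
                & (np.abs(rt_arr - rt) <= rt_tolerance)
            )
            for j in close:
                if sid not in members[j]:
                    members[j][sid] = inten
                    assigned = True
                    break
        if not assigned:
            feat_rt.append(rt)
            feat_mz.append(mz)
            members.append({sid: inten})
            rt_arr = np.asarray(feat_rt)
            mz_arr = np.asarray(feat_mz)

    sample_ids = list(peak_lists)
    fids = [feature_id(block, r, m) for r, m in zip(feat_rt, feat_mz)]
    feats = pd.DataFrame(
        {"block": block, "rt": feat_rt, "mz": feat_mz},
        index=pd.Index(fids, name="feature_id"),
    )
    intens = pd.DataFrame(0.0, index=feats.index, columns=sample_ids)
    for j, mem in enumerate(members):
        for sid, val in mem.items():
            intens.iloc[j, intens.columns.get_loc(sid)] = val
    return PeakTable(feats, intens)


# ---------------------------------------------------------------------------
# Filtering / normalization / transform / scaling
# ---------------------------------------------------------------------------

def filter_missing(table: PeakTable, max_missing: float = 0.20) -> PeakTable:
    """Drop features whose zero (missing) fraction strictly exceeds
    ``max_missing``; a feature at exactly the threshold is kept."""
    if table.n_features == 0:
        raise ValueError("empty peak table")
    zero_frac = (table.intensities == 0).mean(axis=1)
    keep = zero_frac <= max_missing
    return table.subset_features(table.features.index[keep])


def normalize_cell_count(table: PeakTable, meta: pd.DataFrame) -> PeakTable:
    """Rescale each biological sample to the reference (median) cell count.

    intensity := intensity * reference_count / cell_count; QC samples pass
    through unchanged.
    """
    meta_idx = meta.set_index("sample_id")
    missing = [s for s in table.sample_ids if s not in meta_idx.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    sub = meta_idx.loc[table.sample_ids]
    is_qc = (sub["condition"] == "qc").to_numpy()
    counts = sub["cell_count"].to_numpy(dtype=float)
    if np.isnan(counts[~is_qc]).any():
        bad = list(np.asarray(table.sample_ids)[~is_qc & np.isnan(counts)])
        raise ValueError(f"missing cell count for biological sample(s): {bad}")
    reference = float(np.median(counts[~is_qc]))
    factor = np.ones(len(counts))
    factor[~is_qc] = reference / counts[~is_qc]
    out = table.intensities * factor[None, :]
    return PeakTable(table.features.copy(), out)


def log10_transform(table: PeakTable, zero_policy: str = "half_min",
                    on_all_zero: str = "raise") -> pd.DataFrame:
    """Log10 the intensity matrix, returning a samples x features frame.

    Remaining zeros are filled with half the smallest positive intensity of
    that feature (``half_min`` policy).  A feature that is zero in every
    sample cannot be filled and raises — such features must be removed by
    :func:`filter_missing` first.  For small projection sets, where the
    missingness filter was fit on the training data, pass
    ``on_all_zero="global_half_min"`` to fill such features with half the
    table-wide smallest positive intensity instead.
    """
    if zero_policy != "half_min":
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    vals = table.intensities.to_numpy(dtype=float).copy()
    all_zero = (vals == 0).all(axis=1)
    if all_zero.any():
        if on_all_zero == "global_half_min" and (vals > 0).any():
            vals[all_zero] = vals[vals > 0].min() / 2.0
        else:
            bad = table.features.index[all_zero].tolist()
            raise ValueError(f"all-zero feature(s) cannot be log-transformed: {bad}")
    for i in range(vals.shape[0]):
        row = vals[i]
        zeros = row == 0
        if zeros.any():
            row[zeros] = row[~zeros].min() / 2.0
    out = pd.DataFrame(np.log10(vals), index=table.features.index,
                       columns=table.intensities.columns)
    return out.T  # samples x features


def pareto_scale(matrix: pd.DataFrame, blocks: pd.Series | None = None,
                 provenance: dict | None = None) -> ScaledMatrix:
    """Center each feature and divide by the square root of its sample
    standard deviation (n-1 denominator).

    Zero-variance features are centered and left unscaled (their scaled
    column is all zeros).  After scaling, var(x') = sd(x).
    """
    if len(matrix) < 2:
        raise ValueError("Pareto scaling needs at least 2 samples")
    center = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    scale = np.sqrt(sd)
    scale[scale == 0] = 1.0
    X = (matrix - center) / scale
    if blocks is None:
        blocks = pd.Series(
            [c.split("_", 1)[0] if isinstance(c, str) else "RP" for c in matrix.columns],
            index=matrix.columns,
        )
    prov = dict(provenance or {})
    prov.setdefault("scaling", "pareto")
    return ScaledMatrix(X, center, scale, blocks.loc[matrix.columns], prov)


def fuse_blocks(scaled_rp: ScaledMatrix, scaled_hilic: ScaledMatrix) -> ScaledMatrix:
    """Feature-wise concatenation of two per-block scaled matrices ("RP + HI").

    Sample id sets must match; the HILIC rows are reordered to the RP sample
    order, so the result is invariant to sample-order permutations of either
    block.
    """
    ids_rp = set(scaled_rp.sample_ids)
    ids_hi = set(scaled_hilic.sample_ids)
    if ids_rp != ids_hi:
        only_rp = sorted(ids_rp - ids_hi)
        only_hi = sorted(ids_hi - ids_rp)
        raise ValueError(
            f"sample sets differ between blocks: only in RP {only_rp}, "
            f"only in HILIC {only_hi}"
        )
    hi = scaled_hilic.X.loc[scaled_rp.X.index]
    X = pd.concat([scaled_rp.X, hi], axis=1)
    if X.columns.has_duplicates:
        raise ValueError("duplicate feature ids across blocks")
    center = pd.concat([scaled_rp.center, scaled_hilic.center])
    scale = pd.concat([scaled_rp.scale, scaled_hilic.scale])
    blocks = pd.concat([scaled_rp.blocks, scaled_hilic.blocks])
    prov = {"fused": True,
            "rp": scaled_rp.provenance, "hilic": scaled_hilic.provenance}
    return ScaledMatrix(X, center, scale, blocks, prov)


# ---------------------------------------------------------------------------
# Pipeline runner
# ---------------------------------------------------------------------------

_STAGE_ORDER = ("filter", "normalize", "log10", "scale", "fuse")


def run_preprocess(
    table_rp: PeakTable,
    table_hilic: PeakTable,
    meta: pd.DataFrame,
    max_missing: float = 0.20,
) -> tuple[ScaledMatrix, pd.DataFrame]:
    """Run filter -> normalize -> log10 -> Pareto scale -> fuse on both blocks.

    Returns the fused :class:`ScaledMatrix` plus the fused *unscaled* log10
    matrix (samples x features) for steps that refit scaling themselves
    (cross-validation) or need pre-scale values.  Stage order is fixed and
    recorded in provenance.
    """
    stages: list[str] = []
    per_block: dict[str, pd.DataFrame] = {}
    scaled: dict[str, ScaledMatrix] = {}
    counts: dict[str, dict[str, int]] = {}
    for name, tab in (("RP", table_rp), ("HILIC", table_hilic)):
        n0 = tab.n_features
        tab = filter_missing(tab, max_missing=max_missing)
        tab = normalize_cell_count(tab, meta)
        logm = log10_transform(tab)
        blocks = pd.Series(tab.features["block"].to_numpy(), index=logm.columns)
        sm = pareto_scale(logm, blocks,
                          provenance={"filter_max_missing": max_missing,
                                      "log_base": 10, "block": name})
        per_block[name] = logm
        scaled[name] = sm
        counts[name] = {"before_filter": n0, "after_filter": tab.n_features}
    stages.extend(["filter", "normalize", "log10", "scale"])
    fused = fuse_blocks(scaled["RP"], scaled["HILIC"])
    stages.append("fuse")
    assert tuple(stages) == _STAGE_ORDER, "preprocess stage order violated"
    fused.provenance["stage_order"] = stages
    fused.provenance["feature_counts"] = counts
    log_fused = pd.concat(
        [per_block["RP"], per_block["HILIC"].loc[per_block["RP"].index]], axis=1
    )
    return fused, log_fused
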