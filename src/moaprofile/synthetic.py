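"""Synthetic two-block LC-MS study generator with planted marker metabolites.

Emulates the study design the pipeline is built for: a panel of adherent tumor
cell lines, four mechanism-of-action drug classes with several drugs each,
treated vs control conditions in replicate, pooled QC injections, and two
chromatographic blocks (RP and HILIC).  Every class gets a set of planted
marker features whose log10 abundance is shifted in treated samples of that
class only; the ground truth is returned as a manifest so marker recovery and
classification accuracy are measurable.

The generative model, per feature f and biological sample i:

    log10 I_fi = mu_f + cellline_f(line_i) + delta_fi + drug_fi + eps_fi

with mu_f ~ U(3, 6) (baseline log10 intensity), cellline ~ N(0, cell_line_sd)
per (line, feature), eps ~ N(0, noise_sd) technical noise, delta the planted
class shift (+-effect_size, treated samples of the marker's class only) and a
small per-drug idiosyncratic shift ~ N(0, effect_size/5) on its class markers.
Linear intensities are then multiplied by the sample's cell count relative to
the nominal seeding density, zeros are injected at ``missing_rate``, and any
intensity below the detection floor (1% quantile of baseline intensity) is
censored to 0.  Pooled QC samples are the feature-wise mean of all biological
samples with N(0, noise_sd/2) log-noise, inserted at the head of the run and
after every ``qc_interval`` analytical injections.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import BLOCK_MZ_RANGE, CLASS_LABELS, PeakTable, feature_id

#: drug name pools per canonical class (training panel and the held-out set)
DEFAULT_DRUGS = {
    "antimetabolite": ("5FU", "MTX", "AraC"),
    "dna_acting": ("MMC", "DDP", "VP16"),
    "microtubule": ("PTX", "VCR", "DTX"),
    "rna_interference": ("DNR", "EPI", "DACT"),
}

#: retention-time span per block, minutes (RP gradient is the longer one)
BLOCK_RT_RANGE = {"RP": (0.5, 45.0), "HILIC": (0.5, 30.0)}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design knobs; defaults are the emulated study's conditions."""

    n_cell_lines: int = 12
    classes: tuple[str, ...] = CLASS_LABELS
    drugs_per_class: int = 3
    replicates: int = 3
    n_features_rp: int = 300
    n_features_hilic: int = 200
    markers_per_class: int = 12
    effect_size: float = 0.5  # log10-scale shift of planted markers
    noise_sd: float = 0.1  # log10-scale technical noise
    cell_line_sd: float = 0.2  # log10-scale cell-line random effect
    missing_rate: float = 0.05
    qc_interval: int = 6
    cell_count_mean: float = 1.0e6
    cell_count_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("classes must be non-empty")
        for name in ("n_cell_lines", "drugs_per_class", "replicates",
                     "n_features_rp", "n_features_hilic", "markers_per_class",
                     "qc_interval"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        smaller = min(self.n_features_rp, self.n_features_hilic)
        if self.markers_per_class > smaller:
            raise ValueError(
                f"markers_per_class ({self.markers_per_class}) exceeds the "
                f"smaller block's feature count ({smaller})"
            )

    @property
    def n_features(self) -> int:
        return self.n_features_rp + self.n_features_hilic

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


@dataclass
class _StudyDesign:
    """Deterministic structural draw shared by training and new-drug sets."""

    config: SyntheticConfig
    feature_ids: list[str]
    blocks: np.ndarray  # per feature, "RP"/"HILIC"
    rt: np.ndarray
    mz: np.ndarray
    mu: np.ndarray  # baseline log10 intensity per feature
    cell_line_effect: np.ndarray  # lines x features
    cell_lines: list[str]
    marker_idx: dict[str, np.ndarray]  # class -> feature indices
    direction: dict[str, np.ndarray]  # class -> +-1 per marker
    drug_shift: dict[str, np.ndarray]  # drug -> shift per its class markers
    drugs: dict[str, list[str]]  # class -> drug names
    detection_floor: float  # linear-intensity censoring threshold


def _build_design(config: SyntheticConfig) -> _StudyDesign:
    rng = np.random.default_rng([int(config.seed), 101])
    blocks = np.array(
        ["RP"] * config.n_features_rp + ["HILIC"] * config.n_features_hilic
    )
    rt = np.empty(config.n_features)
    mz = np.empty(config.n_features)
    for block in ("RP", "HILIC"):
        m = blocks == block
        lo_rt, hi_rt = BLOCK_RT_RANGE[block]
        lo_mz, hi_mz = BLOCK_MZ_RANGE[block]
        rt[m] = rng.uniform(lo_rt, hi_rt, m.sum())
        mz[m] = rng.uniform(max(lo_mz, 80.0), hi_mz, m.sum())
    fids = [feature_id(b, r, m_) for b, r, m_ in zip(blocks, rt, mz)]
    mu = rng.uniform(3.0, 6.0, config.n_features)
    cell_lines = [f"CL{i + 1:02d}" for i in range(config.n_cell_lines)]
    cl_eff = rng.normal(0.0, config.cell_line_sd,
                        (config.n_cell_lines, config.n_features))

    # disjoint marker features per class, drawn from both blocks
    n_rp, n_hi = config.n_features_rp, config.n_features_hilic
    m = config.markers_per_class
    k_cls = len(config.classes)
    m_rp = int(round(m * n_rp / (n_rp + n_hi)))
    m_rp = min(m_rp, n_rp // k_cls)  # keep per-class draws within each pool
    m_rp = max(m_rp, m - n_hi // k_cls)
    if not 0 <= m_rp <= m or (m - m_rp) * k_cls > n_hi or m_rp * k_cls > n_rp:
        raise ValueError("not enough features to plant disjoint class markers")
    # plant markers only on reliably detected features (baseline above the
    # lower 30% of log10 abundance): a down-shifted marker sitting at the
    # detection limit would be censored to zero and dropped by the
    # missingness filter, which no printed marker table exhibits
    eligible = mu >= np.quantile(mu, 0.30)
    rp_pool = rng.permutation(np.flatnonzero((blocks == "RP") & eligible))
    hi_pool = rng.permutation(np.flatnonzero((blocks == "HILIC") & eligible))
    marker_idx: dict[str, np.ndarray] = {}
    direction: dict[str, np.ndarray] = {}
    rp_ptr = hi_ptr = 0
    for cls in config.classes:
        take_rp = min(m_rp, m)
        take_hi = m - take_rp
        if rp_ptr + take_rp > len(rp_pool) or hi_ptr + take_hi > len(hi_pool):
            raise ValueError("not enough features to plant disjoint class markers")
        idx = np.concatenate([rp_pool[rp_ptr:rp_ptr + take_rp],
                              hi_pool[hi_ptr:hi_ptr + take_hi]])
        rp_ptr += take_rp
        hi_ptr += take_hi
        marker_idx[cls] = np.sort(idx)
        direction[cls] = rng.choice([-1.0, 1.0], size=m)

    drugs = {
        cls: list(DEFAULT_DRUGS.get(cls, ())[: config.drugs_per_class])
        or [f"{cls[:3].upper()}{j + 1}" for j in range(config.drugs_per_class)]
        for cls in config.classes
    }
    for cls in config.classes:  # pad if the pool is shorter than requested
        while len(drugs[cls]) < config.drugs_per_class:
            drugs[cls].append(f"{cls[:3].upper()}{len(drugs[cls]) + 1}")
    drug_shift = {
        d: rng.normal(0.0, config.effect_size / 5.0, m)
        for cls in config.classes
        for d in drugs[cls]
    }
    floor = float(10.0 ** np.quantile(mu, 0.01))
    return _StudyDesign(config, fids, blocks, rt, mz, mu, cl_eff, cell_lines,
                        marker_idx, direction, drug_shift, drugs, floor)


def _simulate_biological(design: _StudyDesign, assign: pd.DataFrame,
                         rng: np.random.Generator,
                         half_shift_classes: tuple[str, ...] = ()) -> np.ndarray:
    """Linear-intensity matrix (features x samples) for biological samples.

    ``assign`` rows carry cell_line, drug, moa_class, condition, cell_count.
    ``half_shift_classes`` activates half-magnitude shifts of several classes
    at once (mixed-mechanism sets); otherwise each treated sample gets the
    full shift of its own class.
    """
    cfg = design.config
    n = len(assign)
    log_i = np.empty((cfg.n_features, n))
    line_pos = {cl: k for k, cl in enumerate(design.cell_lines)}
    for j, row in enumerate(assign.itertuples(index=False)):
        prof = design.mu + design.cell_line_effect[line_pos[row.cell_line]]
        prof = prof + rng.normal(0.0, cfg.noise_sd, cfg.n_features)
        if row.condition == "treated":
            if half_shift_classes:
                for cls in half_shift_classes:
                    idx = design.marker_idx[cls]
                    prof[idx] += 0.5 * cfg.effect_size * design.direction[cls]
            else:
                cls = row.moa_class
                idx = design.marker_idx[cls]
                prof[idx] += cfg.effect_size * design.direction[cls]
                if row.drug in design.drug_shift:
                    prof[idx] += design.drug_shift[row.drug]
        log_i[:, j] = prof
    linear = 10.0 ** log_i
    linear *= (assign["cell_count"].to_numpy() / cfg.cell_count_mean)[None, :]
    if cfg.missing_rate > 0:
        linear[rng.random(linear.shape) < cfg.missing_rate] = 0.0
    linear[linear < design.detection_floor] = 0.0
    return linear


def _draw_cell_counts(rng: np.random.Generator, n: int, cfg: SyntheticConfig) -> np.ndarray:
    counts = rng.normal(cfg.cell_count_mean, cfg.cell_count_cv * cfg.cell_count_mean, n)
    return np.clip(counts, 0.1 * cfg.cell_count_mean, None)


def _split_blocks(design: _StudyDesign, intens: np.ndarray,
                  sample_ids: list[str]) -> tuple[PeakTable, PeakTable]:
    frames = {}
    for block in ("RP", "HILIC"):
        m = design.blocks == block
        feats = pd.DataFrame(
            {"block": block, "rt": design.rt[m], "mz": design.mz[m]},
            index=pd.Index(np.array(design.feature_ids)[m], name="feature_id"),
        )
        vals = pd.DataFrame(intens[m], index=feats.index, columns=sample_ids)
        frames[block] = PeakTable(feats, vals)
    return frames["RP"], frames["HILIC"]


def generate_study(
    config: SyntheticConfig,
) -> tuple[PeakTable, PeakTable, pd.DataFrame, pd.DataFrame]:
    """Simulate the full training study.

    Returns ``(peak_table_rp, peak_table_hilic, sample_meta, marker_manifest)``.
    One treated and one control condition per (cell line, drug), ``replicates``
    samples each, plus pooled QC injections.  Deterministic under
    ``config.seed``.
    """
    design = _build_design(config)
    cfg = config
    rows = []
    for line in design.cell_lines:
        for cls in cfg.classes:
            for drug in design.drugs[cls]:
                for cond in ("treated", "control"):
                    for rep in range(1, cfg.replicates + 1):
                        rows.append((line, drug, cls, cond, rep))
    assign = pd.DataFrame(rows, columns=["cell_line", "drug", "moa_class",
                                         "condition", "replicate"])
    rng = np.random.default_rng([int(cfg.seed), 202])
    assign["cell_count"] = _draw_cell_counts(rng, len(assign), cfg)
    assign["sample_id"] = [f"S{k + 1:04d}" for k in range(len(assign))]

    bio = _simulate_biological(design, assign, rng)

    n_qc = 1 + len(assign) // cfg.qc_interval
    pooled = bio.mean(axis=1)
    qc = pooled[:, None] * 10.0 ** rng.normal(0.0, cfg.noise_sd / 2.0,
                                              (cfg.n_features, n_qc))
    qc[qc < design.detection_floor] = 0.0
    qc_ids = [f"QC{k + 1:03d}" for k in range(n_qc)]

    # injection order: QC at the head of the run and after every qc_interval
    order: list[str] = []
    qc_iter = iter(qc_ids)
    order.append(next(qc_iter))
    for k, sid in enumerate(assign["sample_id"], start=1):
        order.append(sid)
        if k % cfg.qc_interval == 0:
            nxt = next(qc_iter, None)
            if nxt is not None:
                order.append(nxt)
    inj = {sid: k + 1 for k, sid in enumerate(order)}

    meta_bio = assign[["sample_id", "cell_line", "drug", "moa_class",
                       "condition", "cell_count"]].copy()
    meta_qc = pd.DataFrame(
        {"sample_id": qc_ids, "cell_line": pd.NA, "drug": pd.NA,
         "moa_class": pd.NA, "condition": "qc", "cell_count": np.nan}
    )
    meta = pd.concat([meta_bio, meta_qc], ignore_index=True)
    meta["injection_order"] = meta["sample_id"].map(inj)
    meta = meta.sort_values("injection_order", ignore_index=True)

    intens = np.concatenate([bio, qc], axis=1)
    sample_ids = list(assign["sample_id"]) + qc_ids
    col_order = meta["sample_id"].tolist()
    pos = {sid: k for k, sid in enumerate(sample_ids)}
    intens = intens[:, [pos[s] for s in col_order]]
    rp, hilic = _split_blocks(design, intens, col_order)

    manifest = marker_manifest(design)
    return rp, hilic, meta, manifest


def marker_manifest(design: _StudyDesign) -> pd.DataFrame:
    cfg = design.config
    rows = []
    for cls in cfg.classes:
        for idx, direc in zip(design.marker_idx[cls], design.direction[cls]):
            rows.append(
                {"feature_id": design.feature_ids[idx],
                 "block": design.blocks[idx],
                 "moa_class": cls,
                 "direction": "up" if direc > 0 else "down",
                 "log10_shift": direc * cfg.effect_size}
            )
    return pd.DataFrame(rows)


def generate_new_drug_set(
    config: SyntheticConfig,
    model_class: str,
    n_samples: int,
    set_label: str | None = None,
    mixed_pair: tuple[str, str] = ("microtubule", "dna_acting"),
    seed: int | None = None,
) -> tuple[PeakTable, PeakTable, pd.DataFrame]:
    """Simulate a held-out treatment set for projection-based classification.

    ``model_class`` is one of ``config.classes``, or ``"mixed"`` to apply
    half-magnitude shifts of both classes in ``mixed_pair`` simultaneously
    (a compound acting through two mechanisms at once).  The structural draw
    (features, baselines, marker identities) is shared with
    :func:`generate_study` for the same config, so the set projects into the
    training feature space.
    """
    if n_samples < 0:
        raise ValueError("n_samples must be >= 0")
    if model_class != "mixed" and model_class not in config.classes:
        raise ValueError(f"unknown class label {model_class!r}")
    if model_class == "mixed":
        for cls in mixed_pair:
            if cls not in config.classes:
                raise ValueError(f"unknown class label {cls!r} in mixed_pair")
    design = _build_design(config)
    label = set_label or (f"NEW_{model_class}" if model_class != "mixed"
                          else "NEW_" + "+".join(mixed_pair))
    sub_seed = seed if seed is not None else int(config.seed)
    rng = np.random.default_rng([sub_seed, 303, zlib.crc32(label.encode())])
    lines = [design.cell_lines[int(k)]
             for k in rng.integers(0, len(design.cell_lines), n_samples)]
    assign = pd.DataFrame(
        {"cell_line": lines, "drug": label,
         "moa_class": model_class, "condition": "treated"}
    )
    assign["cell_count"] = _draw_cell_counts(rng, n_samples, config)
    assign["sample_id"] = [f"{label}_{k + 1:03d}" for k in range(n_samples)]
    half = tuple(mixed_pair) if model_class == "mixed" else ()
    if n_samples:
        intens = _simulate_biological(design, assign, rng, half_shift_classes=half)
    else:
        intens = np.empty((config.n_features, 0))
    meta = assign[["sample_id", "cell_line", "drug", "moa_class",
                   "condition", "cell_count"]].copy()
    meta["injection_order"] = np.arange(1, n_samples + 1)
    rp, hilic = _split_blocks(design, intens, list(assign["sample_id"]))
    return rp, hilic, meta
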