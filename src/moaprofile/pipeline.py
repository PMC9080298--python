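"""End-to-end orchestration: simulate -> preprocess -> qa -> fit -> validate
-> markers -> predict, driven by one config with a single seed.

Artifacts land in a run directory::

    run/
      inputs/    peak tables, metadata, marker manifest (TSV)
      model/     fitted model (JSON)
      reports/   qa.json, validation.json, markers_<class>.tsv, predictions.json
      plots/     permutation and score-region figures
      manifest.json

The manifest records the config, seed, per-stage sample/feature counts and
SHA-256 hashes of every written file, so a rerun with the same config is
verifiable byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ptio
from . import markers as mk
from . import pca as pca_mod
from . import moa_predict as pr
from . import preprocess as pp
from . import synthetic as syn
from . import validate as val
from .oplsda import cross_validate, fit_oplsda_scaled

STAGES = ("simulate", "preprocess", "qa", "fit", "validate", "markers", "predict")


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    synthetic: dict = field(default_factory=dict)
    max_missing: float = 0.20
    folds: int = 7
    n_orth: int | str = "auto"
    n_perm: int = 99
    margin_threshold: float = 0.2
    new_set_size: int = 36
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})

    _KNOWN = ("out_dir", "seed", "synthetic", "max_missing", "folds", "n_orth",
              "n_perm", "margin_threshold", "new_set_size", "stages")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = [k for k in d if k not in cls._KNOWN]
        if unknown:
            raise ValueError(f"unknown config key(s): {unknown}")
        cfg = cls(**d)
        bad = [s for s in cfg.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stage(s): {bad}")
        full = {s: True for s in STAGES}
        full.update(cfg.stages)
        cfg.stages = full
        syn_keys = {f.name for f in dataclasses.fields(syn.SyntheticConfig)}
        bad = [k for k in cfg.synthetic if k not in syn_keys]
        if bad:
            raise ValueError(f"unknown synthetic config key(s): {bad}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def synthetic_config(self) -> syn.SyntheticConfig:
        d = dict(self.synthetic)
        d.setdefault("seed", self.seed)
        if "classes" in d:
            d["classes"] = tuple(d["classes"])
        return syn.SyntheticConfig(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, msg: str):
        super().__init__(f"stage {stage!r} failed: {msg}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in fixed order; returns the manifest."""
    out = Path(config.out_dir)
    for sub in ("inputs", "model", "reports", "plots"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config": dataclasses.asdict(config),
                      "stages": {}, "files": {}}

    def record(path: Path):
        manifest["files"][str(path.relative_to(out))] = _sha256(path)

    def persist():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    state: dict = {}
    for stage in STAGES:
        if not config.stages.get(stage, True):
            continue
        try:
            _STAGE_FN[stage](config, out, state, manifest, record)
        except PipelineError:
            manifest["stages"][stage] = "failed"
            persist()
            raise
        except Exception as exc:  # abort with the stage name, keep partial manifest
            manifest["stages"][stage] = "failed"
            persist()
            raise PipelineError(stage, str(exc)) from exc
        manifest["stages"][stage] = "ok"
        persist()
    persist()
    return manifest


def _need(state: dict, key: str, stage: str):
    if key not in state:
        raise PipelineError(
            stage, f"missing upstream artifact {key!r}: enable the producing stage"
        )
    return state[key]


def _stage_simulate(config, out, state, manifest, record):
    scfg = config.synthetic_config()
    rp, hi, meta, man = syn.generate_study(scfg)
    ptio.write_peak_table(rp, out / "inputs/rp.tsv")
    ptio.write_peak_table(hi, out / "inputs/hilic.tsv")
    ptio.write_sample_meta(meta, out / "inputs/meta.tsv")
    man.to_csv(out / "inputs/manifest_markers.tsv", sep="\t", index=False)
    for f in ("rp.tsv", "hilic.tsv", "meta.tsv", "manifest_markers.tsv"):
        record(out / "inputs" / f)
    state.update(rp=rp, hilic=hi, meta=meta, marker_manifest=man, syn_config=scfg)
    manifest.setdefault("counts", {})["samples"] = len(meta)
    manifest["counts"]["features"] = rp.n_features + hi.n_features


def _stage_preprocess(config, out, state, manifest, record):
    rp = _need(state, "rp", "preprocess")
    hi = _need(state, "hilic", "preprocess")
    meta = _need(state, "meta", "preprocess")
    fused, log_fused = pp.run_preprocess(rp, hi, meta, max_missing=config.max_missing)
    # normalized pre-log tables for fold changes
    norm = {}
    for name, tab in (("RP", rp), ("HILIC", hi)):
        t = pp.filter_missing(tab, max_missing=config.max_missing)
        norm[name] = pp.normalize_cell_count(t, meta)
    state.update(fused=fused, log_fused=log_fused, norm_tables=norm)
    manifest.setdefault("counts", {})["features_after_filter"] = fused.X.shape[1]


def _stage_qa(config, out, state, manifest, record):
    fused = _need(state, "fused", "qa")
    meta = _need(state, "meta", "qa")
    ncomp = min(10, len(fused.X) - 1, fused.X.shape[1])
    pca = pca_mod.fit_pca(fused, ncomp)
    drift = pca_mod.qc_drift_check(pca, meta, k=2.0)
    report = {
        "explained_variance_fraction": pca.explained_variance_fraction.tolist(),
        "first_two_pc_percent": float(100 * pca.explained_variance_fraction[:2].sum()),
        "qc_verdict": bool(drift.attrs["verdict"]),
        "qc_flags": {i: bool(v) for i, v in drift["pass"].items()},
    }
    (out / "reports/qa.json").write_text(json.dumps(report, indent=2))
    record(out / "reports/qa.json")
    state["pca"] = pca


def _stage_fit(config, out, state, manifest, record):
    fused = _need(state, "fused", "fit")
    log_fused = _need(state, "log_fused", "fit")
    meta = _need(state, "meta", "fit")
    treated = meta[meta["condition"] == "treated"]
    ids = treated["sample_id"].tolist()
    labels = treated.set_index("sample_id").loc[ids, "moa_class"].to_numpy()
    # rescale on the treated subset so the model's center/scale match its data
    sub = pp.pareto_scale(log_fused.loc[ids], fused.blocks,
                          provenance={"subset": "treated"})
    model = fit_oplsda_scaled(sub, labels, n_orth=config.n_orth,
                              auto_seed=config.seed, auto_folds=config.folds)
    cv = cross_validate(log_fused.loc[ids], labels, n_orth=model.n_orth,
                        folds=config.folds, seed=config.seed)
    model.q2 = cv.q2
    model.to_json(out / "model/model.json")
    record(out / "model/model.json")
    state.update(model=model, cv=cv, train_ids=ids, train_labels=labels)
    manifest.setdefault("metrics", {}).update(
        r2y=model.r2y, r2x=model.r2x, q2=cv.q2,
        n_pred=model.n_pred, n_orth=model.n_orth,
    )


def _stage_validate(config, out, state, manifest, record):
    model = _need(state, "model", "validate")
    cv = _need(state, "cv", "validate")
    log_fused = _need(state, "log_fused", "validate")
    ids = _need(state, "train_ids", "validate")
    labels = _need(state, "train_labels", "validate")
    perm = val.permutation_test(
        log_fused.loc[ids], labels, n_perm=config.n_perm, folds=config.folds,
        seed=config.seed, n_orth=model.n_orth,
    )
    anova = val.cv_anova(cv)
    report = {
        "permutation": {
            "n_perm": perm.n_perm,
            "r2_intercept": perm.r2_intercept, "q2_intercept": perm.q2_intercept,
            "r2_original": perm.r2_original, "q2_original": perm.q2_original,
            "exceedance_r2": perm.exceedance_r2, "exceedance_q2": perm.exceedance_q2,
        },
        "cv_anova": dataclasses.asdict(anova),
        "summary": perm.summary(),
    }
    (out / "reports/validation.json").write_text(json.dumps(report, indent=2))
    record(out / "reports/validation.json")
    val.permutation_plot(perm, out / "plots/permutation.png")
    state.update(permutation=perm, cv_anova=anova)
    manifest.setdefault("metrics", {}).update(
        q2_intercept=perm.q2_intercept, r2_intercept=perm.r2_intercept,
        cv_anova_p=anova.p_value,
    )


def _p_flag(p: float) -> str:
    return "<0.001" if p < 0.001 else ("<0.01" if p < 0.01 else "<0.05")


def _stage_markers(config, out, state, manifest, record):
    model = _need(state, "model", "markers")
    meta = _need(state, "meta", "markers")
    log_fused = _need(state, "log_fused", "markers")
    norm = _need(state, "norm_tables", "markers")
    rp = _need(state, "rp", "markers")
    hi = _need(state, "hilic", "markers")
    bio = meta[meta["condition"].isin(["treated", "control"])]["sample_id"].tolist()
    scaled = pp.pareto_scale(log_fused.loc[bio])
    feats = pd.concat([rp.features, hi.features])
    counts = {}
    fc_rows = {}
    for cls in model.levels:
        cands = mk.select_markers(model, scaled, norm, meta, cls,
                                  alpha=0.05, min_auc=0.50)
        selected = [c for c in cands if c.passes]
        counts[cls] = len(selected)
        rows = []
        for rank, c in enumerate(selected, start=1):
            rows.append({
                "class": cls, "no": rank,
                "rt": round(float(feats.loc[c.feature_id, "rt"]), 3),
                "name": c.feature_id,
                "mz": round(float(feats.loc[c.feature_id, "mz"]), 4),
                "p_flag": _p_flag(c.p_adj), "auc": round(c.auc, 3),
                "fc": round(c.fc, 3), "trend": c.trend, "pathway": "",
            })
            fc_rows.setdefault(c.feature_id, {})[cls] = c.fc
        path = out / f"reports/markers_{cls}.tsv"
        pd.DataFrame(
            rows, columns=["class", "no", "rt", "name", "mz", "p_flag",
                           "auc", "fc", "trend", "pathway"]
        ).to_csv(path, sep="\t", index=False)
        record(path)
        mk.candidates_frame(cands).to_csv(
            out / f"reports/marker_stats_{cls}.tsv", sep="\t", index=False
        )
        record(out / f"reports/marker_stats_{cls}.tsv")
    state["marker_counts"] = counts
    manifest.setdefault("counts", {})["markers_per_class"] = counts
    fc_matrix = pd.DataFrame(fc_rows).T.reindex(columns=list(model.levels)).fillna(1.0)
    if len(fc_matrix) >= 2:
        clust = mk.cluster_heatmap(fc_matrix, n_clusters=4,
                                   plot_path=out / "plots/heatmap.png")
        state["heatmap"] = clust
        record(out / "plots/heatmap.png")


def _stage_predict(config, out, state, manifest, record):
    model = _need(state, "model", "predict")
    scfg = _need(state, "syn_config", "predict")
    results = []
    report = {}
    eval_sets = [(cls, f"NEW_{cls}") for cls in model.levels]
    for cls, label in eval_sets:
        rp, hi, meta_new = syn.generate_new_drug_set(
            scfg, cls, config.new_set_size, set_label=label
        )
        res = _classify_new(config, state, model, rp, hi, meta_new, label)
        results.append(res)
        report[label] = _result_dict(res, truth=cls)
    rp, hi, meta_new = syn.generate_new_drug_set(
        scfg, "mixed", config.new_set_size, set_label="NEW_mixed"
    )
    res = _classify_new(config, state, model, rp, hi, meta_new, "NEW_mixed")
    results.append(res)
    report["NEW_mixed"] = _result_dict(res, truth="mixed")
    region = pr.region_report(model, results, plot_path=out / "plots/regions.png")
    report["inside_fractions"] = {
        k: dict(v) for k, v in region.inside_fractions.iterrows()
    }
    (out / "reports/predictions.json").write_text(json.dumps(report, indent=2))
    record(out / "reports/predictions.json")
    record(out / "plots/regions.png")
    state["predictions"] = results


def _classify_new(config, state, model, rp, hi, meta_new, label):
    filt_ids = state["log_fused"].columns
    rp_keep = [f for f in rp.features.index if f in set(filt_ids)]
    hi_keep = [f for f in hi.features.index if f in set(filt_ids)]
    rp = pp.normalize_cell_count(rp.subset_features(rp_keep), meta_new)
    hi = pp.normalize_cell_count(hi.subset_features(hi_keep), meta_new)
    log_rp = pp.log10_transform(rp, on_all_zero="global_half_min")
    log_hi = pp.log10_transform(hi, on_all_zero="global_half_min")
    X_new = pd.concat([log_rp, log_hi], axis=1)
    return pr.classify_set(model, X_new, label,
                           margin_threshold=config.margin_threshold)


def _result_dict(res: pr.PredictionResult, truth: str) -> dict:
    return {
        "truth": truth,
        "majority_class": res.majority_class,
        "fraction_concordant": res.fraction_concordant,
        "mixed_flag": res.mixed_flag,
        "weak_signal": res.weak_signal,
        "top2": list(res.top2),
        "r2_pred": res.r2_pred,
        "q2_ext": res.q2_ext,
        "mean_membership": {k: float(v) for k, v in res.mean_membership.items()},
    }


_STAGE_FN = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "qa": _stage_qa,
    "fit": _stage_fit,
    "validate": _stage_validate,
    "markers": _stage_markers,
    "predict": _stage_predict,
}
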