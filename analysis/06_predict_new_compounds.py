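"""Classify held-out treatment sets by projection onto the frozen model.

Four single-mechanism evaluation sets (one per class, mirroring the
GEM/BCNU/MIT/VDS layout) plus one half-magnitude two-mechanism candidate set
(the DIO analogue) are generated, projected, and called.  The mixed set is
expected to fall between the microtubule and DNA-acting regions and raise
the mixed-mechanism flag.

Writes results/predictions.json and results/plots/regions.png.
"""

import json
import warnings
from pathlib import Path

import pandas as pd

import moaprofile as mp
import moaprofile.preprocess as pp
from moaprofile import io as ptio
from moaprofile.oplsda import OplsModel

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 1
N_PER_SET = 36


def project_set(cfg, train_cols, model_class, label):
    rp, hi, meta = mp.generate_new_drug_set(cfg, model_class, N_PER_SET,
                                            set_label=label)
    keep = set(train_cols)
    parts = []
    for tab in (rp, hi):
        fids = [f for f in tab.features.index if f in keep]
        tab = pp.normalize_cell_count(tab.subset_features(fids), meta)
        parts.append(pp.log10_transform(tab, on_all_zero="global_half_min"))
    return pd.concat(parts, axis=1)


def main() -> None:
    X = pd.read_csv(ROOT / "fused_log10.tsv", sep="\t", index_col=0)
    model = OplsModel.from_json(ROOT / "model/model.json")
    cfg = mp.SyntheticConfig(seed=SEED)

    results, report = [], {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for cls in model.levels:
            label = f"NEW_{cls}"
            res = mp.classify_set(model, project_set(cfg, X.columns, cls, label),
                                  label)
            results.append(res)
            report[label] = {"truth": cls, "call": res.majority_class,
                             "concordance": res.fraction_concordant,
                             "mixed_flag": res.mixed_flag,
                             "r2_pred": res.r2_pred, "q2_ext": res.q2_ext}
            print(f"{label}: called {res.majority_class} "
                  f"({100 * res.fraction_concordant:.0f}% of samples), "
                  f"R2 = {res.r2_pred:.3f}, Q2 = {res.q2_ext:.3f}")
        res = mp.classify_set(model,
                              project_set(cfg, X.columns, "mixed", "NEW_mixed"),
                              "NEW_mixed")
    results.append(res)
    report["NEW_mixed"] = {"truth": "mixed", "top2": list(res.top2),
                           "mixed_flag": res.mixed_flag,
                           "r2_pred": res.r2_pred, "q2_ext": res.q2_ext}
    print(f"NEW_mixed: mixed_flag={res.mixed_flag}, between "
          f"{res.top2[0]} and {res.top2[1]} regions")

    (ROOT / "plots").mkdir(exist_ok=True)
    region = mp.region_report(model, results,
                              plot_path=ROOT / "plots/regions.png")
    report["inside_fractions"] = {
        k: dict(v) for k, v in region.inside_fractions.iterrows()}
    (ROOT / "predictions.json").write_text(json.dumps(report, indent=2))
    print("score-space panels at results/plots/regions.png")


if __name__ == "__main__":
    main()
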