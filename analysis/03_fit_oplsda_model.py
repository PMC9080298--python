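"""Fit the four-class OPLS-DA model on treated samples and cross-validate it.

The model regresses the class-indicator matrix on the Pareto-scaled fused
matrix with 3 predictive components (K - 1) and an automatically chosen
number of orthogonal components.  Sevenfold stratified cross-validation,
with scaling refit inside each fold, yields Q2 (cum.).

Reads results/fused_log10.tsv + metadata; writes results/model/model.json.
"""

import json
from pathlib import Path

import pandas as pd

import moaprofile as mp
import moaprofile.preprocess as pp
from moaprofile import io as ptio

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    X = pd.read_csv(ROOT / "fused_log10.tsv", sep="\t", index_col=0)
    meta = ptio.read_sample_meta(ROOT / "inputs/meta.tsv").set_index("sample_id")
    treated = [s for s in X.index if meta.loc[s, "condition"] == "treated"]
    labels = meta.loc[treated, "moa_class"].to_numpy()

    scaled = pp.pareto_scale(X.loc[treated])
    model = mp.fit_oplsda_scaled(scaled, labels, n_orth="auto", auto_seed=SEED)
    cv = mp.cross_validate(X.loc[treated], labels, n_orth=model.n_orth,
                           folds=7, seed=SEED)
    model.q2 = cv.q2
    (ROOT / "model").mkdir(exist_ok=True)
    model.to_json(ROOT / "model/model.json")

    print(f"fitted on {len(treated)} treated samples, "
          f"{model.n_pred} predictive + {model.n_orth} orthogonal components")
    print(f"R2Y (cum.) = {model.r2y:.3f}, Q2 (cum.) = {cv.q2:.3f} "
          "(sevenfold stratified CV)")
    anova = mp.cv_anova(cv)
    print(f"CV-ANOVA: F = {anova.F:.1f} "
          f"({anova.df_reg}, {anova.df_res} df), p = {anova.p_value:.3g}")


if __name__ == "__main__":
    main()
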