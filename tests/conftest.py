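"""Shared fixtures: a small synthetic study and the models fitted on it.

The small study keeps the full design structure (4 classes x 2 drugs x
treated/control x 3 replicates over 3 cell lines, two blocks, pooled QCs)
at a size where repeated refits stay cheap.
"""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import moaprofile as mp
import moaprofile.preprocess as pp

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config():
    return mp.SyntheticConfig(
        seed=11, n_cell_lines=3, drugs_per_class=2,
        n_features_rp=80, n_features_hilic=60, markers_per_class=8,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return mp.generate_study(small_config)


@pytest.fixture(scope="session")
def small_prep(small_study):
    rp, hi, meta, _ = small_study
    fused, log_fused = mp.run_preprocess(rp, hi, meta)
    return fused, log_fused


@pytest.fixture(scope="session")
def treated_split(small_study, small_prep):
    _, _, meta, _ = small_study
    _, log_fused = small_prep
    ids = meta[meta["condition"] == "treated"]["sample_id"].tolist()
    labels = meta.set_index("sample_id").loc[ids, "moa_class"].to_numpy()
    return ids, labels


@pytest.fixture(scope="session")
def small_model(small_prep, treated_split):
    _, log_fused = small_prep
    ids, labels = treated_split
    scaled = pp.pareto_scale(log_fused.loc[ids])
    model = mp.fit_oplsda_scaled(scaled, labels, n_orth=1)
    return model


def make_new_set_matrix(config, train_columns, model_class, n_samples, **kwargs):
    """Generate a held-out set and return its log10 matrix over the training
    feature space (mirrors the pipeline's projection preprocessing)."""
    rp, hi, meta = mp.generate_new_drug_set(config, model_class, n_samples, **kwargs)
    keep = set(train_columns)
    parts = []
    for tab in (rp, hi):
        fids = [f for f in tab.features.index if f in keep]
        tab = pp.normalize_cell_count(tab.subset_features(fids), meta)
        parts.append(pp.log10_transform(tab, on_all_zero="global_half_min"))
    X = pd.concat(parts, axis=1)
    return X, meta


def classify_quiet(model, X, label, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mp.classify_set(model, X, label, **kwargs)
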