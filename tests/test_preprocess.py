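"""Alignment, filtering, normalization, log/Pareto transforms and block fusion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import moaprofile as mp
import moaprofile.preprocess as pp
from moaprofile.io import PeakTable, feature_id


def make_table(values, sample_ids=None, block="RP"):
    """Features x samples table with synthetic RT/mz."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    sample_ids = sample_ids or [f"S{i}" for i in range(n_samp)]
    rt = np.linspace(1, 40, n_feat)
    mz = np.linspace(150, 900, n_feat)
    fids = [feature_id(block, r, m) for r, m in zip(rt, mz)]
    feats = pd.DataFrame({"block": block, "rt": rt, "mz": mz},
                         index=pd.Index(fids, name="feature_id"))
    return PeakTable(feats, pd.DataFrame(values, index=feats.index,
                                         columns=sample_ids))


def peaks(*triples):
    return pd.DataFrame(list(triples), columns=["rt", "mz", "intensity"])


class TestAlignFeatures:
    def test_nearby_peaks_merge_into_one_feature(self):
        lists = {
            "A": peaks((5.0, 100.00, 1e5)),
            "B": peaks((5.3, 100.03, 9e4)),
        }
        table = mp.align_features(lists)
        assert table.n_features == 1
        assert (table.intensities.to_numpy() > 0).all()

    def test_identical_lists_keep_peak_count(self):
        pl = peaks((5.0, 100.0, 1e5), (9.0, 200.0, 5e4), (20.0, 300.0, 2e5))
        table = mp.align_features({"A": pl.copy(), "B": pl.copy()})
        assert table.n_features == 3
        assert (table.intensities.to_numpy() > 0).all()

    def test_low_intensity_peak_dropped(self):
        # 4% of base-peak intensity falls below the 5% floor
        pl = peaks((5.0, 150.0, 1e6), (9.0, 250.0, 4e4))
        table = mp.align_features({"A": pl})
        assert table.n_features == 1
        assert table.features["mz"].iloc[0] == pytest.approx(150.0)

    def test_distant_peaks_stay_separate(self):
        lists = {
            "A": peaks((5.0, 100.0, 1e5)),
            "B": peaks((5.0, 100.2, 9e4)),  # 0.2 Da > 0.05 Da window
        }
        table = mp.align_features(lists)
        assert table.n_features == 2
        # unmatched entries are zero-filled
        assert (table.intensities.to_numpy() == 0).sum() == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mp.align_features({})


class TestFilterMissing:
    def test_strict_threshold_boundary(self):
        vals = np.ones((2, 10))
        vals[0, :3] = 0  # 30% missing -> removed
        vals[1, :2] = 0  # exactly 20% -> kept
        out = mp.filter_missing(make_table(vals), max_missing=0.20)
        assert out.n_features == 1
        assert (out.intensities.to_numpy()[0] == vals[1]).all()

    def test_no_zeros_identity(self):
        table = make_table(np.full((3, 5), 2.0))
        out = mp.filter_missing(table)
        assert out.equals(table)

    def test_zero_threshold_drops_any_zero(self):
        vals = np.ones((2, 5))
        vals[0, 0] = 0
        out = mp.filter_missing(make_table(vals), max_missing=0.0)
        assert out.n_features == 1

    @given(st.integers(0, 9))
    @settings(max_examples=10, deadline=None)
    def test_idempotent(self, n_zero):
        vals = np.ones((4, 10))
        vals[0, :n_zero] = 0
        once = mp.filter_missing(make_table(vals))
        twice = mp.filter_missing(once) if once.n_features else once
        assert once.equals(twice)


class TestNormalizeCellCount:
    def meta_for(self, table, counts):
        return pd.DataFrame({
            "sample_id": table.sample_ids,
            "cell_line": "A", "drug": "d", "moa_class": "microtubule",
            "condition": "treated", "cell_count": counts,
            "injection_order": range(1, len(table.sample_ids) + 1),
        })

    def test_equal_counts_identity(self):
        table = make_table(np.random.default_rng(0).uniform(1, 9, (3, 4)))
        meta = self.meta_for(table, [1e6] * 4)
        out = mp.normalize_cell_count(table, meta)
        np.testing.assert_allclose(out.intensities, table.intensities)

    def test_double_count_halves_intensity(self):
        table = make_table(np.full((2, 3), 8.0))
        meta = self.meta_for(table, [1e6, 1e6, 2e6])
        out = mp.normalize_cell_count(table, meta)
        np.testing.assert_allclose(out.intensities.iloc[:, 2], 4.0)
        np.testing.assert_allclose(out.intensities.iloc[:, 0], 8.0)

    def test_missing_count_rejected(self):
        table = make_table(np.ones((2, 2)))
        meta = self.meta_for(table, [1e6, np.nan])
        meta.loc[1, "condition"] = "treated"
        with pytest.raises(Exception):
            mp.normalize_cell_count(table, meta)

    def test_qc_unchanged(self):
        table = make_table(np.full((1, 2), 6.0))
        meta = self.meta_for(table, [2e6, np.nan])
        meta.loc[1, ["condition", "drug", "moa_class"]] = ["qc", None, None]
        out = mp.normalize_cell_count(table, meta)
        assert out.intensities.iloc[0, 1] == 6.0


class TestLog10Transform:
    def test_powers_of_ten(self):
        table = make_table([[1.0, 10.0, 100.0]])
        out = mp.log10_transform(table)
        np.testing.assert_allclose(out.to_numpy().ravel(), [0.0, 1.0, 2.0])

    def test_half_min_zero_fill(self):
        table = make_table([[0.0, 10.0]])
        out = mp.log10_transform(table)
        np.testing.assert_allclose(out.to_numpy().ravel(),
                                   [np.log10(5.0), 1.0])

    def test_all_zero_feature_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            mp.log10_transform(make_table([[0.0, 0.0]]))

    def test_orientation_samples_by_features(self):
        table = make_table(np.ones((3, 5)))
        out = mp.log10_transform(table)
        assert out.shape == (5, 3)


class TestParetoScale:
    def test_simple_column(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        out = mp.pareto_scale(X)
        np.testing.assert_allclose(out.X["f"], [-1.0, 0.0, 1.0])

    def test_constant_column_zeroed(self):
        X = pd.DataFrame({"f": [5.0, 5.0, 5.0]})
        out = mp.pareto_scale(X)
        np.testing.assert_allclose(out.X["f"], 0.0)

    def test_scaled_variance_equals_original_sd(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(2, 3, (50, 4)),
                         columns=list("abcd"))
        out = mp.pareto_scale(X)
        np.testing.assert_allclose(out.X.var(axis=0, ddof=1),
                                   X.std(axis=0, ddof=1), rtol=1e-10)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_back_transform_recovers_input(self, seed):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(6, 3)), columns=list("abc"))
        out = mp.pareto_scale(X)
        np.testing.assert_allclose(out.back_transform().to_numpy(),
                                   X.to_numpy(), atol=1e-10)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            mp.pareto_scale(pd.DataFrame({"f": [1.0]}))


class TestFuseBlocks:
    def scaled_pair(self, n_samp=6, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"S{i}" for i in range(n_samp)]
        rp = make_table(rng.uniform(1, 9, (5, n_samp)), ids, block="RP")
        hi = make_table(rng.uniform(1, 9, (3, n_samp)), ids, block="HILIC")
        s_rp = mp.pareto_scale(mp.log10_transform(rp))
        s_hi = mp.pareto_scale(mp.log10_transform(hi))
        return s_rp, s_hi

    def test_feature_concatenation(self):
        s_rp, s_hi = self.scaled_pair()
        fused = mp.fuse_blocks(s_rp, s_hi)
        assert fused.X.shape[1] == 8
        assert set(fused.blocks) == {"RP", "HILIC"}

    def test_sample_order_invariance(self):
        s_rp, s_hi = self.scaled_pair()
        fused = mp.fuse_blocks(s_rp, s_hi)
        perm = s_hi.X.sample(frac=1.0, random_state=1)
        s_hi_perm = pp.ScaledMatrix(perm, s_hi.center, s_hi.scale, s_hi.blocks)
        fused2 = mp.fuse_blocks(s_rp, s_hi_perm)
        pd.testing.assert_frame_equal(fused.X, fused2.X)

    def test_sample_mismatch_lists_ids(self):
        s_rp, s_hi = self.scaled_pair()
        dropped = pp.ScaledMatrix(s_hi.X.iloc[:-1], s_hi.center,
                                  s_hi.scale, s_hi.blocks)
        with pytest.raises(ValueError, match="S5"):
            mp.fuse_blocks(s_rp, dropped)


class TestRunPreprocess:
    def test_stage_order_recorded(self, small_study):
        rp, hi, meta, _ = small_study
        fused, log_fused = mp.run_preprocess(rp, hi, meta)
        assert fused.provenance["stage_order"] == [
            "filter", "normalize", "log10", "scale", "fuse"]
        assert fused.X.shape == log_fused.shape
        assert not fused.X.isna().any().any()

    def test_fusion_does_not_hurt_predictivity(self):
        # fused Q2 at least matches the better single block, as a tendency
        # over seeds (matching the two-block design's motivation)
        diffs = []
        for seed in range(6):
            cfg = mp.SyntheticConfig(seed=400 + seed, n_cell_lines=3,
                                     drugs_per_class=2, n_features_rp=60,
                                     n_features_hilic=50, markers_per_class=6)
            rp, hi, meta, _ = mp.generate_study(cfg)
            treated = meta[meta["condition"] == "treated"]["sample_id"]
            labels = meta.set_index("sample_id").loc[treated, "moa_class"].to_numpy()
            q2s = {}
            for name, tab in (("RP", rp), ("HILIC", hi)):
                t = pp.normalize_cell_count(pp.filter_missing(tab), meta)
                logm = pp.log10_transform(t).loc[treated]
                q2s[name] = mp.cross_validate(logm, labels, n_orth=0,
                                              seed=seed).q2
            fused, log_fused = mp.run_preprocess(rp, hi, meta)
            q2_fused = mp.cross_validate(log_fused.loc[treated], labels,
                                         n_orth=0, seed=seed).q2
            diffs.append(q2_fused - max(q2s.values()))
        assert np.mean(diffs) > -0.01
        assert sum(d >= -0.02 for d in diffs) >= 4
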