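import numpy as np
import pandas as pd
import pytest

from mirstab.data_io import DataError
from mirstab.qpcr import (
    collapse_replicates,
    ct_stability,
    ct_table_from_long,
    delta_ct,
    paired_expression_test,
)
from mirstab.simulate import QpcrAssay, QpcrConfig, generate_qpcr


def _ct_from_dict(d, samples):
    return pd.DataFrame(d, index=pd.Index(samples, name="sample_id"))


class TestCtStability:
    def test_constant_cts_zero_sd(self):
        ct = _ct_from_dict({"a": [20.0, 20.0, 20.0]}, ["s1", "s2", "s3"])
        assert ct_stability(ct, "a").sd == 0.0

    def test_two_cts_sample_sd(self):
        ct = _ct_from_dict({"a": [20.0, 22.0]}, ["s1", "s2"])
        assert ct_stability(ct, "a").sd == pytest.approx(np.sqrt(2))

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(28, 1, size=20)
        ct = _ct_from_dict({"a": vals, "b": vals + 7.5}, [f"s{i}" for i in range(20)])
        assert ct_stability(ct, "a").sd == pytest.approx(ct_stability(ct, "b").sd)

    def test_undetected_excluded_and_counted(self):
        ct = _ct_from_dict({"a": [20.0, np.nan, 24.0]}, ["s1", "s2", "s3"])
        s = ct_stability(ct, "a")
        assert s.n_detected == 2 and s.n_undetected == 1

    def test_single_detection_errors(self):
        ct = _ct_from_dict({"a": [20.0, np.nan]}, ["s1", "s2"])
        with pytest.raises(DataError):
            ct_stability(ct, "a")

    def test_generator_sds_recovered_and_ordered(self):
        cfg = QpcrConfig(
            n_pairs=34,
            assays={
                "tight": QpcrAssay(baseline_ct=28, noise_sd=0.5),
                "loose": QpcrAssay(baseline_ct=28, noise_sd=1.5),
            },
            sample_offset_sd=0.0,
            seed=5,
        )
        ct, meta = generate_qpcr(cfg)
        tight = ct_stability(ct, "tight").sd
        loose = ct_stability(ct, "loose").sd
        assert tight < loose
        assert tight == pytest.approx(0.5, rel=0.25)
        assert loose == pytest.approx(1.5, rel=0.25)


class TestDeltaCt:
    def test_basic_subtraction(self):
        ct = _ct_from_dict({"t": [25.0], "ic": [20.0]}, ["s1"])
        d = delta_ct(ct, "t", "ic")
        assert d.delta_ct["s1"] == 5.0

    def test_identical_assays_zero(self):
        ct = _ct_from_dict({"t": [25.0, 30.0]}, ["s1", "s2"])
        ct["ic"] = ct["t"]
        d = delta_ct(ct, "t", "ic")
        assert (d.delta_ct == 0).all()

    def test_antisymmetry_on_swap(self):
        rng = np.random.default_rng(0)
        ct = _ct_from_dict(
            {"t": rng.normal(28, 1, 10), "ic": rng.normal(25, 1, 10)},
            [f"s{i}" for i in range(10)],
        )
        d1 = delta_ct(ct, "t", "ic").delta_ct
        d2 = delta_ct(ct, "ic", "t").delta_ct
        assert np.allclose(d1, -d2)

    def test_samples_missing_either_ct_dropped(self):
        ct = _ct_from_dict(
            {"t": [25.0, np.nan, 26.0], "ic": [20.0, 21.0, np.nan]},
            ["s1", "s2", "s3"],
        )
        d = delta_ct(ct, "t", "ic")
        assert list(d.delta_ct.index) == ["s1"]
        assert d.n_dropped == 2

    def test_zero_noise_fold_change_arithmetic(self):
        # planted 4-fold tumor up-regulation, stable IC, no noise:
        # tumor dCt is exactly 2 cycles below normal dCt
        cfg = QpcrConfig(
            n_pairs=6,
            assays={
                "target": QpcrAssay(baseline_ct=28, tumor_log2fc=2.0, noise_sd=0.0),
                "ic": QpcrAssay(baseline_ct=25, noise_sd=0.0),
            },
            sample_offset_sd=0.0,
            seed=0,
        )
        ct, meta = generate_qpcr(cfg)
        d = delta_ct(ct, "target", "ic", meta)
        diff = d.group_summary.loc["tumor", "mean"] - d.group_summary.loc["normal", "mean"]
        assert diff == pytest.approx(-2.0)

    def test_drifting_ic_cancels_identical_fold_change(self):
        cfg = QpcrConfig(
            n_pairs=6,
            assays={
                "target": QpcrAssay(baseline_ct=28, tumor_log2fc=2.0, noise_sd=0.0),
                "ic": QpcrAssay(baseline_ct=25, tumor_log2fc=2.0, noise_sd=0.0),
            },
            sample_offset_sd=0.0,
            seed=0,
        )
        ct, meta = generate_qpcr(cfg)
        d = delta_ct(ct, "target", "ic", meta)
        assert np.allclose(d.delta_ct, d.delta_ct.iloc[0])


class TestPairedTest:
    def test_identical_vectors_not_significant(self):
        cfg = QpcrConfig(
            n_pairs=6,
            assays={
                "t": QpcrAssay(baseline_ct=28, noise_sd=0.0),
                "ic": QpcrAssay(baseline_ct=25, noise_sd=0.0),
            },
            sample_offset_sd=0.5,
            seed=1,
        )
        ct, meta = generate_qpcr(cfg)
        res = paired_expression_test(delta_ct(ct, "t", "ic", meta), meta)
        assert res.p == 1.0
        assert res.direction == "none"

    def test_strong_upregulation_detected(self):
        cfg = QpcrConfig(seed=3)
        ct, meta = generate_qpcr(cfg)
        res = paired_expression_test(delta_ct(ct, "target", "ic-stable", meta), meta)
        assert res.direction == "up"
        assert res.p < 0.001

    def test_ttest_variant_agrees_in_direction(self):
        cfg = QpcrConfig(seed=3)
        ct, meta = generate_qpcr(cfg)
        d = delta_ct(ct, "target", "ic-stable", meta)
        res = paired_expression_test(d, meta, method="ttest")
        assert res.direction == "up" and res.p < 0.001

    def test_too_few_pairs_errors(self):
        ct = _ct_from_dict({"t": [25.0, 26.0], "ic": [20.0, 21.0]}, ["p1-T", "p1-N"])
        meta = pd.DataFrame(
            {
                "sample_id": ["p1-T", "p1-N"],
                "patient_id": ["p1", "p1"],
                "tissue": ["tumor", "normal"],
            }
        )
        with pytest.raises(DataError):
            paired_expression_test(delta_ct(ct, "t", "ic"), meta)


class TestReplicates:
    def test_collapse_by_mean_with_sd(self):
        long = pd.DataFrame(
            {
                "sample_id": ["s1"] * 3 + ["s2"] * 3,
                "assay": ["a"] * 6,
                "ct": [20.0, 20.5, 21.0, 25.0, 25.0, 25.0],
            }
        )
        out = collapse_replicates(long)
        assert out.loc[out["sample_id"] == "s1", "ct"].iloc[0] == pytest.approx(20.5)
        assert out.loc[out["sample_id"] == "s2", "ct_sd"].iloc[0] == 0.0
        wide = ct_table_from_long(out[["sample_id", "assay", "ct"]])
        assert wide.loc["s1", "a"] == 20.5
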