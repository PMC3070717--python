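"""Raw-spot filtering, background correction, normalization, log ratios."""
from __future__ import annotations

import numpy as np
import pytest

from xplatde import io_formats as io
from xplatde.io_formats import CLS_CONTROL, CLS_TUMOR, SampleMeta
from xplatde.preprocess import (
    FLAG_CUTOFF,
    FLAG_LOW,
    FLAG_OK,
    PreprocessConfig,
    RawSpotTable,
    RatioMatrix,
    apply_intensity_cutoff,
    background_correct,
    collapse_probes,
    compute_log_ratios,
    flag_low_signal,
    global_median_normalize,
)

CFG = PreprocessConfig()  # k_sigma 1.5, cutoff 2, floor 1


def spot_table(signal, local_bg, local_bg_sd, global_bg=100.0) -> RawSpotTable:
    n = len(signal)
    return RawSpotTable(
        array_id="a1",
        probe_ids=[f"s{i}" for i in range(n)],
        signal=signal,
        local_bg=local_bg,
        local_bg_sd=local_bg_sd,
        global_bg=global_bg,
        flags=np.array([FLAG_OK] * n, dtype=object),
    )


class TestFlagging:
    def test_signal_below_threshold_is_flagged(self):
        # S=100 < 90 + 1.5*10 = 105
        table = flag_low_signal(spot_table([100.0], [90.0], [10.0]), CFG)
        assert table.flags[0] == FLAG_LOW

    def test_signal_above_threshold_stays_ok(self):
        table = flag_low_signal(spot_table([200.0], [90.0], [10.0]), CFG)
        assert table.flags[0] == FLAG_OK

    def test_random_spots_match_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(0, 300, 1000)
        bl = rng.uniform(50, 150, 1000)
        sd = rng.uniform(1, 30, 1000)
        table = flag_low_signal(spot_table(s, bl, sd), CFG)
        for i in range(1000):
            expected = FLAG_LOW if s[i] < bl[i] + 1.5 * sd[i] else FLAG_OK
            assert table.flags[i] == expected


class TestBackgroundCorrection:
    def test_zero_offset_leaves_signals_unchanged(self):
        # median(B_L) == B_G -> offset 0
        table = spot_table([50.0, 80.0, 120.0], [100.0, 100.0, 100.0],
                           [5.0] * 3, global_bg=100.0)
        corrected = background_correct(table, CFG)
        np.testing.assert_array_equal(corrected.signal, [50.0, 80.0, 120.0])

    def test_hand_arithmetic_example(self):
        # S=50, median(B_L)=60, B_G=20 -> 50 - (60-20) = 10
        table = spot_table([50.0], [60.0], [5.0], global_bg=20.0)
        corrected = background_correct(table, CFG)
        assert corrected.signal[0] == 10.0

    def test_floor_clamps_random_table(self):
        rng = np.random.default_rng(1)
        table = spot_table(rng.uniform(0, 50, 200), rng.uniform(100, 200, 200),
                           rng.uniform(1, 10, 200), global_bg=20.0)
        corrected = background_correct(table, CFG)
        assert (corrected.signal >= CFG.floor).all()

    def test_local_mode_subtracts_per_spot_background(self):
        cfg = PreprocessConfig(background_mode="local")
        table = spot_table([150.0, 90.0], [100.0, 80.0], [5.0, 5.0])
        corrected = background_correct(table, cfg)
        np.testing.assert_array_equal(corrected.signal, [50.0, 10.0])

    def test_fully_flagged_array_rejected(self):
        table = spot_table([1.0], [100.0], [5.0])
        table.flags[0] = FLAG_LOW
        with pytest.raises(io.ValidationError, match="no unflagged"):
            background_correct(table, CFG)


class TestIntensityCutoff:
    def test_exact_threshold_retained(self):
        # corrected S exactly 2 x median(B_L): kept (inclusive boundary)
        table = spot_table([200.0, 100.0], [100.0, 100.0], [1.0, 1.0])
        out = apply_intensity_cutoff(table, CFG)
        assert out.flags[0] == FLAG_OK

    def test_below_threshold_flagged(self):
        table = spot_table([190.0, 100.0], [100.0, 100.0], [1.0, 1.0])
        out = apply_intensity_cutoff(table, CFG)
        assert out.flags[0] == FLAG_CUTOFF

    def test_survivor_count_matches_brute_force(self):
        rng = np.random.default_rng(2)
        s = rng.uniform(100, 400, 500)
        bl = rng.uniform(80, 120, 500)
        table = apply_intensity_cutoff(spot_table(s, bl, np.ones(500)), CFG)
        threshold = 2.0 * np.median(bl)
        assert (table.flags == FLAG_OK).sum() == int((s >= threshold).sum())


class TestGlobalMedianNormalize:
    def _study(self, values) -> io.ExpressionStudy:
        values = np.asarray(values, dtype=float)
        return io.ExpressionStudy(
            "p", [f"g{i}" for i in range(values.shape[0])], values,
            [f"s{j}" for j in range(values.shape[1])], io.SCALE_INTENSITY,
        )

    def test_simple_column(self):
        out = global_median_normalize(self._study([[2.0], [4.0], [8.0]]))
        np.testing.assert_allclose(out.values[:, 0], [0.5, 1.0, 2.0])

    def test_constant_column_becomes_ones(self):
        out = global_median_normalize(self._study([[3.0], [3.0], [3.0]]))
        np.testing.assert_array_equal(out.values[:, 0], [1.0, 1.0, 1.0])

    def test_random_column_median_is_one(self):
        rng = np.random.default_rng(3)
        out = global_median_normalize(self._study(rng.lognormal(2, 1, (101, 4))))
        np.testing.assert_allclose(np.median(out.values, axis=0), 1.0, atol=1e-12)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        values = rng.lognormal(2, 1, (51, 2))
        out1 = global_median_normalize(self._study(values))
        scaled = values.copy()
        scaled[:, 1] *= 7.3
        out2 = global_median_normalize(self._study(scaled))
        np.testing.assert_allclose(out1.values, out2.values, rtol=1e-12)

    def test_masked_entries_ignored_for_median_and_untouched(self):
        values = np.array([[2.0], [4.0], [8.0], [np.nan]])
        out = global_median_normalize(self._study(values))
        assert np.isnan(out.values[3, 0])
        np.testing.assert_allclose(out.values[:3, 0], [0.5, 1.0, 2.0])

    def test_log_ratio_scale_rejected(self):
        study = io.ExpressionStudy("p", ["g"], [[0.5]], ["s"], io.SCALE_LOG2RATIO)
        with pytest.raises(io.ValidationError, match="intensity"):
            global_median_normalize(study)


class TestLogRatios:
    def _setup(self, control_cols, tumor_cols):
        values = np.column_stack(control_cols + tumor_cols)
        study = io.ExpressionStudy(
            "p", [f"g{i}" for i in range(values.shape[0])], values,
            [f"c{j}" for j in range(len(control_cols))]
            + [f"t{j}" for j in range(len(tumor_cols))],
            io.SCALE_INTENSITY,
        )
        meta = [SampleMeta(f"c{j}", "p", CLS_CONTROL, "")
                for j in range(len(control_cols))]
        meta += [SampleMeta(f"t{j}", "p", CLS_TUMOR, "g1")
                 for j in range(len(tumor_cols))]
        return study, meta

    def test_tumor_equal_to_control_mean_gives_zero(self):
        # two genes, one control column; tumor column equals the control mean
        study, meta = self._setup([[4.0, 16.0]], [[4.0, 16.0]])
        ratios = compute_log_ratios(study, meta)
        np.testing.assert_allclose(ratios.log2_ratios[:, 0], 0.0)

    def test_doubling_gives_plus_one(self):
        study, meta = self._setup([[4.0]], [[8.0]])
        assert compute_log_ratios(study, meta).log2_ratios[0, 0] == 1.0

    def test_hand_arithmetic_example(self):
        # controls 4 and 16 -> mean 10; tumor 5 -> log2(0.5) = -1
        values = np.array([[4.0, 16.0, 5.0]])
        study = io.ExpressionStudy("p", ["g0"], values, ["c0", "c1", "t0"],
                                   io.SCALE_INTENSITY)
        meta = [SampleMeta("c0", "p", CLS_CONTROL, ""),
                SampleMeta("c1", "p", CLS_CONTROL, ""),
                SampleMeta("t0", "p", CLS_TUMOR, "g1")]
        assert compute_log_ratios(study, meta).log2_ratios[0, 0] == -1.0

    def test_no_controls_rejected(self):
        values = np.array([[1.0]])
        study = io.ExpressionStudy("p", ["g0"], values, ["t0"], io.SCALE_INTENSITY)
        meta = [SampleMeta("t0", "p", CLS_TUMOR, "g1")]
        with pytest.raises(io.ValidationError, match="no control"):
            compute_log_ratios(study, meta)

    def test_masked_and_nonpositive_operands_masked(self):
        values = np.array([[np.nan, 2.0, 4.0], [1.0, 1.0, 0.0]]).T  # 3 genes? no
        values = np.array([[2.0, np.nan], [2.0, 4.0], [2.0, 0.0]])
        study = io.ExpressionStudy("p", ["g0", "g1", "g2"], values,
                                   ["c0", "t0"], io.SCALE_INTENSITY)
        meta = [SampleMeta("c0", "p", CLS_CONTROL, ""),
                SampleMeta("t0", "p", CLS_TUMOR, "g1")]
        ratios = compute_log_ratios(study, meta)
        assert np.isnan(ratios.log2_ratios[0, 0])   # masked tumor
        assert ratios.log2_ratios[1, 0] == 1.0
        assert np.isnan(ratios.log2_ratios[2, 0])   # non-positive tumor

    def test_include_controls_keeps_all_columns(self):
        values = np.array([[4.0, 16.0, 5.0]])
        study = io.ExpressionStudy("p", ["g0"], values, ["c0", "c1", "t0"],
                                   io.SCALE_INTENSITY)
        meta = [SampleMeta("c0", "p", CLS_CONTROL, ""),
                SampleMeta("c1", "p", CLS_CONTROL, ""),
                SampleMeta("t0", "p", CLS_TUMOR, "g1")]
        ratios = compute_log_ratios(study, meta, include_controls=True)
        assert ratios.sample_ids == ["c0", "c1", "t0"]
        np.testing.assert_allclose(
            ratios.log2_ratios[0], np.log2(np.array([4.0, 16.0, 5.0]) / 10.0)
        )


class TestCollapseProbes:
    def test_median_collapse_per_gene(self):
        import pandas as pd

        ratios = RatioMatrix(
            gene_ids=["p1", "p2", "p3"],
            log2_ratios=np.array([[1.0], [3.0], [10.0]]),
            sample_ids=["t0"],
        )
        ann = io.GeneAnnotation(
            "p",
            pd.DataFrame({"probe_id": ["p1", "p2", "p3"],
                          "gene_id": [7, 7, 9],
                          "symbol": ["A", "A", "B"],
                          "chromosome": ["1", "1", "2"]}),
        )
        collapsed = collapse_probes(ratios, ann)
        frame = collapsed.to_frame()
        assert frame.loc[7, "t0"] == 2.0   # median of 1, 3
        assert frame.loc[9, "t0"] == 10.0
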