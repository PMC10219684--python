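"""Calcium trace features, ΔΔCT and ATP reductions against closed forms."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiomat.assays import (
    atp_normalize,
    ddct_relative_expression,
    extract_transients,
    normalize_trace,
    summarize_group,
)
from cardiomat.simulate import (
    SimulationConfig,
    TraceParams,
    simulate_assay_tables,
    simulate_traces,
)


def triangle_trace(dt=0.01):
    t = np.arange(0.0, 4.0, dt)
    y = np.interp(t, [0.0, 1.0, 2.0, 4.0], [0.0, 1.0, 0.0, 0.0])
    return t, y


class TestNormalizeTrace:
    def test_constant_trace_gives_zeros(self):
        t = np.arange(100) * 0.01
        dff, f0 = normalize_trace(t, np.full(100, 5.0))
        assert f0 == pytest.approx(5.0)
        assert np.allclose(dff, 0.0)

    @settings(deadline=None, max_examples=20)
    @given(st.floats(min_value=0.01, max_value=1e4))
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(0)
        t = np.arange(500) * 0.01
        f = 100.0 + 30.0 * np.exp(-(((t - 2.0) / 0.3) ** 2)) + rng.normal(0, 0.5, 500)
        d1, _ = normalize_trace(t, f)
        d2, _ = normalize_trace(t, c * f)
        assert np.allclose(d1, d2, atol=1e-9)

    def test_recovers_generator_baseline_within_one_percent(self):
        cfg = SimulationConfig(seed=17, trace_params=TraceParams(noise_sd=0.0))
        traces, _ = simulate_traces(cfg, n_videos=1, n_cells=1)
        _, f0 = normalize_trace(traces["time_s"].to_numpy(), traces["intensity"].to_numpy())
        assert abs(f0 - 100.0) / 100.0 < 0.01

    def test_nonpositive_baseline_rejected(self):
        t = np.arange(100) * 0.01
        with pytest.raises(ValueError, match="non-positive"):
            normalize_trace(t, np.linspace(-5, -1, 100), detrend=False)


class TestExtractTransients:
    def test_triangle_closed_form(self):
        t, y = triangle_trace()
        f = extract_transients(t, y, min_prominence=0.2)
        assert f.n_transients == 1
        assert f.peak_amplitude == pytest.approx(1.0, abs=1e-9)
        assert f.fwhm == pytest.approx(1.0, abs=0.01)
        assert f.rise_time == pytest.approx(0.8, abs=0.01)
        assert f.decay_time == pytest.approx(0.8, abs=0.01)

    def test_exponential_decay_closed_form(self):
        tau = 0.5
        t = np.arange(0.0, 8.0, 0.01)
        y = np.where(t >= 1.0, np.exp(-(t - 1.0) / tau), 0.0)
        f = extract_transients(t, y, min_prominence=0.2)
        assert f.decay_time == pytest.approx(tau * math.log(9.0), abs=0.01)

    def test_flat_trace_has_no_transients(self):
        t = np.arange(200) * 0.01
        f = extract_transients(t, np.zeros(200), min_prominence=0.1)
        assert f.n_transients == 0
        assert math.isnan(f.peak_amplitude)

    def test_noiseless_kernel_matches_closed_form_tightly(self):
        # high sampling rate so linear interpolation error is negligible
        tp = TraceParams(noise_sd=0.0, sampling_rate=5000.0, duration=4.0,
                         first_beat=1.0, beat_period=10.0)
        cfg = SimulationConfig(seed=0, trace_params=tp)
        traces, truth = simulate_traces(cfg, n_videos=1, n_cells=1)
        tf = truth.extras["trace_features"]["default"]
        dff, _ = normalize_trace(
            traces["time_s"].to_numpy(), traces["intensity"].to_numpy(), detrend=False
        )
        f = extract_transients(traces["time_s"].to_numpy(), dff)
        assert f.peak_amplitude == pytest.approx(tf["peak_amplitude"], abs=1e-6)
        assert f.fwhm == pytest.approx(tf["fwhm"], abs=1e-6)
        assert f.rise_time == pytest.approx(tf["rise_time"], abs=1e-6)
        assert f.decay_time == pytest.approx(tf["decay_time"], abs=1e-6)

    def test_noisy_generator_traces_recover_truth(self):
        cfg = SimulationConfig(seed=23)
        tp = cfg.trace_params
        traces, truth = simulate_traces(cfg, n_videos=4, n_cells=5)
        tf = truth.extras["trace_features"]["default"]
        dt = 1.0 / tp.sampling_rate
        n_ok = 0
        cells = traces.groupby("cell_id")
        for _, grp in cells:
            dff, _ = normalize_trace(grp["time_s"].to_numpy(), grp["intensity"].to_numpy())
            f = extract_transients(grp["time_s"].to_numpy(), dff)
            ok = (
                abs(f.peak_amplitude - tf["peak_amplitude"]) <= 2 * tp.noise_sd
                and abs(f.fwhm - tf["fwhm"]) <= dt
                and abs(f.rise_time - tf["rise_time"]) <= dt
                and abs(f.decay_time - tf["decay_time"]) <= dt
            )
            n_ok += ok
        assert n_ok >= 0.95 * cells.ngroups


class TestSummarizeGroup:
    @staticmethod
    def features_table(values, condition="c", video="v1"):
        return pd.DataFrame(
            {
                "condition": condition,
                "video_id": video,
                "cell_id": [f"{video}_c{i}" for i in range(len(values))],
                "peak_amplitude": values,
            }
        )

    def test_single_cell_video_mean_is_that_cell(self):
        feats = self.features_table([2.5])
        per_video, per_cond = summarize_group(feats, cells_per_video=5, seed=0)
        assert per_video["peak_amplitude"].iloc[0] == 2.5
        assert per_cond["peak_amplitude"].iloc[0] == 2.5

    def test_identical_cells_give_zero_sem(self):
        feats = pd.concat(
            [self.features_table([1.0] * 4, video=f"v{i}") for i in range(3)],
            ignore_index=True,
        )
        _, per_cond = summarize_group(feats, cells_per_video=3, seed=1)
        assert per_cond["peak_amplitude_sem"].iloc[0] == 0.0

    def test_sampled_subsets_match_exhaustive_enumeration(self):
        values = [1.0, 2.0, 4.0, 8.0, 16.0, 32.0]
        feats = self.features_table(values)
        expected_means = {
            round(np.mean(sub), 9) for sub in itertools.combinations(values, 5)
        }
        seen = set()
        for seed in range(60):
            per_video, _ = summarize_group(feats, cells_per_video=5, seed=seed)
            m = round(float(per_video["peak_amplitude"].iloc[0]), 9)
            assert m in expected_means
            seen.add(m)
        assert len(seen) > 1  # the seed actually varies the subset

    def test_empty_features_rejected(self):
        with pytest.raises(ValueError):
            summarize_group(self.features_table([]).iloc[0:0], 5, 0)


class TestDdct:
    @staticmethod
    def ct_table(rows, samples):
        return pd.DataFrame(rows, index=pd.Index(list(rows.keys()), name="gene"), columns=samples).astype(float) if isinstance(rows, dict) else rows

    def test_identical_samples_give_unity(self):
        samples = ["r1", "r2", "t1", "t2"]
        ct = pd.DataFrame(
            {s: [20.0, 25.0] for s in samples}, index=pd.Index(["DDB1", "TNNT2"], name="gene")
        )
        design = pd.DataFrame({"group": ["ref", "ref", "trt", "trt"]}, index=samples)
        rel = ddct_relative_expression(ct, design, "DDB1", "ref")
        assert np.allclose(rel.to_numpy(), 1.0)

    def test_two_cycle_advantage_gives_four_fold(self):
        samples = ["r1", "t1"]
        # ΔCt reference = 7, ΔCt treated = 5 → ΔΔCt = −2 → 4.0
        ct = pd.DataFrame(
            {"r1": [20.0, 27.0], "t1": [20.0, 25.0]},
            index=pd.Index(["DDB1", "GENE"], name="gene"),
        )
        design = pd.DataFrame({"group": ["ref", "trt"]}, index=samples)
        rel = ddct_relative_expression(ct, design, "DDB1", "ref")
        assert rel.loc["GENE", "t1"] == pytest.approx(4.0)
        assert rel.loc["GENE", "r1"] == pytest.approx(1.0)

    @settings(deadline=None, max_examples=20)
    @given(st.floats(min_value=-5, max_value=5))
    def test_global_ct_shift_invariance(self, shift):
        samples = ["r1", "r2", "t1", "t2"]
        rng = np.random.default_rng(3)
        ct = pd.DataFrame(
            rng.uniform(18, 30, (3, 4)),
            index=pd.Index(["DDB1", "A", "B"], name="gene"),
            columns=samples,
        )
        design = pd.DataFrame({"group": ["ref", "ref", "trt", "trt"]}, index=samples)
        r1 = ddct_relative_expression(ct, design, "DDB1", "ref")
        r2 = ddct_relative_expression(ct + shift, design, "DDB1", "ref")
        pd.testing.assert_frame_equal(r1, r2)

    def test_missing_housekeeping_rejected(self):
        ct = pd.DataFrame({"s1": [20.0], "s2": [21.0]}, index=pd.Index(["A"], name="gene"))
        design = pd.DataFrame({"group": ["ref", "trt"]}, index=["s1", "s2"])
        with pytest.raises(ValueError, match="housekeeping"):
            ddct_relative_expression(ct, design, "DDB1", "ref")

    def test_roundtrip_from_generator(self):
        cfg = SimulationConfig(seed=31)
        ct, _, truth = simulate_assay_tables(cfg, ct_noise_sd=0.0)
        rel = ddct_relative_expression(
            ct, truth.extras["ct_design"], "DDB1", "control"
        )
        treated = [c for c in rel.columns if c.startswith("treated")]
        for gene, fold in truth.extras["relative_expression_truth"].items():
            assert rel.loc[gene, treated].mean() == pytest.approx(fold, rel=1e-9)


class TestAtp:
    @staticmethod
    def plate(rows):
        return pd.DataFrame(rows, columns=["group", "luminescence", "absorbance_595", "replicate"])

    def test_control_only_is_unity(self):
        plate = self.plate([("mCherry", 800.0, 0.5, r) for r in range(3)])
        out = atp_normalize(plate)
        assert out.loc["mCherry", "normalized_atp"] == pytest.approx(1.0)

    def test_ratio_arithmetic(self):
        plate = self.plate(
            [("mCherry", 800.0, 0.5, 1), ("treated", 1000.0, 0.5, 1)]
        )
        out = atp_normalize(plate)
        assert out.loc["treated", "normalized_atp"] == pytest.approx(1.25)

    def test_absorbance_rescale_invariance(self):
        rows = [("mCherry", 800.0, 0.4, 1), ("mCherry", 820.0, 0.5, 2), ("trt", 990.0, 0.45, 1)]
        p1 = self.plate(rows)
        p2 = self.plate([(g, lum, 2 * ab, r) for g, lum, ab, r in rows])
        o1, o2 = atp_normalize(p1), atp_normalize(p2)
        pd.testing.assert_series_equal(o1["normalized_atp"], o2["normalized_atp"])

    def test_nonpositive_absorbance_rejected(self):
        with pytest.raises(ValueError, match="absorbance"):
            atp_normalize(self.plate([("mCherry", 800.0, 0.0, 1)]))
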