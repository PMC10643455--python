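"""Free-exponent peak model: evaluation, fitting, saturation rescue, fractions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from phycokit import chromatogram as ch
from phycokit import synth
from phycokit.chromatogram import ChromTrace, NamedPeak, PeakModelParams


class TestEvalPeakModel:
    def test_peak_height(self):
        p = PeakModelParams(A=np.pi, gamma=2.0, a=0.0, eps=0.0)
        assert ch.eval_peak_model(p, 0.0) == pytest.approx(1.0, abs=1e-12)

    def test_unit_area_lorentzian(self):
        p = PeakModelParams(A=1.0, gamma=1.0, a=5.0, eps=0.0)
        area, _ = integrate.quad(lambda x: ch.eval_peak_model(p, x), -np.inf, np.inf)
        assert area == pytest.approx(1.0, abs=1e-6)

    def test_free_exponent_point_value(self):
        p = PeakModelParams(A=1.0, gamma=1.0, a=0.0, eps=1.0)
        assert ch.eval_peak_model(p, 1.0) == pytest.approx((0.5 / 1.25) / np.pi,
                                                           abs=1e-9)

    @given(
        d=st.floats(0.0, 50.0),
        gamma=st.floats(0.1, 10.0),
        eps=st.floats(-0.9, 2.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetric_about_position(self, d, gamma, eps):
        p = PeakModelParams(A=2.0, gamma=gamma, a=7.0, eps=eps)
        left, right = ch.eval_peak_model(p, [7.0 - d, 7.0 + d])
        assert left == pytest.approx(right, rel=1e-12)

    @given(scale=st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_linear_in_height_scaling(self, scale):
        x = np.linspace(0, 20, 101)
        base = ch.eval_peak_model(PeakModelParams(1.0, 2.0, 10.0, 0.5), x)
        scaled = ch.eval_peak_model(PeakModelParams(scale, 2.0, 10.0, 0.5), x)
        assert np.allclose(scaled, scale * base, rtol=1e-12)

    def test_invalid_params_rejected(self):
        for bad in [dict(A=-1, gamma=1, a=0, eps=0), dict(A=1, gamma=0, a=0, eps=0),
                    dict(A=1, gamma=1, a=0, eps=-2.5)]:
            with pytest.raises(ValueError):
                PeakModelParams(**bad)


class TestFitPeak:
    def test_noiseless_self_consistency(self):
        x = np.arange(5.0, 15.0, 0.02)
        true = PeakModelParams(A=2.0, gamma=0.5, a=10.0, eps=0.2)
        res = ch.PeakModel(x, ch.eval_peak_model(true, x)).fit()
        for got, want in [(res.params.A, 2.0), (res.params.gamma, 0.5),
                          (res.params.a, 10.0), (res.params.eps, 0.2)]:
            assert abs(got - want) / want < 1e-4

    def test_noisy_recovery_rate(self):
        # dense sampling: the tail exponent is weakly identified and needs it
        x = np.arange(0.0, 20.0, 0.002)
        true = PeakModelParams(A=2.0, gamma=0.5, a=10.0, eps=0.2)
        clean = ch.eval_peak_model(true, x)
        height = clean.max()
        rng = np.random.default_rng(11)
        hits = 0
        n = 20
        for _ in range(n):
            y = clean + rng.normal(0, 0.01 * height, x.size)
            res = ch.PeakModel(x, y, fit_baseline=False).fit()
            ok = all(
                abs(got - want) / want < 0.05
                for got, want in [(res.params.A, 2.0), (res.params.gamma, 0.5),
                                  (res.params.a, 10.0), (res.params.eps, 0.2)]
            )
            hits += ok
        assert hits >= 0.9 * n

    def test_window_too_small(self):
        with pytest.raises(ValueError, match="8 samples"):
            ch.PeakModel(np.arange(5), np.arange(5))


class TestSaturationRescue:
    def _trace(self, clip=None, seed=0):
        rng = np.random.default_rng(seed)
        x = np.arange(0.0, 40.0, 0.02)
        p = PeakModelParams(A=30.0, gamma=3.0, a=20.0, eps=0.1)
        clean = ch.eval_peak_model(p, x)
        y560 = clean + rng.normal(0, 0.01, x.size)
        if clip is not None:
            y560 = np.minimum(y560, clip * clean.max())
        y280 = 2.0 * clean + rng.normal(0, 0.01, x.size)
        return ChromTrace(x, {560: y560, 280: y280}), p, clean

    def test_clipped_peak_area_recovered(self):
        trace, p, clean = self._trace(clip=0.9)
        fixed = ch.rescale_saturated_channel(trace, (5.0, 14.0))
        res = ch.fit_peak(fixed, 560, (10.0, 30.0))
        truth, _ = integrate.quad(lambda v: ch.eval_peak_model(p, v), 10.0, 30.0)
        assert abs(res.area - truth) / truth < 0.03
        assert fixed.meta["n_saturated"] > 0
        assert fixed.meta["saturation_scale"] == pytest.approx(0.5, rel=0.05)

    def test_unclipped_trace_unchanged(self):
        trace, _, _ = self._trace(clip=None)
        fixed = ch.rescale_saturated_channel(trace, (5.0, 14.0))
        assert np.array_equal(fixed.channels[560], trace.channels[560])
        assert fixed.meta["n_saturated"] == 0

    def test_zero_reference_channel_errors(self):
        x = np.arange(0.0, 10.0, 0.1)
        trace = ChromTrace(x, {560: np.ones_like(x), 280: np.zeros_like(x)})
        with pytest.raises(ValueError):
            ch.rescale_saturated_channel(trace, (0.0, 10.0))

    def test_tiny_linear_region_errors(self):
        trace, _, _ = self._trace()
        with pytest.raises(ValueError, match="4"):
            ch.rescale_saturated_channel(trace, (5.0, 5.05))


class TestSpectrotypeFractions:
    def _pair(self):
        x = np.arange(0.0, 100.0, 0.02)
        pink = np.zeros_like(x)
        for A, a in [(3.0, 25.0), (1.0, 75.0)]:
            pink += ch.eval_peak_model(PeakModelParams(A, 0.5, a, 0.0), x)
        purple = ch.eval_peak_model(PeakModelParams(8.0 / 7.0, 0.5, 50.0, 0.0), x)
        return (
            ChromTrace(x, {560: pink}, "pink"),
            ChromTrace(x, {560: purple}, "purple"),
        )

    NAMED = [
        NamedPeak("p1", "pink", (5.0, 45.0), "S1"),
        NamedPeak("p2", "pink", (55.0, 95.0), "S2"),
        NamedPeak("q1", "purple", (30.0, 70.0), "S3"),
    ]

    def test_arithmetic_oracle(self):
        pink, purple = self._pair()
        table = ch.spectrotype_fractions(pink, purple, self.NAMED)
        got = dict(zip(table.peaks["name"], table.peaks["fraction_of_total"]))
        # areas 3 : 1 : purple 8/7 * 7/8 = 1 -> fractions 0.6, 0.2, 0.2
        assert got["p1"] == pytest.approx(0.6, abs=0.01)
        assert got["p2"] == pytest.approx(0.2, abs=0.01)
        assert got["q1"] == pytest.approx(0.2, abs=0.01)

    def test_purple_seven_eighths_scaling(self):
        pink, purple = self._pair()
        table = ch.spectrotype_fractions(pink, purple, self.NAMED)
        purple_row = table.peaks[table.peaks["name"] == "q1"].iloc[0]
        raw_area, _ = integrate.quad(
            lambda v: ch.eval_peak_model(
                PeakModelParams(8.0 / 7.0, 0.5, 50.0, 0.0), v), 30.0, 70.0)
        assert purple_row["area_560"] == pytest.approx(7.0 / 8.0 * raw_area, rel=1e-3)

    def test_fraction_conservation(self):
        pink, purple = self._pair()
        table = ch.spectrotype_fractions(pink, purple, self.NAMED)
        total = table.peaks["fraction_of_total"].sum() + table.residual_fraction
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_overlapping_windows_rejected(self):
        pink, purple = self._pair()
        bad = self.NAMED + [NamedPeak("p3", "pink", (40.0, 60.0))]
        with pytest.raises(ValueError, match="overlap"):
            ch.spectrotype_fractions(pink, purple, bad)


class TestTraceIO:
    def test_wide_roundtrip(self, tmp_path):
        x = np.arange(0.0, 5.0, 0.5)
        trace = ChromTrace(x, {560: np.sin(x) + 2, 280: np.cos(x) + 2})
        path = tmp_path / "trace.tsv"
        ch.write_trace(trace, path)
        back = ch.read_trace(path)
        assert np.allclose(back.volume, x)
        assert set(back.channels) == {280, 560}
        assert np.allclose(back.channels[560], trace.channels[560])

    def test_long_layout(self, tmp_path):
        path = tmp_path / "long.csv"
        rows = ["volume,channel,value"]
        for v in (0.0, 1.0, 2.0):
            rows += [f"{v},560,{v * 2}", f"{v},280,{v * 3}"]
        path.write_text("\n".join(rows))
        trace = ch.read_trace(path)
        assert np.allclose(trace.channels[560], [0, 2, 4])
        assert np.allclose(trace.channels[280], [0, 3, 6])

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            ChromTrace(np.array([0.0, 0.0, 1.0]), {560: np.zeros(3)})


def test_scenario_end_to_end_recovers_truth(antenna):
    pink, purple, truth = synth.gen_chromatogram(
        antenna["peaks"], volume=antenna["volume"],
        saturation_level=antenna["saturation_level"], seed=2,
    )
    pink = ch.rescale_saturated_channel(pink, antenna["linear_region"]["pink"])
    purple = ch.rescale_saturated_channel(purple, antenna["linear_region"]["purple"])
    table = ch.spectrotype_fractions(pink, purple, antenna["named_peaks"])
    tp = {p["name"]: p for p in truth["peaks"] if "fraction_of_total" in p}
    for _, row in table.peaks.iterrows():
        assert row["fraction_of_total"] == pytest.approx(
            tp[row["name"]]["fraction_of_total"], abs=0.03
        )
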