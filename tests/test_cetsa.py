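"""CETSA densitometry: normalization, apparent Tm50, in-situ delta-Tm."""

import numpy as np
import pytest

from meltshift import (
    DensitometryCurve,
    Tm50Undefined,
    analyze_cetsa_table,
    apparent_tm50,
    cetsa_delta_tm,
    fraction_folded,
    normalize_bands,
    simulate_cetsa,
)

DENSE = np.arange(40.0, 70.1, 1.0)


def curve(temps, intensities, cond="vehicle", rep=1, name="LSS"):
    return DensitometryCurve(name, cond, np.asarray(temps, float),
                             np.asarray(intensities, float), rep)


class TestNormalizeBands:
    def test_divides_by_first_band(self):
        c = curve([40, 45, 50, 55], [100, 80, 50, 20])
        np.testing.assert_allclose(normalize_bands(c), [1.0, 0.8, 0.5, 0.2])

    def test_already_normalized_unchanged(self):
        c = curve([40, 45, 50, 55], [1.0, 0.8, 0.5, 0.2])
        np.testing.assert_allclose(normalize_bands(c), [1.0, 0.8, 0.5, 0.2])

    def test_zero_reference_raises(self):
        c = curve([40, 45, 50, 55], [0.0, 80, 50, 20])
        with pytest.raises(ValueError, match="reference"):
            normalize_bands(c)

    def test_series_shape_validated(self):
        with pytest.raises(ValueError, match="increasing"):
            curve([40, 50, 45, 55], [1, 2, 3, 4])
        with pytest.raises(ValueError, match="4 temperatures"):
            curve([40, 45, 50], [1, 2, 3])


class TestApparentTm50:
    def test_linear_midpoint(self):
        # 0.6 at 50 and 0.4 at 55 bracket 0.5 -> 52.5 by interpolation
        c = curve([45, 50, 55, 60], [1.0, 0.6, 0.4, 0.2])
        assert apparent_tm50(c, method="interpolate") == pytest.approx(52.5)

    def test_fit_and_interpolate_agree_on_dense_clean_curve(self):
        y = fraction_folded(DENSE, -0.6, 53.0, 0.0)
        c = curve(DENSE, y)
        tm_fit = apparent_tm50(c, method="fit")
        tm_int = apparent_tm50(c, method="interpolate")
        assert tm_fit == pytest.approx(53.0, abs=0.05)
        assert tm_int == pytest.approx(53.0, abs=0.05)
        assert abs(tm_fit - tm_int) < 1.0

    def test_no_crossing(self):
        c = curve([45, 50, 55, 60], [1.0, 0.8, 0.65, 0.55])
        with pytest.raises(Tm50Undefined, match="no_crossing"):
            apparent_tm50(c, method="interpolate")

    def test_scale_invariance_of_interpolated_tm50(self):
        temps = [44, 48, 52, 56, 60]
        raw = np.array([900.0, 700.0, 420.0, 220.0, 90.0])
        t1 = apparent_tm50(curve(temps, raw), method="interpolate")
        t2 = apparent_tm50(curve(temps, raw * 37.5), method="interpolate")
        assert t1 == pytest.approx(t2, abs=1e-12)

    def test_auto_uses_interpolation_for_coarse_series(self):
        c = curve([45, 50, 55, 60], [1.0, 0.6, 0.4, 0.2])
        assert apparent_tm50(c, method="auto") == pytest.approx(52.5)


class TestCetsaDeltaTm:
    def test_in_situ_shift_of_5_degrees(self):
        # Tm50 50 degC in vehicle, 55 degC after treatment -> dTm = +5
        ctrl, trt = simulate_cetsa(50.0, 5.0, a=-0.8, p=0.0,
                                   temperatures=DENSE, noise_cv=0.0)
        res = cetsa_delta_tm(ctrl, trt)
        assert res["tm_control"] == pytest.approx(50.0, abs=0.05)
        assert res["tm_treated"] == pytest.approx(55.0, abs=0.05)
        assert res["delta_tm"] == pytest.approx(5.0, abs=0.1)

    def test_in_situ_shift_of_8_degrees(self):
        ctrl, trt = simulate_cetsa(56.0, 8.0, a=-0.8, p=0.0,
                                   temperatures=DENSE, noise_cv=0.0)
        res = cetsa_delta_tm(ctrl, trt)
        assert res["tm_control"] == pytest.approx(56.0, abs=0.05)
        assert res["tm_treated"] == pytest.approx(64.0, abs=0.05)
        assert res["delta_tm"] == pytest.approx(8.0, abs=0.1)

    def test_identical_conditions_zero_shift(self):
        ctrl, trt = simulate_cetsa(52.0, 0.0, temperatures=DENSE, noise_cv=0.0)
        res = cetsa_delta_tm(ctrl, trt)
        assert res["delta_tm"] == pytest.approx(0.0, abs=1e-9)

    def test_replicates_give_paired_t_test(self):
        ctrls, trts = [], []
        for rep in range(1, 4):
            c, t = simulate_cetsa(50.0, 5.0, temperatures=DENSE,
                                  noise_cv=0.02, seed=rep, replicate=rep)
            ctrls.append(c)
            trts.append(t)
        res = cetsa_delta_tm(ctrls, trts)
        assert res["n_replicates"] == 3
        assert res["p_value"] is not None and res["p_value"] < 0.05
        assert res["delta_tm"] == pytest.approx(5.0, abs=0.5)

    def test_recovery_within_half_degree_on_dense_noisy_grids(self):
        # known shift, mild noise, >= 8-point grid, triplicate assay
        grid = np.arange(42.0, 64.1, 2.0)
        for seed in range(5):
            ctrls, trts = [], []
            for rep in range(3):
                c, t = simulate_cetsa(51.0, 3.0, a=-0.7, p=0.05, temperatures=grid,
                                      noise_cv=0.05, seed=seed * 10 + rep,
                                      replicate=rep + 1)
                ctrls.append(c)
                trts.append(t)
            res = cetsa_delta_tm(ctrls, trts)
            assert res["delta_tm"] == pytest.approx(3.0, abs=0.5)

    def test_undefined_tm50_propagates(self):
        flat = curve([45, 50, 55, 60], [1.0, 0.95, 0.9, 0.85])
        ctrl, _ = simulate_cetsa(50.0, 5.0, temperatures=DENSE, noise_cv=0.0)
        with pytest.raises(Tm50Undefined):
            cetsa_delta_tm(ctrl, flat)


class TestAnalyzeTable:
    def test_per_target_results(self):
        import pandas as pd

        rows = []
        for name, tm_c, d in (("LSS", 50.0, 5.0), ("CYP51A1", 56.0, 8.0)):
            ctrl, trt = simulate_cetsa(tm_c, d, temperatures=DENSE, noise_cv=0.0,
                                       target_name=name)
            for c in (ctrl, trt):
                for T, y in zip(c.temperatures, c.intensities):
                    rows.append((name, c.condition, 1, T, y))
        df = pd.DataFrame(
            rows,
            columns=["target_name", "condition", "replicate", "temperature_c", "band_intensity"],
        )
        res = analyze_cetsa_table(df).set_index("target_name")
        assert res.loc["LSS", "delta_tm"] == pytest.approx(5.0, abs=0.1)
        assert res.loc["CYP51A1", "delta_tm"] == pytest.approx(8.0, abs=0.1)
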