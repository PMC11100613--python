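"""Growth, flux, PK, plate-kinetics, and tumor-volume estimation."""

import math

import numpy as np
import pandas as pd
import pytest

from metamech.kinetics import (
    FMOL_TO_UMOL,
    FluxEstimate,
    TimeCourse,
    bh_adjust,
    biolog_compare,
    biolog_initial_rate,
    endpoint_test,
    exoflux,
    fit_growth,
    flux_fold_and_stoichiometry,
    pk_fit,
    tumor_volume,
    welch_t,
)
from metamech.synthetic import generate_plate_trace

from conftest import make_timecourse


# ---------------------------------------------------------------------------
# shared statistics helpers
# ---------------------------------------------------------------------------

def test_welch_by_hand_example():
    t, p, note = welch_t([100, 110, 90], [300, 310, 290])
    assert t == pytest.approx(-24.49489742783178)
    assert p == pytest.approx(1.6483088987181242e-05)
    assert p < 0.01
    assert note == ""


def test_welch_identical_constant_groups():
    t, p, note = welch_t([5.0, 5.0], [5.0, 5.0])
    assert (t, p) == (0.0, 1.0)
    assert "identical" in note


def test_welch_different_constant_groups_capped():
    t, p, note = welch_t([5.0, 5.0], [6.0, 6.0])
    assert abs(t) == 1e6 and p == 0.0
    assert "capped" in note


def test_welch_needs_two_per_group():
    with pytest.raises(ValueError):
        welch_t([1.0], [2.0, 3.0])


def test_bh_adjust_hand_example():
    # p = (0.01, 0.02, 0.03, 0.04): step-up maxima all equal 0.04.
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])


def test_bh_adjust_dominates_p():
    p = np.array([0.001, 0.2, 0.04, 0.9, 0.05])
    q = bh_adjust(p)
    assert np.all(q >= p - 1e-15) and np.all(q <= 1.0)


# ---------------------------------------------------------------------------
# growth fitting
# ---------------------------------------------------------------------------

def test_growth_doubling_every_24h():
    times = np.array([0.0, 24.0, 48.0, 72.0])
    counts = 1e6 * 2.0 ** (times / 24.0)
    fit = fit_growth(make_timecourse(times, counts, "cell_count"))
    assert fit.mu == pytest.approx(math.log(2) / 24.0)  # 0.028881 1/h
    assert fit.n0_fit == pytest.approx(1e6, rel=1e-9)
    assert fit.r_squared == pytest.approx(1.0)


def test_growth_constant_counts():
    fit = fit_growth(make_timecourse([0, 12, 24], [1e6, 1e6, 1e6], "cell_count"))
    assert fit.mu == pytest.approx(0.0, abs=1e-12)


def test_growth_rejects_nonpositive_counts():
    with pytest.raises(ValueError):
        fit_growth(make_timecourse([0, 12, 24], [1e6, 0.0, 1e6], "cell_count"))


# ---------------------------------------------------------------------------
# exometabolomic flux
# ---------------------------------------------------------------------------

def _medium(mu, J, m0=50.0, sign=-1.0, t_end=24.0, n0=1e6):
    times = np.array([0.0, t_end])
    integral = times if mu == 0 else (np.exp(mu * times) - 1.0) / mu
    values = m0 + sign * J * n0 * integral * FMOL_TO_UMOL
    return make_timecourse(times, values, "medium_amount")


def test_exoflux_closed_form_inversion():
    # mu = ln2/24, J = 100 fmol/cell/h over 24 h consumes 3.4625 umol.
    mu = math.log(2) / 24.0
    tc = _medium(mu, 100.0)
    delta = 50.0 - tc.data["value"].iloc[-1]
    assert delta == pytest.approx(3.4624680981335128)
    est = exoflux(tc, mu, 1e6, "consumption")
    assert est.J == pytest.approx(100.0, rel=1e-12)
    assert not est.direction_warning


def test_exoflux_zero_growth_linear_limit():
    tc = _medium(0.0, 100.0)
    est = exoflux(tc, 0.0, 1e6, "consumption")
    assert est.J == pytest.approx(100.0, rel=1e-12)


def test_exoflux_secretion_direction():
    tc = _medium(math.log(2) / 24.0, 200.0, m0=0.0, sign=+1.0)
    est = exoflux(tc, math.log(2) / 24.0, 1e6, "secretion")
    assert est.J == pytest.approx(200.0, rel=1e-12)


def test_exoflux_regression_method_matches_endpoint_noise_free():
    mu = math.log(2) / 24.0
    times = np.array([0.0, 6.0, 12.0, 18.0, 24.0])
    integral = (np.exp(mu * times) - 1.0) / mu
    values = 50.0 - 100.0 * 1e6 * integral * FMOL_TO_UMOL
    tc = make_timecourse(times, values, "medium_amount")
    a = exoflux(tc, mu, 1e6, "consumption", method="endpoint")
    b = exoflux(tc, mu, 1e6, "consumption", method="regression")
    assert a.J == pytest.approx(b.J, rel=1e-9)


def test_exoflux_direction_mismatch_warns():
    tc = _medium(0.0, 100.0, m0=50.0, sign=+1.0)  # medium rising
    with pytest.warns(UserWarning, match="opposite"):
        est = exoflux(tc, 0.0, 1e6, "consumption")
    assert est.J < 0 and est.direction_warning


def test_exoflux_rejects_negative_growth():
    with pytest.raises(ValueError):
        exoflux(_medium(0.0, 100.0), -0.1, 1e6, "consumption")


def _est(J):
    return FluxEstimate(J=J, se=0.0, mu_used=0.0, method="endpoint",
                        direction="consumption")


def test_flux_fold_and_stoichiometry_example():
    comp = flux_fold_and_stoichiometry(
        _est(900.0), _est(100.0), _est(1694.1), _est(94.1))
    assert comp.fold_glc == pytest.approx(9.0)
    assert comp.fold_lac == pytest.approx(18.00318809776833)
    assert comp.delta_ratio == pytest.approx(2.0)
    assert comp.suppressed_reason is None


def test_stoichiometry_suppressed_when_unresolved():
    comp = flux_fold_and_stoichiometry(
        _est(100.0), _est(100.0), _est(200.0), _est(94.1))
    assert comp.delta_ratio is None
    assert "not resolved" in comp.suppressed_reason


# ---------------------------------------------------------------------------
# pharmacokinetics
# ---------------------------------------------------------------------------

def test_pk_exact_halving():
    fit = pk_fit(make_timecourse([0, 48, 96], [2.0, 1.0, 0.5], "concentration"))
    assert fit.t_half == pytest.approx(48.0)
    assert fit.c_first == pytest.approx(2.0)
    assert fit.r_squared == pytest.approx(1.0)


def test_pk_c_first_is_at_first_sampled_time():
    # 9.2 uM at 15 min with t_half 48: c_first must be 9.2, not the t=0 value.
    times = np.array([15.0, 63.0, 111.0])
    conc = 9.2 * 2.0 ** (-(times - 15.0) / 48.0)
    fit = pk_fit(make_timecourse(times, conc, "concentration"))
    assert fit.c_first == pytest.approx(9.2)
    assert fit.t_half == pytest.approx(48.0)


def test_pk_no_elimination():
    fit = pk_fit(make_timecourse([15, 60, 120], [1.0, 1.0, 1.0], "concentration"))
    assert fit.t_half is None and fit.k is None
    assert fit.message == "no measurable elimination"


def test_pk_time_unit_consistency():
    # Rescaling time by 60 (min -> h) rescales the half-life identically.
    times = np.array([15.0, 63.0, 111.0])
    conc = 9.2 * 2.0 ** (-(times - 15.0) / 48.0)
    by_min = pk_fit(make_timecourse(times, conc, "concentration"))
    by_h = pk_fit(make_timecourse(times / 60.0, conc, "concentration"))
    assert by_h.t_half == pytest.approx(by_min.t_half / 60.0)


def test_pk_rejects_nonpositive_concentration():
    with pytest.raises(ValueError):
        pk_fit(make_timecourse([0, 10, 20], [1.0, 0.0, 0.5], "concentration"))


# ---------------------------------------------------------------------------
# plate kinetics
# ---------------------------------------------------------------------------

def test_initial_rate_pure_linear_trace():
    times = np.arange(0, 61, 5, dtype=float)
    a590 = make_timecourse(times, 0.05 + 0.02 * times, "absorbance590")
    a750 = make_timecourse(times, np.zeros_like(times), "absorbance750")
    res = biolog_initial_rate(a590, a750)
    assert res.rate == pytest.approx(0.02)
    assert res.window_points == 12      # ties go to more points
    assert not res.quality_flag


def test_initial_rate_flat_trace_is_zero():
    times = np.arange(0, 61, 5, dtype=float)
    a590 = make_timecourse(times, np.full_like(times, 0.05), "absorbance590")
    a750 = make_timecourse(times, np.zeros_like(times), "absorbance750")
    res = biolog_initial_rate(a590, a750)
    assert res.rate == pytest.approx(0.0, abs=1e-12)
    assert not res.quality_flag


def test_initial_rate_background_subtraction_removes_drift():
    # Shared drift lives in both channels; the estimate must ignore it.
    times = np.arange(0, 6.0, 0.5)
    no_drift, _ = generate_plate_trace(0.02, 1.0, times=times, drift=0.0)
    a590, a750 = generate_plate_trace(0.02, 1.0, times=times, drift=5e-3)
    res = biolog_initial_rate(a590, a750)
    flat750 = generate_plate_trace(0.0, 1.0, times=times, drift=0.0,
                                   baseline=0.05 / 0.6)[1]
    res_clean = biolog_initial_rate(no_drift, flat750)
    assert res.rate == pytest.approx(res_clean.rate, rel=1e-9)
    assert res.rate == pytest.approx(0.02, rel=0.1)


def test_initial_rate_recovery_early_phase():
    # Noise-free saturating trace sampled at 0.5 min over the early phase:
    # the windowed slope recovers the true initial rate within 10% (the
    # exponential's curvature makes coarser sampling biased low).
    a590, a750 = generate_plate_trace(0.02, 1.0, times=np.arange(0, 6.0, 0.5))
    res = biolog_initial_rate(a590, a750)
    assert res.rate == pytest.approx(0.02, rel=0.1)
    assert not res.quality_flag


def test_initial_rate_flags_when_no_window_qualifies(rng):
    times = np.arange(0, 61, 5, dtype=float)
    noisy = 0.05 + 0.001 * times + rng.normal(0, 0.05, times.size)
    a590 = make_timecourse(times, noisy, "absorbance590")
    a750 = make_timecourse(times, np.zeros_like(times), "absorbance750")
    res = biolog_initial_rate(a590, a750)
    assert res.quality_flag
    assert res.window_points == 4


def test_initial_rate_rejects_misaligned_channels():
    a590 = make_timecourse([0, 5, 10, 15], [0, 0.1, 0.2, 0.3], "absorbance590")
    a750 = make_timecourse([0, 5, 10], [0, 0, 0], "absorbance750")
    with pytest.raises(ValueError, match="aligned"):
        biolog_initial_rate(a590, a750)


def _rates_frame(ctrl, trt, substrate="malate", group="drug"):
    rows = []
    for i, r in enumerate(ctrl, 1):
        rows.append((substrate, "control", i, r))
    for i, r in enumerate(trt, 1):
        rows.append((substrate, group, i, r))
    return pd.DataFrame(rows, columns=["substrate", "group", "replicate", "rate"])


def test_biolog_compare_identical_rates():
    df = biolog_compare(_rates_frame([0.02, 0.021, 0.019], [0.02, 0.021, 0.019]))
    assert df["p"].iloc[0] > 0.5
    assert df["log2_ratio"].iloc[0] == pytest.approx(0.0, abs=1e-9)


def test_biolog_compare_exact_halving_zero_variance():
    df = biolog_compare(_rates_frame([0.02, 0.02, 0.02], [0.01, 0.01, 0.01]))
    assert df["log2_ratio"].iloc[0] == pytest.approx(-1.0)
    assert df["p"].iloc[0] == 0.0
    assert "capped" in df["note"].iloc[0]


def test_biolog_compare_requires_three_replicates():
    with pytest.raises(ValueError, match=">= 3"):
        biolog_compare(_rates_frame([0.02, 0.02], [0.01, 0.01, 0.01]))


def test_biolog_compare_adjusts_across_substrates():
    frames = [
        _rates_frame([0.020, 0.021, 0.019], [0.004, 0.0041, 0.0039], s)
        for s in ("malate", "fumarate", "pyruvate", "citrate")
    ]
    df = biolog_compare(pd.concat(frames, ignore_index=True))
    assert len(df) == 4
    assert np.all(df["q"].to_numpy() >= df["p"].to_numpy() - 1e-15)


# ---------------------------------------------------------------------------
# in-vivo summaries
# ---------------------------------------------------------------------------

def test_tumor_volume_example():
    assert tumor_volume(10.0, 8.0) == pytest.approx(320.0)


def test_tumor_volume_cube():
    assert tumor_volume(1.0, 1.0) == pytest.approx(0.5)


def test_tumor_volume_swaps_with_warning():
    with pytest.warns(UserWarning, match="swapped"):
        v = tumor_volume(8.0, 10.0)
    assert v == pytest.approx(320.0)


def test_tumor_volume_rejects_nonpositive():
    with pytest.raises(ValueError):
        tumor_volume(0.0, 5.0)


def test_endpoint_test_separated_arms():
    t, p = endpoint_test([100, 110, 90], [300, 310, 290])
    assert p < 0.01


def test_endpoint_test_identical_arms():
    t, p = endpoint_test([200.0, 200.0, 200.0], [200.0, 200.0, 200.0])
    assert (t, p) == (0.0, 1.0)


def test_endpoint_test_needs_three_per_arm():
    with pytest.raises(ValueError):
        endpoint_test([1.0, 2.0], [1.0, 2.0, 3.0])


def test_timecourse_rejects_unknown_kind():
    with pytest.raises(ValueError):
        TimeCourse("x", "voltage", pd.DataFrame(
            {"time": [0.0], "value": [1.0], "replicate": [1]}))


def test_timecourse_rejects_negative_times():
    with pytest.raises(ValueError):
        make_timecourse([-1.0, 0.0, 1.0], [1, 2, 3], "cell_count")
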