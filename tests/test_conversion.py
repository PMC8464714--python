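"""Pixel-to-dose conversion: OLS fit, output factors, error tables."""

import numpy as np
import pandas as pd
import pytest

from epidose import (
    ConversionModel,
    EpidImage,
    compute_output_factors,
    convert_to_dose,
    fit_conversion,
    off_axis_error_table,
    relative_error_pct,
)
from epidose.exceptions import ConfigurationError, FitError

# reference measurement pairs at off-axis points r = 0, 5, 11 cm:
# (chamber dose mGy, converted dose mGy via CAX coefficients)
REFERENCE_PAIRS = {
    (0.0, "corrected"): (1060.77, 1056.2),
    (0.0, "uncorrected"): (1060.77, 1056.2),
    (5.0, "uncorrected"): (1102.98, 1078.7),
    (5.0, "corrected"): (1102.98, 1097.2),
    (11.0, "uncorrected"): (1094.20, 1035.6),
    (11.0, "corrected"): (1094.20, 1088.9),
}
CAX_A, CAX_B = 0.001398, 3.975


def _samples(a, b, radii=(0.0, 5.0), mus=(50, 100, 200, 400)):
    rows = []
    for r in radii:
        for mu in mus:
            g = 7000.0 * mu * (1 + 0.01 * r)
            rows.append(
                {"radius_cm": r, "mu": mu, "pixel": g, "dose_mGy": a * g + b}
            )
    return pd.DataFrame(rows)


def test_fit_recovers_planted_line_exactly():
    model = fit_conversion(_samples(CAX_A, CAX_B))
    np.testing.assert_allclose(model.a, CAX_A, rtol=1e-12)
    np.testing.assert_allclose(model.b, CAX_B, rtol=1e-10)


def test_two_points_exact_interpolating_line():
    df = pd.DataFrame(
        {
            "radius_cm": [0.0, 0.0],
            "mu": [100, 200],
            "pixel": [1000.0, 2100.0],
            "dose_mGy": [10.0, 21.5],
        }
    )
    model = fit_conversion(df)
    assert model.a0 * 1000.0 + model.b0 == pytest.approx(10.0, rel=1e-12)
    assert model.a0 * 2100.0 + model.b0 == pytest.approx(21.5, rel=1e-12)


def test_ols_matches_normal_equations():
    rng = np.random.default_rng(5)
    rows = []
    for r in (0.0, 3.0, 7.0):
        g = rng.uniform(1e4, 1e6, 12)
        d = 0.0013 * g + 4.2 + rng.normal(0, 5.0, 12)
        for gi, di in zip(g, d):
            rows.append({"radius_cm": r, "mu": gi, "pixel": gi, "dose_mGy": di})
    df = pd.DataFrame(rows)
    model = fit_conversion(df)
    for k, r in enumerate(sorted(df["radius_cm"].unique())):
        sub = df[df["radius_cm"] == r]
        X = np.column_stack([sub["pixel"], np.ones(len(sub))])
        beta = np.linalg.solve(X.T @ X, X.T @ sub["dose_mGy"].to_numpy())
        assert abs(model.a[k] - beta[0]) < 1e-10
        assert abs(model.b[k] - beta[1]) < 1e-7


def test_repeats_averaged_before_fit():
    base = _samples(CAX_A, CAX_B)
    up = base.copy()
    up["dose_mGy"] += 1.0
    down = base.copy()
    down["dose_mGy"] -= 1.0
    model = fit_conversion(pd.concat([up, down], ignore_index=True))
    np.testing.assert_allclose(model.a, CAX_A, rtol=1e-10)
    np.testing.assert_allclose(model.b, CAX_B, rtol=1e-8)


def test_fit_errors():
    one_level = pd.DataFrame(
        {"radius_cm": [0.0], "mu": [100], "pixel": [1.0], "dose_mGy": [1.0]}
    )
    with pytest.raises(FitError):
        fit_conversion(one_level)
    const = pd.DataFrame(
        {
            "radius_cm": [0.0, 0.0],
            "mu": [100, 200],
            "pixel": [5.0, 5.0],
            "dose_mGy": [1.0, 2.0],
        }
    )
    with pytest.raises(FitError):
        fit_conversion(const)


def test_convert_hand_value_and_identity():
    model = ConversionModel(r_cm=np.array([0.0]), a=np.array([CAX_A]), b=np.array([CAX_B]))
    img = EpidImage(pixels=np.full((2, 2), 2.0e6), pixel_pitch_cm=0.039)
    dose = convert_to_dose(img, model, of=0.5)  # G*of = 1e6
    np.testing.assert_allclose(dose.pixels, 1401.975, rtol=1e-12)
    assert dose.meta["units"] == "mGy"

    ident = ConversionModel(r_cm=np.array([0.0]), a=np.array([1.0]), b=np.array([0.0]))
    out = convert_to_dose(img, ident, of=1.0)
    np.testing.assert_array_equal(out.pixels, img.pixels)


def test_of_and_slope_rescaling_commute():
    img = EpidImage(pixels=np.linspace(1, 100, 30).reshape(5, 6))
    m1 = ConversionModel(r_cm=np.array([0.0]), a=np.array([0.002]), b=np.array([3.0]))
    m2 = ConversionModel(r_cm=np.array([0.0]), a=np.array([0.004]), b=np.array([3.0]))
    d1 = convert_to_dose(img, m1, of=1.0)
    d2 = convert_to_dose(img, m2, of=0.5)
    np.testing.assert_allclose(d1.pixels, d2.pixels, rtol=1e-12)


def test_per_radius_interpolation_with_end_hold():
    model = ConversionModel(
        r_cm=np.array([0.0, 10.0]),
        a=np.array([1.0, 2.0]),
        b=np.array([0.0, 10.0]),
        use_cax_only=False,
    )
    a, b = model.coefficients_at(np.array([0.0, 5.0, 10.0, 20.0]))
    np.testing.assert_allclose(a, [1.0, 1.5, 2.0, 2.0])
    np.testing.assert_allclose(b, [0.0, 5.0, 10.0, 10.0])


def test_output_factor_normalization_and_hand_value():
    sides = np.array([6.0, 24.0])
    g = np.array([0.93, 1.0]) * 5e5
    d = np.array([0.95, 1.0]) * 1000.0
    table = compute_output_factors(sides, g, d)
    assert table(24.0) == pytest.approx(1.0)
    assert table(6.0) == pytest.approx(0.95 / 0.93, rel=1e-12)
    with pytest.raises(ConfigurationError):
        compute_output_factors(np.array([6.0]), g[:1], d[:1])


def test_output_factor_decreases_on_simulated_suite(fitted_noiseless):
    of = fitted_noiseless.of_table.of
    assert all(b < a for a, b in zip(of, of[1:]))
    assert of[-1] == pytest.approx(1.0)


def test_relative_error_reference_pairs():
    assert relative_error_pct(*REFERENCE_PAIRS[(0.0, "corrected")]) == 0.4
    assert relative_error_pct(*REFERENCE_PAIRS[(5.0, "uncorrected")]) == 2.2
    assert relative_error_pct(*REFERENCE_PAIRS[(5.0, "corrected")]) == 0.5
    assert relative_error_pct(*REFERENCE_PAIRS[(11.0, "uncorrected")]) == 5.4
    assert relative_error_pct(*REFERENCE_PAIRS[(11.0, "corrected")]) == 0.5
    assert relative_error_pct(1234.5, 1234.5) == 0.0
    # half-up at the rounding boundary: |1000 - 999.5| / 1000 * 100 = 0.05
    assert relative_error_pct(1000.0, 999.5) == 0.1


def test_off_axis_error_table_columns():
    model = ConversionModel(
        r_cm=np.array([0.0]), a=np.array([CAX_A]), b=np.array([CAX_B])
    )
    rows = []
    for (r, mode), (meas, calc) in REFERENCE_PAIRS.items():
        if mode != "corrected":
            continue
        rows.append(
            {"radius_cm": r, "pixel": (calc - CAX_B) / CAX_A, "dose_mGy": meas}
        )
    out = off_axis_error_table(model, pd.DataFrame(rows))
    assert set(out["error_pct"]) == {0.4, 0.5}
    np.testing.assert_allclose(
        out["dose_calc_mGy"], [p[1] for p in rows_calc(rows)], rtol=1e-9
    )


def rows_calc(rows):
    return [(r["radius_cm"], CAX_A * r["pixel"] + CAX_B) for r in rows]
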