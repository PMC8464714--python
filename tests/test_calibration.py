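"""Correction-matrix construction, merging, selection and application."""

import numpy as np
import pytest

from epidose import (
    CorrectionMatrix,
    DoseGrid,
    EpidImage,
    FieldSpec,
    apply_correction,
    build_field_matrix,
    chamber_downsample,
    correct_raw,
    estimate_field_side,
    merge_common_matrix,
    select_matrix,
    symmetry_report,
)
from epidose.calibration import block_mean_at_points, interpolate_matrix_at
from epidose.datatypes import bilinear_sample, value_at_cax
from epidose.exceptions import ConfigurationError, GeometryError


def _panel(pixels, pitch=0.1):
    return EpidImage(pixels=np.asarray(pixels, dtype=float), pixel_pitch_cm=pitch)


def _lattice(n=5, pitch=1.0):
    return DoseGrid(dose_mGy=np.zeros((n, n)), pitch_cm=pitch)


# -- chamber downsampling ----------------------------------------------------

def test_downsample_uniform():
    img = _panel(np.full((80, 80), 3.25))
    out = chamber_downsample(img, _lattice())
    np.testing.assert_allclose(out, 3.25)


def test_downsample_hot_pixel_delta():
    img = _panel(np.zeros((80, 80)))
    base = chamber_downsample(img, _lattice())
    # hot pixel inside the central chamber's 12x12 block
    img.pixels[39, 41] = 144.0
    out = chamber_downsample(img, _lattice())
    diff = out - base
    assert diff[2, 2] == pytest.approx(1.0)  # 144/144
    assert np.count_nonzero(diff) == 1


def test_downsample_matches_bruteforce_loop():
    rng = np.random.default_rng(3)
    img = _panel(rng.uniform(0, 100, (80, 90)))
    lat = _lattice(n=4, pitch=1.3)
    out = chamber_downsample(img, lat)
    for i in range(4):
        for j in range(4):
            x = (j - lat.cax_col) * lat.pitch_cm
            y = -(i - lat.cax_row) * lat.pitch_cm
            r0 = int(np.ceil(img.cax_row - y / img.pixel_pitch_cm))
            c0 = int(np.ceil(img.cax_col + x / img.pixel_pitch_cm))
            block = img.pixels[r0 - 6 : r0 + 6, c0 - 6 : c0 + 6]
            assert out[i, j] == pytest.approx(block.mean(), rel=1e-12)


def test_downsample_outside_panel():
    img = _panel(np.zeros((30, 30)))
    with pytest.raises(GeometryError):
        chamber_downsample(img, _lattice(n=9, pitch=1.0))


# -- build_field_matrix ------------------------------------------------------

def test_proportional_epid_gives_unit_matrix(beam, ideal_response, suite_noiseless):
    from epidose.simulate import simulate_epid_raw, true_dose

    fld = FieldSpec(side_cm=10.0)
    g_raw, df, ff = simulate_epid_raw(beam, ideal_response, fld, seed=4)
    img = correct_raw(g_raw, df, ff)
    ica = true_dose(beam, fld)
    cm = build_field_matrix(img, ica, fld)
    np.testing.assert_allclose(cm.values[cm.mask], 1.0, rtol=1e-9)


def test_ratio_hand_value():
    # lattice with integer CAX so the normalization point is one chamber
    lat = DoseGrid(dose_mGy=np.full((5, 5), 100.0), pitch_cm=1.0)
    lat.dose_mGy[1, 3] = 102.0
    img = _panel(np.full((80, 80), 7.0))
    cm = build_field_matrix(img, lat, FieldSpec(side_cm=4.0))
    assert cm.values[2, 2] == pytest.approx(1.0)
    assert cm.values[1, 3] == pytest.approx(1.02)


def test_mask_is_20pct_isodose(beam, noiseless_response, suite_noiseless):
    f = [f for f in suite_noiseless if f.field.side_cm == 10][0]
    img = correct_raw(f.g_raw, f.df, f.ff)
    cm = build_field_matrix(img, f.ica, f.field)
    expected = np.zeros(f.ica.shape, dtype=bool)
    dmax = f.ica.dose_mGy.max()
    for i in range(f.ica.shape[0]):
        for j in range(f.ica.shape[1]):
            expected[i, j] = f.ica.dose_mGy[i, j] >= 0.20 * dmax
    np.testing.assert_array_equal(cm.mask, expected)


# -- merging -----------------------------------------------------------------

def _cm_const(value, mask, side, n=8):
    vals = np.where(mask, value, np.nan)
    return CorrectionMatrix(
        values=vals, mask=mask, pitch_cm=1.0, sides_cm=(side,)
    )


def test_merge_idempotent_for_identical_values():
    mask = np.zeros((8, 8), dtype=bool)
    mask[2:6, 2:6] = True
    a = _cm_const(1.3, mask, 5.0)
    b = _cm_const(1.3, mask, 10.0)
    merged = merge_common_matrix([a, b])
    np.testing.assert_array_equal(merged.values[mask], a.values[mask])
    np.testing.assert_array_equal(merged.mask, mask)


def test_merge_region_bookkeeping():
    big = np.zeros((8, 8), dtype=bool)
    big[1:7, 1:7] = True
    small = np.zeros((8, 8), dtype=bool)
    small[3:5, 3:5] = True
    merged = merge_common_matrix([_cm_const(1.0, small, 4.0), _cm_const(2.0, big, 8.0)])
    assert (merged.values[small] == 1.0).all()
    assert (merged.values[big & ~small] == 2.0).all()
    assert (merged.source_side[small] == 4.0).all()
    assert (merged.source_side[big & ~small] == 8.0).all()
    np.testing.assert_array_equal(merged.mask, big)


def test_merge_smallest_field_defines_inner_region(fitted_noiseless):
    cm = fitted_noiseless.matrices["small"]
    smallest = fitted_noiseless.per_field_matrices[9.0]
    np.testing.assert_array_equal(
        cm.values[smallest.mask], smallest.values[smallest.mask]
    )


def test_merge_validation():
    mask = np.ones((4, 4), dtype=bool)
    with pytest.raises(ConfigurationError):
        merge_common_matrix([])
    with pytest.raises(ConfigurationError):
        merge_common_matrix([_cm_const(1, mask, 10.0), _cm_const(1, mask, 5.0)])


# -- selection ---------------------------------------------------------------

@pytest.mark.parametrize(
    "side, expected",
    [(7.0, "small"), (10.0, "small"), (12.0, "medium"), (15.0, "medium"),
     (15.1, "large"), (23.0, "large")],
)
def test_select_matrix_regimes(side, expected):
    mats = {
        k: _cm_const(1.0, np.ones((4, 4), dtype=bool), 9.0)
        for k in ("small", "medium", "large")
    }
    for k in mats:
        mats[k].matrix_class = k
    assert select_matrix(side, mats).matrix_class == expected


def test_select_matrix_missing_class():
    with pytest.raises(ConfigurationError):
        select_matrix(7.0, {})


# -- application -------------------------------------------------------------

def test_apply_identity_and_constant():
    img = _panel(np.arange(64.0).reshape(8, 8), pitch=0.5)
    mask = np.ones((5, 5), dtype=bool)
    one = _cm_const(1.0, mask, 5.0)
    np.testing.assert_array_equal(apply_correction(img, one).pixels, img.pixels)
    c = _cm_const(1.05, mask, 5.0)
    np.testing.assert_allclose(
        apply_correction(img, c).pixels, img.pixels * 1.05, rtol=1e-12
    )


def test_apply_node_fidelity(fitted_noiseless):
    cm = fitted_noiseless.matrices["small"]
    ii, jj = np.where(cm.mask)
    x = (jj - cm.cax_col) * cm.pitch_cm
    y = -(ii - cm.cax_row) * cm.pitch_cm
    got = interpolate_matrix_at(cm, x, y)
    np.testing.assert_allclose(got, cm.values[cm.mask], rtol=1e-12)


def test_apply_empty_mask():
    img = _panel(np.ones((8, 8)))
    empty = CorrectionMatrix(
        values=np.full((4, 4), np.nan), mask=np.zeros((4, 4), dtype=bool), pitch_cm=1.0
    )
    with pytest.raises(ConfigurationError):
        apply_correction(img, empty)


# -- diagnostics -------------------------------------------------------------

def test_symmetry_of_symmetric_image():
    y = np.linspace(-1, 1, 41)
    prof = np.exp(-(y**2))
    img = _panel(np.outer(prof, prof), pitch=0.1)
    rep = symmetry_report(img, FieldSpec(side_cm=3.0))
    finite = np.isfinite(rep.inline_ratio)
    np.testing.assert_allclose(rep.inline_ratio[finite], 1.0, rtol=1e-9)
    assert rep.max_asymmetry_pct == pytest.approx(0.0, abs=1e-7)


def test_post_correction_symmetry_and_monotone_improvement(
    suite_noiseless, fitted_noiseless
):
    """Class-matrix correction restores inline symmetry for the regime
    exemplars and never degrades agreement with the chamber array."""
    res = fitted_noiseless
    exemplars = {7.0: "small", 12.0: "medium", 23.0: "large"}
    for f in suite_noiseless:
        img = correct_raw(f.g_raw, f.df, f.ff)
        cm = select_matrix(f.field.side_cm, res.matrices)
        corrected = apply_correction(img, cm)
        if f.field.side_cm in exemplars:
            assert cm.matrix_class == exemplars[f.field.side_cm]
            rep = symmetry_report(corrected, f.field)
            assert rep.max_asymmetry_pct < 1.0
        # monotone improvement of CAX-normalized RMS vs chamber dose
        mask = f.ica.dose_mGy >= 0.2 * f.ica.dose_mGy.max()
        d_norm = f.ica.dose_mGy / value_at_cax(f.ica)

        def rms(image):
            s = chamber_downsample(image, f.ica)
            s_cax = bilinear_sample(
                s, np.array([f.ica.cax_row]), np.array([f.ica.cax_col])
            )[0]
            return np.sqrt(np.mean((s[mask] / s_cax - d_norm[mask]) ** 2))

        assert rms(corrected) <= rms(img) + 1e-12


def test_estimate_field_side(beam, noiseless_response):
    from epidose.simulate import simulate_epid_raw

    fld = FieldSpec(side_cm=12.0)
    g_raw, df, ff = simulate_epid_raw(beam, noiseless_response, fld, seed=6)
    side = estimate_field_side(correct_raw(g_raw, df, ff))
    assert side == pytest.approx(12.0, abs=0.4)


def test_cax_sample_arbitrary_points():
    img = _panel(np.full((80, 80), 5.0))
    out = block_mean_at_points(img, np.array([0.0, 1.0]), np.array([0.0, -1.0]))
    np.testing.assert_allclose(out, 5.0)
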