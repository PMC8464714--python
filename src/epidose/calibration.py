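"""Backscatter / off-axis correction matrices from paired EPID-ICA data.

The support arm behind the panel backscatters low-energy photons into the
detector, breaking the inline (y) symmetry of the image, and the flood
calibration removes the beam's real off-axis shape.  Both defects are
corrected at once by a multiplicative matrix built from square-field
measurements: with both detectors at the same plane, the CAX-normalized
ratio of chamber-array dose to (chamber-matched) EPID signal at every
chamber position is the correction factor there.

Per-field matrices from a range of square fields are merged — values of
larger fields are replaced by those of smaller fields wherever the smaller
field covers the point — into a "common" matrix usable for arbitrary
fields.  Because the backscatter asymmetry changes regime with field size,
three common matrices are kept (built from 9-24, 13-24 and 18-24 cm
fields) and the one matching the field size of the image under test is
applied.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .datatypes import (
    CHAMBER_BLOCK_PX,
    MATRIX_CLASS_RANGES,
    CorrectionMatrix,
    DoseGrid,
    EpidImage,
    FieldSpec,
    SymmetryReport,
    _Grid2D,
    bilinear_sample,
    value_at_cax,
)
from .exceptions import CalibrationDataError, ConfigurationError, GeometryError

#: lattice points are kept where dose >= this fraction of the field maximum
ISODOSE_CUT = 0.20


# ---------------------------------------------------------------------------
# chamber-matched downsampling
# ---------------------------------------------------------------------------

def _integral_image(a: np.ndarray) -> np.ndarray:
    s = np.zeros((a.shape[0] + 1, a.shape[1] + 1))
    np.cumsum(a, axis=0, out=s[1:, 1:])
    np.cumsum(s[1:, 1:], axis=1, out=s[1:, 1:])
    return s


def block_mean_at_points(
    img: EpidImage,
    x_cm: np.ndarray,
    y_cm: np.ndarray,
    block_px: int = CHAMBER_BLOCK_PX,
) -> np.ndarray:
    """Mean of the ``block_px`` x ``block_px`` pixel block nearest each point.

    The block holds the ``block_px`` x ``block_px`` pixels nearest the
    requested position: indices ``[ceil(u) - block_px/2, ceil(u) +
    block_px/2)`` of the fractional index ``u`` per axis.  For a position
    midway between pixels (the usual case for chamber centers) the block
    is exactly centered, which keeps the sampling mirror-symmetric; the
    default 12-pixel block (12 x 0.039 cm ~ 0.47 cm) emulates the 0.45 cm
    chamber aperture.
    """
    x_cm = np.asarray(x_cm, dtype=float)
    y_cm = np.asarray(y_cm, dtype=float)
    row_f, col_f = img.phys_to_index(x_cm, y_cm)
    r0 = np.ceil(row_f).astype(int)
    c0 = np.ceil(col_f).astype(int)
    half = block_px // 2
    lo_r, hi_r = r0 - half, r0 + (block_px - half)
    lo_c, hi_c = c0 - half, c0 + (block_px - half)
    if (lo_r < 0).any() or (hi_r > img.n_rows).any() or (lo_c < 0).any() or (
        hi_c > img.n_cols
    ).any():
        raise GeometryError("sample block extends outside the panel")
    s = _integral_image(img.pixels)
    total = s[hi_r, hi_c] - s[lo_r, hi_c] - s[hi_r, lo_c] + s[lo_r, lo_c]
    return total / float(block_px * block_px)


def chamber_downsample(
    img: EpidImage, lattice: _Grid2D, block_px: int = CHAMBER_BLOCK_PX
) -> np.ndarray:
    """Chamber-matched EPID samples on an ICA lattice.

    Returns a 2D array of ``lattice.shape`` holding, for every chamber
    position, the mean of the pixel block centered on the nearest EPID
    pixel (see :func:`block_mean_at_points`).
    """
    X = np.broadcast_to(lattice.x_coords()[None, :], lattice.shape)
    Y = np.broadcast_to(lattice.y_coords()[:, None], lattice.shape)
    return block_mean_at_points(img, X, Y, block_px=block_px)


# ---------------------------------------------------------------------------
# matrix construction, merging, selection, application
# ---------------------------------------------------------------------------

def build_field_matrix(
    epid_corrected: EpidImage, ica: DoseGrid, field: FieldSpec
) -> CorrectionMatrix:
    """Single-field correction matrix: CAX-normalized dose over pixel ratio.

    ``CM(i,j) = [D(i,j)/D_cax] / [G_s(i,j)/G_s,cax]`` where ``G_s`` is the
    chamber-downsampled EPID image.  The mask keeps lattice points with
    dose at or above 20% of the field maximum (in-field plus penumbra).
    """
    g_s = chamber_downsample(epid_corrected, ica)
    d = ica.dose_mGy
    d_cax = value_at_cax(ica)
    g_cax = float(
        bilinear_sample(g_s, np.array([ica.cax_row]), np.array([ica.cax_col]))[0]
    )
    if d_cax <= 0 or g_cax <= 0:
        raise CalibrationDataError("CAX dose and CAX pixel sample must be positive")
    mask = d >= ISODOSE_CUT * d.max()
    if np.any(g_s[mask] <= 0):
        raise CalibrationDataError("zero pixel sample inside the 20% isodose mask")
    values = np.full(d.shape, np.nan)
    values[mask] = (d[mask] / d_cax) / (g_s[mask] / g_cax)
    return CorrectionMatrix(
        values=values,
        mask=mask,
        pitch_cm=ica.pitch_cm,
        cax_row=ica.cax_row,
        cax_col=ica.cax_col,
        sides_cm=(field.side_cm,),
    )


def merge_common_matrix(
    per_field: list[CorrectionMatrix], matrix_class: str | None = None
) -> CorrectionMatrix:
    """Merge single-field matrices (sides ascending) into a common matrix.

    Starting from the largest field's matrix, every lattice point covered
    by a smaller field's mask takes the smaller field's value; iterating
    from largest to smallest makes the innermost (smallest) field win
    deterministically.  The result mask is the largest field's mask.
    """
    if not per_field:
        raise ConfigurationError("merge requires at least one per-field matrix")
    sides = [m.sides_cm[0] for m in per_field]
    if any(b <= a for a, b in zip(sides, sides[1:])):
        raise ConfigurationError("per-field matrices must be sorted by side, ascending")
    if matrix_class is not None:
        lo, hi = MATRIX_CLASS_RANGES[matrix_class]
        if min(sides) < lo or max(sides) > hi:
            raise ConfigurationError(
                f"sides {sides} outside the {matrix_class} class range {lo}-{hi} cm"
            )
    largest = per_field[-1]
    for m in per_field:
        if not m.same_geometry(largest):
            raise GeometryError("per-field matrices must share lattice geometry")
    values = largest.values.copy()
    source = np.full(values.shape, np.nan)
    for m in sorted(per_field, key=lambda m: -m.sides_cm[0]):
        values[m.mask] = m.values[m.mask]
        source[m.mask] = m.sides_cm[0]
    mask = largest.mask.copy()
    values[~mask] = np.nan
    source[~mask] = np.nan
    return CorrectionMatrix(
        values=values,
        mask=mask,
        pitch_cm=largest.pitch_cm,
        cax_row=largest.cax_row,
        cax_col=largest.cax_col,
        sides_cm=tuple(sides),
        matrix_class=matrix_class,
        source_side=source,
    )


def select_matrix(
    field_side_cm: float, matrices: dict[str, CorrectionMatrix]
) -> CorrectionMatrix:
    """Pick the common matrix matching the field-size backscatter regime.

    Sides up to 10 cm use the small-field matrix (9-24 cm class), sides in
    (10, 15] the medium class (13-24 cm) and larger sides the large class
    (18-24 cm).
    """
    if field_side_cm <= 10.0:
        key = "small"
    elif field_side_cm <= 15.0:
        key = "medium"
    else:
        key = "large"
    try:
        return matrices[key]
    except KeyError:
        raise ConfigurationError(f"no '{key}' common matrix available") from None


def _nearest_fill(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Fill points outside ``mask`` with the nearest defined value."""
    if mask.all():
        return values
    idx = ndimage.distance_transform_edt(
        ~mask, return_distances=False, return_indices=True
    )
    return values[tuple(idx)]


def _bilinear_separable(
    values: np.ndarray, rows: np.ndarray, cols: np.ndarray
) -> np.ndarray:
    """Bilinear sampling on the outer grid of fractional ``rows`` x ``cols``."""
    nr, nc = values.shape
    rows = np.clip(rows, 0.0, nr - 1.0)
    cols = np.clip(cols, 0.0, nc - 1.0)
    r0 = np.clip(np.floor(rows).astype(int), 0, max(nr - 2, 0))
    c0 = np.clip(np.floor(cols).astype(int), 0, max(nc - 2, 0))
    r1 = np.minimum(r0 + 1, nr - 1)
    c1 = np.minimum(c0 + 1, nc - 1)
    fr = (rows - r0)[:, None]
    fc = (cols - c0)[None, :]
    v00 = values[np.ix_(r0, c0)]
    v01 = values[np.ix_(r0, c1)]
    v10 = values[np.ix_(r1, c0)]
    v11 = values[np.ix_(r1, c1)]
    return (
        v00 * (1 - fr) * (1 - fc)
        + v01 * (1 - fr) * fc
        + v10 * fr * (1 - fc)
        + v11 * fr * fc
    )


def apply_correction(epid_corrected: EpidImage, cm: CorrectionMatrix) -> EpidImage:
    """Multiply an EPID image by the correction matrix.

    The matrix lives on the coarse chamber lattice; it is bilinearly
    interpolated to every EPID pixel position.  Outside the defined mask
    (and beyond the lattice extent) the nearest defined value is held
    constant — bilinear is used rather than a higher order to avoid
    overshoot in the penumbra.
    """
    if not cm.mask.any():
        raise ConfigurationError("correction matrix mask is empty")
    filled = _nearest_fill(np.where(cm.mask, cm.values, 0.0), cm.mask)
    rows = cm.cax_row - epid_corrected.y_coords() / cm.pitch_cm
    cols = cm.cax_col + epid_corrected.x_coords() / cm.pitch_cm
    factors = _bilinear_separable(filled, rows, cols)
    return epid_corrected.copy_with(
        epid_corrected.pixels * factors,
        matrix_class=cm.matrix_class,
        matrix_sides=list(cm.sides_cm),
    )


def interpolate_matrix_at(cm: CorrectionMatrix, x_cm, y_cm) -> np.ndarray:
    """Correction factor at arbitrary physical points (same rules as apply)."""
    filled = _nearest_fill(np.where(cm.mask, cm.values, 0.0), cm.mask)
    row, col = cm.phys_to_index(np.asarray(x_cm, float), np.asarray(y_cm, float))
    return bilinear_sample(filled, row, col)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def estimate_field_side(epid: EpidImage, level: float = 0.5) -> float:
    """Equivalent-square side (cm) of the region above ``level`` x image max.

    Used to classify arbitrary (e.g. modulated) fields for matrix
    selection: the area A above the 50% level maps to a square of side
    sqrt(A).
    """
    area_cm2 = np.count_nonzero(epid.pixels >= level * epid.pixels.max()) * (
        epid.pixel_pitch_cm**2
    )
    return float(np.sqrt(area_cm2))


def symmetry_report(
    epid: EpidImage, field: FieldSpec, threshold: float = ISODOSE_CUT
) -> SymmetryReport:
    """Inline symmetry and inline/crossline diagnostics through the CAX.

    ``inline_ratio(d) = P(+d)/P(-d)`` along the inline axis;
    ``inline_crossline_ratio(d) = G(inline -d)/G(crossline -d)``; both
    defined only where the samples exceed ``threshold`` of the profile
    maximum.  ``max_asymmetry_pct`` is ``max |inline_ratio - 1| * 100``.
    """
    pitch = epid.pixel_pitch_cm
    max_inline = min(epid.cax_row, epid.n_rows - 1 - epid.cax_row) * pitch
    max_cross = min(epid.cax_col, epid.n_cols - 1 - epid.cax_col) * pitch
    d_max = min(max_inline, max_cross)
    offsets = np.arange(1, int(np.floor(d_max / pitch)) + 1) * pitch

    def _sample(x, y):
        row, col = epid.phys_to_index(np.asarray(x, float), np.asarray(y, float))
        return bilinear_sample(epid.pixels, np.atleast_1d(row), np.atleast_1d(col))

    zeros = np.zeros_like(offsets)
    p_in_pos = _sample(zeros, offsets)
    p_in_neg = _sample(zeros, -offsets)
    p_cr_neg = _sample(-offsets, zeros)
    cax = _sample(0.0, 0.0)[0]
    ref = max(cax, p_in_pos.max(), p_in_neg.max(), p_cr_neg.max())
    cut = threshold * ref

    inline_ratio = np.full(offsets.shape, np.nan)
    ok = (p_in_pos >= cut) & (p_in_neg >= cut)
    inline_ratio[ok] = p_in_pos[ok] / p_in_neg[ok]

    ic_ratio = np.full(offsets.shape, np.nan)
    ok2 = (p_in_neg >= cut) & (p_cr_neg >= cut)
    ic_ratio[ok2] = p_in_neg[ok2] / p_cr_neg[ok2]

    max_asym = float(np.nanmax(np.abs(inline_ratio - 1.0)) * 100.0) if ok.any() else 0.0
    return SymmetryReport(
        side_cm=field.side_cm,
        offsets_cm=offsets,
        inline_ratio=inline_ratio,
        inline_crossline_ratio=ic_ratio,
        max_asymmetry_pct=max_asym,
    )
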