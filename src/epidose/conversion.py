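"""Linear pixel-value to absolute-dose conversion and field output factors.

The EPID signal is linear in dose, so at every off-axis radius r a
straight line

    D(r) = a(r) * G(r) + b(r)

maps (chamber-matched) pixel value to dose in mGy; the coefficients are
fitted from a monitor-unit series on a large reference field.  On a
matrix-corrected image the coefficients barely vary with r, so the
central-axis pair (a(0), b(0)) can be applied everywhere — that is the
default operating mode, with the per-radius table retained for
diagnostics.

A single conversion line cannot serve every field size because panel and
chamber array see field-size scatter differently; the field output factor
OF(s), normalized to the 24 cm reference field, reconciles the two before
conversion: D = a * (G * OF) + b.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import EpidImage, OutputFactorTable
from .exceptions import ConfigurationError, FitError

#: default off-axis radius grid (cm): the CAX plus chamber positions out to
#: the lattice corner-adjacent radius 11.047 cm
DEFAULT_RADII_CM: tuple[float, ...] = (
    0.0, 1.142, 1.904, 2.666, 3.428, 4.190, 4.952, 5.714,
    6.476, 7.237, 7.999, 8.761, 9.523, 10.285, 11.047,
)


@dataclass
class ConversionModel:
    """Per-radius linear dose-conversion coefficients.

    ``a`` is in mGy per pixel unit, ``b`` in mGy; ``a_se``/``b_se`` carry
    the OLS standard errors (NaN when the fit is saturated, i.e. two
    points).  With ``use_cax_only`` (the validated default) the r = 0
    coefficients are applied at every pixel.
    """

    r_cm: np.ndarray
    a: np.ndarray
    b: np.ndarray
    a_se: np.ndarray | None = None
    b_se: np.ndarray | None = None
    use_cax_only: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.r_cm = np.asarray(self.r_cm, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a_se is not None:
            self.a_se = np.asarray(self.a_se, dtype=float)
        if self.b_se is not None:
            self.b_se = np.asarray(self.b_se, dtype=float)
        if np.any(np.diff(self.r_cm) <= 0):
            raise ConfigurationError("radius grid must be strictly increasing")
        if np.any(self.a <= 0):
            raise FitError("fitted a(r) must be positive")

    @property
    def a0(self) -> float:
        return float(self.a[0]) if self.r_cm[0] == 0 else float(np.interp(0, self.r_cm, self.a))

    @property
    def b0(self) -> float:
        return float(self.b[0]) if self.r_cm[0] == 0 else float(np.interp(0, self.r_cm, self.b))

    def coefficients_at(self, r) -> tuple[np.ndarray, np.ndarray]:
        """(a, b) at radius r — CAX pair if ``use_cax_only``, else linear in
        r with end values held beyond the grid."""
        r = np.asarray(r, dtype=float)
        if self.use_cax_only:
            return np.full(r.shape, self.a0), np.full(r.shape, self.b0)
        return np.interp(r, self.r_cm, self.a), np.interp(r, self.r_cm, self.b)

    def flatness(self) -> float:
        """max_r |a(r)/a(0) - 1| — how far the per-radius slopes stray from CAX."""
        return float(np.max(np.abs(self.a / self.a0 - 1.0)))


def _ols_se(grp: pd.DataFrame, g, d, slope, inter) -> tuple[float, float]:
    """Standard errors of the per-radius OLS line.

    Detector noise is proportional to signal, so the residual variance
    grows with MU and the classical homoscedastic formula is wrong.  When
    every MU level carries repeated measurements, their spread gives a
    direct, pooled estimate of the per-point measurement variance (relative
    variance pooled across levels, then scaled back per point), which is
    propagated through the OLS weights.  Without repeats, HC1
    heteroscedasticity-robust errors from the residuals are used.
    """
    k = len(g)
    if (grp["n_rep"] >= 2).all():
        n_rep = grp["n_rep"].to_numpy()
        rel2_x = float(np.mean(grp["pixel_var"].to_numpy() / np.maximum(g, 1e-300) ** 2))
        rel2_y = float(
            np.mean(grp["dose_mGy_var"].to_numpy() / np.maximum(np.abs(d), 1e-300) ** 2)
        )
        var_e = (rel2_y * d**2 + slope**2 * rel2_x * g**2) / n_rep
    else:
        X = np.column_stack([g, np.ones_like(g)])
        e = d - X @ np.array([slope, inter])
        var_e = e**2 * (k / (k - 2))
    gbar = g.mean()
    sxx = np.sum((g - gbar) ** 2)
    c = (g - gbar) / sxx
    w_b = 1.0 / k - gbar * c
    return float(np.sqrt(np.sum(c**2 * var_e))), float(np.sqrt(np.sum(w_b**2 * var_e)))


def fit_conversion(
    samples: pd.DataFrame, use_cax_only: bool = True, min_mu_levels: int = 2
) -> ConversionModel:
    """Fit D = a(r) G + b(r) by per-radius ordinary least squares.

    Parameters
    ----------
    samples
        Long-format table with columns ``radius_cm``, ``mu``, ``pixel``,
        ``dose_mGy`` — one row per (radius, MU level, repeat).  Repeated
        measurements at the same (radius, MU) are averaged before fitting.
    use_cax_only
        Operating mode stored on the model (see :class:`ConversionModel`).

    Raises
    ------
    FitError
        Fewer than ``min_mu_levels`` distinct MU levels at some radius, or
        constant pixel values (degenerate regressor).
    """
    required = {"radius_cm", "mu", "pixel", "dose_mGy"}
    if not required.issubset(samples.columns):
        raise ConfigurationError(f"samples must have columns {sorted(required)}")
    grouped = samples.groupby(["radius_cm", "mu"])[["pixel", "dose_mGy"]]
    averaged = grouped.mean().reset_index().sort_values(["radius_cm", "mu"])
    counts = grouped.size().reset_index(name="n_rep")
    variances = grouped.var(ddof=1).reset_index()
    averaged = averaged.merge(counts, on=["radius_cm", "mu"]).merge(
        variances, on=["radius_cm", "mu"], suffixes=("", "_var")
    )

    radii, a, b, a_se, b_se = [], [], [], [], []
    for r, grp in averaged.groupby("radius_cm"):
        if len(grp) < min_mu_levels:
            raise FitError(f"radius {r}: need >= {min_mu_levels} distinct MU levels")
        g = grp["pixel"].to_numpy()
        d = grp["dose_mGy"].to_numpy()
        if np.ptp(g) == 0:
            raise FitError(f"radius {r}: constant pixel values, cannot fit")
        if len(grp) == 2:  # exact interpolating line, no residual dof
            slope = (d[1] - d[0]) / (g[1] - g[0])
            inter = d[0] - slope * g[0]
            se_s = se_i = np.nan
        else:
            res = stats.linregress(g, d)
            slope, inter = res.slope, res.intercept
            se_s, se_i = _ols_se(grp, g, d, slope, inter)
        radii.append(float(r))
        a.append(slope)
        b.append(inter)
        a_se.append(se_s)
        b_se.append(se_i)
    return ConversionModel(
        r_cm=np.array(radii),
        a=np.array(a),
        b=np.array(b),
        a_se=np.array(a_se),
        b_se=np.array(b_se),
        use_cax_only=use_cax_only,
        meta={"n_rows": int(len(samples))},
    )


def convert_to_dose(
    epid_corrected: EpidImage, model: ConversionModel, of: float = 1.0
) -> EpidImage:
    """Convert a (matrix-corrected) EPID image to absolute dose (mGy).

    Every pixel becomes ``a(r) * (G * of) + b(r)`` with r the pixel's
    off-axis radius; the returned image carries ``units='mGy'`` in its
    metadata.
    """
    if of <= 0:
        raise ConfigurationError("output factor must be positive")
    r = epid_corrected.radius_map()
    a, b = model.coefficients_at(r)
    dose = a * (epid_corrected.pixels * of) + b
    return epid_corrected.copy_with(dose, units="mGy", output_factor=float(of))


def compute_output_factors(
    sides_cm, cax_pixel, cax_dose_mGy, reference_side_cm: float = 24.0
) -> OutputFactorTable:
    """Field output factors from CAX pixel/dose series over square fields.

    ``OF(s) = [D(s)/D(ref)] / [G(s)/G(ref)]`` with the 24 cm field as
    reference, so OF(ref) = 1 exactly.
    """
    sides = np.asarray(sides_cm, dtype=float)
    g = np.asarray(cax_pixel, dtype=float)
    d = np.asarray(cax_dose_mGy, dtype=float)
    if not (sides.shape == g.shape == d.shape):
        raise ConfigurationError("sides/pixel/dose series must align")
    ref = np.isclose(sides, reference_side_cm)
    if not ref.any():
        raise ConfigurationError(
            f"reference side {reference_side_cm} cm missing from the series"
        )
    i = int(np.argmax(ref))
    of = (d / d[i]) / (g / g[i])
    return OutputFactorTable(sides_cm=sides, of=of, reference_side_cm=reference_side_cm)


def relative_error_pct(measured_mGy: float, calculated_mGy: float) -> float:
    """|measured - calculated| / measured * 100, rounded half-up to 1 decimal."""
    if measured_mGy == 0:
        raise ZeroDivisionError("measured dose is zero")
    err = abs(measured_mGy - calculated_mGy) / abs(measured_mGy) * 100.0
    return float(Decimal(repr(err)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def off_axis_error_table(model: ConversionModel, samples: pd.DataFrame) -> pd.DataFrame:
    """Dose errors at off-axis points using the CAX conversion coefficients.

    ``samples`` has columns ``radius_cm``, ``pixel``, ``dose_mGy`` (the
    chamber-measured reference).  Returns the input plus ``dose_calc_mGy``
    (CAX-coefficient conversion) and ``error_pct`` (one decimal, half-up).
    """
    required = {"radius_cm", "pixel", "dose_mGy"}
    if not required.issubset(samples.columns):
        raise ConfigurationError(f"samples must have columns {sorted(required)}")
    out = samples.copy()
    out["dose_calc_mGy"] = model.a0 * out["pixel"] + model.b0
    out["error_pct"] = [
        relative_error_pct(m, c) for m, c in zip(out["dose_mGy"], out["dose_calc_mGy"])
    ]
    return out
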