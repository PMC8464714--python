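"""Top-level Model/Results interface for EPID portal-dose calibration.

:class:`PortalDoseCalibration` is built from measured (or simulated)
calibration data — paired EPID/chamber-array square fields plus an MU
series on the reference field — and ``fit()`` estimates every artifact the
dose pipeline needs:

* three common backscatter/off-axis correction matrices (small / medium /
  large field-size regimes),
* the field output factor table OF(s),
* per-radius linear pixel-to-dose coefficients (corrected and, for
  diagnostics, uncorrected),
* symmetry diagnostics before and after correction.

The returned :class:`PortalDoseResults` converts new acquisitions to
absolute dose and validates them against chamber-array references with
gamma analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import calibration as cal
from . import conversion as conv
from .correction import correct_raw
from .datatypes import (
    MATRIX_CLASS_RANGES,
    CorrectionMatrix,
    DoseGrid,
    EpidImage,
    GammaCriteria,
    OutputFactorTable,
    bilinear_sample,
    value_at_cax,
)
from .exceptions import ConfigurationError
from .gamma import GammaResult, GammaSummary, gamma_2d, gamma_report
from .simulate import (
    DEFAULT_SEED,
    BeamModel,
    CalibrationField,
    EpidResponseModel,
    make_calibration_suite,
    make_mu_series,
)


class PortalDoseCalibration:
    """Calibration model for converting EPID images to absolute dose.

    Parameters
    ----------
    calibration_fields
        Paired square-field acquisitions (EPID raw/dark/flood triplet plus
        the chamber-array dose), spanning 3-24 cm sides; sides 9-24 cm
        feed the common correction matrices and the full range feeds the
        output-factor table.
    mu_series
        Acquisitions of the reference (24 cm) field at several MU levels
        for the pixel-to-dose fit; ``None`` skips the conversion fit.
    radii_cm
        Off-axis radii at which conversion coefficients are tabulated.
    """

    def __init__(
        self,
        calibration_fields: list[CalibrationField],
        mu_series: list[CalibrationField] | None = None,
        radii_cm=conv.DEFAULT_RADII_CM,
        reference_side_cm: float = 24.0,
    ):
        if not calibration_fields:
            raise ConfigurationError("at least one calibration field is required")
        self.calibration_fields = sorted(
            calibration_fields, key=lambda f: f.field.side_cm
        )
        self.mu_series = mu_series
        self.radii_cm = np.asarray(radii_cm, dtype=float)
        self.reference_side_cm = reference_side_cm

    @classmethod
    def from_simulation(
        cls,
        beam: BeamModel | None = None,
        response: EpidResponseModel | None = None,
        sides_cm=tuple(range(3, 25)),
        mu: float = 100.0,
        mu_levels=(25, 50, 100, 200, 300, 400, 500, 600),
        repeats: int = 3,
        seed: int = DEFAULT_SEED,
        **kwargs,
    ) -> "PortalDoseCalibration":
        """Simulate the full measurement session and wrap it as a model.

        Defaults mirror the calibration protocol: square fields of
        3-24 cm at 100 MU, and a 24 cm MU series repeated three times
        with levels spanning 25-600 MU.
        """
        beam = beam if beam is not None else BeamModel()
        response = response if response is not None else EpidResponseModel()
        suite = make_calibration_suite(beam, response, sides_cm, mu=mu, seed=seed)
        series = make_mu_series(
            beam, response, mu_levels, side_cm=24.0, repeats=repeats, seed=seed
        )
        obj = cls(suite, series, **kwargs)
        obj.beam = beam
        obj.response = response
        return obj

    # -- fitting ------------------------------------------------------------

    def fit(self, use_cax_only: bool = True) -> "PortalDoseResults":
        corrected = {
            f.field.side_cm: correct_raw(f.g_raw, f.df, f.ff)
            for f in self.calibration_fields
        }
        per_field = {
            f.field.side_cm: cal.build_field_matrix(
                corrected[f.field.side_cm], f.ica, f.field
            )
            for f in self.calibration_fields
        }
        sides = sorted(per_field)

        matrices: dict[str, CorrectionMatrix] = {}
        for klass, (lo, hi) in MATRIX_CLASS_RANGES.items():
            members = [per_field[s] for s in sides if lo <= s <= hi]
            if members:
                matrices[klass] = cal.merge_common_matrix(members, klass)

        of_table = self._fit_output_factors(corrected)
        model_corr, model_unc = self._fit_conversion(matrices, use_cax_only)
        symmetry = self._symmetry_diagnostics(corrected, matrices)

        return PortalDoseResults(
            model=self,
            matrices=matrices,
            per_field_matrices=per_field,
            of_table=of_table,
            conversion_model=model_corr,
            conversion_model_uncorrected=model_unc,
            symmetry=symmetry,
            lattice=self.calibration_fields[0].ica,
        )

    def _cax_pixel(self, img: EpidImage) -> float:
        return float(cal.block_mean_at_points(img, np.array([0.0]), np.array([0.0]))[0])

    def _fit_output_factors(self, corrected) -> OutputFactorTable | None:
        sides = sorted(corrected)
        if not any(np.isclose(s, self.reference_side_cm) for s in sides):
            return None
        by_side = {f.field.side_cm: f for f in self.calibration_fields}
        g = [self._cax_pixel(corrected[s]) for s in sides]
        d = [value_at_cax(by_side[s].ica) for s in sides]
        return conv.compute_output_factors(
            sides, g, d, reference_side_cm=self.reference_side_cm
        )

    def conversion_samples(
        self, matrices, corrected_mode: bool, mu_series=None
    ) -> pd.DataFrame:
        """Chamber-matched (pixel, dose) samples along the crossline axis at
        each tabulated radius, for every MU acquisition of the series."""
        rows = []
        xs = self.radii_cm
        ys = np.zeros_like(xs)
        for rec in mu_series if mu_series is not None else self.mu_series:
            img = correct_raw(rec.g_raw, rec.df, rec.ff)
            if corrected_mode:
                m = cal.select_matrix(rec.field.side_cm, matrices)
                img = cal.apply_correction(img, m)
            pix = cal.block_mean_at_points(img, xs, ys)
            ri, ci = rec.ica.phys_to_index(xs, ys)
            dose = bilinear_sample(rec.ica.dose_mGy, ri, ci)
            for r, p, d in zip(xs, pix, dose):
                rows.append(
                    {"radius_cm": r, "mu": rec.field.mu, "pixel": p, "dose_mGy": d}
                )
        return pd.DataFrame(rows)

    def _fit_conversion(self, matrices, use_cax_only):
        if not self.mu_series:
            return None, None
        model_corr = conv.fit_conversion(
            self.conversion_samples(matrices, True), use_cax_only=use_cax_only
        )
        model_unc = conv.fit_conversion(
            self.conversion_samples(matrices, False), use_cax_only=use_cax_only
        )
        return model_corr, model_unc

    def _symmetry_diagnostics(self, corrected, matrices) -> pd.DataFrame:
        rows = []
        for f in self.calibration_fields:
            img = corrected[f.field.side_cm]
            pre = cal.symmetry_report(img, f.field)
            try:
                m = cal.select_matrix(f.field.side_cm, matrices)
            except ConfigurationError:
                continue
            post = cal.symmetry_report(cal.apply_correction(img, m), f.field)
            rows.append(
                {
                    "side_cm": f.field.side_cm,
                    "matrix_class": m.matrix_class,
                    "asymmetry_pre_pct": pre.max_asymmetry_pct,
                    "asymmetry_post_pct": post.max_asymmetry_pct,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class PortalDoseResults:
    """Fitted calibration artifacts plus conversion / validation methods."""

    model: PortalDoseCalibration
    matrices: dict[str, CorrectionMatrix]
    per_field_matrices: dict[float, CorrectionMatrix]
    of_table: OutputFactorTable | None
    conversion_model: conv.ConversionModel | None
    conversion_model_uncorrected: conv.ConversionModel | None
    symmetry: pd.DataFrame
    lattice: DoseGrid

    # -- applying the calibration -------------------------------------------

    def convert_image(
        self,
        g_raw: EpidImage,
        df: EpidImage,
        ff: EpidImage,
        side_cm: float | None = None,
        matrix_class: str | None = None,
        apply_matrix: bool = True,
    ) -> tuple[EpidImage, DoseGrid]:
        """Full chain raw -> absolute dose: flatten, correct, scale, convert.

        Returns the per-pixel dose image (mGy) and its chamber-matched
        samples on the reference lattice.  The field side is estimated
        from the image (equivalent square of the 50% region) unless given;
        ``matrix_class`` overrides the size-based matrix selection.
        """
        if self.conversion_model is None:
            raise ConfigurationError("no conversion model fitted")
        img = correct_raw(g_raw, df, ff)
        side = side_cm if side_cm is not None else cal.estimate_field_side(img)
        if apply_matrix:
            m = (
                self.matrices[matrix_class]
                if matrix_class is not None
                else cal.select_matrix(side, self.matrices)
            )
            img = cal.apply_correction(img, m)
        of = self.of_table(side) if self.of_table is not None else 1.0
        dose = conv.convert_to_dose(img, self.conversion_model, of=of)
        samples = self.lattice.copy_with(
            cal.chamber_downsample(dose, self.lattice), side_cm=side, units="mGy"
        )
        return dose, samples

    def validate(
        self,
        fields,
        criteria: tuple[GammaCriteria, ...] = (
            GammaCriteria(3.0, 3.0),
            GammaCriteria(2.0, 2.0),
        ),
        apply_matrix: bool = True,
    ) -> dict[str, tuple[list[GammaResult], GammaSummary]]:
        """Gamma-validate acquisitions against their chamber references.

        ``fields`` is any iterable of objects with ``g_raw``/``df``/``ff``
        and an ``ica`` reference (simulated calibration or pseudo-IMRT
        fields).  Returns, per criteria label, the per-field results and
        the aggregate mean +- SD summary.
        """
        out: dict[str, tuple[list[GammaResult], GammaSummary]] = {}
        converted = []
        for f in fields:
            _, samples = self.convert_image(
                f.g_raw, f.df, f.ff, apply_matrix=apply_matrix
            )
            converted.append((f, samples))
        for crit in criteria:
            results = [gamma_2d(f.ica, s, crit) for f, s in converted]
            out[crit.label()] = (results, gamma_report(results))
        return out

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        """Human-readable account of the fitted calibration."""
        lines = []
        w = 72
        lines.append("=" * w)
        lines.append("EPID Portal Dose Calibration Results".center(w))
        lines.append("=" * w)
        sides = sorted(self.per_field_matrices)
        lines.append(f"Calibration fields:      {len(sides)} squares, "
                     f"{sides[0]:g}-{sides[-1]:g} cm")
        for klass in ("small", "medium", "large"):
            if klass in self.matrices:
                m = self.matrices[klass]
                lines.append(
                    f"  {klass:<6} matrix:        sides {m.sides_cm[0]:g}-"
                    f"{m.sides_cm[-1]:g} cm, {int(m.mask.sum())} chambers defined"
                )
        if self.of_table is not None:
            lines.append(
                f"Output factors:          OF({self.of_table.sides_cm[0]:g} cm) = "
                f"{self.of_table.of[0]:.4f} ... OF({self.of_table.reference_side_cm:g} cm)"
                f" = 1.0000"
            )
        if self.conversion_model is not None:
            cm_, cu = self.conversion_model, self.conversion_model_uncorrected
            lines.append(
                f"Dose conversion (CAX):   a = {cm_.a0:.6g} mGy/pixel, "
                f"b = {cm_.b0:.4g} mGy"
            )
            lines.append(
                f"a(r) flatness:           corrected {cm_.flatness()*100:.3f}% | "
                f"uncorrected {cu.flatness()*100:.3f}%"
            )
        if len(self.symmetry):
            lines.append(
                "Inline asymmetry:        pre "
                f"{self.symmetry['asymmetry_pre_pct'].max():.2f}% max -> post "
                f"{self.symmetry['asymmetry_post_pct'].max():.2f}% max"
            )
        lines.append("=" * w)
        return "\n".join(lines)
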