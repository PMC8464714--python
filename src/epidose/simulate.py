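"""Synthetic linac / EPID / chamber-array fixtures.

The generator produces physically plausible ground truth for the whole
calibration chain:

* a 6 MV-like beam with off-axis "horns" (quadratic off-axis ratio), an
  erf-shaped penumbra, a monotone field-size output curve and a linear
  MU response;
* an EPID response with (i) a flood-field pattern that — by default —
  equals the beam's own horned large-field profile (flood flattening then
  erases the horns exactly as on a real panel), (ii) an additive support-arm
  backscatter term linear in the inline coordinate whose sign switches
  with field size (positive inline excess for small fields, symmetric in
  the middle band, negative for large fields), (iii) a field-size scatter
  over-response, and (iv) multiplicative Gaussian noise;
* the chamber array as a noiseless reference sampling the same
  high-resolution dose through 0.45 cm-aperture (12 x 12 pixel) averaging.

The high-resolution dose is computed once on the EPID grid and box-averaged
to chamber apertures, so both detectors see a single source of truth.  All
randomness flows from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import erf

from .calibration import chamber_downsample
from .datatypes import (
    DoseGrid,
    EpidImage,
    FieldSpec,
    default_epid_geometry,
    default_ica_geometry,
)
from .exceptions import ConfigurationError, GeometryError

DEFAULT_SEED = 20210909


def _default_output_vs_field(side_cm: float) -> float:
    """Relative CAX output vs square-field side, normalized at 10 cm."""
    return 1.0 + 0.04 * np.log(side_cm / 10.0)


@dataclass
class BeamModel:
    """Linac output model: profile, penumbra, output curve, MU linearity."""

    horn_coeff: float = 3.0e-4  # fractional dose increase per cm^2 -> ~3.6% at r=11
    penumbra_sigma_cm: float = 0.3
    output_vs_field: Callable[[float], float] = _default_output_vs_field
    mu_slope_mGy: float = 10.0
    mu_intercept_mGy: float = 0.0

    def profile(self, r_cm):
        """Off-axis ratio, 1 on the CAX."""
        return 1.0 + self.horn_coeff * np.asarray(r_cm, dtype=float) ** 2

    def cax_dose_mGy(self, field: FieldSpec) -> float:
        return (self.mu_slope_mGy * field.mu + self.mu_intercept_mGy) * float(
            self.output_vs_field(field.side_cm)
        )

    def edge(self, u, half_width_cm: float):
        """erf rolloff of a field edge at +-half_width_cm."""
        s = self.penumbra_sigma_cm * np.sqrt(2.0)
        u = np.asarray(u, dtype=float)
        return 0.5 * (erf((half_width_cm - u) / s) + erf((half_width_cm + u) / s))


def _default_backscatter_amp(side_cm: float) -> float:
    """Signed inline-asymmetry amplitude: the three field-size regimes.

    Positive (inline+ reads high) for sides <= 10 cm, zero in the
    symmetric 10-15 cm band, negative beyond 15 cm.  The amplitude is
    constant within each regime — the premise behind correcting a whole
    regime with one merged matrix.
    """
    if side_cm <= 10.0:
        return 0.04
    if side_cm <= 15.0:
        return 0.0
    return -0.04


def _default_field_size_response(side_cm: float) -> float:
    """EPID scatter over-response vs field size (relative gain)."""
    return 1.0 + 0.015 * np.log(side_cm / 10.0)


@dataclass
class EpidResponseModel:
    """Panel response: gain, flood pattern, backscatter, noise."""

    gain: float = 715.0  # pixel units per mGy
    dark_level: float = 50.0  # pixel units
    flood_dose_mGy: float = 100.0  # uniform fluence behind the flood image
    backscatter_amp: Callable[[float], float] = _default_backscatter_amp
    backscatter_scale_cm: float = 10.0
    field_size_response: Callable[[float], float] = _default_field_size_response
    flood_profile: Callable | None = None  # None -> the beam's horned profile
    noise_sd_rel: float = 0.005

    @classmethod
    def ideal(cls, noise_sd_rel: float = 0.0) -> "EpidResponseModel":
        """All distortions off: flat flood, no backscatter, flat field-size
        response — the end-to-end identity configuration."""
        return cls(
            backscatter_amp=lambda s: 0.0,
            field_size_response=lambda s: 1.0,
            flood_profile=lambda r: np.ones_like(np.asarray(r, dtype=float)),
            noise_sd_rel=noise_sd_rel,
        )


@dataclass
class CalibrationField:
    """One paired acquisition: EPID triplet plus the chamber-array dose.

    ``ica`` is noiseless and doubles as the ground-truth dose for oracle
    checks (the chamber array is the reference instrument).
    """

    field: FieldSpec
    g_raw: EpidImage
    df: EpidImage
    ff: EpidImage
    ica: DoseGrid


def _check_field_fits(field: FieldSpec, lattice) -> None:
    # one-pitch margin: the 24 cm reference field reaches just past the
    # outermost chamber ring of the 23.6 cm-span lattice
    half = field.side_cm / 2.0
    limit = min(lattice.x_coords().max(), lattice.y_coords().max()) + lattice._pitch()
    if half > limit:
        raise GeometryError(
            f"{field.side_cm} cm field exceeds the {type(lattice).__name__} extent"
        )


def dose_highres(
    beam: BeamModel, field: FieldSpec, epid_geom: EpidImage | None = None
) -> np.ndarray:
    """True dose (mGy) on the EPID pixel grid for a square field."""
    g = epid_geom if epid_geom is not None else default_epid_geometry()
    half = field.side_cm / 2.0
    ex = beam.edge(g.x_coords(), half)[None, :]
    ey = beam.edge(g.y_coords(), half)[:, None]
    return beam.cax_dose_mGy(field) * beam.profile(g.radius_map()) * ex * ey


def true_dose(
    beam: BeamModel,
    field: FieldSpec,
    lattice: DoseGrid | None = None,
    epid_geom: EpidImage | None = None,
) -> DoseGrid:
    """Chamber-array measurement of the true dose (noiseless reference).

    The high-resolution dose is box-averaged over the chamber aperture at
    every lattice position.
    """
    lattice = lattice if lattice is not None else default_ica_geometry()
    _check_field_fits(field, lattice)
    g = epid_geom if epid_geom is not None else default_epid_geometry()
    hr = g.copy_with(dose_highres(beam, field, g))
    sampled = chamber_downsample(hr, lattice)
    return lattice.copy_with(sampled, side_cm=field.side_cm, mu=field.mu)


def _backscatter_term(
    response: EpidResponseModel, dose_hr: np.ndarray, y_cm: np.ndarray, side_cm: float
) -> np.ndarray:
    """Additive inline-linear backscatter, confined to the irradiated area."""
    amp = float(response.backscatter_amp(side_cm))
    return amp * (y_cm[:, None] / response.backscatter_scale_cm) * dose_hr


def simulate_epid_raw(
    beam: BeamModel,
    response: EpidResponseModel,
    field: FieldSpec,
    epid_geom: EpidImage | None = None,
    seed: int = DEFAULT_SEED,
    dose_hr: np.ndarray | None = None,
    side_for_response: float | None = None,
) -> tuple[EpidImage, EpidImage, EpidImage]:
    """Simulate one acquisition: (raw image, dark field, flood field).

    ``G_raw = DF + fsr(s) * gain * [dose + backscatter] * (1 + noise)``;
    the flood field carries the flood profile (by default the beam's own
    horned open-field shape, so flood flattening erases the horns from
    subsequently corrected images) but no field-specific backscatter; the
    dark field is a constant positive baseline.  Identical seeds give
    identical arrays.
    """
    g = epid_geom if epid_geom is not None else default_epid_geometry()
    side = side_for_response if side_for_response is not None else field.side_cm
    if dose_hr is None:
        dose_hr = dose_highres(beam, field, g)
    rng = np.random.default_rng(seed)
    r = g.radius_map()
    fp = (
        response.flood_profile(r)
        if response.flood_profile is not None
        else beam.profile(r)
    )
    fsr = float(response.field_size_response(side))
    signal = fsr * response.gain * (
        dose_hr + _backscatter_term(response, dose_hr, g.y_coords(), side)
    )
    noise1 = 1.0 + response.noise_sd_rel * rng.standard_normal(g.shape)
    noise2 = 1.0 + response.noise_sd_rel * rng.standard_normal(g.shape)
    g_raw = g.copy_with(
        response.dark_level + signal * noise1,
        kind="raw", side_cm=field.side_cm, mu=field.mu, seed=seed,
    )
    ff = g.copy_with(
        response.dark_level + fp * response.gain * response.flood_dose_mGy * noise2,
        kind="flood", seed=seed,
    )
    df = g.copy_with(np.full(g.shape, response.dark_level), kind="dark")
    return g_raw, df, ff


def make_calibration_suite(
    beam: BeamModel,
    response: EpidResponseModel,
    sides_cm,
    mu: float = 100.0,
    lattice: DoseGrid | None = None,
    epid_geom: EpidImage | None = None,
    seed: int = DEFAULT_SEED,
) -> list[CalibrationField]:
    """Paired EPID/ICA acquisitions of square fields (default 100 MU each)."""
    sides = [float(s) for s in sides_cm]
    if len(set(sides)) != len(sides):
        raise ConfigurationError("duplicate field sides in the calibration suite")
    lattice = lattice if lattice is not None else default_ica_geometry()
    out = []
    child_seeds = np.random.SeedSequence(seed).generate_state(len(sides)) % (2**31)
    for s, child in zip(sides, child_seeds):
        fld = FieldSpec(side_cm=s, mu=mu)
        g_raw, df, ff = simulate_epid_raw(
            beam, response, fld, epid_geom=epid_geom, seed=int(child)
        )
        ica = true_dose(beam, fld, lattice=lattice, epid_geom=epid_geom)
        out.append(CalibrationField(field=fld, g_raw=g_raw, df=df, ff=ff, ica=ica))
    return out


def make_mu_series(
    beam: BeamModel,
    response: EpidResponseModel,
    mu_levels,
    side_cm: float = 24.0,
    repeats: int = 1,
    lattice: DoseGrid | None = None,
    epid_geom: EpidImage | None = None,
    seed: int = DEFAULT_SEED,
) -> list[CalibrationField]:
    """MU-linearity series on one (default 24 cm) field, optionally repeated."""
    lattice = lattice if lattice is not None else default_ica_geometry()
    out = []
    n = len(list(mu_levels)) * repeats
    child_seeds = np.random.SeedSequence(seed + 1).generate_state(n) % (2**31)
    k = 0
    for mu in mu_levels:
        fld = FieldSpec(side_cm=side_cm, mu=float(mu))
        ica = true_dose(beam, fld, lattice=lattice, epid_geom=epid_geom)
        for _ in range(repeats):
            g_raw, df, ff = simulate_epid_raw(
                beam, response, fld, epid_geom=epid_geom, seed=int(child_seeds[k])
            )
            k += 1
            out.append(CalibrationField(field=fld, g_raw=g_raw, df=df, ff=ff, ica=ica))
    return out


@dataclass
class ImrtField:
    """A pseudo-modulated field built from weighted rectangular segments."""

    segments: list  # (x_center, y_center, width_x, width_y, weight)
    mu: float
    equivalent_side_cm: float
    g_raw: EpidImage
    df: EpidImage
    ff: EpidImage
    ica: DoseGrid


def make_imrt_field(
    beam: BeamModel,
    response: EpidResponseModel,
    rng: np.random.Generator,
    n_segments: int = 4,
    mu: float = 100.0,
    lattice: DoseGrid | None = None,
    epid_geom: EpidImage | None = None,
) -> ImrtField:
    """One pseudo-IMRT field: a sum of overlapping rectangular segments.

    Segment centers, widths and weights are drawn from ``rng``; the inline
    backscatter amplitude and field-size response follow the equivalent
    square (side sqrt(A) of the 50% area) of the composite dose.
    """
    g = epid_geom if epid_geom is not None else default_epid_geometry()
    lattice = lattice if lattice is not None else default_ica_geometry()
    base = beam.mu_slope_mGy * mu + beam.mu_intercept_mGy
    x = g.x_coords()
    y = g.y_coords()
    dose_hr = np.zeros(g.shape)
    segments = []
    for _ in range(n_segments):
        wx = rng.uniform(4.0, 14.0)
        wy = rng.uniform(4.0, 14.0)
        cx = rng.uniform(-4.0, 4.0)
        cy = rng.uniform(-4.0, 4.0)
        w = rng.uniform(0.3, 1.0)
        ex = beam.edge(x - cx, wx / 2.0)[None, :]
        ey = beam.edge(y - cy, wy / 2.0)[:, None]
        dose_hr += w * base * ex * ey
        segments.append((cx, cy, wx, wy, w))
    dose_hr /= max(1.0, sum(s[4] for s in segments))
    dose_hr *= beam.profile(g.radius_map())
    area = np.count_nonzero(dose_hr >= 0.5 * dose_hr.max()) * g.pixel_pitch_cm**2
    eq_side = float(np.sqrt(area))
    fld = FieldSpec(side_cm=max(eq_side, 1.0), mu=mu)
    g_raw, df, ff = simulate_epid_raw(
        beam,
        response,
        fld,
        epid_geom=g,
        seed=int(rng.integers(0, 2**31 - 1)),
        dose_hr=dose_hr,
        side_for_response=eq_side,
    )
    hr = g.copy_with(dose_hr)
    ica = lattice.copy_with(chamber_downsample(hr, lattice), kind="imrt", mu=mu)
    return ImrtField(
        segments=segments,
        mu=mu,
        equivalent_side_cm=eq_side,
        g_raw=g_raw,
        df=df,
        ff=ff,
        ica=ica,
    )
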