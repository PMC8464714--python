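"""Core in-memory containers for EPID portal dosimetry.

Two detector lattices appear throughout the package:

* the amorphous-silicon flat panel (default 768 x 1024 pixels, 0.039 cm
  pitch, 30 x 40 cm^2 at a source-to-detector distance of 100 cm), held by
  :class:`EpidImage`;
* the ionization-chamber array (default 32 x 32 chambers, 0.762 cm pitch,
  24 x 24 cm^2), held by :class:`DoseGrid`.

Shared coordinate convention
----------------------------
Physical coordinates are in cm at the isocenter plane with the origin on
the beam central axis (CAX).  ``x`` is the crossline axis and increases
with column index; ``y`` is the inline axis and increases as the row index
*decreases* (rows run toward the inline-negative, gantry-target side).
The off-axis radius is ``r = sqrt(x^2 + y^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .exceptions import ConfigurationError, GeometryError

EPID_SHAPE = (768, 1024)
EPID_PITCH_CM = 0.039
ICA_SHAPE = (32, 32)
ICA_PITCH_CM = 0.762
CHAMBER_DIAMETER_CM = 0.45
#: pixels averaged per chamber sample: 12 * 0.039 cm ~ 0.468 cm ~ chamber bore
CHAMBER_BLOCK_PX = 12


class _Grid2D:
    """Mixin providing physical-coordinate bookkeeping for a regular lattice."""

    # subclasses define: _values() -> np.ndarray, pitch (cm), cax_row, cax_col

    @property
    def n_rows(self) -> int:
        return self._values().shape[0]

    @property
    def n_cols(self) -> int:
        return self._values().shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self._values().shape

    def x_coords(self) -> np.ndarray:
        """Crossline coordinate (cm) of every column."""
        return (np.arange(self.n_cols) - self.cax_col) * self._pitch()

    def y_coords(self) -> np.ndarray:
        """Inline coordinate (cm) of every row (decreasing with row index)."""
        return -(np.arange(self.n_rows) - self.cax_row) * self._pitch()

    def phys_to_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Fractional (row, col) lattice index of physical point(s) (x, y) cm."""
        col = np.asarray(x) / self._pitch() + self.cax_col
        row = self.cax_row - np.asarray(y) / self._pitch()
        return row, col

    def index_to_phys(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        x = (np.asarray(col) - self.cax_col) * self._pitch()
        y = -(np.asarray(row) - self.cax_row) * self._pitch()
        return x, y

    def radius_map(self) -> np.ndarray:
        """Off-axis radius r (cm) at every lattice point."""
        x = self.x_coords()[None, :]
        y = self.y_coords()[:, None]
        return np.hypot(x, y)

    def same_geometry(self, other: "_Grid2D", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self._pitch() - other._pitch()) <= tol
            and abs(self.cax_row - other.cax_row) <= tol
            and abs(self.cax_col - other.cax_col) <= tol
        )


@dataclass
class EpidImage(_Grid2D):
    """A 2D EPID pixel-value image with panel geometry.

    ``pixels`` are detector units (raw, dark, flood, or corrected signal);
    after conversion the same container may carry dose in mGy (``meta`` then
    records ``units='mGy'``).
    """

    pixels: np.ndarray
    pixel_pitch_cm: float = EPID_PITCH_CM
    cax_row: float | None = None
    cax_col: float | None = None
    sdd_cm: float = 100.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise GeometryError(f"EPID image must be 2D, got ndim={self.pixels.ndim}")
        if self.pixel_pitch_cm <= 0:
            raise GeometryError("pixel_pitch_cm must be positive")
        if self.cax_row is None:
            self.cax_row = (self.pixels.shape[0] - 1) / 2.0
        if self.cax_col is None:
            self.cax_col = (self.pixels.shape[1] - 1) / 2.0
        if not (0 <= self.cax_row < self.pixels.shape[0]):
            raise GeometryError("cax_row outside panel")
        if not (0 <= self.cax_col < self.pixels.shape[1]):
            raise GeometryError("cax_col outside panel")

    def _values(self) -> np.ndarray:
        return self.pixels

    def _pitch(self) -> float:
        return self.pixel_pitch_cm

    def copy_with(self, pixels: np.ndarray, **meta) -> "EpidImage":
        """Same geometry, new pixel payload; ``meta`` entries are merged."""
        return EpidImage(
            pixels=np.asarray(pixels, dtype=float),
            pixel_pitch_cm=self.pixel_pitch_cm,
            cax_row=self.cax_row,
            cax_col=self.cax_col,
            sdd_cm=self.sdd_cm,
            meta={**self.meta, **meta},
        )


@dataclass
class DoseGrid(_Grid2D):
    """Absolute dose (mGy) on the ionization-chamber-array lattice."""

    dose_mGy: np.ndarray
    pitch_cm: float = ICA_PITCH_CM
    cax_row: float | None = None
    cax_col: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.dose_mGy = np.asarray(self.dose_mGy, dtype=float)
        if self.dose_mGy.ndim != 2:
            raise GeometryError(f"dose grid must be 2D, got ndim={self.dose_mGy.ndim}")
        if self.pitch_cm <= 0:
            raise GeometryError("pitch_cm must be positive")
        if self.cax_row is None:
            self.cax_row = (self.dose_mGy.shape[0] - 1) / 2.0
        if self.cax_col is None:
            self.cax_col = (self.dose_mGy.shape[1] - 1) / 2.0

    def _values(self) -> np.ndarray:
        return self.dose_mGy

    def _pitch(self) -> float:
        return self.pitch_cm

    def copy_with(self, dose_mGy: np.ndarray, **meta) -> "DoseGrid":
        return DoseGrid(
            dose_mGy=np.asarray(dose_mGy, dtype=float),
            pitch_cm=self.pitch_cm,
            cax_row=self.cax_row,
            cax_col=self.cax_col,
            meta={**self.meta, **meta},
        )


def default_ica_geometry() -> DoseGrid:
    """An empty 32 x 32 chamber lattice carrying only geometry."""
    return DoseGrid(dose_mGy=np.zeros(ICA_SHAPE), pitch_cm=ICA_PITCH_CM)


def default_epid_geometry() -> EpidImage:
    """An empty 768 x 1024 panel carrying only geometry."""
    return EpidImage(pixels=np.zeros(EPID_SHAPE), pixel_pitch_cm=EPID_PITCH_CM)


@dataclass(frozen=True)
class FieldSpec:
    """A square treatment field: side length (cm at isocenter), MU, dose rate."""

    side_cm: float
    mu: float = 100.0
    dose_rate_mu_min: float = 600.0

    def __post_init__(self):
        if self.side_cm <= 0:
            raise GeometryError("field side must be positive")
        if self.mu <= 0:
            raise GeometryError("MU must be positive")


@dataclass
class CorrectionMatrix(_Grid2D):
    """CAX-normalized dose-to-pixel ratio field on the chamber lattice.

    ``values[i, j]`` multiplies the (CAX-normalized) EPID signal to restore
    both inline backscatter symmetry and the true off-axis profile; ``mask``
    marks the chambers where the ratio is defined (dose >= 20% of the
    field maximum for at least one contributing field).  ``source_side``
    records, per chamber, the side length (cm) of the calibration field
    whose ratio survives the merge (NaN outside the mask).
    """

    values: np.ndarray
    mask: np.ndarray
    pitch_cm: float = ICA_PITCH_CM
    cax_row: float | None = None
    cax_col: float | None = None
    sides_cm: tuple = ()
    matrix_class: str | None = None  # "small" | "medium" | "large" | None
    source_side: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise GeometryError("values/mask shape mismatch")
        if self.cax_row is None:
            self.cax_row = (self.values.shape[0] - 1) / 2.0
        if self.cax_col is None:
            self.cax_col = (self.values.shape[1] - 1) / 2.0
        if self.source_side is None:
            ss = np.full(self.values.shape, np.nan)
            if len(self.sides_cm) == 1:
                ss[self.mask] = self.sides_cm[0]
            self.source_side = ss
        self.sides_cm = tuple(float(s) for s in self.sides_cm)
        masked = self.values[self.mask]
        if masked.size and not (np.all(np.isfinite(masked)) and np.all(masked > 0)):
            raise GeometryError("correction values must be finite and > 0 on the mask")

    def _values(self) -> np.ndarray:
        return self.values

    def _pitch(self) -> float:
        return self.pitch_cm


#: side-length ranges (cm) of the fields merged into each common matrix
MATRIX_CLASS_RANGES: dict[str, tuple[float, float]] = {
    "small": (9.0, 24.0),
    "medium": (13.0, 24.0),
    "large": (18.0, 24.0),
}


@dataclass
class OutputFactorTable:
    """Field output factor OF(s), normalized so OF at the 24 cm reference is 1.

    OF reconciles the field-size dependence of EPID scatter response with
    that of the chamber array: OF(s) = [D(s)/D(ref)] / [G(s)/G(ref)].
    """

    sides_cm: np.ndarray
    of: np.ndarray
    reference_side_cm: float = 24.0

    def __post_init__(self):
        self.sides_cm = np.asarray(self.sides_cm, dtype=float)
        self.of = np.asarray(self.of, dtype=float)
        order = np.argsort(self.sides_cm)
        self.sides_cm = self.sides_cm[order]
        self.of = self.of[order]

    def __call__(self, side_cm: float) -> float:
        """OF at ``side_cm``; intermediate sides linearly interpolated."""
        return float(np.interp(side_cm, self.sides_cm, self.of))


@dataclass(frozen=True)
class GammaCriteria:
    """Global gamma criteria: dose difference (% of reference max) and DTA (mm)."""

    dose_diff_pct: float = 3.0
    dta_mm: float = 3.0
    low_dose_threshold_pct: float = 5.0
    search_radius_mm: float | None = None  # default 3 x dta
    eval_supersampling: int = 10
    #: normalize the dose difference to each point's own reference dose
    #: instead of the reference maximum (not used by the validated chain)
    local_norm: bool = False

    def __post_init__(self):
        if min(self.dose_diff_pct, self.dta_mm, self.low_dose_threshold_pct) <= 0:
            raise ConfigurationError("gamma criteria must be positive")
        if self.eval_supersampling < 1:
            raise ConfigurationError("eval_supersampling must be >= 1")
        if self.search_radius_mm is None:
            object.__setattr__(self, "search_radius_mm", 3.0 * self.dta_mm)
        if self.search_radius_mm < self.dta_mm:
            raise ConfigurationError("search radius must cover at least one DTA")

    def label(self) -> str:
        mode = "local " if self.local_norm else ""
        return (
            f"{self.dose_diff_pct:g}%/{self.dta_mm:g}mm "
            f"({mode}th {self.low_dose_threshold_pct:g}%)"
        )


@dataclass
class GammaResult:
    """Per-point gamma map plus pass-rate / mean-gamma summaries."""

    gamma_map: np.ndarray  # NaN below the low-dose threshold
    pass_rate_pct: float
    mean_gamma: float
    n_evaluated: int
    criteria: GammaCriteria


@dataclass
class SymmetryReport:
    """Inline-profile symmetry diagnostics for one field.

    ``inline_ratio`` tabulates P(+y)/P(-y) at inline offsets ``offsets_cm``;
    ``inline_crossline_ratio`` tabulates G(inline -d)/G(crossline -d).
    Ratios are defined only where both samples exceed 20% of the profile
    maximum (NaN elsewhere).
    """

    side_cm: float
    offsets_cm: np.ndarray
    inline_ratio: np.ndarray
    inline_crossline_ratio: np.ndarray
    max_asymmetry_pct: float


def bilinear_sample(values: np.ndarray, row: np.ndarray, col: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of ``values`` at fractional (row, col) indices.

    Indices are clamped to the array extent, so queries outside the lattice
    hold the edge value constant.
    """
    values = np.asarray(values, dtype=float)
    nr, nc = values.shape
    row = np.clip(np.asarray(row, dtype=float), 0.0, nr - 1.0)
    col = np.clip(np.asarray(col, dtype=float), 0.0, nc - 1.0)
    r0 = np.clip(np.floor(row).astype(int), 0, nr - 2) if nr > 1 else np.zeros_like(row, int)
    c0 = np.clip(np.floor(col).astype(int), 0, nc - 2) if nc > 1 else np.zeros_like(col, int)
    r1 = np.minimum(r0 + 1, nr - 1)
    c1 = np.minimum(c0 + 1, nc - 1)
    fr = row - r0
    fc = col - c0
    v00 = values[r0, c0]
    v01 = values[r0, c1]
    v10 = values[r1, c0]
    v11 = values[r1, c1]
    return (
        v00 * (1 - fr) * (1 - fc)
        + v01 * (1 - fr) * fc
        + v10 * fr * (1 - fc)
        + v11 * fr * fc
    )


def value_at_cax(grid: _Grid2D) -> float:
    """Lattice value at the central axis (bilinear if the CAX index is fractional)."""
    return float(
        bilinear_sample(grid._values(), np.array([grid.cax_row]), np.array([grid.cax_col]))[0]
    )
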