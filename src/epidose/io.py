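"""On-disk formats for images, dose grids, matrices and models.

The canonical interchange format is a plain CSV matrix plus a JSON sidecar
(`<stem>.json`) carrying geometry and provenance — human-diffable and
lossless at full float precision.  DICOM RT Image import is supported
read-only via pydicom; chamber-array exports in the whitespace-delimited
OPG dialect (header lines start with a non-numeric token) are read-only
too.  Correction matrices, conversion models and output-factor tables are
versioned JSON documents.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .conversion import ConversionModel
from .datatypes import CorrectionMatrix, DoseGrid, EpidImage, OutputFactorTable
from .exceptions import FormatError, MetadataError

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1
_CSV_FMT = "%.17g"  # round-trips float64 exactly


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _load_matrix_csv(path: Path) -> np.ndarray:
    try:
        arr = np.loadtxt(path, delimiter=",", ndmin=2)
    except (ValueError, OSError) as e:
        if isinstance(e, OSError) and not Path(path).exists():
            raise
        raise FormatError(f"{path}: not a numeric CSV matrix ({e})") from e
    if arr.ndim != 2:
        raise FormatError(f"{path}: pixel data is not 2D")
    return arr


# ---------------------------------------------------------------------------
# EPID images
# ---------------------------------------------------------------------------

def write_epid_image(img: EpidImage, path) -> None:
    path = Path(path)
    np.savetxt(path, img.pixels, delimiter=",", fmt=_CSV_FMT)
    sidecar = {
        "format_version": FORMAT_VERSION,
        "type": "epid_image",
        "pixel_pitch_cm": img.pixel_pitch_cm,
        "cax_row": img.cax_row,
        "cax_col": img.cax_col,
        "sdd_cm": img.sdd_cm,
        "meta": img.meta,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def _read_epid_csv(path: Path, allow_defaults: bool) -> EpidImage:
    arr = _load_matrix_csv(path)
    if not np.isfinite(arr).all():
        raise FormatError(f"{path}: non-finite pixel value(s)")
    sidecar = _sidecar_path(path)
    kwargs: dict = {}
    if sidecar.exists():
        try:
            doc = json.loads(sidecar.read_text())
        except json.JSONDecodeError as e:
            raise FormatError(f"{sidecar}: invalid sidecar JSON ({e})") from e
        kwargs = {
            "pixel_pitch_cm": doc.get("pixel_pitch_cm", 0.039),
            "cax_row": doc.get("cax_row"),
            "cax_col": doc.get("cax_col"),
            "sdd_cm": doc.get("sdd_cm", 100.0),
            "meta": doc.get("meta", {}),
        }
    elif allow_defaults:
        logger.warning("%s: no sidecar, using default panel geometry", path)
    else:
        raise MetadataError(f"{path}: sidecar with geometry metadata required")
    return EpidImage(pixels=arr, **kwargs)


def _read_epid_dicom(path: Path) -> EpidImage:
    import pydicom

    try:
        ds = pydicom.dcmread(str(path), force=True)
        arr = ds.pixel_array.astype(float)
    except Exception as e:  # pydicom raises a zoo of exceptions
        raise FormatError(f"{path}: unreadable DICOM ({e})") from e
    if arr.ndim != 2:
        raise FormatError(f"{path}: DICOM pixel data is not 2D")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    pitch_cm = 0.039
    spacing = getattr(ds, "ImagePlanePixelSpacing", None)
    if spacing is not None:
        pitch_cm = float(spacing[0]) / 10.0
        sid = getattr(ds, "RTImageSID", None)
        sad = getattr(ds, "RadiationMachineSAD", None)
        if sid and sad:  # rescale detector-plane pitch to the isocenter plane
            pitch_cm *= float(sad) / float(sid)
    sdd_cm = float(getattr(ds, "RTImageSID", 1000.0)) / 10.0
    meta = {"source": "dicom", "sop_class": str(getattr(ds, "SOPClassUID", ""))}
    return EpidImage(pixels=arr, pixel_pitch_cm=pitch_cm, sdd_cm=sdd_cm, meta=meta)


def read_epid_image(path, format: str = "auto", allow_defaults: bool = True) -> EpidImage:
    """Read an EPID image from CSV(+JSON sidecar) or DICOM RT Image.

    ``format='auto'`` dispatches on the file suffix (``.dcm`` -> DICOM).
    Without a sidecar the default panel geometry is assumed (warning
    logged) unless ``allow_defaults`` is false.
    """
    path = Path(path)
    if format == "dicom" or (format == "auto" and path.suffix.lower() == ".dcm"):
        return _read_epid_dicom(path)
    return _read_epid_csv(path, allow_defaults)


# ---------------------------------------------------------------------------
# dose grids
# ---------------------------------------------------------------------------

def write_dose_grid(grid: DoseGrid, path) -> None:
    path = Path(path)
    np.savetxt(path, grid.dose_mGy, delimiter=",", fmt=_CSV_FMT)
    sidecar = {
        "format_version": FORMAT_VERSION,
        "type": "dose_grid",
        "pitch_cm": grid.pitch_cm,
        "cax_row": grid.cax_row,
        "cax_col": grid.cax_col,
        "meta": grid.meta,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def _check_dose(arr: np.ndarray, path) -> None:
    if not np.isfinite(arr).all():
        raise FormatError(f"{path}: non-finite dose value(s)")
    if (arr < 0).any():
        raise FormatError(f"{path}: negative dose value(s)")


def _read_opg(path: Path) -> np.ndarray:
    """Whitespace-delimited chamber-array export: any line whose first token
    is not a number is header/comment."""
    rows = []
    for line in Path(path).read_text().splitlines():
        tokens = line.replace(",", " ").split()
        if not tokens:
            continue
        try:
            float(tokens[0])
        except ValueError:
            continue
        try:
            rows.append([float(t) for t in tokens])
        except ValueError as e:
            raise FormatError(f"{path}: mixed numeric/non-numeric data row") from e
    if not rows:
        raise FormatError(f"{path}: no numeric data rows")
    if len({len(r) for r in rows}) != 1:
        raise FormatError(f"{path}: ragged data block")
    return np.array(rows)


def read_dose_grid(path, format: str = "auto") -> DoseGrid:
    """Read a chamber-array dose grid from CSV(+sidecar) or OPG-style text."""
    path = Path(path)
    if format == "opg" or (format == "auto" and path.suffix.lower() == ".opg"):
        arr = _read_opg(path)
    else:
        arr = _load_matrix_csv(path)
    _check_dose(arr, path)
    sidecar = _sidecar_path(path)
    kwargs: dict = {}
    if sidecar.exists():
        doc = json.loads(sidecar.read_text())
        kwargs = {
            "pitch_cm": doc.get("pitch_cm", 0.762),
            "cax_row": doc.get("cax_row"),
            "cax_col": doc.get("cax_col"),
            "meta": doc.get("meta", {}),
        }
    return DoseGrid(dose_mGy=arr, **kwargs)


# ---------------------------------------------------------------------------
# correction matrices / models (versioned JSON)
# ---------------------------------------------------------------------------

def _nan_to_none(a: np.ndarray) -> list:
    return [[None if not np.isfinite(v) else v for v in row] for row in a]


def _none_to_nan(rows: list) -> np.ndarray:
    return np.array(
        [[np.nan if v is None else float(v) for v in row] for row in rows], dtype=float
    )


def _load_versioned(path, expect_type: str) -> dict:
    try:
        doc = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as e:
        raise FormatError(f"{path}: invalid or truncated JSON ({e})") from e
    if not isinstance(doc, dict) or doc.get("type") != expect_type:
        raise FormatError(f"{path}: not a serialized {expect_type}")
    if doc.get("format_version") != FORMAT_VERSION:
        raise FormatError(
            f"{path}: format_version {doc.get('format_version')!r}, "
            f"expected {FORMAT_VERSION}"
        )
    return doc


def write_correction_matrix(cm: CorrectionMatrix, path) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "type": "correction_matrix",
        "values": _nan_to_none(cm.values),
        "mask": cm.mask.astype(int).tolist(),
        "source_side": _nan_to_none(cm.source_side),
        "pitch_cm": cm.pitch_cm,
        "cax_row": cm.cax_row,
        "cax_col": cm.cax_col,
        "sides_cm": list(cm.sides_cm),
        "matrix_class": cm.matrix_class,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def read_correction_matrix(path) -> CorrectionMatrix:
    doc = _load_versioned(path, "correction_matrix")
    try:
        return CorrectionMatrix(
            values=_none_to_nan(doc["values"]),
            mask=np.array(doc["mask"], dtype=bool),
            pitch_cm=doc["pitch_cm"],
            cax_row=doc["cax_row"],
            cax_col=doc["cax_col"],
            sides_cm=tuple(doc["sides_cm"]),
            matrix_class=doc["matrix_class"],
            source_side=_none_to_nan(doc["source_side"]),
        )
    except KeyError as e:
        raise FormatError(f"{path}: missing field {e}") from e


def write_conversion_model(model: ConversionModel, path) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "type": "conversion_model",
        "r_cm": model.r_cm.tolist(),
        "a": model.a.tolist(),
        "b": model.b.tolist(),
        "a_se": _nan_to_none(model.a_se[None, :])[0] if model.a_se is not None else None,
        "b_se": _nan_to_none(model.b_se[None, :])[0] if model.b_se is not None else None,
        "use_cax_only": model.use_cax_only,
        "meta": model.meta,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def read_conversion_model(path) -> ConversionModel:
    doc = _load_versioned(path, "conversion_model")
    se = lambda key: (  # noqa: E731
        None if doc.get(key) is None else _none_to_nan([doc[key]])[0]
    )
    return ConversionModel(
        r_cm=np.array(doc["r_cm"]),
        a=np.array(doc["a"]),
        b=np.array(doc["b"]),
        a_se=se("a_se"),
        b_se=se("b_se"),
        use_cax_only=doc["use_cax_only"],
        meta=doc.get("meta", {}),
    )


def write_output_factors(table: OutputFactorTable, path) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "type": "output_factors",
        "sides_cm": table.sides_cm.tolist(),
        "of": table.of.tolist(),
        "reference_side_cm": table.reference_side_cm,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def read_output_factors(path) -> OutputFactorTable:
    doc = _load_versioned(path, "output_factors")
    return OutputFactorTable(
        sides_cm=np.array(doc["sides_cm"]),
        of=np.array(doc["of"]),
        reference_side_cm=doc["reference_side_cm"],
    )
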