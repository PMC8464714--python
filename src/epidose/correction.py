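"""Raw EPID image correction with dark- and flood-field images.

The panel's acquisition chain reports raw pixel values contaminated by a
per-pixel dark offset and a per-pixel gain pattern.  The standard
correction is

    G_EPID = (G_raw - DF) / (FF - DF) * FF_mean

where ``DF`` is the dark field, ``FF`` the flood field and ``FF_mean`` the
arithmetic mean of the flood field over the whole panel.  Dividing by the
flood field flattens the per-pixel gain but also erases the beam's true
off-axis shape ("horns") — that defect is what the correction matrices of
:mod:`epidose.calibration` later restore.
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import EpidImage
from .exceptions import FloodFieldError, GeometryError

logger = logging.getLogger(__name__)

#: pixels with 0 < FF - DF <= DEAD_PIXEL_EPS * FF_mean are treated as dead
DEAD_PIXEL_EPS = 1e-3


def _infill_dead(values: np.ndarray, dead: np.ndarray) -> np.ndarray:
    """Replace dead pixels by the median of valid pixels in a growing window."""
    out = values.copy()
    nr, nc = values.shape
    valid = ~dead
    for r, c in np.argwhere(dead):
        for half in (1, 2, 4, 8, 16, 32):
            r0, r1 = max(0, r - half), min(nr, r + half + 1)
            c0, c1 = max(0, c - half), min(nc, c + half + 1)
            patch = values[r0:r1, c0:c1][valid[r0:r1, c0:c1]]
            if patch.size:
                out[r, c] = np.median(patch)
                break
        else:  # whole panel dead-adjacent; leave 0
            out[r, c] = 0.0
    return out


def correct_raw(
    g_raw: EpidImage,
    df: EpidImage,
    ff: EpidImage,
    dead_pixel_eps: float = DEAD_PIXEL_EPS,
) -> EpidImage:
    """Apply the dark/flood-field correction to a raw EPID image.

    Parameters
    ----------
    g_raw, df, ff
        Raw image, dark field and flood field on identical panel geometry.
    dead_pixel_eps
        Pixels where ``FF - DF`` is positive but below ``dead_pixel_eps *
        FF_mean`` are considered defective; they are masked out and
        in-filled with the median of nearby valid pixels.

    Returns
    -------
    EpidImage
        The flattened image.  ``meta`` records ``n_dead_pixels`` and
        ``n_clipped_negative`` (negative results are clipped to zero).

    Raises
    ------
    GeometryError
        If the three images do not share panel geometry.
    FloodFieldError
        If ``FF - DF <= 0`` anywhere (panel not fully illuminated by the
        flood exposure); the error carries the offending pixel count.
    """
    if not (g_raw.same_geometry(df) and g_raw.same_geometry(ff)):
        raise GeometryError("raw/dark/flood images must share panel geometry")

    denom = ff.pixels - df.pixels
    n_bad = int(np.count_nonzero(denom <= 0))
    if n_bad:
        raise FloodFieldError(n_bad)

    ff_mean = float(ff.pixels.mean())
    dead = denom <= dead_pixel_eps * ff_mean
    n_dead = int(np.count_nonzero(dead))

    with np.errstate(divide="ignore", invalid="ignore"):
        out = (g_raw.pixels - df.pixels) / denom * ff_mean
    if n_dead:
        out = _infill_dead(out, dead)
        logger.warning("in-filled %d dead pixel(s) (FF-DF below threshold)", n_dead)

    n_clipped = int(np.count_nonzero(out < 0))
    if n_clipped:
        logger.info("clipped %d negative pixel(s) to zero", n_clipped)
        out = np.clip(out, 0.0, None)

    return g_raw.copy_with(
        out, corrected="dark_flood", n_dead_pixels=n_dead, n_clipped_negative=n_clipped
    )
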