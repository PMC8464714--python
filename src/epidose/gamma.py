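"""2D global gamma-index comparison of dose distributions.

For every reference point with dose at or above the low-dose threshold,

    gamma = min over evaluated positions p within the search radius of
            sqrt( (D_eval(p) - D_ref)^2 / (dd * max(D_ref))^2
                  + |p - p_ref|^2 / dta^2 )

with dd the global dose-difference criterion (fraction of the reference
maximum) and dta the distance-to-agreement.  The evaluated distribution
is resampled (bilinear) at ``eval_supersampling`` times its native
resolution before the search, the standard discrete approximation to the
continuous minimum.  A point passes when gamma <= 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import DoseGrid, EpidImage, GammaCriteria, GammaResult, _Grid2D
from .exceptions import AnalysisError, ConfigurationError, GeometryError

#: numeric guard so an exactly-critical point (gamma == 1) passes despite
#: floating-point rounding in the ratio
_PASS_TOL = 1e-9


def _grid_arrays(obj) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(values, x_coords, y_coords) of a DoseGrid or dose-carrying EpidImage."""
    if isinstance(obj, DoseGrid):
        return obj.dose_mGy, obj.x_coords(), obj.y_coords()
    if isinstance(obj, EpidImage):
        return obj.pixels, obj.x_coords(), obj.y_coords()
    if isinstance(obj, _Grid2D):
        return obj._values(), obj.x_coords(), obj.y_coords()
    raise GeometryError(f"cannot interpret {type(obj).__name__} as a dose grid")


def supersample(values: np.ndarray, x: np.ndarray, y: np.ndarray, k: int):
    """Bilinear resampling at k x native resolution (nodes preserved).

    New axes subdivide every lattice interval into k steps, endpoints
    inclusive, so native nodes appear exactly in the fine grid.
    """
    ny, nx = values.shape
    fi = np.arange((ny - 1) * k + 1) / k if ny > 1 else np.zeros(1)
    fj = np.arange((nx - 1) * k + 1) / k if nx > 1 else np.zeros(1)
    i0 = np.minimum(np.floor(fi).astype(int), max(ny - 2, 0))
    j0 = np.minimum(np.floor(fj).astype(int), max(nx - 2, 0))
    i1 = np.minimum(i0 + 1, ny - 1)
    j1 = np.minimum(j0 + 1, nx - 1)
    ti = (fi - i0)[:, None]
    tj = (fj - j0)[None, :]
    fine = (
        values[np.ix_(i0, j0)] * (1 - ti) * (1 - tj)
        + values[np.ix_(i0, j1)] * (1 - ti) * tj
        + values[np.ix_(i1, j0)] * ti * (1 - tj)
        + values[np.ix_(i1, j1)] * ti * tj
    )
    xs = np.interp(fj, np.arange(nx), x)
    ys = np.interp(fi, np.arange(ny), y)
    return fine, xs, ys


def gamma_2d(reference: DoseGrid, evaluated, criteria: GammaCriteria) -> GammaResult:
    """Global gamma of ``evaluated`` against ``reference`` at reference points.

    ``evaluated`` may be a :class:`DoseGrid` or a dose-carrying
    :class:`EpidImage`; both must share the physical coordinate frame
    (cm, origin on the CAX).  Points of the reference below
    ``low_dose_threshold_pct`` of its maximum are excluded (NaN in the
    gamma map and absent from the summaries).
    """
    ref, xr, yr = _grid_arrays(reference)
    ev, xe, ye = _grid_arrays(evaluated)
    if ref.size == 0 or not np.isfinite(ref).any() or ref.max() <= 0:
        raise AnalysisError("reference distribution empty or non-positive")
    if ev.size == 0 or not np.isfinite(ev).any():
        raise AnalysisError("evaluated distribution empty")

    fine, xs, ys = supersample(ev, xe, ye, criteria.eval_supersampling)
    dd_abs = criteria.dose_diff_pct / 100.0 * ref.max()
    dta_cm = criteria.dta_mm / 10.0
    radius_cm = criteria.search_radius_mm / 10.0
    thresh = criteria.low_dose_threshold_pct / 100.0 * ref.max()

    # per-axis candidate windows (fine axes are monotone)
    xs_sorted = np.sort(xs)
    ys_sorted = np.sort(ys)
    x_lo = np.searchsorted(xs_sorted, xr - radius_cm, side="left")
    x_hi = np.searchsorted(xs_sorted, xr + radius_cm, side="right")
    y_lo = np.searchsorted(ys_sorted, yr - radius_cm, side="left")
    y_hi = np.searchsorted(ys_sorted, yr + radius_cm, side="right")
    x_asc = xs[0] <= xs[-1]
    y_asc = ys[0] <= ys[-1]
    nxs, nys = len(xs), len(ys)

    gamma_map = np.full(ref.shape, np.nan)
    for i in range(ref.shape[0]):
        if y_asc:
            ja, jb = y_lo[i], y_hi[i]
        else:  # descending axis: mirror the sorted-window indices
            ja, jb = nys - y_hi[i], nys - y_lo[i]
        dy2 = (ys[ja:jb] - yr[i]) ** 2
        for j in range(ref.shape[1]):
            if ref[i, j] < thresh:
                continue
            if ja >= jb:
                gamma_map[i, j] = np.inf
                continue
            if x_asc:
                ka, kb = x_lo[j], x_hi[j]
            else:
                ka, kb = nxs - x_hi[j], nxs - x_lo[j]
            if ka >= kb:
                gamma_map[i, j] = np.inf
                continue
            dx2 = (xs[ka:kb] - xr[j]) ** 2
            dist2 = dy2[:, None] + dx2[None, :]
            inside = dist2 <= radius_cm**2
            if not inside.any():
                gamma_map[i, j] = np.inf
                continue
            ddiff = fine[ja:jb, ka:kb] - ref[i, j]
            denom = (
                criteria.dose_diff_pct / 100.0 * ref[i, j]
                if criteria.local_norm
                else dd_abs
            )
            g2 = ddiff**2 / denom**2 + dist2 / dta_cm**2
            gamma_map[i, j] = np.sqrt(g2[inside].min())

    evaluated_pts = np.isfinite(ref) & (ref >= thresh)
    n_eval = int(np.count_nonzero(evaluated_pts))
    if n_eval == 0:
        raise AnalysisError("no reference points above the low-dose threshold")
    g = gamma_map[evaluated_pts]
    pass_rate = float(np.count_nonzero(g <= 1.0 + _PASS_TOL) / n_eval * 100.0)
    mean_gamma = float(np.mean(g[np.isfinite(g)])) if np.isfinite(g).any() else np.inf
    return GammaResult(
        gamma_map=gamma_map,
        pass_rate_pct=pass_rate,
        mean_gamma=mean_gamma,
        n_evaluated=n_eval,
        criteria=criteria,
    )


@dataclass
class GammaSummary:
    """Aggregate of per-field gamma results at one criteria set."""

    criteria: GammaCriteria
    n_fields: int
    pass_rate_mean: float
    pass_rate_sd: float
    mean_gamma_mean: float
    mean_gamma_sd: float

    def as_dict(self) -> dict:
        return {
            "criteria": self.criteria.label(),
            "n_fields": self.n_fields,
            "pass_rate_mean": self.pass_rate_mean,
            "pass_rate_sd": self.pass_rate_sd,
            "mean_gamma_mean": self.mean_gamma_mean,
            "mean_gamma_sd": self.mean_gamma_sd,
        }


def gamma_report(results: list[GammaResult]) -> GammaSummary:
    """Mean and sample SD of pass rates / mean gammas across fields.

    All results must share one criteria set; a single result reports
    SD = 0.
    """
    if not results:
        raise ConfigurationError("gamma_report needs at least one result")
    crit = results[0].criteria
    if any(r.criteria != crit for r in results):
        raise ConfigurationError("cannot aggregate results with mixed gamma criteria")
    rates = np.array([r.pass_rate_pct for r in results])
    means = np.array([r.mean_gamma for r in results])
    sd = lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0  # noqa: E731
    return GammaSummary(
        criteria=crit,
        n_fields=len(results),
        pass_rate_mean=float(rates.mean()),
        pass_rate_sd=sd(rates),
        mean_gamma_mean=float(means.mean()),
        mean_gamma_sd=sd(means),
    )
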