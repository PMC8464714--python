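"""Shared fixtures: simulated measurement sessions and the gamma oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest

from epidose import (
    BeamModel,
    DoseGrid,
    EpidImage,
    EpidResponseModel,
    PortalDoseCalibration,
    make_calibration_suite,
)
from epidose.gamma import supersample

SEED = 20210909
MU_LEVELS = (25, 50, 75, 100, 150, 200, 300, 400, 500, 600)


@pytest.fixture(scope="session")
def beam() -> BeamModel:
    return BeamModel()


@pytest.fixture(scope="session")
def noiseless_response() -> EpidResponseModel:
    """Distortions on (horned flood, backscatter, field-size response), no noise."""
    return EpidResponseModel(noise_sd_rel=0.0)


@pytest.fixture(scope="session")
def ideal_response() -> EpidResponseModel:
    """All distortions off — the end-to-end identity configuration."""
    return EpidResponseModel.ideal()


@pytest.fixture(scope="session")
def suite_noiseless(beam, noiseless_response):
    """Square fields 3-24 cm at 100 MU, noiseless, full distortions."""
    return make_calibration_suite(
        beam, noiseless_response, range(3, 25), mu=100.0, seed=SEED
    )


@pytest.fixture(scope="session")
def fitted_noiseless(beam, noiseless_response, suite_noiseless):
    """Fitted calibration on the noiseless suite (single MU repeat)."""
    from epidose.simulate import make_mu_series

    series = make_mu_series(
        beam, noiseless_response, MU_LEVELS, repeats=1, seed=SEED
    )
    return PortalDoseCalibration(suite_noiseless, series).fit()


@pytest.fixture(scope="session")
def fitted_noisy(beam):
    """Fitted calibration under realistic 0.5% relative noise, MU repeats x3."""
    response = EpidResponseModel(noise_sd_rel=0.005)
    model = PortalDoseCalibration.from_simulation(
        beam=beam,
        response=response,
        mu_levels=MU_LEVELS,
        repeats=3,
        seed=SEED,
    )
    return model, model.fit()


# ---------------------------------------------------------------------------
# small-geometry helpers for plumbing tests (full panel is overkill there)
# ---------------------------------------------------------------------------

def small_panel(pixels=None, n_rows=96, n_cols=128, pitch=0.3) -> EpidImage:
    if pixels is None:
        pixels = np.zeros((n_rows, n_cols))
    return EpidImage(pixels=pixels, pixel_pitch_cm=pitch)


def small_lattice(n=9, pitch=2.0) -> DoseGrid:
    return DoseGrid(dose_mGy=np.zeros((n, n)), pitch_cm=pitch)


@pytest.fixture()
def tiny_geometry():
    return small_panel, small_lattice


# ---------------------------------------------------------------------------
# independent gamma oracle: exhaustive scalar-loop search
# ---------------------------------------------------------------------------

def gamma_bruteforce_map(reference: DoseGrid, evaluated: DoseGrid, criteria):
    """Exhaustive gamma: plain Python loops over every supersampled evaluated
    position within the search radius (no vectorized shortcuts)."""
    ref, xr, yr = reference.dose_mGy, reference.x_coords(), reference.y_coords()
    fine, xs, ys = supersample(
        evaluated.dose_mGy,
        evaluated.x_coords(),
        evaluated.y_coords(),
        criteria.eval_supersampling,
    )
    dd = criteria.dose_diff_pct / 100.0 * ref.max()
    dta = criteria.dta_mm / 10.0
    rad = criteria.search_radius_mm / 10.0
    thresh = criteria.low_dose_threshold_pct / 100.0 * ref.max()
    out = np.full(ref.shape, np.nan)
    for i in range(ref.shape[0]):
        for j in range(ref.shape[1]):
            if ref[i, j] < thresh:
                continue
            best = math.inf
            for a in range(len(ys)):
                for b in range(len(xs)):
                    d2 = (ys[a] - yr[i]) ** 2 + (xs[b] - xr[j]) ** 2
                    if d2 > rad * rad:
                        continue
                    val = (fine[a, b] - ref[i, j]) ** 2 / dd**2 + d2 / dta**2
                    if val < best:
                        best = val
            out[i, j] = math.sqrt(best) if best < math.inf else math.inf
    return out


@pytest.fixture(scope="session")
def gamma_bruteforce():
    return gamma_bruteforce_map
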