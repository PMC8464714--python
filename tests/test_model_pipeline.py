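"""Model/Results layer and the file-based pipeline."""

import json

import numpy as np
import pytest

from epidose import (
    BeamModel,
    EpidResponseModel,
    GammaCriteria,
    PortalDoseCalibration,
    convert_to_dose,
)
from epidose import calibration as cal
from epidose import io as eio
from epidose.datatypes import DoseGrid, EpidImage
from epidose.exceptions import ConfigurationError
from epidose.pipeline import PipelineConfig, run_pipeline
from epidose.simulate import make_calibration_suite, make_mu_series

SMALL_PANEL = dict(n_rows=96, n_cols=128, pitch=0.3)


def _small_geometry():
    panel = EpidImage(pixels=np.zeros((96, 128)), pixel_pitch_cm=0.3)
    lattice = DoseGrid(dose_mGy=np.zeros((9, 9)), pitch_cm=2.0)
    return panel, lattice


def _small_model(noise=0.0, ideal=False):
    panel, lattice = _small_geometry()
    beam = BeamModel()
    resp = EpidResponseModel.ideal(noise) if ideal else EpidResponseModel(noise_sd_rel=noise)
    suite = make_calibration_suite(
        beam, resp, [9, 13, 18], lattice=lattice, epid_geom=panel, seed=31
    )
    series = make_mu_series(
        beam, resp, (50, 200, 600), side_cm=18.0,
        lattice=lattice, epid_geom=panel, seed=31,
    )
    model = PortalDoseCalibration(
        suite, series, radii_cm=(0.0, 2.0, 4.0, 6.0), reference_side_cm=18.0
    )
    model._beam, model._resp = beam, resp
    return model, suite


def test_end_to_end_identity_with_distortions_off():
    """With flat flood, no backscatter, no noise, the full pipeline returns
    the true dose to well under 0.1% inside the 20% isodose region."""
    model, suite = _small_model(ideal=True)
    res = model.fit()
    f = [s for s in suite if s.field.side_cm == 13][0]
    _, samples = res.convert_image(f.g_raw, f.df, f.ff, side_cm=13.0)
    mask = f.ica.dose_mGy >= 0.2 * f.ica.dose_mGy.max()
    rel = np.abs(samples.dose_mGy[mask] / f.ica.dose_mGy[mask] - 1.0)
    assert rel.max() < 1e-3


def test_summary_reports_fit(fitted_noiseless):
    text = fitted_noiseless.summary()
    assert "Calibration fields" in text
    assert "small" in text and "medium" in text and "large" in text
    assert "a(r) flatness" in text
    # corrected flatter than uncorrected
    assert (
        fitted_noiseless.conversion_model.flatness()
        < fitted_noiseless.conversion_model_uncorrected.flatness()
    )


def test_validate_structure(fitted_noiseless, suite_noiseless):
    f = [s for s in suite_noiseless if s.field.side_cm == 12][0]
    out = fitted_noiseless.validate([f], criteria=(GammaCriteria(3, 3),))
    (results, summary), = out.values()
    assert len(results) == 1
    assert summary.n_fields == 1
    assert 0 <= summary.pass_rate_mean <= 100


def test_output_factor_commutes_with_matrix(fitted_noiseless):
    img = EpidImage(pixels=np.random.default_rng(2).uniform(0, 1e5, (768, 1024)))
    cm = fitted_noiseless.matrices["medium"]
    model = fitted_noiseless.conversion_model
    of = 1.02
    a = convert_to_dose(cal.apply_correction(img, cm), model, of=of)
    scaled = img.copy_with(img.pixels * of)
    b = convert_to_dose(cal.apply_correction(scaled, cm), model, of=1.0)
    np.testing.assert_allclose(a.pixels, b.pixels, rtol=1e-12)


@pytest.fixture()
def pipeline_dir(tmp_path):
    model, suite = _small_model()
    res = model.fit()
    art = tmp_path / "artifacts"
    art.mkdir()
    for klass, cm in res.matrices.items():
        eio.write_correction_matrix(cm, art / f"matrix_{klass}.json")
    eio.write_conversion_model(res.conversion_model, art / "model.json")
    eio.write_output_factors(res.of_table, art / "of.json")
    f = [s for s in suite if s.field.side_cm == 13][0]
    eio.write_epid_image(f.g_raw, tmp_path / "field13_raw.csv")
    eio.write_epid_image(f.df, art / "dark.csv")
    eio.write_epid_image(f.ff, art / "flood.csv")
    eio.write_dose_grid(f.ica, tmp_path / "field13_ica.csv")
    config = PipelineConfig(
        dark_field=str(art / "dark.csv"),
        flood_field=str(art / "flood.csv"),
        matrices={k: str(art / f"matrix_{k}.json") for k in res.matrices},
        conversion_model=str(art / "model.json"),
        output_factors=str(art / "of.json"),
        out_dir=str(tmp_path / "out"),
    )
    return config, tmp_path


def test_pipeline_runs_and_is_deterministic(pipeline_dir):
    config, tmp_path = pipeline_dir
    raws = [str(tmp_path / "field13_raw.csv")]
    refs = [str(tmp_path / "field13_ica.csv")]
    report = run_pipeline(config, raws, refs)
    first = (tmp_path / "out" / "report.json").read_bytes()
    assert report["fields"][0]["matrix_class"] in {"small", "medium", "large"}
    label = GammaCriteria(3.0, 3.0).label()
    assert report["fields"][0]["gamma"][label]["pass_rate_pct"] == 100.0
    assert label in report["aggregate"]

    run_pipeline(config, raws, refs)
    assert (tmp_path / "out" / "report.json").read_bytes() == first


def test_pipeline_missing_flood_named(pipeline_dir):
    config, tmp_path = pipeline_dir
    config.flood_field = str(tmp_path / "nope_flood.csv")
    with pytest.raises(ConfigurationError, match="nope_flood"):
        run_pipeline(config, [str(tmp_path / "field13_raw.csv")])


def test_cli_gamma_and_convert(tmp_path, pipeline_dir):
    from click.testing import CliRunner

    from epidose.cli import main

    config, src = pipeline_dir
    ref = src / "field13_ica.csv"
    runner = CliRunner()
    out = tmp_path / "gamma.json"
    r = runner.invoke(
        main,
        ["gamma", "--ref", str(ref), "--eval", str(ref), "--out", str(out)],
    )
    assert r.exit_code == 0, r.output
    doc = json.loads(out.read_text())
    assert doc["pass_rate_pct"] == 100.0
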