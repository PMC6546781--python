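import datetime as dt

import numpy as np
import pytest

from camtrap_community.field_data import (
    Deployment,
    DetectionRecord,
    SiteCovariates,
    write_dataset,
)


def make_record(site="S001", species="native01", when="2015-06-01T12:00:00", indiv=""):
    return DetectionRecord(
        site_id=site,
        species_id=species,
        timestamp=dt.datetime.fromisoformat(when),
        individual_id=indiv,
    )


def make_deployment(
    site="S001",
    brand="KeepGuard",
    start="2015-01-01",
    end="2015-12-31",
    malfunction=(),
):
    return Deployment(
        site_id=site,
        camera_brand=brand,
        active_intervals=[(dt.date.fromisoformat(start), dt.date.fromisoformat(end))],
        malfunction_intervals=[
            (dt.date.fromisoformat(a), dt.date.fromisoformat(b)) for a, b in malfunction
        ],
    )


def make_covariates(site="S001", **kwargs):
    defaults = dict(
        x=1000.0,
        y=2000.0,
        dist_settlement_m=500.0,
        dist_water_m=200.0,
        elevation_m=300.0,
        slope_deg=10.0,
        solar_radiation=1.0,
        vegetation="broadleaf",
    )
    defaults.update(kwargs)
    return SiteCovariates(site_id=site, **defaults)


@pytest.fixture
def toy_dataset_paths(tmp_path):
    """Three small valid CSV tables on disk; returns their paths."""
    records = [
        make_record("S001", "native01", "2015-06-01T08:00:00"),
        make_record("S001", "dog", "2015-06-01T09:30:00"),
        make_record("S002", "native01", "2015-07-15T22:10:00"),
    ]
    deployments = {
        "S001": make_deployment("S001", "KeepGuard", "2015-01-01", "2015-12-31"),
        "S002": make_deployment("S002", "Reconyx", "2015-06-01", "2015-09-30"),
    }
    covariates = {
        "S001": make_covariates("S001"),
        "S002": make_covariates("S002", dist_settlement_m=1500.0),
    }
    paths = (
        tmp_path / "detections.csv",
        tmp_path / "deployments.csv",
        tmp_path / "covariates.csv",
    )
    write_dataset(records, deployments, covariates, *paths)
    return paths


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
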