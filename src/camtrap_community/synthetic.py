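"""Synthetic camera-trap studies with known generative truth.

Generates the three input tables (detections, deployments, covariates)
from the same statistical structure the analysis assumes: species
coefficients drawn from normal community hyper-distributions,
logit-linear occurrence/detection, binomial occasion-level detection,
and detection clock times from species- (and optionally season-)
specific von Mises mixtures. Invasive-carnivore (dog/cat) event streams
are generated first and their *realized* activity indices are the ones
used in the occupancy design, so the pipeline's internally computed RAI
matches the truth used to simulate occupancy.

All quantities without a printed anchor (distance distributions, hyper
values, diel mixtures) are illustrative defaults, not estimates.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from camtrap_community.activity import compute_trap_nights, filter_independent_events
from camtrap_community.field_data import (
    CAMERA_BRANDS,
    Deployment,
    DetectionRecord,
    Season,
    VEGETATION_CLASSES,
    assign_season,
)
from camtrap_community.occupancy.design import (
    DesignMatrix,
    OCC_COLUMNS,
    DET_COLUMNS,
    prepare_covariates,
)
from camtrap_community.occupancy.history import DetectionHistory, occasion_windows

logger = logging.getLogger(__name__)

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class DielMixture:
    """Von Mises mixture over time-of-day angles."""

    weights: tuple[float, ...]
    means: tuple[float, ...]
    kappas: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.weights) == len(self.means) == len(self.kappas)):
            raise ValueError("weights/means/kappas must have equal length")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if any(w < 0 for w in self.weights) or any(k <= 0 for k in self.kappas):
            raise ValueError("weights must be >= 0 and kappas > 0")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=n, p=np.asarray(self.weights))
        vals = np.empty(n)
        for c in range(len(self.weights)):
            mask = comp == c
            vals[mask] = rng.vonmises(self.means[c] - math.pi, self.kappas[c], mask.sum()) + math.pi
        return np.mod(vals, TWO_PI)


CREPUSCULAR = DielMixture(
    weights=(0.5, 0.5), means=(math.pi / 2, 3 * math.pi / 2), kappas=(3.0, 3.0)
)
NOCTURNAL = DielMixture(weights=(1.0,), means=(0.0,), kappas=(2.0,))
DOG_DIEL = DielMixture(  # mainly diurnal with dawn/dusk peaks
    weights=(0.5, 0.25, 0.25),
    means=(math.pi, math.pi / 2, 3 * math.pi / 2),
    kappas=(2.0, 4.0, 4.0),
)
CAT_DIEL = DielMixture(  # active all day with dawn/dusk peaks
    weights=(0.4, 0.3, 0.3),
    means=(math.pi, math.pi / 2, 3 * math.pi / 2),
    kappas=(0.3, 3.0, 3.0),
)


def default_occ_hyper() -> dict[str, tuple[float, float]]:
    return {
        "intercept": (-0.5, 1.0),
        "dist_settlement": (0.5, 0.3),
        "dog_rai": (1.0, 0.5),
        "dog_rai_sq": (-1.0, 0.5),
        "cat_rai": (0.2, 0.4),
        "cat_rai_sq": (-0.2, 0.4),
    }


def default_det_hyper() -> dict[str, tuple[float, float]]:
    return {
        "intercept": (-1.0, 0.5),
        "brand_cuddeback": (-0.2, 0.3),
        "brand_reconyx": (-0.4, 0.3),
        "dog_rai": (0.1, 0.3),
        "cat_rai": (0.2, 0.3),
    }


@dataclass
class SimulationConfig:
    n_sites: int = 121
    n_species: int = 9
    occ_hyper: dict[str, tuple[float, float]] = field(default_factory=default_occ_hyper)
    det_hyper: dict[str, tuple[float, float]] = field(default_factory=default_det_hyper)
    occasion_length_days: int = 10
    mean_deployment_days: float = 143.0
    sd_deployment_days: float = 30.0
    min_deployment_days: int = 70
    study_start: dt.date = dt.date(2012, 3, 1)
    study_span_days: int = 5 * 365
    malfunction_prob: float = 0.15
    malfunction_max_days: int = 14
    brand_probs: tuple[float, float, float] = (0.4, 0.3, 0.3)  # KeepGuard, Cuddeback, Reconyx
    # lognormal (mean of log, sd of log) for the invasive-carnivore RAI targets
    dog_rai_lognormal: tuple[float, float] = (0.0, 0.8)
    cat_rai_lognormal: tuple[float, float] = (-0.8, 0.8)
    # illustrative site covariate generators
    dist_settlement_lognormal: tuple[float, float] = (6.2, 0.9)  # ~50-3000 m
    area_m: float = 15000.0
    mean_records_per_detection: float = 1.5
    diel_natives: DielMixture = CREPUSCULAR
    diel_dog: DielMixture = DOG_DIEL
    diel_cat: DielMixture = CAT_DIEL
    # optional per-(species, season) mixture overrides for seasonal diel shifts
    diel_seasonal: dict[tuple[str, Season], DielMixture] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_sites < 1 or self.n_species < 1:
            raise ValueError("n_sites and n_species must be >= 1")
        for name, hyper, cols in (
            ("occ_hyper", self.occ_hyper, OCC_COLUMNS),
            ("det_hyper", self.det_hyper, DET_COLUMNS),
        ):
            for col in cols:
                if col not in hyper:
                    raise ValueError(f"{name}: missing entry for column {col!r}")
                mu, sd = hyper[col]
                if sd <= 0:
                    raise ValueError(f"{name}[{col!r}]: sd must be > 0, got {sd}")
        if abs(sum(self.brand_probs) - 1.0) > 1e-9:
            raise ValueError("brand_probs must sum to 1")
        if self.occasion_length_days < 1:
            raise ValueError("occasion_length_days must be >= 1")
        if self.mean_records_per_detection < 1.0:
            raise ValueError("mean_records_per_detection must be >= 1")

    def species_names(self) -> list[str]:
        return [f"native{str(i + 1).zfill(2)}" for i in range(self.n_species)]


def paper_scale_config() -> SimulationConfig:
    """Config mirroring the study's dimensions: 121 sites, 9 native
    species, 143-day mean deployments. Hyper values are illustrative."""
    return SimulationConfig(n_sites=121, n_species=9, mean_deployment_days=143.0)


@dataclass
class SyntheticTruth:
    species: list[str]
    sites: list[str]
    alpha: np.ndarray  # (S, P_occ)
    beta: np.ndarray  # (S, P_det)
    z: np.ndarray  # (S, J)
    psi: np.ndarray
    p: np.ndarray
    y: np.ndarray  # (S, J) occasions with >=1 detection, as generated
    K: np.ndarray
    occ_hyper: dict[str, tuple[float, float]]
    det_hyper: dict[str, tuple[float, float]]
    dog_rai: np.ndarray  # realized, per site
    cat_rai: np.ndarray
    occ_design: DesignMatrix
    det_design: DesignMatrix


@dataclass
class SimulatedStudy:
    detections: pd.DataFrame
    deployments: pd.DataFrame
    covariates: pd.DataFrame
    truth: SyntheticTruth


def simulate_diel_samples(
    mixture: DielMixture, n: int, seed: int | None = None
) -> np.ndarray:
    """I.i.d. time-of-day angles from a von Mises mixture."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return mixture.sample(n, np.random.default_rng(seed))


def _random_time(rng: np.random.Generator, mixture: DielMixture) -> dt.time:
    angle = float(mixture.sample(1, rng)[0])
    secs = angle / TWO_PI * 86400.0
    secs = min(secs, 86399.0)
    h, rem = divmod(int(secs), 3600)
    m, s = divmod(rem, 60)
    return dt.time(h, m, s)


def _simulate_deployments(
    config: SimulationConfig, rng: np.random.Generator
) -> dict[str, Deployment]:
    deployments = {}
    for j in range(config.n_sites):
        site = f"S{str(j + 1).zfill(3)}"
        brand = CAMERA_BRANDS[rng.choice(3, p=np.asarray(config.brand_probs))]
        start = config.study_start + dt.timedelta(days=int(rng.integers(0, config.study_span_days)))
        length = max(
            config.min_deployment_days,
            int(round(rng.normal(config.mean_deployment_days, config.sd_deployment_days))),
        )
        end = start + dt.timedelta(days=length - 1)
        malfunction = []
        if rng.random() < config.malfunction_prob and length > 2 * config.malfunction_max_days:
            gap_len = int(rng.integers(2, config.malfunction_max_days + 1))
            gap_start = start + dt.timedelta(days=int(rng.integers(5, length - gap_len - 5)))
            malfunction.append((gap_start, gap_start + dt.timedelta(days=gap_len - 1)))
        deployments[site] = Deployment(
            site_id=site,
            camera_brand=brand,
            active_intervals=[(start, end)],
            malfunction_intervals=malfunction,
        )
    return deployments


def _carnivore_records(
    config: SimulationConfig,
    rng: np.random.Generator,
    deployments: Mapping[str, Deployment],
) -> list[DetectionRecord]:
    records = []
    for species, (mlog, slog), mixture in (
        ("dog", config.dog_rai_lognormal, config.diel_dog),
        ("cat", config.cat_rai_lognormal, config.diel_cat),
    ):
        for site in sorted(deployments):
            dep = deployments[site]
            nights = sorted(dep.effort_dates())
            target_rai = float(rng.lognormal(mlog, slog))
            count = int(rng.poisson(target_rai * len(nights) / 100.0))
            for _ in range(count):
                night = nights[int(rng.integers(0, len(nights)))]
                t = _random_time(rng, mixture)
                records.append(
                    DetectionRecord(site, species, dt.datetime.combine(night, t))
                )
    return records


def simulate_community(
    config: SimulationConfig | None = None, seed: int = 0
) -> SimulatedStudy:
    """Generate a full synthetic study; same (config, seed) is byte-reproducible."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    species = config.species_names()

    deployments = _simulate_deployments(config, rng)
    sites = sorted(deployments)
    trap_nights = {s: compute_trap_nights(deployments[s]) for s in sites}

    # invasive carnivores first: their realized RAI feeds the design
    carnivore_raw = _carnivore_records(config, rng, deployments)
    carnivore_events = filter_independent_events(carnivore_raw)
    counts = {("dog", s): 0 for s in sites} | {("cat", s): 0 for s in sites}
    for ev in carnivore_events:
        counts[(ev.species_id, ev.site_id)] += 1
    dog_rai = np.array([100.0 * counts[("dog", s)] / trap_nights[s] for s in sites])
    cat_rai = np.array([100.0 * counts[("cat", s)] / trap_nights[s] for s in sites])

    # site covariates (illustrative distributions)
    n = len(sites)
    mlog, slog = config.dist_settlement_lognormal
    covariates = pd.DataFrame(
        {
            "site_id": sites,
            "x": np.round(rng.uniform(0.0, config.area_m, n), 1),
            "y": np.round(rng.uniform(0.0, config.area_m, n), 1),
            "dist_settlement_m": np.round(np.clip(rng.lognormal(mlog, slog, n), 20.0, 5000.0), 1),
            "dist_water_m": np.round(np.clip(rng.lognormal(5.5, 0.8, n), 5.0, 3000.0), 1),
            "elevation_m": np.round(rng.uniform(56.0, 1120.0, n), 1),
            "slope_deg": np.round(rng.uniform(0.0, 45.0, n), 1),
            "solar_radiation": np.round(rng.uniform(0.5, 1.5, n), 3),
            "vegetation": [VEGETATION_CLASSES[c] for c in rng.choice(3, size=n)],
        }
    )

    rai_table = pd.DataFrame(
        {
            "site_id": sites * 2,
            "species_id": ["dog"] * n + ["cat"] * n,
            "rai": np.concatenate([dog_rai, cat_rai]),
        }
    )
    brands = {s: deployments[s].camera_brand for s in sites}
    occ_design, det_design, _ = prepare_covariates(covariates, rai_table, brands)

    # species coefficients from the community hyper-distributions
    S = config.n_species
    alpha = np.column_stack(
        [rng.normal(*config.occ_hyper[c], size=S) for c in occ_design.columns]
    )
    beta = np.column_stack(
        [rng.normal(*config.det_hyper[c], size=S) for c in det_design.columns]
    )
    psi = expit(alpha @ occ_design.X.T)
    p = expit(beta @ det_design.X.T)
    z = (rng.random((S, n)) < psi).astype(int)

    windows = {s: occasion_windows(deployments[s], config.occasion_length_days) for s in sites}
    K = np.array([len(windows[s]) for s in sites], dtype=int)

    y = np.zeros((S, n), dtype=int)
    records: list[DetectionRecord] = []
    geom_p = 1.0 / config.mean_records_per_detection
    for j, site in enumerate(sites):
        effort = deployments[site].effort_dates()
        for i, sp in enumerate(species):
            if z[i, j] == 0:
                continue
            detected = rng.random(K[j]) < p[i, j]
            y[i, j] = int(detected.sum())
            for w in np.flatnonzero(detected):
                w0, w1 = windows[site][w]
                nights = sorted(d for d in effort if w0 <= d <= w1)
                n_rec = int(rng.geometric(geom_p))
                for _ in range(n_rec):
                    night = nights[int(rng.integers(0, len(nights)))]
                    mixture = config.diel_seasonal.get(
                        (sp, assign_season(night)), config.diel_natives
                    )
                    records.append(
                        DetectionRecord(site, sp, dt.datetime.combine(night, _random_time(rng, mixture)))
                    )

    records.extend(carnivore_raw)
    records.sort(key=lambda r: (r.site_id, r.species_id, r.timestamp))
    detections = pd.DataFrame(
        {
            "site_id": [r.site_id for r in records],
            "species_id": [r.species_id for r in records],
            "timestamp": [r.timestamp.isoformat() for r in records],
            "individual_id": ["" for _ in records],
        }
    )

    dep_rows = []
    for site in sites:
        dep = deployments[site]
        for kind, ivals in (
            ("active", dep.active_intervals),
            ("malfunction", dep.malfunction_intervals),
        ):
            for s0, s1 in ivals:
                dep_rows.append(
                    {
                        "site_id": site,
                        "camera_brand": dep.camera_brand,
                        "kind": kind,
                        "start_date": s0.isoformat(),
                        "end_date": s1.isoformat(),
                    }
                )
    deployments_df = pd.DataFrame(
        dep_rows, columns=["site_id", "camera_brand", "kind", "start_date", "end_date"]
    )

    truth = SyntheticTruth(
        species=species,
        sites=sites,
        alpha=alpha,
        beta=beta,
        z=z,
        psi=psi,
        p=p,
        y=y,
        K=K,
        occ_hyper=dict(config.occ_hyper),
        det_hyper=dict(config.det_hyper),
        dog_rai=dog_rai,
        cat_rai=cat_rai,
        occ_design=occ_design,
        det_design=det_design,
    )
    return SimulatedStudy(
        detections=detections,
        deployments=deployments_df,
        covariates=covariates,
        truth=truth,
    )


def simulate_detection_matrix(
    n_sites: int,
    n_species: int,
    K: int,
    occ_hyper: Mapping[str, tuple[float, float]],
    det_hyper: Mapping[str, tuple[float, float]],
    seed: int = 0,
) -> tuple[DetectionHistory, DesignMatrix, DesignMatrix, SyntheticTruth]:
    """Fast matrix-level generator for parameter-recovery experiments.

    Non-intercept covariates are i.i.d. standard normals, standardized
    to exact mean 0 / sd 1 as the design contract requires. ``K`` is the
    same occasion count at every site.
    """
    rng = np.random.default_rng(seed)
    sites = [f"S{str(j + 1).zfill(4)}" for j in range(n_sites)]
    species = [f"sp{str(i + 1).zfill(2)}" for i in range(n_species)]

    def _design(hyper: Mapping[str, tuple[float, float]]) -> DesignMatrix:
        cols = list(hyper)
        mats = []
        for c in cols:
            if c == "intercept":
                mats.append(np.ones(n_sites))
            else:
                v = rng.standard_normal(n_sites)
                mats.append((v - v.mean()) / v.std(ddof=0))
        return DesignMatrix(sites=sites, columns=cols, X=np.column_stack(mats))

    occ_design = _design(occ_hyper)
    det_design = _design(det_hyper)
    alpha = np.column_stack(
        [rng.normal(*occ_hyper[c], size=n_species) for c in occ_design.columns]
    )
    beta = np.column_stack(
        [rng.normal(*det_hyper[c], size=n_species) for c in det_design.columns]
    )
    psi = expit(alpha @ occ_design.X.T)
    p = expit(beta @ det_design.X.T)
    z = (rng.random((n_species, n_sites)) < psi).astype(int)
    y = rng.binomial(K, z * p)

    history = DetectionHistory(
        species=species,
        sites=sites,
        y=y,
        K=np.full(n_sites, K, dtype=int),
        brand=["KeepGuard"] * n_sites,
        occasion_length_days=1,
    )
    truth = SyntheticTruth(
        species=species,
        sites=sites,
        alpha=alpha,
        beta=beta,
        z=z,
        psi=psi,
        p=p,
        y=y,
        K=history.K,
        occ_hyper=dict(occ_hyper),
        det_hyper=dict(det_hyper),
        dog_rai=np.zeros(n_sites),
        cat_rai=np.zeros(n_sites),
        occ_design=occ_design,
        det_design=det_design,
    )
    return history, occ_design, det_design, truth
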