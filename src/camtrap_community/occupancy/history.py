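"""Discretize continuous camera effort into detection occasions.

Each deployment's calendar span is cut into consecutive windows of
``occasion_length_days`` starting at the first active date. A window
counts as an occasion iff it contains at least one effort night; an
occasion is a detection for species i iff it contains at least one
independent event of that species.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from camtrap_community.activity import IndependentEvent
from camtrap_community.field_data import Deployment

logger = logging.getLogger(__name__)


@dataclass
class DetectionHistory:
    """Species x site occasion-detection counts plus per-site effort."""

    species: list[str]
    sites: list[str]
    y: np.ndarray  # (n_species, n_sites) occasions with >=1 detection
    K: np.ndarray  # (n_sites,) occasion counts
    brand: list[str] = field(default_factory=list)
    occasion_length_days: int = 10

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        self.K = np.asarray(self.K, dtype=int)
        if self.y.shape != (len(self.species), len(self.sites)):
            raise ValueError(
                f"y shape {self.y.shape} does not match "
                f"({len(self.species)} species, {len(self.sites)} sites)"
            )
        if self.K.shape != (len(self.sites),):
            raise ValueError("K must have one entry per site")
        if np.any(self.K < 1):
            raise ValueError("included sites must have K >= 1")
        if np.any(self.y < 0) or np.any(self.y > self.K[None, :]):
            raise ValueError("y must satisfy 0 <= y <= K per site")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def occasion_windows(
    deployment: Deployment, occasion_length_days: int
) -> list[tuple[dt.date, dt.date]]:
    """Consecutive windows (inclusive date bounds) holding >=1 effort night."""
    if occasion_length_days < 1:
        raise ValueError("occasion_length_days must be >= 1")
    effort = deployment.effort_dates()
    if not effort:
        return []
    start = min(d for ival in deployment.active_intervals for d in ival)
    last = max(effort)
    windows = []
    w0 = start
    step = dt.timedelta(days=occasion_length_days)
    while w0 <= last:
        w1 = w0 + step - dt.timedelta(days=1)
        if any(w0 <= d <= w1 for d in effort):
            windows.append((w0, w1))
        w0 = w0 + step
    return windows


def build_detection_history(
    events: Sequence[IndependentEvent],
    deployments: Mapping[str, Deployment],
    occasion_length_days: int = 10,
    species: Sequence[str] | None = None,
) -> DetectionHistory:
    """Build the species x site occasion-detection matrix.

    Sites whose effort yields zero occasions are dropped with a warning.
    """
    if species is None:
        species = sorted({e.species_id for e in events})
    species = list(species)
    sp_index = {s: i for i, s in enumerate(species)}

    sites = []
    windows_by_site = {}
    brands = []
    for site_id in sorted(deployments):
        wins = occasion_windows(deployments[site_id], occasion_length_days)
        if not wins:
            logger.warning("site %s has no effort; excluded from detection history", site_id)
            continue
        sites.append(site_id)
        windows_by_site[site_id] = wins
        brands.append(deployments[site_id].camera_brand)

    site_index = {s: j for j, s in enumerate(sites)}
    K = np.array([len(windows_by_site[s]) for s in sites], dtype=int)
    hit: set[tuple[int, int, int]] = set()
    for ev in events:
        j = site_index.get(ev.site_id)
        i = sp_index.get(ev.species_id)
        if j is None or i is None:
            continue
        d = ev.timestamp.date()
        for w, (w0, w1) in enumerate(windows_by_site[ev.site_id]):
            if w0 <= d <= w1:
                hit.add((i, j, w))
                break
    y = np.zeros((len(species), len(sites)), dtype=int)
    for i, j, _ in hit:
        y[i, j] += 1
    return DetectionHistory(
        species=species,
        sites=sites,
        y=y,
        K=K,
        brand=brands,
        occasion_length_days=occasion_length_days,
    )
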