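"""Relative activity indices from camera-trap detections.

RAI = 100 x independent detections / trap-nights. Detections of the
same species at the same site are collapsed into independent events
using a 30-minute rule; individually distinguishable animals form
separate streams and are never collapsed into each other.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from camtrap_community.field_data import (
    Deployment,
    DetectionRecord,
    Season,
    assign_season,
)

logger = logging.getLogger(__name__)

#: combined sample size at or below which the Mann-Whitney p-value is exact
EXACT_MW_LIMIT = 20


@dataclass(frozen=True)
class IndependentEvent:
    site_id: str
    species_id: str
    timestamp: dt.datetime
    season: Season
    individual_id: str = ""


def filter_independent_events(
    records: Iterable[DetectionRecord], interval_minutes: float = 30.0
) -> list[IndependentEvent]:
    """Collapse raw triggers into independent events.

    Within each (site, species, individual) stream, ordered by time, a
    record is kept iff it is the first of the stream or its gap from the
    *last retained* record is at least ``interval_minutes``. Measuring
    from the last retained record (rather than the preceding raw record)
    keeps an unbroken chain of rapid triggers from collapsing hours of
    activity into a single event.
    """
    if interval_minutes < 0:
        raise ValueError(f"interval_minutes must be >= 0, got {interval_minutes}")
    gap = dt.timedelta(minutes=interval_minutes)
    streams: dict[tuple[str, str, str], list[DetectionRecord]] = {}
    for rec in records:
        streams.setdefault((rec.site_id, rec.species_id, rec.individual_id), []).append(rec)

    kept: list[IndependentEvent] = []
    for key in sorted(streams):
        last_retained: dt.datetime | None = None
        for rec in sorted(streams[key], key=lambda r: r.timestamp):
            if last_retained is None or rec.timestamp - last_retained >= gap:
                kept.append(
                    IndependentEvent(
                        site_id=rec.site_id,
                        species_id=rec.species_id,
                        timestamp=rec.timestamp,
                        season=assign_season(rec.timestamp),
                        individual_id=rec.individual_id,
                    )
                )
                last_retained = rec.timestamp
    kept.sort(key=lambda e: (e.site_id, e.species_id, e.timestamp, e.individual_id))
    return kept


def compute_trap_nights(deployment: Deployment) -> int:
    """Nights of functioning effort: active nights minus malfunction nights.

    A trap-night is a calendar date with any active effort; partial first
    and last days count as whole nights.
    """
    return len(deployment.effort_dates())


def compute_rai(
    events: Sequence[IndependentEvent],
    trap_nights_by_site: Mapping[str, int],
    species: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Events per 100 trap-nights for every (site, species) pair.

    The output covers the full grid of sites in ``trap_nights_by_site``
    crossed with the species list (defaulting to the species seen in
    ``events``); pairs with no events get rai = 0.
    """
    if species is None:
        species = sorted({e.species_id for e in events})
    species = list(species)
    sites = sorted(trap_nights_by_site)

    counts: dict[tuple[str, str], int] = {}
    for ev in events:
        if ev.site_id not in trap_nights_by_site:
            raise ValueError(f"event at site {ev.site_id} with no trap-night entry")
        counts[(ev.site_id, ev.species_id)] = counts.get((ev.site_id, ev.species_id), 0) + 1

    rows = []
    for site in sites:
        nights = int(trap_nights_by_site[site])
        for sp in species:
            n = counts.get((site, sp), 0)
            if n > 0 and nights <= 0:
                raise ValueError(
                    f"site {site} has {n} events of {sp} but zero trap-nights"
                )
            rai = 100.0 * n / nights if nights > 0 else 0.0
            rows.append(
                {
                    "site_id": site,
                    "species_id": sp,
                    "events": n,
                    "trap_nights": nights,
                    "rai": rai,
                }
            )
    return pd.DataFrame(rows, columns=["site_id", "species_id", "events", "trap_nights", "rai"])


def _monthly_effort(deployment: Deployment) -> dict[tuple[int, int], int]:
    """Effort nights per (year, month)."""
    out: dict[tuple[int, int], int] = {}
    for d in deployment.effort_dates():
        key = (d.year, d.month)
        out[key] = out.get(key, 0) + 1
    return out


def seasonal_effort_days(deployment: Deployment) -> dict[Season, int]:
    """Total effort nights per season (pooled across years)."""
    out: dict[Season, int] = {}
    for (_, month), n in _monthly_effort(deployment).items():
        s = Season.from_month(month)
        out[s] = out.get(s, 0) + n
    return out


def seasonal_rai(
    events: Sequence[IndependentEvent],
    deployments: Mapping[str, Deployment],
    min_days_per_season: int = 60,
    min_seasons: int = 2,
    species: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Seasonal RAI: the mean of a season's monthly RAIs at each site.

    Only sites with at least ``min_days_per_season`` effort nights in at
    least ``min_seasons`` seasons qualify, which keeps seasonal
    comparisons from confounding season with site turnover. Monthly RAI
    uses each calendar month's own effort denominator; months without
    effort are omitted from the seasonal mean, not zero-filled.
    """
    if species is None:
        species = sorted({e.species_id for e in events})
    species = list(species)

    qualifying: dict[str, set[Season]] = {}
    for site_id, dep in deployments.items():
        good = {
            s for s, days in seasonal_effort_days(dep).items() if days >= min_days_per_season
        }
        if len(good) >= min_seasons:
            qualifying[site_id] = good
    if not qualifying:
        logger.warning("seasonal_rai: no site qualifies (min %d days in %d seasons)",
                       min_days_per_season, min_seasons)
        return pd.DataFrame(
            columns=["site_id", "species_id", "season", "n_months", "rai"]
        )

    month_counts: dict[tuple[str, str, int, int], int] = {}
    for ev in events:
        if ev.site_id in qualifying:
            key = (ev.site_id, ev.species_id, ev.timestamp.year, ev.timestamp.month)
            month_counts[key] = month_counts.get(key, 0) + 1

    rows = []
    for site_id in sorted(qualifying):
        effort = _monthly_effort(deployments[site_id])
        for sp in species:
            per_season: dict[Season, list[float]] = {}
            for (year, month), nights in effort.items():
                season = Season.from_month(month)
                if season not in qualifying[site_id] or nights == 0:
                    continue
                n = month_counts.get((site_id, sp, year, month), 0)
                per_season.setdefault(season, []).append(100.0 * n / nights)
            for season in Season:
                if season in per_season:
                    vals = per_season[season]
                    rows.append(
                        {
                            "site_id": site_id,
                            "species_id": sp,
                            "season": season.value,
                            "n_months": len(vals),
                            "rai": float(np.mean(vals)),
                        }
                    )
    return pd.DataFrame(rows, columns=["site_id", "species_id", "season", "n_months", "rai"])


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U for sample a, with 0.5 credit for ties."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt + 0.5 * eq)


def mann_whitney_u(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact permutation p for combined n <= EXACT_MW_LIMIT (enumerating
    every split of the pooled values, so ties are handled exactly);
    otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney_u requires two non-empty samples")
    u_obs = _u_statistic(a, b)
    n1, n2 = a.size, b.size
    if n1 + n2 <= EXACT_MW_LIMIT:
        pooled = np.concatenate([a, b])
        center = n1 * n2 / 2.0
        obs_dev = abs(u_obs - center)
        idx = range(n1 + n2)
        hits = total = 0
        for combo in combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(combo)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - center) >= obs_dev - 1e-12:
                hits += 1
        p = hits / total
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    return u_obs, min(1.0, p)
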