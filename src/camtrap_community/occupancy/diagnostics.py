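"""Convergence diagnostics and posterior summaries."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from camtrap_community.occupancy.model import PosteriorSamples

logger = logging.getLogger(__name__)

RHAT_THRESHOLD = 1.1


def gelman_rubin(chains_of_draws: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor.

    ``chains_of_draws`` is (m chains, n draws). Returns
    sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain variance
    and B/n the (ddof=1) variance of the chain means. Constant chains
    (W = 0) return 1.0 with a warning.
    """
    draws = np.asarray(chains_of_draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2 or draws.shape[1] < 2:
        raise ValueError("need >=2 chains of equal length n >= 2")
    m, n = draws.shape
    within = draws.var(axis=1, ddof=1)
    w = float(within.mean())
    b_over_n = float(draws.mean(axis=1).var(ddof=1))
    if w == 0.0:
        logger.warning("gelman_rubin: constant chains (W = 0); returning 1.0")
        return 1.0
    var_plus = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_plus / w))


@dataclass
class ConvergenceReport:
    table: pd.DataFrame  # columns: parameter, rhat, passed
    threshold: float = RHAT_THRESHOLD

    @property
    def converged(self) -> bool:
        return bool(self.table["passed"].all())

    @property
    def max_rhat(self) -> float:
        return float(self.table["rhat"].max())


def convergence_report(
    samples: "PosteriorSamples", threshold: float = RHAT_THRESHOLD
) -> ConvergenceReport:
    """R-hat for every monitored (community-level) parameter."""
    rows = []
    for name, chains in samples.monitored_chains().items():
        rhat = gelman_rubin(chains)
        rows.append({"parameter": name, "rhat": rhat, "passed": bool(rhat < threshold)})
    return ConvergenceReport(table=pd.DataFrame(rows), threshold=threshold)


def central_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed percentile interval (linear-interpolation percentiles)."""
    tail = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(np.asarray(draws, dtype=float), [tail, 100.0 - tail])
    return float(lo), float(hi)


def _summary_row(draws: np.ndarray) -> dict[str, float]:
    draws = np.asarray(draws, dtype=float).ravel()
    lo, hi = central_interval(draws)
    return {
        "mean": float(draws.mean()),
        "sd": float(draws.std(ddof=0)),
        "ci_low": lo,
        "ci_high": hi,
    }


def summarize_posterior(samples: "PosteriorSamples") -> pd.DataFrame:
    """Tidy posterior summary: community hyper-parameters and species coefficients.

    One row per parameter with posterior mean, SD and the equal-tailed
    95% interval; ``level`` is 'community' for hyper-parameters and
    'species' for species coefficients.
    """
    rows = []
    for block, columns, mu, sd in (
        ("occurrence", samples.occ_columns, samples.mu_alpha, samples.sd_alpha),
        ("detection", samples.det_columns, samples.mu_beta, samples.sd_beta),
    ):
        if mu is None:
            continue
        for k, col in enumerate(columns):
            for stat, arr in (("mean", mu), ("sd", sd)):
                rows.append(
                    {
                        "block": block,
                        "level": "community",
                        "parameter": f"{col}.{stat}",
                        "species": "",
                        **_summary_row(arr[..., k]),
                    }
                )
    for block, columns, coef in (
        ("occurrence", samples.occ_columns, samples.alpha),
        ("detection", samples.det_columns, samples.beta),
    ):
        for i, sp in enumerate(samples.species):
            for k, col in enumerate(columns):
                rows.append(
                    {
                        "block": block,
                        "level": "species",
                        "parameter": col,
                        "species": sp,
                        **_summary_row(coef[..., i, k]),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["block", "level", "parameter", "species", "mean", "sd", "ci_low", "ci_high"],
    )


def site_richness(samples: "PosteriorSamples") -> tuple[pd.DataFrame, dict[str, float]]:
    """Posterior species richness per site and study-wide summaries.

    Richness sums the latent occurrence draws z (not psi) so that
    conditioning on the observed detections propagates. The study-level
    dict reports both readings of a mean richness: averaging the
    posterior-mean site richness over sites, and summarizing the
    per-draw across-site mean.
    """
    z = samples.z  # (chains, draws, S, J)
    rich = z.sum(axis=2, dtype=float)  # (chains, draws, J)
    flat = rich.reshape(-1, rich.shape[-1])  # (ndraws, J)
    rows = []
    for j, site in enumerate(samples.sites):
        rows.append({"site_id": site, **_summary_row(flat[:, j])})
    site_df = pd.DataFrame(rows, columns=["site_id", "mean", "sd", "ci_low", "ci_high"])

    per_draw_mean = flat.mean(axis=1)
    lo, hi = central_interval(per_draw_mean)
    study = {
        "mean_of_site_means": float(site_df["mean"].mean()),
        "sd_of_site_means": float(site_df["mean"].std(ddof=0)),
        "mean_over_draws": float(per_draw_mean.mean()),
        "sd_over_draws": float(per_draw_mean.std(ddof=0)),
        "ci_low_over_draws": lo,
        "ci_high_over_draws": hi,
    }
    return site_df, study
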