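"""Stepwise covariate retention by community-level credible intervals.

Detection candidates (e.g. season, brand contrasts) are evaluated first
in a single joint fit and the non-significant ones dropped; occurrence
candidates are then added one at a time, in the user-supplied order, to
the running base model. A candidate is retained iff the 95% posterior
interval of its community-level mean excludes zero. Every fit and
decision is recorded in an audit log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from camtrap_community.occupancy.design import DesignMatrix
from camtrap_community.occupancy.diagnostics import central_interval
from camtrap_community.occupancy.history import DetectionHistory
from camtrap_community.occupancy.model import (
    MCMCConfig,
    PosteriorSamples,
    PriorConfig,
    fit_community_occupancy,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Candidate:
    """A site-level covariate column proposed for one of the two designs."""

    name: str
    values: np.ndarray
    role: Literal["occurrence", "detection"]


@dataclass
class SelectionResult:
    occ_design: DesignMatrix
    det_design: DesignMatrix
    audit: pd.DataFrame
    retained: list[str] = field(default_factory=list)


def _community_ci(
    samples: PosteriorSamples, block: str, column: str, level: float = 0.95
) -> tuple[float, float]:
    return central_interval(samples.hyper_mean_draws(block, column), level)


def stepwise_covariate_selection(
    history: DetectionHistory,
    occ_design: DesignMatrix,
    det_design: DesignMatrix,
    candidates: Sequence[Candidate],
    priors: PriorConfig | None = None,
    mcmc: MCMCConfig | None = None,
    level: float = 0.95,
) -> SelectionResult:
    """Run the stepwise retention procedure; returns final designs + audit."""
    occ = occ_design
    det = det_design
    audit_rows: list[dict] = []
    retained: list[str] = []

    det_candidates = [c for c in candidates if c.role == "detection"]
    occ_candidates = [c for c in candidates if c.role == "occurrence"]

    if det_candidates:
        trial_det = det
        for cand in det_candidates:
            trial_det = trial_det.with_column(cand.name, cand.values)
        samples = fit_community_occupancy(history, occ, trial_det, priors, mcmc)
        keep = []
        for cand in det_candidates:
            lo, hi = _community_ci(samples, "det", cand.name, level)
            keep_it = lo > 0.0 or hi < 0.0
            audit_rows.append(
                {
                    "phase": "detection",
                    "candidate": cand.name,
                    "ci_low": lo,
                    "ci_high": hi,
                    "retained": keep_it,
                    "max_rhat": samples.convergence.max_rhat,
                }
            )
            if keep_it:
                keep.append(cand)
        for cand in keep:
            det = det.with_column(cand.name, cand.values)
            retained.append(f"detection:{cand.name}")

    for cand in occ_candidates:
        trial_occ = occ.with_column(cand.name, cand.values)
        samples = fit_community_occupancy(history, trial_occ, det, priors, mcmc)
        lo, hi = _community_ci(samples, "occ", cand.name, level)
        keep_it = lo > 0.0 or hi < 0.0
        audit_rows.append(
            {
                "phase": "occurrence",
                "candidate": cand.name,
                "ci_low": lo,
                "ci_high": hi,
                "retained": keep_it,
                "max_rhat": samples.convergence.max_rhat,
            }
        )
        if keep_it:
            occ = trial_occ
            retained.append(f"occurrence:{cand.name}")

    audit = pd.DataFrame(
        audit_rows,
        columns=["phase", "candidate", "ci_low", "ci_high", "retained", "max_rhat"],
    )
    return SelectionResult(occ_design=occ, det_design=det, audit=audit, retained=retained)
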