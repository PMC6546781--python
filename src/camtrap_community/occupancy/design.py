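"""Design matrices for the occurrence and detection linear predictors.

Continuous covariates are standardized to mean 0, sd 1 across sites.
Dog and cat activity indices enter as log(RAI + 1) before
standardization, and their quadratic terms are the elementwise squares
of the standardized linear columns (so the quadratics are *not*
themselves re-standardized).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

OCC_COLUMNS = (
    "intercept",
    "dist_settlement",
    "dog_rai",
    "dog_rai_sq",
    "cat_rai",
    "cat_rai_sq",
)
DET_COLUMNS = ("intercept", "brand_cuddeback", "brand_reconyx", "dog_rai", "cat_rai")

REFERENCE_BRAND = "KeepGuard"


@dataclass
class DesignMatrix:
    sites: list[str]
    columns: list[str]
    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.sites), len(self.columns)):
            raise ValueError(
                f"design shape {self.X.shape} != ({len(self.sites)}, {len(self.columns)})"
            )

    def with_column(self, name: str, values: np.ndarray) -> "DesignMatrix":
        values = np.asarray(values, dtype=float).reshape(-1)
        if values.shape[0] != len(self.sites):
            raise ValueError("new column length mismatch")
        return DesignMatrix(
            sites=list(self.sites),
            columns=list(self.columns) + [name],
            X=np.column_stack([self.X, values]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.sites, columns=self.columns)


@dataclass
class TransformRecord:
    """Means/sds used for standardization, for back-transformation."""

    center: dict[str, float] = field(default_factory=dict)
    scale: dict[str, float] = field(default_factory=dict)
    log1p_columns: tuple[str, ...] = ()


def standardize(values: np.ndarray, name: str, record: TransformRecord) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    mu = float(np.mean(values))
    sd = float(np.std(values, ddof=0))
    if sd == 0:
        raise ValueError(f"covariate {name!r} has zero variance")
    record.center[name] = mu
    record.scale[name] = sd
    return (values - mu) / sd


def prepare_covariates(
    covariates: pd.DataFrame,
    rai_table: pd.DataFrame,
    brands: Mapping[str, str],
) -> tuple[DesignMatrix, DesignMatrix, TransformRecord]:
    """Build occurrence and detection designs for the modeled sites.

    ``covariates`` needs columns site_id and dist_settlement_m;
    ``rai_table`` needs site_id, species_id, rai with rows for species
    'dog' and 'cat'; ``brands`` maps site_id to camera brand.
    """
    cov = covariates.set_index("site_id") if "site_id" in covariates.columns else covariates
    sites = sorted(cov.index.astype(str))

    rai_wide = (
        rai_table[rai_table["species_id"].isin(["dog", "cat"])]
        .pivot(index="site_id", columns="species_id", values="rai")
        .reindex(sites)
    )
    for sp in ("dog", "cat"):
        if sp not in rai_wide.columns or rai_wide[sp].isna().any():
            missing = (
                sites if sp not in rai_wide.columns
                else rai_wide.index[rai_wide[sp].isna()].tolist()
            )
            raise ValueError(f"missing {sp} RAI for site(s) {missing[:5]}")

    record = TransformRecord(log1p_columns=("dog_rai", "cat_rai"))
    dist = standardize(
        cov.loc[sites, "dist_settlement_m"].to_numpy(float), "dist_settlement", record
    )
    dog = standardize(np.log1p(rai_wide["dog"].to_numpy(float)), "dog_rai", record)
    cat = standardize(np.log1p(rai_wide["cat"].to_numpy(float)), "cat_rai", record)

    n = len(sites)
    occ = DesignMatrix(
        sites=sites,
        columns=list(OCC_COLUMNS),
        X=np.column_stack([np.ones(n), dist, dog, dog**2, cat, cat**2]),
    )

    missing_brand = [s for s in sites if s not in brands]
    if missing_brand:
        raise ValueError(f"missing camera brand for site(s) {missing_brand[:5]}")
    cudd = np.array([1.0 if brands[s] == "Cuddeback" else 0.0 for s in sites])
    reco = np.array([1.0 if brands[s] == "Reconyx" else 0.0 for s in sites])
    det = DesignMatrix(
        sites=sites,
        columns=list(DET_COLUMNS),
        X=np.column_stack([np.ones(n), cudd, reco, dog, cat]),
    )
    return occ, det, record


def correlation_screen(
    columns: pd.DataFrame | Mapping[str, Sequence[float]],
    r_threshold: float = 0.3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise Pearson correlations with a collinearity flag.

    A pair is flagged when |r| >= ``r_threshold``; the p-value (at
    ``alpha``) is reported alongside for the screening report.
    """
    df = pd.DataFrame(columns)
    if len(df) < 3:
        raise ValueError("correlation screen needs at least 3 rows")
    rows = []
    for a, b in combinations(df.columns, 2):
        r, p = stats.pearsonr(df[a].to_numpy(float), df[b].to_numpy(float))
        rows.append(
            {
                "var_a": a,
                "var_b": b,
                "r": float(r),
                "p": float(p),
                "significant": bool(p <= alpha),
                "flagged": bool(abs(r) >= r_threshold),
            }
        )
    return pd.DataFrame(rows, columns=["var_a", "var_b", "r", "p", "significant", "flagged"])
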