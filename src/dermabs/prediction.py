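"""Posterior predictions and prediction-interval upper limits on the percent scale.

Default-value candidates come from 90% prediction intervals for new
substances, studies and within-study groups: per posterior draw the upper
95% limit is ``inv_logit(lp + z * sqrt(V)) * 100`` where ``lp`` is the
cell's linear predictor, ``z`` the 95% standard-normal quantile and ``V``
the summed random-effect variances at the requested level. Three nested
levels are supported:

* ``substance`` — only between-substance variation (status-specific);
* ``substance+study`` — plus between-study variation;
* ``substance+study+within`` — plus within-study variation (the most
  conservative, used for the final default values).

The residual variance is never part of ``V``: prediction targets the mean
absorption of a new group, not a single replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .dataset import FORMULATION_CATEGORIES, STATUSES, CategoryKey
from .diagnostics import hpdi

__all__ = [
    "Z_95",
    "VARIANCE_LEVELS",
    "PredictionSummary",
    "mean_prediction",
    "pi_upper",
    "summarize_prediction",
    "prediction_table",
]

#: Standard-normal 95% quantile: the upper limit of a two-sided 90% interval.
Z_95: float = float(norm.ppf(0.95))

VARIANCE_LEVELS = ("substance", "substance+study", "substance+study+within")

_CATEGORY_EFFECT = {
    "organic_solvent": None,  # reference
    "other": "beta_other",
    "solid": "beta_solid",
    "water_based": "beta_water_based",
}


def _linear_predictor(draws: pd.DataFrame, status: str, category: str) -> np.ndarray:
    if status not in STATUSES:
        raise ValueError(f"unknown status {status!r}")
    if category not in FORMULATION_CATEGORIES:
        raise ValueError(f"unknown formulation category {category!r}")
    lp = draws["alpha"].to_numpy(dtype=float).copy()
    if status == "concentrate":
        lp += draws["beta_concentrate"].to_numpy(dtype=float)
    eff = _CATEGORY_EFFECT[category]
    if eff is not None:
        lp += draws[eff].to_numpy(dtype=float)
    return lp


def mean_prediction(
    draws: pd.DataFrame, status: str | None = None, category: str | None = None
) -> np.ndarray:
    """Per-draw mean percent absorbed for one cell of the design.

    When only one predictor is given, the other is held at its reference
    category (status: dilution; formulation category: organic solvent), so
    e.g. ``mean_prediction(d, status="concentrate")`` is the average
    concentrate effect.
    """
    status = status or "dilution"
    category = category or "organic_solvent"
    return expit(_linear_predictor(draws, status, category)) * 100.0


def pi_upper(
    draws: pd.DataFrame,
    status: str,
    category: str,
    variance_level: str = "substance+study+within",
) -> np.ndarray:
    """Per-draw upper 95% limit of the 90% prediction interval, in percent.

    The substance variance entering ``V`` is status-specific: the dilution
    variance for dilutions, the concentrate variance for concentrates.
    """
    if variance_level not in VARIANCE_LEVELS:
        raise ValueError(
            f"variance_level must be one of {VARIANCE_LEVELS}, got {variance_level!r}"
        )
    lp = _linear_predictor(draws, status, category)
    var_col = (
        "var_substance_dilution" if status == "dilution" else "var_substance_concentrate"
    )
    V = draws[var_col].to_numpy(dtype=float).copy()
    if variance_level in ("substance+study", "substance+study+within"):
        V += draws["var_study"].to_numpy(dtype=float)
    if variance_level == "substance+study+within":
        V += draws["var_within"].to_numpy(dtype=float)
    if np.any(V < 0):
        raise ValueError("negative total random-effect variance in posterior draws")
    return expit(lp + Z_95 * np.sqrt(V)) * 100.0


@dataclass(frozen=True)
class PredictionSummary:
    """Posterior summary of a prediction-draw vector for one cell and level."""

    category_key: CategoryKey | None
    variance_level: str | None
    posterior_median: float  # percent
    posterior_p95: float  # percent
    hpdi: tuple[float, float]  # percent


def summarize_prediction(
    values: np.ndarray,
    *,
    category_key: CategoryKey | None = None,
    variance_level: str | None = None,
    hpdi_mass: float = 0.95,
) -> PredictionSummary:
    """Median, 95th percentile and 95% HPDI of a vector of prediction draws."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("no prediction draws to summarise")
    interval = hpdi(x, hpdi_mass) if x.size >= 20 else (float(x.min()), float(x.max()))
    return PredictionSummary(
        category_key=category_key,
        variance_level=variance_level,
        posterior_median=float(np.median(x)),
        posterior_p95=float(np.quantile(x, 0.95)),
        hpdi=interval,
    )


def prediction_table(draws: pd.DataFrame, *, round_percent: bool = True) -> pd.DataFrame:
    """Default-value table: one row per cell x variance level.

    Columns: formulation_category, status, variance_level, posterior_median,
    posterior_p95, hpdi_low, hpdi_high — all in percent. ``round_percent``
    rounds the median and 95th percentile to whole percent (report style);
    HPDIs keep full precision.
    """
    rows = []
    for cat in FORMULATION_CATEGORIES:
        for status in STATUSES:
            for level in VARIANCE_LEVELS:
                s = summarize_prediction(
                    pi_upper(draws, status, cat, level),
                    category_key=CategoryKey(cat, status),
                    variance_level=level,
                )
                med, p95 = s.posterior_median, s.posterior_p95
                if round_percent:
                    med, p95 = round(med), round(p95)
                rows.append(
                    {
                        "formulation_category": cat,
                        "status": status,
                        "variance_level": level,
                        "posterior_median": med,
                        "posterior_p95": p95,
                        "hpdi_low": s.hpdi[0],
                        "hpdi_high": s.hpdi[1],
                    }
                )
    return pd.DataFrame(rows)
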