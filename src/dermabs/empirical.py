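"""Empirical percentile approach with distribution-free upper confidence limits.

For each analysis category the default value candidates are the sample 95th
percentile of the observed absorption fractions and a distribution-free
upper 95% confidence limit for that percentile. The confidence limit is the
k-th order statistic, with k chosen as the smallest count of successes whose
cumulative binomial probability (n draws, success probability 0.95) reaches
the confidence level — the classical order-statistic bound, exact without
any distributional assumption on the absorption values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import CategoryKey
from .preprocessing import PreparedDataset

__all__ = ["EmpiricalResult", "order_stat_index", "empirical_default", "empirical_table"]


@dataclass(frozen=True)
class EmpiricalResult:
    """Empirical default-value summary for one category."""

    category_key: CategoryKey | None
    n: int
    p95: float  # percent
    ucl95: float  # percent, upper confidence limit of the percentile
    k: int  # order-statistic index used for the limit


def order_stat_index(n: int, p: float = 0.95, conf: float = 0.95) -> int:
    """Smallest k with BinomialCDF(k; n, p) >= conf, clamped into [1, n].

    The k-th smallest of n observations then exceeds the population
    p-quantile with probability at least ``conf``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 < p < 1 and 0 < conf < 1):
        raise ValueError("p and conf must lie in (0, 1)")
    k = int(stats.binom.ppf(conf, n, p))
    # ppf returns the smallest k with CDF >= conf; guard the float boundary
    while k < n and stats.binom.cdf(k, n, p) < conf:
        k += 1
    return max(k, 1)


def empirical_default(
    values: Sequence[float],
    p: float = 0.95,
    conf: float = 0.95,
    *,
    category: CategoryKey | None = None,
    quantile_method: str = "linear",
) -> EmpiricalResult:
    """Sample p-quantile and its order-statistic upper confidence limit, in percent.

    ``quantile_method`` is any convention accepted by :func:`numpy.quantile`;
    the default linear interpolation between order statistics matches the
    common statistical-software default. The confidence limit itself is
    always an exact order statistic (no interpolation).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empirical_default requires at least one value")
    n = arr.size
    p95 = float(np.quantile(arr, p, method=quantile_method)) * 100.0
    k = order_stat_index(n, p, conf)
    ucl95 = float(np.sort(arr)[k - 1]) * 100.0
    return EmpiricalResult(category_key=category, n=n, p95=p95, ucl95=ucl95, k=k)


def empirical_table(
    prepared: PreparedDataset,
    p: float = 0.95,
    conf: float = 0.95,
    *,
    quantile_method: str = "linear",
    round_percent: bool = False,
) -> pd.DataFrame:
    """Per-category empirical summary over all categories present in the data.

    Returns one row per (formulation_category, status) with replicate count,
    the sample 95th percentile and its upper 95% confidence limit in
    percent. ``round_percent`` rounds the two summaries to whole percent
    for report-style output; full precision is the default.
    """
    rows = []
    for (cat, status), grp in prepared.table.groupby(
        ["formulation_category", "status"], sort=True
    ):
        res = empirical_default(
            grp["fraction_absorbed"].to_numpy(),
            p,
            conf,
            category=CategoryKey(cat, status),
            quantile_method=quantile_method,
        )
        rows.append(
            {
                "formulation_category": cat,
                "status": status,
                "n": res.n,
                "p95_percent": round(res.p95) if round_percent else res.p95,
                "ucl95_percent": round(res.ucl95) if round_percent else res.ucl95,
                "k": res.k,
            }
        )
    return pd.DataFrame(rows)
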