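"""Censoring-aware ingestion and per-product occurrence summaries."""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import ProductSummary

#: Default limit of quantification (µg/kg) of the reference GC-MS method.
DEFAULT_LOQ = 25.0

CENSOR_POLICIES = ("zero", "half_loq", "loq")


def substitute_censored(samples: pd.DataFrame, policy: str = "half_loq",
                        loq: float = DEFAULT_LOQ) -> pd.DataFrame:
    """Replace below-LOQ concentrations according to a substitution policy.

    Censored records carry the LOQ in their concentration field, not a
    measurement; this maps them to 0, LOQ/2 or LOQ before aggregation.
    Uncensored records pass through untouched.
    """
    if policy not in CENSOR_POLICIES:
        raise ValueError(f"unknown censoring policy {policy!r}; choose from {CENSOR_POLICIES}")
    if loq <= 0:
        raise ValueError("loq must be > 0")
    out = samples.copy()
    mask = out["censored"].astype(bool)
    if not mask.any():
        return out
    value = {"zero": 0.0, "half_loq": loq / 2.0, "loq": loq}[policy]
    out.loc[mask, "concentration_ug_kg"] = value
    return out


def summarize_product(values: Iterable[float], product: str = "",
                      percentile_method: str = "linear") -> ProductSummary:
    """Summary statistics for one product's concentrations.

    sd uses the n−1 denominator; the 95th percentile interpolates linearly
    between order statistics by default (``percentile_method`` accepts any
    numpy quantile method — p95 on n ≈ 20 is method-sensitive, so it is
    kept configurable).  A single observation gets sd = 0 with a warning.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError(f"no samples for product {product!r}")
    if arr.size == 1:
        warnings.warn(f"{product or 'product'}: single observation, sd set to 0", stacklevel=2)
        sd = 0.0
    else:
        sd = float(np.std(arr, ddof=1))
    return ProductSummary(
        product=product,
        n=int(arr.size),
        mean=float(np.mean(arr)),
        sd=sd,
        median=float(np.percentile(arr, 50, method=percentile_method)),
        p95=float(np.percentile(arr, 95, method=percentile_method)),
        min=float(np.min(arr)),
        max=float(np.max(arr)),
    )


def summarize(samples: pd.DataFrame, percentile_method: str = "linear") -> list[ProductSummary]:
    """One :class:`ProductSummary` per product, in first-appearance order."""
    if samples.empty:
        raise ValueError("no samples to summarize")
    order = samples["product"].drop_duplicates().tolist()
    return [
        summarize_product(samples.loc[samples["product"] == name, "concentration_ug_kg"],
                          product=name, percentile_method=percentile_method)
        for name in order
    ]


def summaries_frame(summaries: Sequence[ProductSummary], digits: int | None = None) -> pd.DataFrame:
    """Tabulate summaries; ``digits=0`` gives survey-table presentation rounding."""
    df = pd.DataFrame([{
        "product": s.product, "n": s.n, "mean": s.mean, "sd": s.sd,
        "median": s.median, "p95": s.p95, "min": s.min, "max": s.max,
    } for s in summaries])
    if digits is not None:
        num = ["mean", "sd", "median", "p95", "min", "max"]
        df[num] = df[num].round(digits)
        if digits == 0:
            df[num] = df[num].astype(int)
    return df
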