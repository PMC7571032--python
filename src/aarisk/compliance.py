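"""Benchmark-level screening of occurrence statistics and raw samples.

Benchmark levels (EU Reg. 2017/2158 style) are mitigation triggers, not
legal limits; a value exactly at the benchmark is compliant ("should not
exceed" reads as ≤ compliant), so exceedance is strict throughout.
Benchmarks are configuration data, letting other regulations be screened.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import ProductSpec, ProductSummary

SCREEN_STATISTICS = ("mean", "median", "p95", "max")


@dataclass(frozen=True)
class BenchmarkScreen:
    product: str
    statistic: str
    value: float
    benchmark_level: float
    exceeds: bool
    margin: float  # value − benchmark, µg/kg


def screen_benchmark(summary: ProductSummary, spec: ProductSpec,
                     statistic: str = "median") -> BenchmarkScreen:
    """Flag whether a summary statistic strictly exceeds the benchmark."""
    if statistic not in SCREEN_STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {SCREEN_STATISTICS}")
    value = summary.statistic(statistic)
    return BenchmarkScreen(
        product=summary.product,
        statistic=statistic,
        value=value,
        benchmark_level=spec.benchmark_level,
        exceeds=value > spec.benchmark_level,
        margin=value - spec.benchmark_level,
    )


def sample_exceedance_fraction(concentrations: Iterable[float], spec: ProductSpec) -> float:
    """Fraction of individual samples strictly above the benchmark level."""
    arr = np.asarray(list(concentrations), dtype=float)
    if arr.size == 0:
        raise ValueError("no samples")
    return float(np.mean(arr > spec.benchmark_level))


def screening_report(summaries: Sequence[ProductSummary], specs: Sequence[ProductSpec],
                     statistics: Sequence[str] = ("mean", "median", "p95")) -> pd.DataFrame:
    """Screen every product × statistic; one tidy row each."""
    by_name = {s.product: s for s in specs}
    rows = []
    for summary in summaries:
        spec = by_name.get(summary.product)
        if spec is None:
            raise ValueError(f"no benchmark configured for product {summary.product!r}")
        for stat in statistics:
            scr = screen_benchmark(summary, spec, stat)
            rows.append({
                "product": scr.product, "statistic": scr.statistic, "value": scr.value,
                "benchmark_level": scr.benchmark_level, "exceeds": scr.exceeds,
                "margin": scr.margin,
            })
    return pd.DataFrame(rows)
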