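"""Deterministic dietary exposure and margin-of-exposure risk characterization.

Daily intake of the contaminant is

    DI = C × Q / BW

with C the occurrence concentration in µg/kg (≡ ng/g), Q the daily
consumption in g/day and BW the body weight in kg, so DI comes out in
ng/kg bw/day with no further unit factor.  Two concentration scenarios are
crossed with two consumer percentiles per age group: the best scenario (BS)
uses the median concentration, the worst scenario (WS) the 95th percentile;
consumption enters at the median and the 95th-percentile consumer.

Risk characterization divides a benchmark-dose lower bound by the intake,

    MOE = BMDL10 / DI

with BMDL10 in mg/kg bw/day, hence the explicit 10⁶ mg→ng conversion.
Larger MOE is safer; concern is classified against each endpoint's
threshold (see :class:`aarisk.datatypes.Endpoint` for the boundary
conventions).  Comparisons always use unrounded values; rounding
(half away from zero, as survey tables print) is presentation-only.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .datatypes import ConsumptionProfile, Endpoint, IntakeResult, MoeResult, ProductSummary

#: mg → ng
_MG_TO_NG = 1e6


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (table presentation)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def daily_intake(c: float, q: float, bw: float) -> float:
    """DI = C·Q/BW in ng/kg bw/day (C in µg/kg, Q in g/day, BW in kg)."""
    if bw <= 0:
        raise ValueError("body weight must be > 0")
    if c < 0 or q < 0:
        raise ValueError("concentration and consumption must be >= 0")
    return c * q / bw


def scenario_grid(summaries: Iterable[ProductSummary],
                  profiles: Iterable[ConsumptionProfile],
                  age_groups: Sequence[str] | None = None) -> list[IntakeResult]:
    """Full BS/WS × consumer-percentile intake grid.

    For every product with a consumption profile and every age group:
    4 cells = {median, p95 consumer} × {BS: C = median, WS: C = p95}.
    Products lacking a profile for a requested age group raise, naming
    every missing (product, age group) pair; covered cells are unaffected.
    """
    summaries = list(summaries)
    profiles = list(profiles)
    by_key: Mapping[tuple[str, str], ConsumptionProfile] = {
        (p.product, p.age_group): p for p in profiles
    }
    if len(by_key) != len(profiles):
        raise ValueError("duplicate (product, age_group) consumption profiles")
    products_with_profiles = [s for s in summaries if any(p.product == s.product for p in profiles)]
    if age_groups is None:
        age_groups = list(dict.fromkeys(p.age_group for p in profiles))

    missing = [
        (s.product, g) for s in products_with_profiles for g in age_groups
        if (s.product, g) not in by_key
    ]
    if missing:
        raise ValueError(f"missing consumption profiles for cells: {missing}")

    results = []
    for s in products_with_profiles:
        for group in age_groups:
            prof = by_key[(s.product, group)]
            for percentile, q in (("median", prof.q_median), ("p95", prof.q_p95)):
                for scenario, c in (("BS", s.median), ("WS", s.p95)):
                    results.append(IntakeResult(
                        product=s.product, age_group=group,
                        consumer_percentile=percentile, scenario=scenario,
                        di=daily_intake(c, q, prof.bw),
                    ))
    return results


def intake_frame(results: Sequence[IntakeResult], rounded: bool = False) -> pd.DataFrame:
    df = pd.DataFrame([{
        "product": r.product, "age_group": r.age_group,
        "consumer_percentile": r.consumer_percentile, "scenario": r.scenario,
        "di_ng_kg_bw_day": round_half_away(r.di) if rounded else r.di,
    } for r in results])
    return df


def margin_of_exposure(di: float, endpoint: Endpoint,
                       cell: IntakeResult | None = None) -> MoeResult:
    """MOE = BMDL10·10⁶ / DI, classified against the endpoint threshold.

    DI = 0 makes the MOE undefined; the result is reported as
    ``not_computable`` rather than as an infinite margin.
    """
    product, group, pct, scen = ("", "", "median", "BS")
    if cell is not None:
        product, group, pct, scen = (cell.product, cell.age_group,
                                     cell.consumer_percentile, cell.scenario)
    if di < 0:
        raise ValueError("daily intake must be >= 0")
    if di == 0:
        return MoeResult(product=product, age_group=group, consumer_percentile=pct,
                         scenario=scen, endpoint=endpoint.name, moe=None,
                         concern="not_computable")
    moe = endpoint.bmdl10 * _MG_TO_NG / di
    concern = "low_concern" if endpoint.low_concern(moe) else "concern"
    return MoeResult(product=product, age_group=group, consumer_percentile=pct,
                     scenario=scen, endpoint=endpoint.name, moe=moe, concern=concern)


def classify_concern(moe: float, endpoint: Endpoint) -> str:
    """Concern class for an already-computed MOE (unrounded comparison)."""
    if moe <= 0:
        raise ValueError("MOE must be > 0")
    return "low_concern" if endpoint.low_concern(moe) else "concern"


def moe_grid(intakes: Sequence[IntakeResult], endpoints: Sequence[Endpoint]) -> list[MoeResult]:
    """Margin of exposure for every intake cell × endpoint."""
    return [margin_of_exposure(cell.di, ep, cell=cell) for cell in intakes for ep in endpoints]


def moe_frame(results: Sequence[MoeResult], rounded: bool = False) -> pd.DataFrame:
    return pd.DataFrame([{
        "product": r.product, "age_group": r.age_group,
        "consumer_percentile": r.consumer_percentile, "scenario": r.scenario,
        "endpoint": r.endpoint,
        "moe": (None if r.moe is None else (round_half_away(r.moe) if rounded else r.moe)),
        "concern": r.concern,
    } for r in results])
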