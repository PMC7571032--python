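"""Seeded generators for occurrence samples, recipes and consumption tables.

Concentrations are drawn by rejection from the parent normal distribution,
truncated to the product's observed min–max envelope (bounds sit within
about 1.5 sd of the mean in the default calibration, so rejection is
cheap).  The configured mean/sd therefore parametrize the *parent* normal;
the moments of the generated data are those of the truncated distribution.

Determinism contract: a fixed ``GeneratorConfig.seed`` yields byte-identical
output.  Each generator call derives its own independent stream from the
config seed, split per product in declaration order, so adding products at
the end of the list never perturbs earlier products' draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import defaults
from .datatypes import ProductModel

#: Sub-stream identifiers so separate generator calls never share a stream.
_OCCURRENCE_STREAM = 0
_CONSUMPTION_STREAM = 1

OCCURRENCE_COLUMNS = [
    "product", "category", "concentration_ug_kg", "censored",
    "moisture_pct", "sugars_pct", "salt_pct",
]
CONSUMPTION_COLUMNS = ["product", "age_group", "q_median_g_day", "q_p95_g_day", "bw_kg"]


@dataclass
class GeneratorConfig:
    """Everything the generators need: products, demography, and a seed."""

    seed: int
    products: list[ProductModel]
    age_groups: tuple[str, ...] = defaults.AGE_GROUPS
    bw_by_group: Mapping[str, float] = field(default_factory=lambda: dict(defaults.BODY_WEIGHTS))
    #: Optional exact targets: (product, age_group) -> (q_median, q_p95) in g/day.
    consumption_targets: Optional[Mapping[tuple[str, str], tuple[float, float]]] = None
    #: Products entering the consumption table (defaults to all products).
    consumption_products: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        if not self.products:
            raise ValueError("product list must not be empty")
        if not self.age_groups:
            raise ValueError("need at least one age group")
        for group in self.age_groups:
            if group not in self.bw_by_group:
                raise ValueError(f"missing body weight for age group {group!r}")
            if self.bw_by_group[group] <= 0:
                raise ValueError(f"body weight for {group!r} must be > 0")

    @property
    def total_samples(self) -> int:
        return sum(p.n_samples for p in self.products)


def default_config(seed: int = 0) -> GeneratorConfig:
    """The calibrated 200-sample survey configuration (see :mod:`aarisk.defaults`)."""
    targets = {
        (p.product, p.age_group): (p.q_median, p.q_p95)
        for p in defaults.calibrated_consumption()
    }
    return GeneratorConfig(
        seed=seed,
        products=defaults.product_models(),
        consumption_targets=targets,
        consumption_products=list(defaults.EXPOSURE_PRODUCTS),
    )


def truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                     lo: float, hi: float, size: int) -> np.ndarray:
    """Rejection-sample ``size`` draws from N(mean, sd) restricted to [lo, hi]."""
    if lo > hi:
        raise ValueError("lo > hi")
    if lo == hi:
        return np.full(size, float(lo))
    accept = norm.cdf((hi - mean) / sd) - norm.cdf((lo - mean) / sd)
    if accept < 1e-9:
        raise ValueError(
            f"truncation interval [{lo}, {hi}] carries ~no mass under "
            f"N({mean}, {sd}); refusing to rejection-sample"
        )
    out = np.empty(0)
    while out.size < size:
        want = size - out.size
        draw = rng.normal(mean, sd, size=max(int(want / accept) + 16, 16))
        out = np.concatenate([out, draw[(draw >= lo) & (draw <= hi)]])
    return out[:size]


def generate_occurrence(config: GeneratorConfig) -> pd.DataFrame:
    """Fabricate one occurrence record per sample, tidy, one row each.

    Concentrations: truncated-normal per product; recipe attributes
    (moisture, sugars, salt %): uniform within the product's recipe range.
    All records are quantified (``censored`` False) — the calibrated survey
    found every sample above the LOQ; censoring enters only through
    ingested real data.
    """
    streams = np.random.SeedSequence((config.seed, _OCCURRENCE_STREAM)).spawn(len(config.products))
    frames = []
    for model, stream in zip(config.products, streams):
        rng = np.random.default_rng(stream)
        n = model.n_samples
        conc = truncated_normal(rng, model.conc_mean, model.conc_sd,
                                model.conc_min, model.conc_max, n)
        frames.append(pd.DataFrame({
            "product": model.name,
            "category": model.category,
            "concentration_ug_kg": conc,
            "censored": False,
            "moisture_pct": rng.uniform(*model.moisture_range, size=n),
            "sugars_pct": rng.uniform(*model.sugars_range, size=n),
            "salt_pct": rng.uniform(*model.salt_range, size=n),
        }))
    return pd.concat(frames, ignore_index=True)[OCCURRENCE_COLUMNS]


def generate_consumption(config: GeneratorConfig) -> pd.DataFrame:
    """Fabricate a consumption table: one row per product × age group.

    With ``consumption_targets`` set, the table carries exactly those
    quantities (the calibrated fixture inverts them from published intakes).
    Otherwise median consumption is drawn uniformly in 40–160 g/day — the
    span of staple-bread consumption across age groups — and the
    95th-percentile consumer eats 1.5–3.5× the median.
    """
    names = list(config.consumption_products or [p.name for p in config.products])
    streams = np.random.SeedSequence((config.seed, _CONSUMPTION_STREAM)).spawn(len(names))
    rows = []
    for product, stream in zip(names, streams):
        rng = np.random.default_rng(stream)
        for group in config.age_groups:
            bw = config.bw_by_group[group]
            if config.consumption_targets is not None:
                key = (product, group)
                if key not in config.consumption_targets:
                    raise ValueError(f"no consumption target for {key}")
                q_med, q_p95 = config.consumption_targets[key]
            else:
                q_med = rng.uniform(40.0, 160.0)
                q_p95 = q_med * rng.uniform(1.5, 3.5)
            if q_med < 0 or q_p95 < q_med:
                raise ValueError(
                    f"{product}/{group}: need q_p95 >= q_median >= 0, "
                    f"got {q_med}, {q_p95}"
                )
            rows.append((product, group, q_med, q_p95, bw))
    return pd.DataFrame(rows, columns=CONSUMPTION_COLUMNS)
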