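"""Domain types shared across the survey-analysis pipeline.

All concentrations are in µg/kg (equivalently ng/g), consumption in g/day,
body weight in kg, daily intake in ng/kg bw/day, and benchmark doses
(BMDL10) in mg/kg bw/day.  Keeping the unit regime on the dataclasses keeps
every conversion explicit and testable in one place (:mod:`aarisk.exposure`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

CATEGORIES = ("bread", "sweets")

#: Scenario labels: BS uses the median concentration, WS the 95th percentile.
SCENARIOS = ("BS", "WS")

#: Consumer percentiles of the consumption distribution.
CONSUMER_PERCENTILES = ("median", "p95")


def _check_interval(name: str, rng: tuple[float, float]) -> tuple[float, float]:
    lo, hi = float(rng[0]), float(rng[1])
    if lo > hi:
        raise ValueError(f"{name} bounds out of order: {lo} > {hi}")
    return (lo, hi)


@dataclass(frozen=True)
class ProductModel:
    """Distributional model of one product's acrylamide occurrence.

    ``conc_mean``/``conc_sd`` parametrize the *parent* normal distribution;
    samples are drawn by rejection within ``[conc_min, conc_max]``, so the
    moments of generated data are those of the truncated distribution, not
    the parent.  ``conc_median``/``conc_p95`` optionally carry observed
    quantiles for calibrated studies (used by the exposure grid).
    """

    name: str
    category: str
    conc_mean: float
    conc_sd: float
    conc_min: float
    conc_max: float
    n_samples: int
    moisture_range: tuple[float, float]
    sugars_range: tuple[float, float]
    salt_range: tuple[float, float]
    conc_median: Optional[float] = None
    conc_p95: Optional[float] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.conc_sd <= 0:
            raise ValueError(f"{self.name}: conc_sd must be > 0")
        if self.conc_min > self.conc_max:
            raise ValueError(f"{self.name}: conc_min > conc_max")
        if self.conc_min == self.conc_max:
            # degenerate point mass: every draw is the single admissible value
            if self.conc_mean != self.conc_min:
                raise ValueError(f"{self.name}: point-mass bounds require conc_mean == conc_min")
        elif not (self.conc_min < self.conc_mean < self.conc_max):
            raise ValueError(
                f"{self.name}: need conc_min < conc_mean < conc_max, got "
                f"{self.conc_min}, {self.conc_mean}, {self.conc_max}"
            )
        if self.n_samples < 1:
            raise ValueError(f"{self.name}: n_samples must be >= 1")
        for attr in ("moisture_range", "sugars_range", "salt_range"):
            object.__setattr__(
                self, attr, _check_interval(f"{self.name}.{attr}", getattr(self, attr))
            )


@dataclass(frozen=True)
class ProductSummary:
    """Per-product occurrence summary (survey-table row)."""

    product: str
    n: int
    mean: float
    sd: float
    median: float
    p95: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if not (self.min <= self.median <= self.p95 <= self.max):
            raise ValueError(
                f"{self.product}: summary ordering violated: "
                f"min={self.min} median={self.median} p95={self.p95} max={self.max}"
            )

    def statistic(self, name: str) -> float:
        """Return one of the summary statistics by name."""
        if name not in ("mean", "median", "p95", "min", "max", "sd"):
            raise ValueError(f"unknown statistic {name!r}")
        return float(getattr(self, name))


@dataclass(frozen=True)
class ProductSpec:
    """Product identity plus its regulatory benchmark level (µg/kg)."""

    product: str
    category: str
    benchmark_level: float

    def __post_init__(self) -> None:
        if self.benchmark_level <= 0:
            raise ValueError("benchmark_level must be > 0")


@dataclass(frozen=True)
class ConsumptionProfile:
    """Median and 95th-percentile daily consumption for one product × age group."""

    product: str
    age_group: str
    q_median: float
    q_p95: float
    bw: float

    def __post_init__(self) -> None:
        if self.bw <= 0:
            raise ValueError("body weight must be > 0")
        if self.q_median < 0 or self.q_p95 < self.q_median:
            raise ValueError(
                f"{self.product}/{self.age_group}: need q_p95 >= q_median >= 0, "
                f"got median={self.q_median}, p95={self.q_p95}"
            )


@dataclass(frozen=True)
class IntakeResult:
    """Daily intake for one (product, age group, consumer percentile, scenario) cell."""

    product: str
    age_group: str
    consumer_percentile: str
    scenario: str
    di: float  # ng/kg bw/day

    def __post_init__(self) -> None:
        if self.consumer_percentile not in CONSUMER_PERCENTILES:
            raise ValueError(f"unknown consumer percentile {self.consumer_percentile!r}")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.di < 0:
            raise ValueError("daily intake must be >= 0")


@dataclass(frozen=True)
class Endpoint:
    """Toxicological endpoint: a BMDL10 and its MOE threshold of low concern.

    ``threshold_inclusive`` encodes the boundary convention: the neurotoxic
    endpoint is of low concern at MOE >= 125 ("125 or above"), whereas the
    carcinogenic endpoint requires MOE strictly > 10,000.
    """

    name: str
    bmdl10: float  # mg/kg bw/day
    moe_threshold: float
    threshold_inclusive: bool

    def __post_init__(self) -> None:
        if self.bmdl10 <= 0:
            raise ValueError("bmdl10 must be > 0")
        if self.moe_threshold <= 0:
            raise ValueError("moe_threshold must be > 0")

    def low_concern(self, moe: float) -> bool:
        if self.threshold_inclusive:
            return moe >= self.moe_threshold
        return moe > self.moe_threshold


@dataclass(frozen=True)
class MoeResult:
    """Margin of exposure for one intake cell × one endpoint."""

    product: str
    age_group: str
    consumer_percentile: str
    scenario: str
    endpoint: str
    moe: Optional[float]  # None when DI = 0 (MOE not computable)
    concern: str  # "low_concern" | "concern" | "not_computable"


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted calibration line: response = intercept + slope * concentration."""

    slope: float
    intercept: float
    residual_sd: float
    n: int
    concentrations: tuple[float, ...] = field(default=(), repr=False)
    responses: tuple[float, ...] = field(default=(), repr=False)


@dataclass(frozen=True)
class LetterAssignment:
    """Compact-letter-display letters for one group."""

    group: str
    letters: frozenset[str]

    def __post_init__(self) -> None:
        if not self.letters:
            raise ValueError(f"{self.group}: every group needs at least one letter")

    @property
    def label(self) -> str:
        return "".join(sorted(self.letters))
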