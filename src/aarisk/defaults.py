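"""Built-in study calibration: a 200-sample Italian baked-goods survey.

The default configuration reproduces the structure of a market survey of
acrylamide in ten Italian baked products (five bread-type, five sweets),
screened against the EU Regulation 2017/2158 benchmark levels, with a
deterministic exposure assessment for four bread-type products across three
age groups.  The per-product summary statistics, recipe ranges, benchmark
levels and the published daily-intake grid are data of that survey and are
treated as inputs here.

Consumption quantities are not published for the survey; the calibrated
profiles derive them by inverting the intake equation DI = C·Q/BW against
the published best-scenario intakes and median concentrations, which makes
the published intake grid an end-to-end regression surface for the
pipeline (see docs/methods.md for the one published cell this cannot
reproduce).
"""

from __future__ import annotations

from .datatypes import ConsumptionProfile, Endpoint, ProductModel, ProductSpec, ProductSummary

AGE_GROUPS = ("adolescents", "adults", "elderly")

#: Nominal Italian body weights (kg); the survey used one weight for adults
#: and the elderly.  Overridable in any GeneratorConfig.
BODY_WEIGHTS = {"adolescents": 55.0, "adults": 70.0, "elderly": 70.0}

# name, category, mean, sd, min, max, median, p95, n, moisture, sugars, salt, benchmark
_PRODUCT_TABLE = [
    ("Bread",              "bread",  57.0, 18.0,  31.0,  90.0,  55.0,  82.0, 22, (41, 43), (1.0, 1.2), (1.6, 1.8), 50.0),
    ("Bread rolls",        "bread",  52.0,  8.0,  42.0,  67.0,  55.0,  64.0, 22, (42, 48), (1.0, 1.2), (1.5, 1.7), 50.0),
    ("Wholemeal bread",    "bread",  61.0, 10.0,  44.0,  88.0,  60.0,  80.0, 22, (41, 45), (1.0, 1.2), (1.6, 1.8), 50.0),
    ("Friselle",           "bread", 358.0, 36.0, 306.0, 454.0, 353.0, 403.0, 18, (39, 42), (1.1, 1.3), (1.7, 1.9), 350.0),
    ("Wholemeal Friselle", "bread", 384.0, 37.0, 328.0, 450.0, 375.0, 450.0, 18, (35, 40), (1.2, 1.4), (1.5, 1.8), 350.0),
    ("Butter cookies",     "sweets", 310.0, 36.0, 249.0, 350.0, 330.0, 346.0, 20, (14, 18), (36, 39), (0.5, 0.8), 350.0),
    ("Baba cake",          "sweets", 292.0, 62.0, 207.0, 400.0, 278.0, 391.0, 20, (43, 46), (5, 6),   (0.0, 0.1), 300.0),
    ("Ice cream wafers",   "sweets", 337.0,  5.0, 330.0, 346.0, 336.0, 344.0, 20, (34, 35), (22, 24), (0.0, 0.1), 350.0),
    ("Frolla cake",        "sweets", 362.0, 11.0, 350.0, 380.0, 356.0, 380.0, 18, (30, 32), (3, 5),   (0.0, 0.1), 300.0),
    ("Croissants",         "sweets", 313.0, 55.0, 204.0, 396.0, 330.0, 382.0, 20, (36, 38), (10, 12), (1.0, 1.1), 300.0),
]


def product_models() -> list[ProductModel]:
    """Distributional models of the ten surveyed products."""
    return [
        ProductModel(
            name=row[0], category=row[1], conc_mean=row[2], conc_sd=row[3],
            conc_min=row[4], conc_max=row[5], conc_median=row[6], conc_p95=row[7],
            n_samples=row[8], moisture_range=row[9], sugars_range=row[10],
            salt_range=row[11],
        )
        for row in _PRODUCT_TABLE
    ]


def benchmark_specs() -> list[ProductSpec]:
    """EU 2017/2158 benchmark levels for the surveyed products (µg/kg)."""
    return [ProductSpec(product=r[0], category=r[1], benchmark_level=r[12]) for r in _PRODUCT_TABLE]


def reference_summaries() -> list[ProductSummary]:
    """Survey summary statistics as published (the calibration surface).

    These are the *observed* per-product statistics of the 200-sample
    survey; use :func:`aarisk.occurrence.summarize` to recompute summaries
    from raw or generated samples instead.
    """
    return [
        ProductSummary(product=r[0], n=r[8], mean=r[2], sd=r[3], median=r[6],
                       p95=r[7], min=r[4], max=r[5])
        for r in _PRODUCT_TABLE
    ]


# Published daily-intake grid (ng/kg bw/day), bread-type products only
# (bread rolls are pooled with bread in the consumption database, and
# sweets consumption rates were unavailable): per product and age group,
# (BS, WS) for median consumers and for 95th-percentile consumers.
PUBLISHED_INTAKE = {
    ("Bread", "adolescents"):              {"median": (84, 125), "p95": (236, 351)},
    ("Bread", "adults"):                   {"median": (59, 88),  "p95": (189, 281)},
    ("Bread", "elderly"):                  {"median": (71, 105), "p95": (165, 246)},
    ("Wholemeal bread", "adolescents"):    {"median": (75, 100), "p95": (137, 182)},
    ("Wholemeal bread", "adults"):         {"median": (43, 57),  "p95": (171, 229)},
    ("Wholemeal bread", "elderly"):        {"median": (60, 80),  "p95": (174, 232)},
    ("Friselle", "adolescents"):           {"median": (68, 78),  "p95": (173, 197)},
    ("Friselle", "adults"):                {"median": (67, 77),  "p95": (161, 184)},
    ("Friselle", "elderly"):               {"median": (81, 92),  "p95": (197, 225)},
    ("Wholemeal Friselle", "adolescents"): {"median": (50, 70),  "p95": (230, 276)},
    ("Wholemeal Friselle", "adults"):      {"median": (86, 103), "p95": (214, 257)},
    ("Wholemeal Friselle", "elderly"):     {"median": (114, 137), "p95": (213, 255)},
}

EXPOSURE_PRODUCTS = ("Bread", "Wholemeal bread", "Friselle", "Wholemeal Friselle")


def endpoints() -> list[Endpoint]:
    """Default toxicological endpoints for acrylamide risk characterization.

    BMDL10 values: 0.43 mg/kg bw/day (peripheral-nerve axonal degeneration,
    rats) and 0.17 mg/kg bw/day (Harderian-gland adenocarcinomas, mice).
    Low-concern thresholds: MOE of 125 or above (neurotoxicity, inclusive)
    and strictly above 10,000 (carcinogenicity).
    """
    return [
        Endpoint(name="neurotoxic", bmdl10=0.43, moe_threshold=125.0, threshold_inclusive=True),
        Endpoint(name="carcinogenic", bmdl10=0.17, moe_threshold=10_000.0, threshold_inclusive=False),
    ]


def calibrated_consumption() -> list[ConsumptionProfile]:
    """Consumption profiles inverted from the published best-scenario intakes.

    Q = DI_BS × BW / C_median, per product × age group, separately for the
    median-consumer and 95th-percentile-consumer intake tables; the
    pipeline therefore reproduces every published BS intake exactly.
    """
    medians = {r[0]: r[6] for r in _PRODUCT_TABLE}
    profiles = []
    for (product, group), cells in PUBLISHED_INTAKE.items():
        bw = BODY_WEIGHTS[group]
        c_med = medians[product]
        q_median = cells["median"][0] * bw / c_med
        q_p95 = cells["p95"][0] * bw / c_med
        profiles.append(ConsumptionProfile(product=product, age_group=group,
                                           q_median=q_median, q_p95=q_p95, bw=bw))
    return profiles
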