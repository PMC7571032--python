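"""CSV/YAML ingestion with row-level validation diagnostics.

CSV dialect is fixed: UTF-8, comma separators, "." decimal, mandatory
header row.  Validation failures are collected per row/column and reported
together; a hard failure anywhere blocks downstream stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .datatypes import CATEGORIES, ConsumptionProfile

OCCURRENCE_COLUMNS = [
    "product", "category", "concentration_ug_kg", "censored",
    "moisture_pct", "sugars_pct", "salt_pct",
]
CONSUMPTION_COLUMNS = ["product", "age_group", "q_median_g_day", "q_p95_g_day", "bw_kg"]


@dataclass(frozen=True)
class ValidationIssue:
    file: str
    row: Optional[int]  # 0-based data row; None for file-level issues
    column: Optional[str]
    message: str
    severity: str = "error"  # "error" | "warning"

    def __str__(self) -> str:
        loc = self.file
        if self.row is not None:
            loc += f":row {self.row}"
        if self.column:
            loc += f":{self.column}"
        return f"[{self.severity}] {loc}: {self.message}"


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def add(self, **kwargs) -> None:
        self.issues.append(ValidationIssue(**kwargs))

    def extend(self, other: "ValidationReport") -> None:
        self.issues.extend(other.issues)

    def raise_if_failed(self) -> None:
        if not self.ok:
            errors = [str(i) for i in self.issues if i.severity == "error"]
            raise ValidationError("input validation failed:\n" + "\n".join(errors))


class ValidationError(ValueError):
    pass


def _require_columns(df: pd.DataFrame, required: Sequence[str], file: str,
                     report: ValidationReport) -> bool:
    missing = [c for c in required if c not in df.columns]
    for col in missing:
        report.add(file=file, row=None, column=col, message="missing required column")
    return not missing


def read_occurrence(path: str | Path) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate a tidy occurrence CSV (one row per sample)."""
    file = str(path)
    df = pd.read_csv(path)
    report = ValidationReport()
    if not _require_columns(df, OCCURRENCE_COLUMNS, file, report):
        return df, report
    for idx, row in df.iterrows():
        if row["category"] not in CATEGORIES:
            report.add(file=file, row=int(idx), column="category",
                       message=f"unknown category {row['category']!r}")
        conc = row["concentration_ug_kg"]
        if pd.isna(conc) or conc < 0:
            report.add(file=file, row=int(idx), column="concentration_ug_kg",
                       message=f"concentration must be >= 0, got {conc!r}")
    return df, report


def read_consumption(path: str | Path,
                     known_products: Optional[Sequence[str]] = None
                     ) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate a consumption-profile CSV (product × age group rows).

    Hard failures: bw ≤ 0, negative consumption, q_p95 < q_median (never
    silently reordered — it signals corrupted quantile extraction),
    duplicate (product, age_group) rows, and products absent from
    ``known_products`` when given.
    """
    file = str(path)
    df = pd.read_csv(path)
    report = ValidationReport()
    if not _require_columns(df, CONSUMPTION_COLUMNS, file, report):
        return df, report
    for idx, row in df.iterrows():
        if known_products is not None and row["product"] not in known_products:
            report.add(file=file, row=int(idx), column="product",
                       message=f"unknown product {row['product']!r}")
        if pd.isna(row["bw_kg"]) or row["bw_kg"] <= 0:
            report.add(file=file, row=int(idx), column="bw_kg",
                       message=f"body weight must be > 0, got {row['bw_kg']!r}")
        if row["q_median_g_day"] < 0:
            report.add(file=file, row=int(idx), column="q_median_g_day",
                       message="consumption must be >= 0")
        if row["q_p95_g_day"] < row["q_median_g_day"]:
            report.add(file=file, row=int(idx), column="q_p95_g_day",
                       message=f"q_p95 ({row['q_p95_g_day']}) < q_median "
                               f"({row['q_median_g_day']})")
    dupes = df.duplicated(subset=["product", "age_group"], keep=False)
    for idx in df.index[dupes]:
        report.add(file=file, row=int(idx), column=None,
                   message=f"duplicate (product, age_group) row: "
                           f"({df.loc[idx, 'product']!r}, {df.loc[idx, 'age_group']!r})")
    return df, report


def consumption_profiles(df: pd.DataFrame) -> list[ConsumptionProfile]:
    return [
        ConsumptionProfile(product=r["product"], age_group=r["age_group"],
                           q_median=float(r["q_median_g_day"]),
                           q_p95=float(r["q_p95_g_day"]), bw=float(r["bw_kg"]))
        for _, r in df.iterrows()
    ]


def parse_range(value) -> tuple[float, float]:
    """Parse a "lo-hi" range cell; en-dash separators are normalized."""
    if isinstance(value, (tuple, list)):
        return float(value[0]), float(value[1])
    text = str(value).replace("–", "-").replace("—", "-")
    parts = text.split("-")
    if len(parts) != 2:
        raise ValueError(f"cannot parse range {value!r}")
    return float(parts[0]), float(parts[1])


def load_yaml(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: expected a mapping at top level")
    return data
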