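"""Inferential layer: one-way ANOVA, Tukey HSD, compact letter display,
Spearman rank correlation, and a locally weighted smoother with CI band.

ANOVA, Tukey–Kramer and Spearman are delegated to scipy; the compact letter
display (insert-and-absorb) and the local-linear smoother (with pointwise
confidence band from the equivalent kernel) are implemented here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import LetterAssignment

DEFAULT_ALPHA = 0.01  # survey-table convention: Tukey letters at p < 0.01

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


# ---------------------------------------------------------------------------
# ANOVA + Tukey HSD
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_resid: int
    #: True when the within-group variance is exactly zero but means differ;
    #: F is then infinite and p is reported as 0.
    degenerate: bool = False


def _validated_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(list(vals), dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {name!r} needs at least 2 observations")
        out[str(name)] = arr
    return out


def anova_oneway(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA on possibly unbalanced groups."""
    g = _validated_groups(groups)
    arrays = list(g.values())
    n_total = sum(a.size for a in arrays)
    df_between = len(arrays) - 1
    df_resid = n_total - len(arrays)
    grand = np.concatenate(arrays)
    ssw = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    if ssw == 0.0:
        ssb = sum(a.size * (a.mean() - grand.mean()) ** 2 for a in arrays)
        if ssb == 0.0:
            raise ValueError("all observations identical: F is 0/0, ANOVA undefined")
        return AnovaResult(f=math.inf, p=0.0, df_between=df_between,
                           df_resid=df_resid, degenerate=True)
    f, p = stats.f_oneway(*arrays)
    return AnovaResult(f=float(f), p=float(p), df_between=df_between, df_resid=df_resid)


@dataclass(frozen=True)
class PairwiseResult:
    """Symmetric Tukey HSD p-values and the derived significance matrix."""

    pvalues: pd.DataFrame
    significant: pd.DataFrame  # bool, True = means differ at alpha
    alpha: float


def tukey_hsd(groups: Mapping[str, Sequence[float]], alpha: float = DEFAULT_ALPHA) -> PairwiseResult:
    """All-pairs studentized-range test with the Tukey–Kramer unequal-n correction."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    g = _validated_groups(groups)
    names = list(g)
    arrays = [g[n] for n in names]
    ssw = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    if ssw == 0.0:
        # zero residual variance: any difference in means is infinitely separated
        pmat = np.ones((len(names), len(names)))
        for i, j in itertools.combinations(range(len(names)), 2):
            if arrays[i].mean() != arrays[j].mean():
                pmat[i, j] = pmat[j, i] = 0.0
    else:
        res = stats.tukey_hsd(*arrays)
        pmat = np.asarray(res.pvalue, dtype=float)
        np.fill_diagonal(pmat, 1.0)
    pvalues = pd.DataFrame(pmat, index=names, columns=names)
    return PairwiseResult(pvalues=pvalues, significant=pvalues < alpha, alpha=alpha)


# ---------------------------------------------------------------------------
# Compact letter display
# ---------------------------------------------------------------------------

def compact_letters(significant: pd.DataFrame,
                    order: Optional[Sequence[str]] = None) -> list[LetterAssignment]:
    """Insert-and-absorb compact letter display.

    Input is a symmetric boolean matrix, True where a pair differs
    significantly.  Output satisfies the defining property exactly: two
    groups share at least one letter iff their comparison is
    non-significant.  Letters are assigned lexicographically following the
    given group order (default: matrix index order).

    The algorithm starts from a single class containing every group; each
    significant pair splits every class containing both members into two
    copies (one without each member), after which classes contained in
    another class are absorbed.
    """
    if not significant.index.equals(significant.columns):
        raise ValueError("significance matrix must have matching index and columns")
    mat = significant.astype(bool)
    if not mat.values.T.tolist() == mat.values.tolist():
        raise ValueError("significance matrix must be symmetric")
    if bool(np.diag(mat.values).any()):
        raise ValueError("a group cannot differ significantly from itself")
    groups = list(order) if order is not None else list(mat.index)
    if set(groups) != set(mat.index):
        raise ValueError("order must be a permutation of the matrix groups")

    classes: list[set[str]] = [set(groups)]
    for g1, g2 in itertools.combinations(groups, 2):
        if not mat.loc[g1, g2]:
            continue
        updated: list[set[str]] = []
        for cls in classes:
            if g1 in cls and g2 in cls:
                updated.append(cls - {g1})
                updated.append(cls - {g2})
            else:
                updated.append(cls)
        # absorb: drop empty classes, duplicates, and subsets of another class
        nonempty = [cls for cls in updated if cls]
        classes = []
        for i, cls in enumerate(nonempty):
            redundant = any(
                cls < other or (cls == other and j < i)
                for j, other in enumerate(nonempty) if j != i
            )
            if not redundant:
                classes.append(cls)

    rank = {g: i for i, g in enumerate(groups)}
    classes.sort(key=lambda cls: sorted(rank[g] for g in cls))
    if len(classes) > len(_LETTERS):
        raise ValueError("more letter classes than available letters")
    assignments = {g: set() for g in groups}
    for letter, cls in zip(_LETTERS, classes):
        for g in cls:
            assignments[g].add(letter)
    return [LetterAssignment(group=g, letters=frozenset(assignments[g])) for g in groups]


# ---------------------------------------------------------------------------
# Rank correlation
# ---------------------------------------------------------------------------

def spearman(x: Sequence[float], y: Sequence[float], method: str = "t") -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    ``method="t"`` uses the large-sample t approximation for the two-sided
    p-value; ``method="exact"`` enumerates all pairings (n ≤ 10 only).
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must have the same length")
    if xa.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise ValueError("constant input: rank correlation undefined")
    rho, p = stats.spearmanr(xa, ya)
    if method == "t":
        return float(rho), float(p)
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    if xa.size > 10:
        raise ValueError("exact permutation p-value supported only for n <= 10")
    rx = stats.rankdata(xa)
    ry = stats.rankdata(ya)
    rx = rx - rx.mean()
    denom_x = math.sqrt(float(rx @ rx))

    def _rho(perm_ry: np.ndarray) -> float:
        ryc = perm_ry - perm_ry.mean()
        return float(rx @ ryc) / (denom_x * math.sqrt(float(ryc @ ryc)))

    observed = abs(_rho(ry))
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(_rho(np.asarray(perm))) >= observed - 1e-12:
            count += 1
    return float(rho), count / total


# ---------------------------------------------------------------------------
# Locally weighted smoother
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SmootherFit:
    grid: np.ndarray
    fitted: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    span: float


def _local_linear_weights(x: np.ndarray, x0: float, span: float) -> np.ndarray:
    """Equivalent-kernel row l(x0): fitted(x0) = l(x0) @ y, tricube weights."""
    n = x.size
    k = max(2, math.ceil(span * n))
    d = np.abs(x - x0)
    h = np.partition(d, min(k - 1, n - 1))[min(k - 1, n - 1)]
    if h == 0:
        nz = d[d > 0]
        h = nz.min() if nz.size else 1.0
    w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
    if np.count_nonzero(w) < 2:
        w = np.where(d <= h, 1.0, 0.0)
    design = np.column_stack([np.ones(n), x - x0])
    wd = design * w[:, None]
    xtwx = design.T @ wd
    # local-linear value at x0 is the intercept of the weighted fit
    try:
        beta_rows = np.linalg.solve(xtwx, wd.T)
    except np.linalg.LinAlgError:
        # collapsed design (all weighted x identical): weighted mean
        return w / w.sum()
    return beta_rows[0]


def fit_smoother(x: Sequence[float], y: Sequence[float], span: float = 0.75,
                 grid: Optional[Sequence[float]] = None, ci_level: float = 0.95,
                 n_grid: int = 50) -> SmootherFit:
    """Locally weighted linear regression with a pointwise CI band.

    The band is a normal approximation: at each grid point the fit is a
    linear combination l(x0)·y of the responses, so its variance is
    σ̂²‖l(x0)‖², with σ̂² the residual variance of the smoother at the data
    points.  Extrapolation beyond the data range is refused.
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must have the same length")
    if xa.size < 10:
        raise ValueError("need at least 10 observations to smooth")
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    if np.unique(xa).size < 2:
        raise ValueError("x is constant; nothing to smooth over")
    lo, hi = float(xa.min()), float(xa.max())
    if grid is None:
        ga = np.linspace(lo, hi, n_grid)
    else:
        ga = np.asarray(list(grid), dtype=float)
        if ga.min() < lo or ga.max() > hi:
            raise ValueError("grid extends outside the data range (extrapolation refused)")

    # residual variance from the smoother evaluated at the data points
    hat_diag = np.empty(xa.size)
    fitted_at_data = np.empty(xa.size)
    for i, xi in enumerate(xa):
        li = _local_linear_weights(xa, float(xi), span)
        fitted_at_data[i] = li @ ya
        hat_diag[i] = li[i]
    df_resid = max(xa.size - hat_diag.sum(), 1.0)
    sigma2 = float(np.sum((ya - fitted_at_data) ** 2) / df_resid)

    z = stats.norm.ppf(0.5 + ci_level / 2)
    fitted = np.empty(ga.size)
    half = np.empty(ga.size)
    for i, x0 in enumerate(ga):
        l0 = _local_linear_weights(xa, float(x0), span)
        fitted[i] = l0 @ ya
        half[i] = z * math.sqrt(sigma2 * float(l0 @ l0))
    return SmootherFit(grid=ga, fitted=fitted, ci_low=fitted - half,
                       ci_high=fitted + half, span=span)
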