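"""Trait-association statistics: Spearman rank correlation and Welch's t.

Operates on per-isolate phenotype tables (swarming area, biofilm index,
acetate growth ratio, competitive index ...).  Missing values are excluded
pairwise with reported counts rather than silently list-deleted.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SPEARMAN_EXACT_MAX_N = 10


@dataclass
class SpearmanResult:
    r_s: float | None
    p_two_sided: float | None
    n: int
    n_excluded: int = 0
    method: str = "t-approximation"
    degenerate: bool = False


def spearman(x, y, method: str = "t") -> SpearmanResult:
    """Two-sided Spearman rank correlation with average-rank ties.

    ``method='t'`` (default) uses the t approximation
    t = r_s * sqrt((n-2)/(1-r_s^2)) with df = n-2, the conventional behaviour
    at moderate n.  ``method='exact'`` enumerates all rank permutations
    (n <= 10 only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    n_excluded = int((~mask).sum())
    if n_excluded:
        logger.info("spearman: excluded %d incomplete pairs", n_excluded)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        raise ValueError(f"spearman needs at least 3 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(None, None, n, n_excluded, degenerate=True)

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r_s = float(np.corrcoef(rx, ry)[0, 1])

    if method == "t":
        if abs(r_s) >= 1.0:
            p = 0.0
        else:
            t = r_s * math.sqrt((n - 2) / (1.0 - r_s * r_s))
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
        return SpearmanResult(r_s, min(p, 1.0), n, n_excluded, method="t-approximation")
    if method == "exact":
        if n > SPEARMAN_EXACT_MAX_N:
            raise ValueError(
                f"exact permutation limited to n <= {SPEARMAN_EXACT_MAX_N}, got {n}"
            )
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r_perm = np.corrcoef(rx, perm)[0, 1]
            if abs(r_perm) >= abs(r_s) - 1e-12:
                count += 1
            total += 1
        return SpearmanResult(r_s, count / total, n, n_excluded, method="exact-permutation")
    raise ValueError(f"unknown method {method!r}")


@dataclass
class WelchResult:
    mean_a: float
    mean_b: float
    t: float | None
    df: float | None
    p_two_sided: float | None
    n_a: int
    n_b: int
    degenerate: bool = False

    @property
    def df_1dp(self) -> float | None:
        """Welch-Satterthwaite df rounded to one decimal (reporting convention)."""
        return None if self.df is None else round(self.df, 1)


def welch_t(group_a, group_b, log2_transform: bool = False) -> WelchResult:
    """Two-sided Welch's t-test, optionally on log2-transformed values."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if log2_transform:
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValueError("log2 transform requires strictly positive values")
        a = np.log2(a)
        b = np.log2(b)
    mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
    var_a, var_b = float(np.var(a, ddof=1)), float(np.var(b, ddof=1))
    if var_a == 0.0 and var_b == 0.0:
        return WelchResult(mean_a, mean_b, None, None, None, a.size, b.size, degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(
        mean_a, mean_b, float(res.statistic), float(res.df), float(res.pvalue),
        a.size, b.size,
    )


class PhenotypeTable:
    """Per-isolate trait table with correlation and group-comparison helpers."""

    def __init__(self, frame: pd.DataFrame, isolate_column: str = "isolate"):
        if isolate_column in frame.columns:
            if frame[isolate_column].duplicated().any():
                raise ValueError("one row per isolate required")
            frame = frame.set_index(isolate_column)
        self.frame = frame

    @classmethod
    def from_csv(cls, path, isolate_column: str = "isolate") -> "PhenotypeTable":
        return cls(pd.read_csv(path), isolate_column)

    def trait(self, name) -> np.ndarray:
        return self.frame[name].to_numpy(dtype=float)

    def correlate(self, traits=None, method: str = "t") -> pd.DataFrame:
        """All-pairs Spearman correlation over the given (numeric) traits."""
        if traits is None:
            traits = [c for c in self.frame.columns
                      if pd.api.types.is_numeric_dtype(self.frame[c])]
        rows = []
        for t1, t2 in itertools.combinations(traits, 2):
            res = spearman(self.trait(t1), self.trait(t2), method=method)
            rows.append({
                "trait_x": t1, "trait_y": t2, "r_s": res.r_s,
                "p_two_sided": res.p_two_sided, "n": res.n,
                "n_excluded": res.n_excluded,
            })
        return pd.DataFrame(rows)

    def group_compare(self, trait, group_column, log2_transform: bool = True):
        """Welch comparison of one trait between the two levels of a group label."""
        groups = self.frame[group_column]
        levels = sorted(groups.dropna().unique())
        if len(levels) != 2:
            raise ValueError(f"group column {group_column!r} must have exactly 2 levels")
        a = self.frame.loc[groups == levels[0], trait].to_numpy(dtype=float)
        b = self.frame.loc[groups == levels[1], trait].to_numpy(dtype=float)
        return levels, welch_t(a, b, log2_transform=log2_transform)
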