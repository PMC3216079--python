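"""Study-level statistics for damage-percentage tables.

The study design compares 5 surgical approaches with 5 hips each; because
samples are small and skewed, groups are described by medians with ranges
and compared with the rank-based Kruskal–Wallis test (ties-corrected H,
chi-square approximation with k − 1 degrees of freedom). Secondary-outcome
significance thresholds use the Bonferroni correction (alpha / m).
Dichotomous structure outcomes (released external rotators, transected
nerves, ligament states) are tabulated as frequencies without testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DamageTable:
    """Hips × approaches matrix of damage percentages.

    ``data`` has one column per approach and one row per hip; all values
    must lie in [0, 100]. Ragged groups (NaN-padded columns) are allowed.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[1] < 1:
            raise ValueError("damage table needs at least one approach column")
        numeric = self.data.apply(pd.to_numeric, errors="coerce")
        if numeric.isna().all(axis=0).any():
            empty = numeric.columns[numeric.isna().all(axis=0)].tolist()
            raise ValueError(f"empty group column(s): {empty}")
        bad = (numeric < 0) | (numeric > 100)
        if bad.any().any():
            rows, cols = np.nonzero(bad.to_numpy())
            r, c = rows[0], cols[0]
            raise ValueError(
                f"damage percentage out of [0, 100] at row {numeric.index[r]!r}, "
                f"column {numeric.columns[c]!r}: {numeric.iat[r, c]}"
            )
        self.data = numeric

    @property
    def approaches(self) -> list[str]:
        return list(self.data.columns)

    def groups(self) -> dict[str, np.ndarray]:
        """Per-approach value arrays with missing entries dropped."""
        return {c: self.data[c].dropna().to_numpy(dtype=float) for c in self.data.columns}

    def to_csv(self, path) -> None:
        self.data.to_csv(path)


class KruskalWallisResult(NamedTuple):
    statistic: float  # ties-corrected H
    df: int
    pvalue: float


@dataclass
class GroupSummary:
    """Per-group medians and ranges plus the joint Kruskal–Wallis test."""

    table: pd.DataFrame  # columns: median, min, max; one row per approach
    test: KruskalWallisResult | None = None

    def to_dict(self) -> dict:
        d = {"groups": self.table.to_dict(orient="index")}
        if self.test is not None:
            d["kruskal_wallis"] = {
                "H": self.test.statistic,
                "df": self.test.df,
                "p": self.test.pvalue,
            }
        return d

    def __str__(self) -> str:
        lines = ["Group summary (median, range)"]
        for name, row in self.table.iterrows():
            lines.append(
                f"  {name}: {row['median']:g} ({row['min']:g}-{row['max']:g})"
            )
        if self.test is not None:
            lines.append(
                f"Kruskal-Wallis: H={self.test.statistic:.3f}, df={self.test.df}, "
                f"p={self.test.pvalue:.3g}"
            )
        return "\n".join(lines)


def summarize_groups(table: DamageTable, with_test: bool = True) -> GroupSummary:
    """Medians and ranges per approach; optionally the joint K-W test.

    Medians use the standard midpoint rule (mean of the two central order
    statistics for even group sizes).
    """
    groups = table.groups()
    rows = {}
    for name, vals in groups.items():
        if vals.size == 0:
            raise ValueError(f"group {name!r} is empty")
        rows[name] = {
            "median": float(np.median(vals)),
            "min": float(vals.min()),
            "max": float(vals.max()),
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")[["median", "min", "max"]]
    test = kruskal_wallis(table) if with_test and len(groups) >= 2 else None
    return GroupSummary(table=frame, test=test)


def kruskal_wallis(table: DamageTable | list) -> KruskalWallisResult:
    """Joint k-group Kruskal–Wallis test with mid-rank tie correction.

    Returns the ties-corrected H statistic, k − 1 degrees of freedom and the
    chi-square-approximation p-value. If every observation is identical the
    test is degenerate and (H=0, p=1) is returned.
    """
    if isinstance(table, DamageTable):
        samples = list(table.groups().values())
    else:
        samples = [np.asarray(g, dtype=float) for g in table]
    if len(samples) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    for g in samples:
        if g.size == 0:
            raise ValueError("Kruskal-Wallis groups must be non-empty")
    df = len(samples) - 1
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return KruskalWallisResult(0.0, df, 1.0)
    h, p = stats.kruskal(*samples)
    return KruskalWallisResult(float(h), df, float(p))


def kruskal_wallis_pairwise(
    table: DamageTable, reference: str
) -> dict[str, KruskalWallisResult]:
    """Two-group K-W test of each approach against a reference approach."""
    groups = table.groups()
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not in table")
    ref = groups[reference]
    return {
        name: kruskal_wallis([ref, vals])
        for name, vals in groups.items()
        if name != reference
    }


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha / m for m comparisons."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1 or int(m) != m:
        raise ValueError(f"number of comparisons must be a positive integer, got {m}")
    return alpha / m


def tabulate_dichotomous(
    records: pd.DataFrame, n_per_group: int = 5
) -> pd.DataFrame:
    """Frequency table of dichotomous structure outcomes per approach.

    ``records`` is long- or wide-form: either columns
    ``(category, structure, <approach columns...>)`` with integer counts, or
    ``(category, structure, approach, count)``. Counts must lie in
    [0, n_per_group]. Returns a wide table indexed by (category, structure).
    """
    records = records.copy()
    if {"approach", "count"}.issubset(records.columns):
        wide = records.pivot_table(
            index=["category", "structure"],
            columns="approach",
            values="count",
            aggfunc="sum",
            fill_value=0,
        )
    else:
        wide = records.set_index(["category", "structure"])
    wide = wide.apply(pd.to_numeric)
    if ((wide < 0) | (wide > n_per_group)).any().any():
        raise ValueError(f"counts must lie in [0, {n_per_group}]")
    return wide
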