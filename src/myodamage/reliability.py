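"""Inter-/intra-observer reliability of damage percentages via the ICC.

The intraclass correlation coefficient quantifies how reproducible the
damage measurement is when independent assessors repeat the only subjective
step of the pipeline: picking the training regions that define the stain
color models. The variant implemented is ICC(2,1) — two-way random effects,
absolute agreement, single measurement — assembled from the standard
two-way ANOVA mean squares:

    ICC(2,1) = (MS_subjects - MS_error) /
               (MS_subjects + (k-1)·MS_error + (k/n)·(MS_raters - MS_error))

with n subjects and k raters. Raters are treated as a random sample of
interchangeable assessors, and absolute agreement (not mere consistency)
matters because the damage percentages are compared across approaches on an
absolute scale. Negative estimates are reported as computed, not truncated.

``simulate_raters`` emulates the repeated assessment: each simulated rater
re-samples its own training regions on every slice and re-runs the full
segmentation, yielding a subjects × raters ratings matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .segmentation import StainSegmentation
from .simulate import SliceFixture, generate_training_regions


@dataclass
class RatingsMatrix:
    """Complete subjects × raters grid of damage percentages."""

    values: np.ndarray
    subjects: list[str] | None = None
    raters: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ratings must be a 2-D subjects × raters array")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError(f"need at least 2 subjects and 2 raters, got {n}×{k}")
        if np.isnan(self.values).any():
            raise ValueError("ratings matrix must have no missing cells")
        if self.subjects is None:
            self.subjects = [f"subject_{i + 1}" for i in range(n)]
        if self.raters is None:
            self.raters = [f"rater_{j + 1}" for j in range(k)]

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "RatingsMatrix":
        return cls(
            values=frame.to_numpy(dtype=float),
            subjects=[str(i) for i in frame.index],
            raters=[str(c) for c in frame.columns],
        )

    @classmethod
    def from_csv(cls, path) -> "RatingsMatrix":
        return cls.from_dataframe(pd.read_csv(path, index_col=0))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subjects, columns=self.raters)


@dataclass
class ICCResult:
    """ICC point estimate together with the ANOVA mean squares used."""

    icc: float
    ms_subjects: float
    ms_raters: float
    ms_error: float
    n_subjects: int
    n_raters: int
    formulation: str = "ICC(2,1) two-way random effects, absolute agreement, single measure"
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "icc": self.icc,
            "ms_subjects": self.ms_subjects,
            "ms_raters": self.ms_raters,
            "ms_error": self.ms_error,
            "n_subjects": self.n_subjects,
            "n_raters": self.n_raters,
            "formulation": self.formulation,
            "degenerate": self.degenerate,
        }


def icc_single_rater(ratings: RatingsMatrix | np.ndarray) -> ICCResult:
    """ICC(2,1) from the two-way ANOVA decomposition of a ratings grid.

    Degenerate inputs are handled explicitly: if every cell is identical the
    raters agree perfectly and 1.0 is returned with a warning; if there is
    no between-subject variance the coefficient is not meaningful and the
    result is flagged ``degenerate`` with a warning.
    """
    if not isinstance(ratings, RatingsMatrix):
        ratings = RatingsMatrix(np.asarray(ratings))
    x = ratings.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)

    ss_total = float(((x - grand) ** 2).sum())
    ss_subjects = float(k * ((row_means - grand) ** 2).sum())
    ss_raters = float(n * ((col_means - grand) ** 2).sum())
    ss_error = ss_total - ss_subjects - ss_raters

    ms_subjects = ss_subjects / (n - 1)
    ms_raters = ss_raters / (k - 1)
    ms_error = ss_error / ((n - 1) * (k - 1))

    # degeneracy is detected on the raw values, not the computed sums of
    # squares, which carry ~1e-28 rounding noise for constant input
    if np.ptp(x) == 0.0:
        warnings.warn(
            "all ratings identical: zero total variance; raters agree exactly, ICC set to 1",
            stacklevel=2,
        )
        return ICCResult(1.0, ms_subjects, ms_raters, ms_error, n, k, degenerate=True)

    denom = ms_subjects + (k - 1) * ms_error + (k / n) * (ms_raters - ms_error)
    if np.ptp(row_means) == 0.0:
        warnings.warn(
            "no between-subject variance: ICC is degenerate and not interpretable",
            stacklevel=2,
        )
        icc = (ms_subjects - ms_error) / denom if denom != 0 else float("nan")
        return ICCResult(float(icc), ms_subjects, ms_raters, ms_error, n, k, degenerate=True)

    icc = (ms_subjects - ms_error) / denom
    return ICCResult(float(icc), ms_subjects, ms_raters, ms_error, n, k)


def simulate_raters(
    fixtures: Sequence[SliceFixture],
    n_raters: int = 2,
    seeds: Sequence[int] | None = None,
    n_regions: int = 10,
    region_size: int = 10,
    k: float = 1.7,
) -> RatingsMatrix:
    """Simulate independent assessors re-measuring every slice.

    Each rater has its own base seed; for each fixture the rater re-samples
    ``n_regions`` training rectangles per stain class and re-runs the full
    segmentation over the fixture's bounding box. Returns the fixtures ×
    raters matrix of damage percentages.
    """
    if seeds is None:
        seeds = list(range(1, n_raters + 1))
    if len(seeds) != n_raters:
        raise ValueError(f"need {n_raters} rater seeds, got {len(seeds)}")
    values = np.empty((len(fixtures), n_raters))
    for i, fixture in enumerate(fixtures):
        for j, rater_seed in enumerate(seeds):
            # distinct sub-seed per (rater, fixture) cell, < 2**31
            cell_seed = (int(rater_seed) * 1_000_003 + i) % (2**31)
            try:
                regions = generate_training_regions(
                    fixture, n_regions=n_regions, region_size=region_size, seed=cell_seed
                )
                res = StainSegmentation(
                    fixture.image,
                    regions.yellow_regions,
                    regions.blue_regions,
                    fixture.bbox,
                    k=k,
                ).fit()
            except ValueError as e:
                raise ValueError(f"fixture {i}, rater {j} ({rater_seed}): {e}") from e
            values[i, j] = res.damage_pct
    return RatingsMatrix(
        values=values,
        subjects=[f"slice_{i + 1}" for i in range(len(fixtures))],
        raters=[f"rater_{j + 1}" for j in range(n_raters)],
    )
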