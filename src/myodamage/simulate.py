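"""Synthetic stained-slice images and study tables with known ground truth.

No photographs from the original cadaver study are available, so every
downstream stage is exercised on synthetic data. A slice is modelled as an
ellipse on a plain background — the simplest convex shape with a
controllable damaged fraction for a planar muscle cross-section. The
damaged (yellow) part is a contiguous chord cut: ellipse pixels are swept
column by column and the first ``round(f * N)`` of them are labelled
damaged, so the realized fraction is exact up to pixel quantization.
Colors are base RGB triples plus iid per-channel Gaussian noise, clipped
to [0, 255].

The study-table generator emulates the shape of a 5-approach × 5-hip
damage-percentage table: integer percentages drawn from truncated normal
distributions centered on the requested group medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .group_stats import DamageTable
from .segmentation import Region

# Truth label codes (distinct from segmentation label codes on purpose:
# truth knows "background", segmentation knows "uncolored").
TRUTH_BACKGROUND = 0
TRUTH_DAMAGED = 1
TRUTH_UNDAMAGED = 2

_RGB = tuple[float, float, float]


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of one synthetic stained-slice image.

    Defaults give a 640×480 canvas with an ellipse of semi-axes 240×180
    centered on it — large enough that even a 5%-damaged sliver admits ten
    pure 10×10 training squares. Base colors are a saturated latex yellow
    and blue on a light gray background. ``noise_sd`` is the per-channel
    Gaussian SD in 8-bit intensity units.
    """

    width: int = 640
    height: int = 480
    center: tuple[float, float] | None = None  # (cx, cy); canvas center if None
    semi_axes: tuple[float, float] | None = None  # (a, b); 0.375 * (w, h) if None
    true_fraction: float = 0.5
    base_yellow: _RGB = (220.0, 200.0, 60.0)
    base_blue: _RGB = (50.0, 70.0, 180.0)
    base_background: _RGB = (235.0, 235.0, 235.0)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_fraction <= 1.0:
            raise ValueError(f"true_fraction must be in [0, 1], got {self.true_fraction}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be non-negative, got {self.noise_sd}")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("canvas dimensions must be positive")
        for name in ("base_yellow", "base_blue", "base_background"):
            rgb = getattr(self, name)
            if len(rgb) != 3 or any(not 0 <= c <= 255 for c in rgb):
                raise ValueError(f"{name} components must lie in [0, 255], got {rgb}")
        cx, cy = self.ellipse_center
        a, b = self.ellipse_axes
        if a <= 0 or b <= 0:
            raise ValueError("ellipse semi-axes must be positive")
        if cx - a < 0 or cx + a > self.width - 1 or cy - b < 0 or cy + b > self.height - 1:
            raise ValueError(
                f"ellipse (center=({cx}, {cy}), semi-axes=({a}, {b})) "
                f"does not fit the {self.width}x{self.height} canvas"
            )

    @property
    def ellipse_center(self) -> tuple[float, float]:
        return self.center if self.center is not None else (self.width / 2.0, self.height / 2.0)

    @property
    def ellipse_axes(self) -> tuple[float, float]:
        return self.semi_axes if self.semi_axes is not None else (0.375 * self.width, 0.375 * self.height)

    def to_dict(self) -> dict:
        return {
            "width": self.width,
            "height": self.height,
            "center": list(self.ellipse_center),
            "semi_axes": list(self.ellipse_axes),
            "true_fraction": self.true_fraction,
            "base_yellow": list(self.base_yellow),
            "base_blue": list(self.base_blue),
            "base_background": list(self.base_background),
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }


@dataclass
class SliceFixture:
    """A synthetic slice image together with its ground truth.

    ``truth_labels`` holds per-pixel labels in {background, damaged,
    undamaged}; ``true_fraction`` is the realized damaged share of the
    stained pixels (exact count ratio, which can differ from the requested
    fraction by at most one pixel of quantization).
    """

    image: np.ndarray
    truth_labels: np.ndarray
    true_fraction: float
    bbox: Region
    params: SimulationParams

    @property
    def damaged_mask(self) -> np.ndarray:
        return self.truth_labels == TRUTH_DAMAGED

    @property
    def undamaged_mask(self) -> np.ndarray:
        return self.truth_labels == TRUTH_UNDAMAGED


@dataclass
class RegionSet:
    """Training rectangles for both stain classes."""

    yellow_regions: list[Region]
    blue_regions: list[Region]
    region_size: int = 10


def generate_slice_image(params: SimulationParams) -> SliceFixture:
    """Render a synthetic stained cross-section with known ground truth.

    Deterministic for a fixed seed. The noise field is drawn once as
    standard normals and scaled by ``noise_sd``, so for a fixed seed a
    larger ``noise_sd`` deviates (weakly) more from the base colors.
    """
    cx, cy = params.ellipse_center
    a, b = params.ellipse_axes
    yy, xx = np.mgrid[0 : params.height, 0 : params.width]
    ellipse = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    n_total = int(np.count_nonzero(ellipse))
    if n_total == 0:
        raise ValueError("ellipse covers no pixels")
    n_damaged = int(round(params.true_fraction * n_total))

    # chord cut: sweep the ellipse column by column (then row) and label the
    # first n_damaged pixels damaged — contiguous, with exact pixel count
    ys, xs = np.nonzero(ellipse)
    order = np.lexsort((ys, xs))
    labels = np.full((params.height, params.width), TRUTH_BACKGROUND, dtype=np.uint8)
    labels[ys[order[:n_damaged]], xs[order[:n_damaged]]] = TRUTH_DAMAGED
    labels[ys[order[n_damaged:]], xs[order[n_damaged:]]] = TRUTH_UNDAMAGED

    base = np.empty((params.height, params.width, 3), dtype=np.float64)
    base[:] = params.base_background
    base[labels == TRUTH_DAMAGED] = params.base_yellow
    base[labels == TRUTH_UNDAMAGED] = params.base_blue

    rng = np.random.default_rng(params.seed)
    z = rng.standard_normal(base.shape)
    image = np.clip(np.rint(base + params.noise_sd * z), 0, 255).astype(np.uint8)

    x0, x1 = int(xs.min()), int(xs.max())
    y0, y1 = int(ys.min()), int(ys.max())
    bbox = Region(x=x0, y=y0, w=x1 - x0 + 1, h=y1 - y0 + 1)
    return SliceFixture(
        image=image,
        truth_labels=labels,
        true_fraction=n_damaged / n_total,
        bbox=bbox,
        params=params,
    )


def _admissible_corners(mask: np.ndarray, size: int) -> np.ndarray:
    """(y, x) top-left corners whose size×size square lies fully inside mask."""
    h, w = mask.shape
    if h < size or w < size:
        return np.empty((0, 2), dtype=np.int64)
    # integral-image window sums; a corner is admissible iff the window is pure
    ii = np.pad(np.cumsum(np.cumsum(mask.astype(np.int64), axis=0), axis=1), ((1, 0), (1, 0)))
    sums = ii[size:, size:] - ii[:-size, size:] - ii[size:, :-size] + ii[:-size, :-size]
    ys, xs = np.nonzero(sums == size * size)
    return np.column_stack([ys, xs])


def generate_training_regions(
    fixture: SliceFixture,
    n_regions: int = 10,
    region_size: int = 10,
    seed: int = 0,
) -> RegionSet:
    """Sample pure, non-overlapping training rectangles for both classes.

    Corners are drawn uniformly at random among all placements whose square
    lies entirely inside the class's truth area; placements overlapping an
    already accepted rectangle of the same class are rejected and redrawn.
    Deterministic for a fixed seed.
    """
    if n_regions < 1 or region_size < 1:
        raise ValueError("n_regions and region_size must be positive")
    rng = np.random.default_rng(seed)
    out: dict[str, list[Region]] = {}
    for label, mask in (("yellow", fixture.damaged_mask), ("blue", fixture.undamaged_mask)):
        corners = _admissible_corners(mask, region_size)
        if len(corners) < n_regions:
            raise ValueError(
                f"the {label} class area is too small: only {len(corners)} admissible "
                f"{region_size}x{region_size} placements, need at least {n_regions}"
            )
        chosen: list[Region] = []
        attempts = 0
        max_attempts = 10_000 * n_regions
        while len(chosen) < n_regions:
            if attempts >= max_attempts:
                raise ValueError(
                    f"could not place {n_regions} non-overlapping {region_size}x"
                    f"{region_size} regions in the {label} class area"
                )
            attempts += 1
            y, x = corners[rng.integers(len(corners))]
            cand = Region(x=int(x), y=int(y), w=region_size, h=region_size)
            if any(cand.overlaps(r) for r in chosen):
                continue
            chosen.append(cand)
        out[label] = chosen
    return RegionSet(yellow_regions=out["yellow"], blue_regions=out["blue"], region_size=region_size)


def generate_study_table(
    group_medians: list[float],
    spread: float,
    n_per_group: int,
    seed: int = 0,
    group_labels: list[str] | None = None,
) -> DamageTable:
    """Simulate a hips × approaches damage-percentage table.

    Each group's values are drawn from a normal distribution centered on its
    stated median with SD ``spread``, truncated to [0, 100] and rounded to
    integer percent (study tables report integers). Deterministic for a
    fixed seed.
    """
    medians = [float(m) for m in group_medians]
    if n_per_group < 2:
        raise ValueError(f"n_per_group must be at least 2, got {n_per_group}")
    if not 0 <= spread <= 100:
        raise ValueError(f"spread must be in [0, 100], got {spread}")
    for m in medians:
        if not 0 <= m <= 100:
            raise ValueError(f"group medians must be in [0, 100], got {m}")
    if group_labels is None:
        group_labels = [f"approach_{i + 1}" for i in range(len(medians))]
    if len(group_labels) != len(medians):
        raise ValueError("group_labels must match group_medians in length")

    rng = np.random.default_rng(seed)
    columns = {}
    for label, m in zip(group_labels, medians):
        if spread == 0:
            vals = np.full(n_per_group, m)
        else:
            lo, hi = (0.0 - m) / spread, (100.0 - m) / spread
            vals = stats.truncnorm.rvs(lo, hi, loc=m, scale=spread, size=n_per_group, random_state=rng)
        columns[label] = np.clip(np.rint(vals), 0, 100).astype(int)
    import pandas as pd

    frame = pd.DataFrame(columns, index=pd.RangeIndex(1, n_per_group + 1, name="hip"))
    return DamageTable(frame)
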