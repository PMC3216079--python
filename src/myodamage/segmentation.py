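"""Color-class segmentation of stained muscle cross-section photographs.

A muscle cross-section cut at the midsubstance level (MCSA, perpendicular to
the fiber direction) is stained yellow where fibers are disrupted and blue
where they are intact, then photographed. Each stain class is modelled by
per-channel RGB means and standard deviations estimated from small training
regions sampled inside the stain; a pixel inside the segmentation bounding
box belongs to a class when every channel lies within mean ± k·SD of that
class (k = 1.7 by default). The damage percentage is

    alpha = 100 * n_yellow / (n_yellow + n_blue),

the yellow share of all *colored* pixels — pixels matching neither class
(background, shadows) are excluded from the denominator.

Conventions, fixed once and used everywhere:

* coordinates are 0-based and half-open; ``x`` is the column, ``y`` the row;
* standard deviations use the sample convention (``ddof=1``) over the pooled
  pixels of all training regions of a class;
* a channel with zero SD matches only on exact equality;
* a pixel inside both class boxes is assigned to the class with the smaller
  SD-normalized Euclidean distance to the class mean (ties go to yellow and
  are logged);
* images are 8-bit RGB.

The :class:`StainSegmentation` model object bundles the image, training
regions and bounding box; :meth:`StainSegmentation.fit` estimates both color
models, classifies the pixels and returns a
:class:`StainSegmentationResults` with the counts, the damage percentage and
diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

# Label codes used in LabelMap arrays.
UNCOLORED = 0
YELLOW = 1
BLUE = 2

DEFAULT_K = 1.7


def _as_rgb8(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB image of shape (h, w, 3), got {image.shape}")
    if image.dtype != np.uint8:
        arr = np.asarray(image)
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("channel values must lie in [0, 255]")
        image = arr.astype(np.uint8)
    return image


@dataclass(frozen=True)
class Region:
    """Axis-aligned pixel rectangle, 0-based, half-open.

    Covers columns ``[x, x + w)`` and rows ``[y, y + h)``.
    """

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"region extents must be positive, got w={self.w}, h={self.h}")
        if self.x < 0 or self.y < 0:
            raise ValueError(f"region origin must be non-negative, got x={self.x}, y={self.y}")

    @property
    def area(self) -> int:
        return self.w * self.h

    def contains_region(self, other: "Region") -> bool:
        return (
            self.x <= other.x
            and self.y <= other.y
            and other.x + other.w <= self.x + self.w
            and other.y + other.h <= self.y + self.h
        )

    def overlaps(self, other: "Region") -> bool:
        return (
            self.x < other.x + other.w
            and other.x < self.x + self.w
            and self.y < other.y + other.h
            and other.y < self.y + self.h
        )

    def slices(self) -> tuple[slice, slice]:
        """(row, column) slices for indexing a numpy image."""
        return slice(self.y, self.y + self.h), slice(self.x, self.x + self.w)

    def inside_image(self, image: np.ndarray) -> bool:
        h, w = image.shape[:2]
        return self.x + self.w <= w and self.y + self.h <= h

    def to_dict(self) -> dict:
        return {"x": self.x, "y": self.y, "w": self.w, "h": self.h}

    @classmethod
    def from_dict(cls, d: dict) -> "Region":
        return cls(int(d["x"]), int(d["y"]), int(d["w"]), int(d["h"]))


@dataclass(frozen=True)
class ColorClassModel:
    """Per-channel RGB color model of one stain class.

    A pixel ``p`` matches the class iff ``|p_c - mean_c| <= k * sd_c`` on
    every channel ``c``. ``sd`` follows the sample convention (ddof=1) over
    the pooled training pixels.
    """

    class_label: str
    mean: tuple[float, float, float]
    sd: tuple[float, float, float]
    k: float = DEFAULT_K
    n_pixels: int = 0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"SD multiplier k must be positive, got {self.k}")
        if any(s < 0 for s in self.sd):
            raise ValueError(f"standard deviations must be non-negative, got {self.sd}")

    def matches(self, pixels: np.ndarray) -> np.ndarray:
        """Boolean match mask for an (..., 3) float or integer pixel array."""
        pixels = np.asarray(pixels, dtype=np.float64)
        mean = np.asarray(self.mean)
        half = self.k * np.asarray(self.sd)
        return np.all(np.abs(pixels - mean) <= half, axis=-1)

    def normalized_sq_distance(self, pixels: np.ndarray) -> np.ndarray:
        """Squared SD-normalized Euclidean distance to the class mean.

        Zero-SD channels contribute ``(p - mean)**2`` unscaled; for pixels
        that match the class those channels are exactly zero anyway.
        """
        pixels = np.asarray(pixels, dtype=np.float64)
        mean = np.asarray(self.mean)
        sd = np.asarray(self.sd)
        safe = np.where(sd > 0, sd, 1.0)
        z = (pixels - mean) / safe
        return np.sum(z * z, axis=-1)

    def to_dict(self) -> dict:
        return {
            "class_label": self.class_label,
            "mean": list(self.mean),
            "sd": list(self.sd),
            "k": self.k,
            "n_pixels": self.n_pixels,
        }


@dataclass
class LabelMap:
    """Per-pixel class labels over a segmentation bounding box.

    ``labels`` has shape ``(bbox.h, bbox.w)`` with values in
    ``{UNCOLORED, YELLOW, BLUE}``. ``n_both`` counts pixels that satisfied
    both class boxes before tie-breaking; ``n_ties`` counts the subset at
    exactly equal normalized distance (assigned to yellow).
    """

    labels: np.ndarray
    bbox: Region
    n_both: int = 0
    n_ties: int = 0

    def __post_init__(self) -> None:
        if self.labels.shape != (self.bbox.h, self.bbox.w):
            raise ValueError(
                f"label array shape {self.labels.shape} does not match bbox {self.bbox}"
            )

    @property
    def n_yellow(self) -> int:
        return int(np.count_nonzero(self.labels == YELLOW))

    @property
    def n_blue(self) -> int:
        return int(np.count_nonzero(self.labels == BLUE))

    @property
    def n_uncolored(self) -> int:
        return int(np.count_nonzero(self.labels == UNCOLORED))


@dataclass
class SegmentationResult:
    """Pixel counts and damage percentage for one segmented slice."""

    n_yellow: int
    n_blue: int
    n_uncolored: int
    damage_pct: float
    bbox: Region
    yellow_model: ColorClassModel | None = None
    blue_model: ColorClassModel | None = None
    n_both: int = 0
    n_ties: int = 0

    @property
    def damage_pct_rounded(self) -> int:
        """Damage percentage rounded to the nearest integer (study-table convention)."""
        return int(round(self.damage_pct))

    @property
    def n_colored(self) -> int:
        return self.n_yellow + self.n_blue

    def to_dict(self) -> dict:
        return {
            "n_yellow": self.n_yellow,
            "n_blue": self.n_blue,
            "n_uncolored": self.n_uncolored,
            "n_both": self.n_both,
            "n_ties": self.n_ties,
            "damage_pct": self.damage_pct,
            "damage_pct_rounded": self.damage_pct_rounded,
            "bbox": self.bbox.to_dict(),
            "yellow_model": self.yellow_model.to_dict() if self.yellow_model else None,
            "blue_model": self.blue_model.to_dict() if self.blue_model else None,
        }


def fit_color_class(
    image: np.ndarray,
    regions: list[Region],
    class_label: str,
    k: float = DEFAULT_K,
) -> ColorClassModel:
    """Estimate a stain-class color model from training regions.

    Pools the pixels of all ``regions`` and computes the per-channel mean and
    sample standard deviation (ddof=1). The result is invariant to the order
    of the regions and to how the same pixel multiset is partitioned into
    regions.
    """
    image = _as_rgb8(image)
    if not regions:
        raise ValueError(f"no training regions supplied for class {class_label!r}")
    for r in regions:
        if not r.inside_image(image):
            raise ValueError(f"training region {r} lies outside the {image.shape[1]}x{image.shape[0]} image")
    pooled = np.concatenate(
        [image[r.slices()].reshape(-1, 3).astype(np.float64) for r in regions]
    )
    # lexicographic sort makes the float reductions independent of region
    # order and of how the pixel multiset was partitioned into regions
    pooled = pooled[np.lexsort(pooled.T[::-1])]
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0, ddof=1) if pooled.shape[0] > 1 else np.zeros(3)
    return ColorClassModel(
        class_label=class_label,
        mean=tuple(mean),
        sd=tuple(sd),
        k=k,
        n_pixels=pooled.shape[0],
    )


def classify_pixels(
    image: np.ndarray,
    bbox: Region,
    yellow: ColorClassModel,
    blue: ColorClassModel,
) -> LabelMap:
    """Label every pixel in ``bbox`` as yellow, blue or uncolored.

    A pixel matches a class iff each channel lies within mean ± k·SD of that
    class. Pixels matching exactly one class get that label; pixels matching
    both get the class with the smaller SD-normalized Euclidean distance to
    the class mean (ties to yellow, logged); pixels matching neither are
    uncolored.
    """
    image = _as_rgb8(image)
    if not bbox.inside_image(image):
        raise ValueError(f"bounding box {bbox} lies outside the image")
    if yellow.k != blue.k:
        raise ValueError(
            f"class models were fitted with different k ({yellow.k} vs {blue.k})"
        )
    window = image[bbox.slices()].astype(np.float64)
    in_yellow = yellow.matches(window)
    in_blue = blue.matches(window)

    labels = np.full(window.shape[:2], UNCOLORED, dtype=np.uint8)
    labels[in_yellow & ~in_blue] = YELLOW
    labels[in_blue & ~in_yellow] = BLUE

    both = in_yellow & in_blue
    n_both = int(np.count_nonzero(both))
    n_ties = 0
    if n_both:
        dy = yellow.normalized_sq_distance(window[both])
        db = blue.normalized_sq_distance(window[both])
        # ties go to yellow
        assign = np.where(dy <= db, YELLOW, BLUE).astype(np.uint8)
        n_ties = int(np.count_nonzero(dy == db))
        labels[both] = assign
        if n_ties:
            logger.warning(
                "%d pixel(s) equidistant from both class means; assigned to yellow",
                n_ties,
            )
        logger.info(
            "%d of %d bbox pixels (%.2f%%) matched both classes",
            n_both,
            labels.size,
            100.0 * n_both / labels.size,
        )
    return LabelMap(labels=labels, bbox=bbox, n_both=n_both, n_ties=n_ties)


def damage_percentage(
    labels: LabelMap,
    yellow: ColorClassModel | None = None,
    blue: ColorClassModel | None = None,
) -> SegmentationResult:
    """Damage percentage alpha = 100 * n_yellow / (n_yellow + n_blue).

    Uncolored pixels are reported for quality control but excluded from the
    denominator. Raises if no pixel was colored (the ratio is undefined).
    """
    n_yellow, n_blue, n_unc = labels.n_yellow, labels.n_blue, labels.n_uncolored
    if n_yellow + n_blue == 0:
        raise ValueError(
            "no pixel in the bounding box matched either stain class; "
            "the damage percentage is undefined"
        )
    pct = 100.0 * n_yellow / (n_yellow + n_blue)
    return SegmentationResult(
        n_yellow=n_yellow,
        n_blue=n_blue,
        n_uncolored=n_unc,
        damage_pct=pct,
        bbox=labels.bbox,
        yellow_model=yellow,
        blue_model=blue,
        n_both=labels.n_both,
        n_ties=labels.n_ties,
    )


@dataclass
class SegmentationConfig:
    """Training regions, bounding box and SD multiplier for one slice."""

    yellow_regions: list[Region]
    blue_regions: list[Region]
    bbox: Region
    k: float = DEFAULT_K

    def to_dict(self) -> dict:
        return {
            "yellow_regions": [r.to_dict() for r in self.yellow_regions],
            "blue_regions": [r.to_dict() for r in self.blue_regions],
            "bbox": self.bbox.to_dict(),
            "k": self.k,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentationConfig":
        return cls(
            yellow_regions=[Region.from_dict(r) for r in d["yellow_regions"]],
            blue_regions=[Region.from_dict(r) for r in d["blue_regions"]],
            bbox=Region.from_dict(d["bbox"]),
            k=float(d.get("k", DEFAULT_K)),
        )


def segment_slice(image: np.ndarray, config: SegmentationConfig) -> SegmentationResult:
    """Run the full pipeline: fit both color models, classify, count.

    Convenience wrapper around :class:`StainSegmentation`.
    """
    return StainSegmentation.from_config(image, config).fit().result


class StainSegmentation:
    """Two-class stain color model for one cross-section photograph.

    Parameters
    ----------
    image
        8-bit RGB array, shape ``(h, w, 3)``.
    yellow_regions, blue_regions
        Training rectangles sampled inside the damaged (yellow) and intact
        (blue) stain.
    bbox
        Bounding box over which pixels are classified and counted.
    k
        SD multiplier defining each class's acceptance box (default 1.7).
    """

    def __init__(
        self,
        image: np.ndarray,
        yellow_regions: list[Region],
        blue_regions: list[Region],
        bbox: Region,
        k: float = DEFAULT_K,
    ) -> None:
        self.image = _as_rgb8(image)
        self.yellow_regions = list(yellow_regions)
        self.blue_regions = list(blue_regions)
        self.bbox = bbox
        self.k = k

    @classmethod
    def from_config(cls, image: np.ndarray, config: SegmentationConfig) -> "StainSegmentation":
        return cls(image, config.yellow_regions, config.blue_regions, config.bbox, config.k)

    def fit(self) -> "StainSegmentationResults":
        """Estimate both color models, classify the bbox and count pixels."""
        try:
            yellow = fit_color_class(self.image, self.yellow_regions, "yellow", self.k)
            blue = fit_color_class(self.image, self.blue_regions, "blue", self.k)
        except ValueError as e:
            raise ValueError(f"color model fitting failed: {e}") from e
        try:
            labels = classify_pixels(self.image, self.bbox, yellow, blue)
        except ValueError as e:
            raise ValueError(f"pixel classification failed: {e}") from e
        try:
            result = damage_percentage(labels, yellow, blue)
        except ValueError as e:
            raise ValueError(f"damage percentage failed: {e}") from e
        logger.info(
            "segmented bbox %s: yellow=%d blue=%d uncolored=%d both=%d damage=%.2f%%",
            self.bbox,
            result.n_yellow,
            result.n_blue,
            result.n_uncolored,
            result.n_both,
            result.damage_pct,
        )
        return StainSegmentationResults(self, labels, result)


class StainSegmentationResults:
    """Fitted color models, label map and damage percentage for one slice."""

    def __init__(
        self,
        model: StainSegmentation,
        labels: LabelMap,
        result: SegmentationResult,
    ) -> None:
        self.model = model
        self.labels = labels
        self.result = result

    @property
    def damage_pct(self) -> float:
        return self.result.damage_pct

    @property
    def yellow_model(self) -> ColorClassModel:
        return self.result.yellow_model

    @property
    def blue_model(self) -> ColorClassModel:
        return self.result.blue_model

    def summary(self) -> str:
        r = self.result
        ym, bm = r.yellow_model, r.blue_model
        lines = [
            "Stain segmentation results",
            "==========================",
            f"bounding box        : x={r.bbox.x} y={r.bbox.y} w={r.bbox.w} h={r.bbox.h}",
            f"SD multiplier k     : {ym.k:g}",
            f"yellow model        : mean=({ym.mean[0]:.1f}, {ym.mean[1]:.1f}, {ym.mean[2]:.1f})"
            f" sd=({ym.sd[0]:.2f}, {ym.sd[1]:.2f}, {ym.sd[2]:.2f}) n={ym.n_pixels}",
            f"blue model          : mean=({bm.mean[0]:.1f}, {bm.mean[1]:.1f}, {bm.mean[2]:.1f})"
            f" sd=({bm.sd[0]:.2f}, {bm.sd[1]:.2f}, {bm.sd[2]:.2f}) n={bm.n_pixels}",
            f"yellow pixels       : {r.n_yellow}",
            f"blue pixels         : {r.n_blue}",
            f"uncolored pixels    : {r.n_uncolored}",
            f"both-class pixels   : {r.n_both} (ties: {r.n_ties})",
            f"damage percentage   : {r.damage_pct:.2f}% (rounded: {r.damage_pct_rounded}%)",
        ]
        return "\n".join(lines)

    def label_image(self) -> np.ndarray:
        """RGB visualization of the label map (yellow/blue/gray)."""
        palette = np.array(
            [[128, 128, 128], [255, 220, 0], [0, 70, 255]], dtype=np.uint8
        )
        return palette[self.labels.labels]

    def plot(self, ax=None):
        """Show the original bbox window next to the segmented labels."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, axes = plt.subplots(1, 2, figsize=(8, 4))
        else:
            axes = ax
        window = self.model.image[self.result.bbox.slices()]
        axes[0].imshow(window)
        axes[0].set_title("stained slice (bbox)")
        axes[1].imshow(self.label_image())
        axes[1].set_title(f"segmentation ({self.result.damage_pct:.1f}% damaged)")
        for a in axes:
            a.set_axis_off()
        return axes
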