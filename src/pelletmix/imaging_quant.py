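"""Image-based quantification of germling aggregation.

Mirrors the microscopy workflow for dual-reporter co-cultures: the green and
red fluorescence channels are merged into an 8-bit greyscale picture used
only to *detect* regions containing fluorescent particles; mean green and
red intensities are then measured per region on the original channels, and
each region is classified by its green:red ratio — above 1.2 it is a purely
green particle, below 0.15 purely red, and anything between (a particle
containing hyphae of both reporter strains) counts as aggregated.  Replicate
class lists are summarized into an aggregated fraction (mean ± sd across
replicates, at least 500 particles per replicate expected).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label

from ._errors import EmptyInputError, ParameterError, ShapeMismatchError

__all__ = [
    "FluorClass",
    "RegionMeasure",
    "AggregationSummary",
    "merge_channels",
    "segment_particles",
    "measure_regions",
    "classify_region",
    "summarize_aggregation",
    "quantify_image_pair",
]

RATIO_HI = 1.2
RATIO_LO = 0.15
MIN_AREA = 20
MIN_PARTICLES_PER_REPLICATE = 500


class FluorClass(enum.Enum):
    """Exhaustive, mutually exclusive color classes of a detected region."""

    GREEN = "green"
    RED = "red"
    AGGREGATED = "aggregated"


@dataclass
class RegionMeasure:
    """Per-region measurement: area and mean intensity in each raw channel."""

    region_id: int
    area: int
    mean_green: float
    mean_red: float


@dataclass
class AggregationSummary:
    """Replicate-level aggregation statistics.

    ``fraction_mean`` / ``fraction_sd`` are the across-replicate mean and
    sample standard deviation of the aggregated fraction (sd is None with a
    single replicate).
    """

    counts: list[dict[str, int]]
    fractions: list[float]
    fraction_mean: float
    fraction_sd: float | None
    total_particles: int


def merge_channels(green: np.ndarray, red: np.ndarray) -> np.ndarray:
    """Average the two channels and rescale to an 8-bit greyscale image.

    The merge exists only for detection; intensity measurements are done on
    the original channels.
    """
    green = np.asarray(green, dtype=float)
    red = np.asarray(red, dtype=float)
    if green.shape != red.shape:
        raise ShapeMismatchError(f"channel shapes differ: {green.shape} vs {red.shape}")
    merged = (green + red) / 2.0
    peak = merged.max()
    if peak > 0:
        merged = merged * (255.0 / peak)
    return np.round(merged).astype(np.uint8)


def segment_particles(grey: np.ndarray, min_area: int = MIN_AREA) -> np.ndarray:
    """Label connected foreground regions of an 8-bit greyscale image.

    Foreground is everything above the Otsu threshold; connected components
    smaller than ``min_area`` pixels are discarded as speckle.  Returns a
    label map (0 = background, 1..k = regions); a blank image yields zero
    regions rather than an error.
    """
    grey = np.asarray(grey)
    if grey.ndim != 2:
        raise ParameterError("segment_particles expects a single-channel 2-D image")
    if min_area < 1:
        raise ParameterError("min_area: must be >= 1")
    if np.ptp(grey) == 0:
        return np.zeros(grey.shape, dtype=np.int32)
    thr = threshold_otsu(grey)
    labels = sk_label(grey > thr)
    if labels.max() == 0:
        return labels.astype(np.int32)
    areas = np.bincount(labels.ravel())
    keep = np.flatnonzero(areas >= min_area)
    keep = keep[keep != 0]
    remap = np.zeros(areas.size, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1)
    return remap[labels]


def measure_regions(
    labels: np.ndarray, green: np.ndarray, red: np.ndarray
) -> list[RegionMeasure]:
    """Mean green/red intensity per labeled region, measured on the raw
    (un-merged) channels."""
    labels = np.asarray(labels)
    green = np.asarray(green, dtype=float)
    red = np.asarray(red, dtype=float)
    if not (labels.shape == green.shape == red.shape):
        raise ShapeMismatchError("label map and channel images must share dimensions")
    n = int(labels.max())
    if n == 0:
        return []
    flat = labels.ravel()
    areas = np.bincount(flat, minlength=n + 1)
    sums_g = np.bincount(flat, weights=green.ravel(), minlength=n + 1)
    sums_r = np.bincount(flat, weights=red.ravel(), minlength=n + 1)
    return [
        RegionMeasure(
            region_id=k,
            area=int(areas[k]),
            mean_green=float(sums_g[k] / areas[k]),
            mean_red=float(sums_r[k] / areas[k]),
        )
        for k in range(1, n + 1)
    ]


def classify_region(
    mean_green: float,
    mean_red: float,
    hi: float = RATIO_HI,
    lo: float = RATIO_LO,
) -> FluorClass:
    """Classify a region by its green:red ratio.

    Strictly above ``hi`` is GREEN, strictly below ``lo`` is RED; everything
    between, boundaries included, is AGGREGATED.  A region with zero red and
    positive green has ratio +inf (GREEN); both-zero regions cannot arise
    from above-threshold detection and raise an error.
    """
    if mean_green < 0 or mean_red < 0:
        raise ParameterError("mean intensities must be non-negative")
    if not lo < hi:
        raise ParameterError("lo: must be below hi")
    if mean_red == 0:
        if mean_green == 0:
            raise ParameterError(
                "region with zero intensity in both channels; inconsistent segmentation"
            )
        return FluorClass.GREEN
    ratio = mean_green / mean_red
    if ratio > hi:
        return FluorClass.GREEN
    if ratio < lo:
        return FluorClass.RED
    return FluorClass.AGGREGATED


def summarize_aggregation(
    replicates: Sequence[Sequence[FluorClass]],
    min_particles: int = MIN_PARTICLES_PER_REPLICATE,
) -> AggregationSummary:
    """Aggregated-fraction statistics across replicate class lists."""
    if not replicates:
        raise EmptyInputError("no replicates given")
    counts = []
    fractions = []
    for i, rep in enumerate(replicates):
        rep = list(rep)
        if not rep:
            raise EmptyInputError(f"replicate {i} contains no particles")
        if len(rep) < min_particles:
            warnings.warn(
                f"replicate {i} has only {len(rep)} particles (< {min_particles})",
                stacklevel=2,
            )
        c = {cls.value: sum(1 for x in rep if x is cls) for cls in FluorClass}
        counts.append(c)
        fractions.append(c["aggregated"] / len(rep))
    sd = float(np.std(fractions, ddof=1)) if len(fractions) >= 2 else None
    return AggregationSummary(
        counts=counts,
        fractions=[float(f) for f in fractions],
        fraction_mean=float(np.mean(fractions)),
        fraction_sd=sd,
        total_particles=sum(sum(c.values()) for c in counts),
    )


def quantify_image_pair(
    green: np.ndarray,
    red: np.ndarray,
    hi: float = RATIO_HI,
    lo: float = RATIO_LO,
    min_area: int = MIN_AREA,
) -> tuple[pd.DataFrame, list[FluorClass]]:
    """Detect, measure and classify every particle in one channel pair.

    Returns a region table (region_id, area, mean_green, mean_red, ratio,
    cls) and the class list for summarization.
    """
    merged = merge_channels(green, red)
    labels = segment_particles(merged, min_area=min_area)
    measures = measure_regions(labels, green, red)
    classes = [classify_region(m.mean_green, m.mean_red, hi=hi, lo=lo) for m in measures]
    table = pd.DataFrame(
        {
            "region_id": [m.region_id for m in measures],
            "area": [m.area for m in measures],
            "mean_green": [m.mean_green for m in measures],
            "mean_red": [m.mean_red for m in measures],
            "ratio": [
                np.inf if m.mean_red == 0 else m.mean_green / m.mean_red for m in measures
            ],
            "cls": [c.value for c in classes],
        }
    )
    return table, classes
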