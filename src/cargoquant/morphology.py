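"""Lysosome shape analysis: segmentation and eccentricity distributions.

Opposing motor teams pulling on one organelle (a tug-of-war) deform it; the
deformation is quantified per frame as the *eccentricity* of each segmented
object's equivalent ellipse of second central moments,
``e = sqrt(1 - (b/a)^2)`` with semi-axes ``a >= b``. 0 is a perfect circle
and values approaching 1 are highly elongated objects. Because deformations
are dynamic, eccentricities are pooled over consecutive frames without
tracking object identity: a persistent object contributes one measurement
per frame. Pooled distributions from two conditions are compared with the
two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage import filters, measure, morphology as skmorph, segmentation

from .errors import InputError
from .stats import TestResult, hypothesis_test

__all__ = [
    "OrganelleDetection",
    "SegmentationParams",
    "EccentricityDistribution",
    "KSComparison",
    "segment_frame",
    "filter_by_area",
    "pool_eccentricities",
    "compare_distributions",
]

#: default area gate in squared pixels (objects outside are discarded)
DEFAULT_MIN_AREA = 8.0
DEFAULT_MAX_AREA = 200.0

#: fixed histogram bin edges, width 0.05 over [0, 1]
ECC_BIN_EDGES = np.round(np.arange(0.0, 1.0001, 0.05), 10)


@dataclass
class OrganelleDetection:
    """One labeled object in one frame."""

    frame_index: int
    label: int
    centroid: tuple[float, float]  # (row, col), px
    area: float  # px^2
    eccentricity: float  # in [0, 1]


@dataclass
class SegmentationParams:
    """Background reduction and thresholding choices.

    Median filtering (disk footprint of ``median_radius`` px; 0 disables)
    followed by Otsu thresholding; 8-connectivity labeling. Border-touching
    objects are kept unless ``exclude_border`` is set.
    """

    median_radius: int = 2
    exclude_border: bool = False


def segment_frame(
    image: np.ndarray,
    params: SegmentationParams | None = None,
    frame_index: int = 0,
) -> list[OrganelleDetection]:
    """Segment one intensity frame into labeled objects.

    Returns an empty list when thresholding leaves no foreground (e.g. an
    all-zero or constant frame).
    """
    if params is None:
        params = SegmentationParams()
    image = np.asarray(image)
    if image.ndim != 2:
        raise InputError(f"expected a single-channel 2-D frame, got shape {image.shape}")

    work = image
    if params.median_radius > 0:
        work = filters.median(image, footprint=skmorph.disk(params.median_radius))
    flat = work.ravel()
    if flat.min() == flat.max():
        return []
    threshold = filters.threshold_otsu(work)
    binary = work > threshold
    if params.exclude_border:
        binary = segmentation.clear_border(binary)
    labels = measure.label(binary, connectivity=2)
    detections = []
    for region in measure.regionprops(labels):
        detections.append(
            OrganelleDetection(
                frame_index=frame_index,
                label=int(region.label),
                centroid=(float(region.centroid[0]), float(region.centroid[1])),
                area=float(region.area),
                eccentricity=float(region.eccentricity),
            )
        )
    return detections


def filter_by_area(
    detections: Sequence[OrganelleDetection],
    min_area: float = DEFAULT_MIN_AREA,
    max_area: float = DEFAULT_MAX_AREA,
) -> list[OrganelleDetection]:
    """Keep detections with ``min_area <= area <= max_area`` (order preserved)."""
    if not min_area < max_area:
        raise InputError("min_area must be smaller than max_area")
    return [d for d in detections if min_area <= d.area <= max_area]


@dataclass
class EccentricityDistribution:
    """Pooled per-frame, per-object eccentricities for one condition."""

    condition: str
    values: np.ndarray
    n_cells: int
    n_frames_per_cell: int
    bin_edges: np.ndarray
    histogram: np.ndarray  # counts, sum == len(values)

    @classmethod
    def from_values(
        cls,
        values: Sequence[float],
        condition: str = "",
        n_cells: int = 0,
        n_frames_per_cell: int = 0,
    ) -> "EccentricityDistribution":
        values = np.asarray(values, dtype=float)
        if values.size and (values.min() < 0 or values.max() > 1):
            raise InputError("eccentricities must lie in [0, 1]")
        counts, _ = np.histogram(values, bins=ECC_BIN_EDGES)
        return cls(
            condition=condition,
            values=values,
            n_cells=n_cells,
            n_frames_per_cell=n_frames_per_cell,
            bin_edges=ECC_BIN_EDGES.copy(),
            histogram=counts,
        )


def pool_eccentricities(
    stacks: Mapping[str, np.ndarray],
    n_frames: int = 100,
    params: SegmentationParams | None = None,
    min_area: float = DEFAULT_MIN_AREA,
    max_area: float = DEFAULT_MAX_AREA,
    condition: str = "",
) -> EccentricityDistribution:
    """Segment the first ``n_frames`` of each per-cell stack and pool.

    No per-object deduplication is performed: an object visible in every
    frame contributes one eccentricity per frame. The area gate (default
    8-200 px^2) is applied per detection before pooling.
    """
    values: list[float] = []
    for cell_id, stack in stacks.items():
        stack = np.asarray(stack)
        if stack.ndim != 3:
            raise InputError(f"stack for cell {cell_id!r} must be 3-D (frames, rows, cols)")
        if stack.shape[0] < n_frames:
            raise InputError(
                f"cell {cell_id!r} has {stack.shape[0]} frames, {n_frames} requested"
            )
        for frame_index in range(n_frames):
            detections = segment_frame(stack[frame_index], params, frame_index=frame_index)
            for d in filter_by_area(detections, min_area, max_area):
                values.append(d.eccentricity)
    return EccentricityDistribution.from_values(
        values,
        condition=condition,
        n_cells=len(stacks),
        n_frames_per_cell=n_frames,
    )


@dataclass
class KSComparison:
    statistic: float
    p_value: float
    result: TestResult
    histogram_table: pd.DataFrame


def compare_distributions(
    a: EccentricityDistribution, b: EccentricityDistribution
) -> KSComparison:
    """Two-sample KS test plus a side-by-side normalized histogram table."""
    if a.values.size == 0 or b.values.size == 0:
        raise InputError("cannot compare an empty eccentricity distribution")
    result = hypothesis_test("ks", a.values, b.values)
    table = pd.DataFrame(
        {
            "bin_left": a.bin_edges[:-1],
            "bin_right": a.bin_edges[1:],
            f"freq_{a.condition or 'a'}": a.histogram / a.values.size,
            f"freq_{b.condition or 'b'}": b.histogram / b.values.size,
        }
    )
    return KSComparison(
        statistic=result.statistic,
        p_value=result.p_value,
        result=result,
        histogram_table=table,
    )


def detections_to_frame(detections: Sequence[OrganelleDetection]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "frame_index": [d.frame_index for d in detections],
            "label": [d.label for d in detections],
            "centroid_row": [d.centroid[0] for d in detections],
            "centroid_col": [d.centroid[1] for d in detections],
            "area_px2": [d.area for d in detections],
            "eccentricity": [d.eccentricity for d in detections],
        }
    )
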