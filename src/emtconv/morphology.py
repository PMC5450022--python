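"""Cell detection, shape features and morphology-rule classification.

Cells are detected as connected components of a label (or binary) image.
Each cell yields the features the live-cell tracing software measures:
the geometric gravity center (unweighted centroid), perimeter-to-area
ratio, ellipse-equivalent length-to-width ratio, skeleton-endpoint
neurite count and, when a nucleus channel is present, the
nucleus-to-cytosol area ratio.

Classification applies three ordered rules (first match wins):

* neuron-like — length-to-width ratio over 5 and at least two neurite
  outgrowths around the cell body;
* shrunken — small size, nearly spherical shape (length-to-width < 1.5)
  and a high nucleus-to-cytosol ratio (over 1:5);
* MEF-like — large size and a low nucleus-to-cytosol ratio (below 1:10);

anything else is *unclassified*.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from math import sqrt
from typing import Iterable, Optional, Sequence

import numpy as np
from skimage import measure
from skimage.morphology import skeletonize

NEURON_LIKE = "neuron-like"
SHRUNKEN = "shrunken"
MEF_LIKE = "MEF-like"
UNCLASSIFIED = "unclassified"

CLASSES = (NEURON_LIKE, SHRUNKEN, MEF_LIKE, UNCLASSIFIED)


@dataclass(frozen=True)
class ClassThresholds:
    """Thresholds for the morphology rules.

    ``area_small`` / ``area_large`` quantify the "small cell size" /
    "large size" wording; they default to values calibrated once against
    the synthetic archetype area distributions (shrunken cells sit well
    below 300 px², MEF-like cells well above 700 px²) because no
    physical pixel scale is defined.
    """

    lw_neuron: float = 5.0
    min_neurites: int = 2
    lw_shrunken: float = 1.5
    nc_shrunken: float = 0.2   # 1:5
    nc_mef: float = 0.1        # 1:10
    area_small: float = 300.0
    area_large: float = 700.0
    min_neurite_len: float = 5.0

    def __post_init__(self) -> None:
        if not self.lw_neuron > self.lw_shrunken >= 1:
            raise ValueError("require lw_neuron > lw_shrunken >= 1")
        if not 0 < self.nc_mef < self.nc_shrunken:
            raise ValueError("require 0 < nc_mef < nc_shrunken")
        if not self.area_small < self.area_large:
            raise ValueError("require area_small < area_large")


@dataclass
class CellObservation:
    """One detected cell in one frame.

    ``frame`` is in hours since hour 0 (frames are 60 min apart, so the
    frame index doubles as the hour). Coordinates are 0-based (row, col)
    pixels, origin top-left.
    """

    frame: int
    label: int
    centroid: tuple[float, float]
    area: float
    perimeter: float
    length: float
    width: float
    neurite_count: int
    nucleus_area: Optional[float] = None
    assigned_class: Optional[str] = None

    @property
    def perimeter_to_area(self) -> float:
        return self.perimeter / self.area

    @property
    def length_to_width(self) -> float:
        return self.length / self.width

    @property
    def nucleus_to_cytosol(self) -> Optional[float]:
        if self.nucleus_area is None:
            return None
        cytosol = self.area - self.nucleus_area
        if cytosol <= 0:
            return float("inf")
        return self.nucleus_area / cytosol

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("area must be positive")
        if self.width <= 0:
            raise ValueError("width must be positive")


@dataclass
class ShapeFeatures:
    area: float
    perimeter: float
    centroid: tuple[float, float]
    length: float
    width: float
    neurite_count: int
    nucleus_area: Optional[float] = None

    @property
    def length_to_width(self) -> float:
        return self.length / self.width

    @property
    def nucleus_to_cytosol(self) -> Optional[float]:
        if self.nucleus_area is None:
            return None
        cytosol = self.area - self.nucleus_area
        return self.nucleus_area / cytosol if cytosol > 0 else float("inf")


def _axis_lengths(coords: np.ndarray) -> tuple[float, float]:
    """Ellipse-equivalent axis lengths: 4·sqrt(eigenvalues) of the pixel
    coordinate covariance (population covariance, no continuity
    correction). Each axis is floored at 1 px — a single pixel has unit
    extent by convention."""
    if len(coords) == 1:
        return 1.0, 1.0
    cov = np.cov(coords.T, ddof=0)
    eigvals = np.linalg.eigvalsh(np.atleast_2d(cov))
    eigvals = np.clip(eigvals, 0.0, None)
    minor, major = 4.0 * np.sqrt(eigvals[0]), 4.0 * np.sqrt(eigvals[-1])
    return max(float(major), 1.0), max(float(minor), 1.0)


_NEIGHBORS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def count_neurites(mask: np.ndarray, min_len: float = 5.0) -> int:
    """Count neurite outgrowths as skeleton endpoints beyond the soma.

    The soma is the largest inscribed disc (centered at the maximum of
    the Euclidean distance transform). The mask is skeletonized; an
    endpoint (skeleton pixel with at most one skeleton neighbour) counts
    as a neurite tip when its geodesic distance along the skeleton from
    the soma disc exceeds ``min_len`` pixels (diagonal steps cost √2).
    """
    from scipy import ndimage

    mask = np.asarray(mask, dtype=bool)
    if mask.sum() <= 1:
        return 0
    skel = skeletonize(mask)
    pts = set(zip(*np.nonzero(skel)))
    if not pts:
        return 0

    edt = ndimage.distance_transform_edt(mask)
    center = np.unravel_index(np.argmax(edt), edt.shape)
    radius = float(edt[center])

    def in_soma(p: tuple[int, int]) -> bool:
        return (p[0] - center[0]) ** 2 + (p[1] - center[1]) ** 2 <= radius**2

    sources = [p for p in pts if in_soma(p)]
    if not sources:
        # skeleton misses the soma disc (very thin shapes): seed from the
        # skeleton pixel closest to the soma center
        sources = [min(pts, key=lambda p: (p[0] - center[0]) ** 2 + (p[1] - center[1]) ** 2)]

    dist = {p: 0.0 for p in sources}
    queue = deque(sources)
    while queue:
        p = queue.popleft()
        for dr, dc in _NEIGHBORS8:
            q = (p[0] + dr, p[1] + dc)
            if q in pts:
                d = dist[p] + (sqrt(2.0) if dr and dc else 1.0)
                if q not in dist or d < dist[q]:
                    dist[q] = d
                    queue.append(q)

    n = 0
    for p in pts:
        deg = sum((p[0] + dr, p[1] + dc) in pts for dr, dc in _NEIGHBORS8)
        if deg <= 1 and dist.get(p, 0.0) > min_len:
            n += 1
    return n


def shape_features(
    mask: np.ndarray,
    nucleus_mask: Optional[np.ndarray] = None,
    min_neurite_len: float = 5.0,
) -> ShapeFeatures:
    """Measure one connected component.

    Perimeter uses the weighted line-segment estimator of
    :func:`skimage.measure.perimeter` (4-connectivity border
    transitions). Length/width are ellipse-equivalent axes from the
    pixel-covariance eigendecomposition; a degenerate 1-pixel mask gets
    length = width = 1 and zero neurites.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    coords = np.argwhere(mask)
    if coords.size == 0:
        raise ValueError("empty mask")
    area = float(len(coords))
    centroid = (float(coords[:, 0].mean()), float(coords[:, 1].mean()))
    length, width = _axis_lengths(coords.astype(float))
    perimeter = float(measure.perimeter(mask)) if area > 1 else 4.0
    neurites = count_neurites(mask, min_len=min_neurite_len)
    nucleus_area = None
    if nucleus_mask is not None:
        nucleus_area = float(np.count_nonzero(np.asarray(nucleus_mask, dtype=bool) & mask))
    return ShapeFeatures(area, perimeter, centroid, length, width, neurites, nucleus_area)


def detect_cells(
    frame_image: np.ndarray,
    nucleus_image: Optional[np.ndarray] = None,
    *,
    frame: int = 0,
    min_area: int = 5,
    min_neurite_len: float = 5.0,
) -> list[CellObservation]:
    """Detect cells in one frame and measure them.

    ``frame_image`` is a 2-D integer label image (one label per cell) or
    a binary image, in which case connected components are labeled
    internally with 8-connectivity. ``nucleus_image`` when given marks
    nucleus pixels (labels or binary); nucleus area is counted inside
    each cell's mask. Observations are returned sorted by label.
    """
    img = np.asarray(frame_image)
    if img.ndim != 2:
        raise ValueError(f"frame image must be 2-D, got shape {img.shape}")
    if img.dtype == bool or img.max(initial=0) <= 1:
        labels = measure.label(img > 0, connectivity=2)
    else:
        labels = img.astype(np.int64)

    nuc = np.asarray(nucleus_image) if nucleus_image is not None else None
    out: list[CellObservation] = []
    for rp in measure.regionprops(labels):
        if rp.area < min_area:
            continue
        mask = rp.image
        nmask = None
        if nuc is not None:
            nmask = nuc[rp.slice] > 0
        f = shape_features(mask, nmask, min_neurite_len=min_neurite_len)
        r0, c0 = rp.bbox[0], rp.bbox[1]
        out.append(
            CellObservation(
                frame=frame,
                label=int(rp.label),
                centroid=(f.centroid[0] + r0, f.centroid[1] + c0),
                area=f.area,
                perimeter=f.perimeter,
                length=f.length,
                width=f.width,
                neurite_count=f.neurite_count,
                nucleus_area=f.nucleus_area,
            )
        )
    out.sort(key=lambda o: o.label)
    return out


def classify_cell(obs: CellObservation, t: ClassThresholds = ClassThresholds()) -> str:
    """Assign one of the four classes, first match wins.

    Rules needing the nucleus-to-cytosol ratio (shrunken, MEF-like)
    cannot fire when no nucleus was measured.
    """
    nc = obs.nucleus_to_cytosol
    if obs.length_to_width > t.lw_neuron and obs.neurite_count >= t.min_neurites:
        return NEURON_LIKE
    if (
        nc is not None
        and obs.length_to_width < t.lw_shrunken
        and obs.area < t.area_small
        and nc > t.nc_shrunken
    ):
        return SHRUNKEN
    if nc is not None and obs.area > t.area_large and nc < t.nc_mef:
        return MEF_LIKE
    return UNCLASSIFIED


def classify_frame(
    observations: Iterable[CellObservation], t: ClassThresholds = ClassThresholds()
) -> list[CellObservation]:
    """Classify every observation (in place) and return the list."""
    obs = list(observations)
    for o in obs:
        o.assigned_class = classify_cell(o, t)
    return obs


@dataclass(frozen=True)
class OverlapResult:
    jaccard: float          # 100·|∩|/|∪|
    recall: float           # 100·|∩|/|truth| (secondary, vs-marker recall)
    n_predicted: int
    n_truth: int
    vacuous: bool = False   # both sets empty → agreement by convention


def marker_overlap(predicted: Iterable[int], truth_positive: Iterable[int]) -> OverlapResult:
    """Overlap between morphology-called cells and marker-positive truth.

    Overlap is Jaccard (intersection over union) in percent; recall
    against the marker set is reported alongside. Two empty sets agree
    vacuously (100%, flagged).
    """
    p, t = set(predicted), set(truth_positive)
    if not p and not t:
        return OverlapResult(100.0, 100.0, 0, 0, vacuous=True)
    inter = len(p & t)
    jac = 100.0 * inter / len(p | t)
    rec = 100.0 * inter / len(t) if t else 0.0
    return OverlapResult(jac, rec, len(p), len(t))
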