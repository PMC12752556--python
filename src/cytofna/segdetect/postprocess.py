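"""HSV debris rejection and mask-to-detection post-processing.

The segmentation mask is first cleaned by a component-wise HSV colour filter
(red-blood-cell debris sits in a narrow saturated red hue band well separated
from haematoxylin-stained nuclei), then connected components are turned into
nucleus/cluster detections: oversized components are split by a
distance-transform watershed, and each object is scored with its mean
foreground probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2hsv
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label, regionprops
from skimage.segmentation import watershed

log = logging.getLogger(__name__)

__all__ = ["HsvRange", "SplitParams", "Detection", "default_hsv_ranges",
           "hsv_debris_filter", "detections_from_mask"]


@dataclass(frozen=True)
class HsvRange:
    """Per-channel [low, high) bounds in [0,1]; ``mode`` 'reject' or 'keep'.

    The high bound is exclusive except when it equals 1.0 (so fully saturated
    channels are still matchable).
    """
    hue: tuple = (0.0, 1.0)
    saturation: tuple = (0.0, 1.0)
    value: tuple = (0.0, 1.0)
    mode: str = "reject"

    def __post_init__(self):
        for lo, hi in (self.hue, self.saturation, self.value):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("require 0 <= low <= high <= 1 per channel")
        if self.mode not in ("reject", "keep"):
            raise ValueError("mode must be 'reject' or 'keep'")

    def contains(self, hsv_median: np.ndarray) -> bool:
        for x, (lo, hi) in zip(hsv_median,
                               (self.hue, self.saturation, self.value)):
            inside = (x >= lo) and (x < hi or (hi >= 1.0 and x <= hi))
            if not inside:
                return False
        return True


def default_hsv_ranges() -> list[HsvRange]:
    """Reject saturated red components (RBC debris) on either side of hue 0."""
    return [
        HsvRange(hue=(0.0, 0.05), saturation=(0.5, 1.0), mode="reject"),
        HsvRange(hue=(0.95, 1.0), saturation=(0.5, 1.0), mode="reject"),
    ]


def hsv_debris_filter(image: np.ndarray, mask: np.ndarray,
                      ranges: list[HsvRange] | None) -> np.ndarray:
    """Remove whole connected components whose median HSV matches a reject
    range (or matches no keep range, when keep ranges are supplied).

    Removal is component-wise, never pixel-wise, so nuclei are never
    fragmented. With no ranges the mask is returned unchanged.
    """
    if image.shape[:2] != mask.shape:
        raise ValueError("mask must align with image")
    if not ranges:
        log.warning("hsv_debris_filter called with no ranges: identity")
        return mask.copy()
    hsv = rgb2hsv(image)
    lab = cc_label(mask > 0, connectivity=2)
    out = mask.copy().astype(bool)
    rejects = [r for r in ranges if r.mode == "reject"]
    keeps = [r for r in ranges if r.mode == "keep"]
    for region in regionprops(lab):
        coords = region.coords
        med = np.median(hsv[coords[:, 0], coords[:, 1]], axis=0)
        drop = any(r.contains(med) for r in rejects)
        if keeps and not any(r.contains(med) for r in keeps):
            drop = True
        if drop:
            out[coords[:, 0], coords[:, 1]] = False
    return out


@dataclass(frozen=True)
class SplitParams:
    """Watershed splitting controls (pixel units at 256-px tiles)."""
    max_single_area: float = 4000.0   # larger components get watershed-split
    min_peak_distance: int = 7
    min_area: float = 30.0            # smaller objects are discarded


@dataclass
class Detection:
    bbox: tuple                 # (x0, y0, x1, y1), 0-based half-open
    instance_mask: np.ndarray   # bool raster cropped to bbox
    kind: str                   # 'nucleus' | 'cluster'
    score: float                # mean foreground probability in [0,1]
    n_seeds: int = 1

    def __post_init__(self):
        if not self.instance_mask.any():
            raise ValueError("detection mask must have foreground")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must be in [0,1]")

    @property
    def area(self) -> int:
        return int(self.instance_mask.sum())


def _component_seeds(comp_mask: np.ndarray, min_peak_distance: int):
    dist = ndi.distance_transform_edt(comp_mask)
    peaks = peak_local_max(dist, min_distance=min_peak_distance,
                           labels=comp_mask.astype(int), exclude_border=False)
    return dist, peaks


def detections_from_mask(mask: np.ndarray, probability_raster: np.ndarray,
                         split_params: SplitParams | None = None,
                         cluster_area_threshold: float = 1200.0):
    """Connected components -> list of scored nucleus/cluster detections.

    Components above ``max_single_area`` are split by a distance-transform
    watershed seeded at distance maxima at least ``min_peak_distance`` apart.
    An object is a cluster when its area exceeds ``cluster_area_threshold`` or
    it contains >= 2 watershed seeds. Objects below ``min_area`` are dropped.
    """
    sp = split_params or SplitParams()
    mask = mask.astype(bool)
    if not mask.any():
        return []
    lab = cc_label(mask, connectivity=2)
    detections = []
    for region in regionprops(lab):
        comp = lab == region.label
        if np.isfinite(sp.max_single_area) and region.area > sp.max_single_area:
            dist, peaks = _component_seeds(comp, sp.min_peak_distance)
            if len(peaks) >= 2:
                markers = np.zeros_like(lab)
                for i, (r, c) in enumerate(peaks, start=1):
                    markers[r, c] = i
                ws = watershed(-dist, markers=markers, mask=comp)
                pieces = [(ws == i, 1) for i in range(1, len(peaks) + 1)]
            else:
                pieces = [(comp, max(1, len(peaks)))]
        else:
            _, peaks = _component_seeds(comp, sp.min_peak_distance)
            pieces = [(comp, max(1, len(peaks)))]
        for piece, nseeds in pieces:
            area = int(piece.sum())
            if area < sp.min_area or area == 0:
                continue
            ys, xs = np.nonzero(piece)
            y0, y1 = int(ys.min()), int(ys.max()) + 1
            x0, x1 = int(xs.min()), int(xs.max()) + 1
            kind = ("cluster" if area > cluster_area_threshold or nseeds >= 2
                    else "nucleus")
            score = float(np.clip(probability_raster[piece].mean(), 0.0, 1.0))
            detections.append(Detection(bbox=(x0, y0, x1, y1),
                                        instance_mask=piece[y0:y1, x0:x1],
                                        kind=kind, score=score,
                                        n_seeds=int(nseeds)))
    return detections
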