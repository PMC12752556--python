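"""Readers/writers for on-disk artifacts: slide manifests, detections
(GeoJSON/CSV), run configuration with hashing.

Coordinate conventions: 0-based, row-major rasters, origin top-left,
half-open boxes [x0,x1) x [y0,y1). GeoJSON polygons are written
counter-clockwise in image coordinates.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from .segdetect import Detection

__all__ = ["SlideManifest", "read_manifest", "write_detections",
           "read_detections", "RunConfig", "config_hash", "ParseError"]

MAGNIFICATIONS = ("20x", "40x")
STAINS = ("pap", "he")


class ParseError(ValueError):
    pass


@dataclass
class SlideManifest:
    slide_id: str
    tiles: list            # ordered tile paths (absolute)
    magnification: str = "20x"
    stain: str = "pap"
    true_tbs: str | None = None
    braf: int | None = None


def read_manifest(path) -> SlideManifest:
    path = Path(path)
    d = json.loads(path.read_text())
    tiles = [path.parent / t for t in d["tiles"]]
    for t in tiles:
        if not t.exists():
            raise ParseError(f"tile not found: {t}")
    if d.get("magnification", "20x") not in MAGNIFICATIONS:
        raise ParseError(f"unknown magnification {d['magnification']}")
    if d.get("stain", "pap") not in STAINS:
        raise ParseError(f"unknown stain {d['stain']}")
    return SlideManifest(slide_id=d["slide_id"], tiles=tiles,
                         magnification=d.get("magnification", "20x"),
                         stain=d.get("stain", "pap"),
                         true_tbs=d.get("true_tbs"), braf=d.get("braf"))


# ---------------------------------------------------------------------------
# detections

def _mask_polygon(det: Detection):
    """Counter-clockwise outline of the detection mask in image coords."""
    from skimage.measure import find_contours
    x0, y0, _, _ = det.bbox
    padded = np.pad(det.instance_mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    c = max(contours, key=len)            # (row, col) pairs
    xs = c[:, 1] - 1 + x0
    ys = c[:, 0] - 1 + y0
    area2 = np.sum(xs[:-1] * ys[1:] - xs[1:] * ys[:-1])
    if area2 < 0:                         # enforce CCW (shoelace, y down)
        xs, ys = xs[::-1], ys[::-1]
    return [[float(x), float(y)] for x, y in zip(xs, ys)]


def write_detections(path, detections):
    path = Path(path)
    if path.suffix == ".geojson":
        feats = []
        for det in detections:
            feats.append({
                "type": "Feature",
                "geometry": {"type": "Polygon",
                             "coordinates": [_mask_polygon(det)]},
                "properties": {"bbox": list(det.bbox), "kind": det.kind,
                               "score": round(float(det.score), 6),
                               "n_seeds": int(det.n_seeds)},
            })
        path.write_text(json.dumps(
            {"type": "FeatureCollection", "features": feats}, indent=1))
    elif path.suffix == ".csv":
        rows = [dict(x0=d.bbox[0], y0=d.bbox[1], x1=d.bbox[2], y1=d.bbox[3],
                     kind=d.kind, score=round(float(d.score), 6))
                for d in detections]
        pd.DataFrame(rows, columns=["x0", "y0", "x1", "y1", "kind",
                                    "score"]).to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported extension {path.suffix}")
    return path


def _rasterize(coords, bbox):
    from skimage.draw import polygon
    x0, y0, x1, y1 = bbox
    arr = np.zeros((y1 - y0, x1 - x0), dtype=bool)
    xs = np.array([p[0] for p in coords]) - x0
    ys = np.array([p[1] for p in coords]) - y0
    rr, cc = polygon(ys, xs, shape=arr.shape)
    arr[rr, cc] = True
    if not arr.any():                     # degenerate 1-px outline
        arr[np.clip(ys.astype(int), 0, arr.shape[0] - 1),
            np.clip(xs.astype(int), 0, arr.shape[1] - 1)] = True
    return arr


def read_detections(path):
    """Read detections; boxes/kinds exact, scores to 6 decimals.

    GeoJSON masks are re-rasterized from the stored polygon; CSV carries
    boxes only, so masks are filled rectangles.
    """
    path = Path(path)
    dets = []
    if path.suffix == ".geojson":
        try:
            d = json.loads(path.read_text())
        except json.JSONDecodeError as e:
            raise ParseError(f"malformed GeoJSON: {e}") from e
        for i, f in enumerate(d.get("features", [])):
            try:
                bbox = tuple(int(v) for v in f["properties"]["bbox"])
                if bbox[2] <= bbox[0] or bbox[3] <= bbox[1]:
                    raise ValueError("empty box")
                mask = _rasterize(f["geometry"]["coordinates"][0], bbox)
                dets.append(Detection(
                    bbox=bbox, instance_mask=mask,
                    kind=f["properties"]["kind"],
                    score=float(f["properties"]["score"]),
                    n_seeds=int(f["properties"].get("n_seeds", 1))))
            except (KeyError, ValueError, TypeError) as e:
                raise ParseError(f"invalid feature index {i}: {e}") from e
    elif path.suffix == ".csv":
        df = pd.read_csv(path)
        for i, row in df.iterrows():
            bbox = (int(row.x0), int(row.y0), int(row.x1), int(row.y1))
            if bbox[2] <= bbox[0] or bbox[3] <= bbox[1]:
                raise ParseError(f"invalid box at row {i}: {bbox}")
            mask = np.ones((bbox[3] - bbox[1], bbox[2] - bbox[0]), dtype=bool)
            dets.append(Detection(bbox=bbox, instance_mask=mask,
                                  kind=str(row.kind), score=float(row.score)))
    else:
        raise ValueError(f"unsupported extension {path.suffix}")
    return dets


# ---------------------------------------------------------------------------
# run configuration

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SegStageConfig(_Strict):
    threshold: float = 0.5
    init_seed: int = 0


class DetectStageConfig(_Strict):
    max_single_area: float = 4000.0
    min_peak_distance: int = 7
    min_area: float = 30.0
    cluster_area_threshold: float = 1200.0


class CellStageConfig(_Strict):
    crop_size: int = 72            # context crop; net center-crops further


class DiagnoseStageConfig(_Strict):
    avg_a: float = 10.0
    avg_b: float = 5.0
    glob_cell: float = 60.0


class IamStageConfig(_Strict):
    enabled: bool = False
    reference_profile: str | None = None
    feather_radius: float = 3.0


class RunConfig(_Strict):
    """Full resolved pipeline configuration; unknown keys are rejected."""
    seed: int = 0
    log_level: str = "INFO"
    seg: SegStageConfig = SegStageConfig()
    detect: DetectStageConfig = DetectStageConfig()
    cell: CellStageConfig = CellStageConfig()
    diagnose: DiagnoseStageConfig = DiagnoseStageConfig()
    iam: IamStageConfig = IamStageConfig()


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
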