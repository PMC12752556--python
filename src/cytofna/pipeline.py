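"""End-to-end slide pipeline: (optional IAM) -> segment -> HSV filter ->
detect -> morphometry -> classify -> agreement gate -> aggregate ->
adequacy rule -> slide classifier -> optional gene cascade.

Also hosts the desk-scale training fixtures (segmentation net, cell net,
morphology GBT trained on the synthetic generator) shared by the CLI and
the validation suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import iam as iam_mod
from .cellclass import (CellCall, CellNet, CellTrainConfig, TINY_CELL,
                        agreement_gate, build_cell_net, classify_patches,
                        train_cell_net)
from .diagnose import (DecisionRuleParams, GeneClassifier, WsiClassifier,
                       predict_tbs)
from .io import RunConfig, SlideManifest, config_hash
from .schema import DEFAULT_SCHEMA, REJECTED
from .segdetect import (Detection, SegTrainConfig, SplitParams, TINY_SEG,
                        build_seg_net, default_hsv_ranges, hsv_debris_filter,
                        detections_from_mask, nuclear_morphometry,
                        segment_patch, train_seg_net)
from .segdetect.gbt import classify_morpho, train_morpho_gbt
from .synthcyto import SynthConfig, render_cell_crop, render_patch
from .wsifeat import aggregate_slide_features, registry_default

log = logging.getLogger(__name__)

__all__ = ["PipelineModels", "extract_crop", "process_tile", "slide_features",
           "run_pipeline", "train_fixture_models", "cohort_features",
           "PIPELINE_CLASSES", "tile128_config"]

#: classes the desk-scale fixture models are trained on (distinct rendering
#: styles; the remaining schema classes stay valid outputs but untrained)
PIPELINE_CLASSES = ("C1", "C4", "C5", "C6", "C9", "C10")


def tile128_config(**overrides) -> RunConfig:
    """RunConfig with detection parameters rescaled for 128-px tiles.

    The library defaults are stated at 256-px tile scale; at 128 px single
    nuclei are ~80-600 px^2, so components above 700 px^2 are merged
    neighbours and are watershed-split with a 5-px peak separation.
    """
    cfg = {"detect": {"max_single_area": 700.0, "min_peak_distance": 5,
                      "min_area": 30.0, "cluster_area_threshold": 700.0}}
    cfg.update(overrides)
    return RunConfig(**cfg)


@dataclass
class PipelineModels:
    seg: object
    cell: CellNet
    morpho: object
    wsi: WsiClassifier | None = None
    gene: GeneClassifier | None = None


def extract_crop(image: np.ndarray, det: Detection, size: int) -> np.ndarray:
    """Square context crop centred on the detection, edge-padded at borders."""
    x0, y0, x1, y1 = det.bbox
    cx, cy = (x0 + x1) // 2, (y0 + y1) // 2
    h, w = image.shape[:2]
    half = size // 2
    ys = slice(max(0, cy - half), min(h, cy - half + size))
    xs = slice(max(0, cx - half), min(w, cx - half + size))
    crop = image[ys, xs]
    py0 = max(0, half - cy)
    px0 = max(0, half - cx)
    if crop.shape[:2] != (size, size):
        crop = np.pad(crop, ((py0, size - py0 - crop.shape[0]),
                             (px0, size - px0 - crop.shape[1]), (0, 0)),
                      mode="edge")
    return crop


def process_tile(image: np.ndarray, models: PipelineModels,
                 config: RunConfig | None = None):
    """One tile through segmentation, filtering, detection, morphometry,
    classification and the agreement gate.

    Returns ``(detections, gated calls, morpho vectors)`` with morpho None
    for cluster-kind detections.
    """
    config = config or RunConfig()
    mask, prob = segment_patch(image, models.seg, config.seg.threshold)
    mask = hsv_debris_filter(image, mask, default_hsv_ranges())
    sp = SplitParams(max_single_area=config.detect.max_single_area,
                     min_peak_distance=config.detect.min_peak_distance,
                     min_area=config.detect.min_area)
    dets = detections_from_mask(mask, prob, sp,
                                config.detect.cluster_area_threshold)
    if not dets:
        return [], [], []
    morphos = []
    crops = []
    for det in dets:
        morphos.append(nuclear_morphometry(image, det))
        crops.append(extract_crop(image, det, config.cell.crop_size))
    net_out = classify_patches(np.stack(crops), models.cell)
    calls = []
    for i, (det, (probs, net_class)) in enumerate(zip(dets, net_out)):
        morpho_class, _ = classify_morpho(morphos[i], models.morpho)
        calls.append(CellCall(detection_id=i, prob_vector=probs,
                              net_class=net_class, morpho_class=morpho_class))
    calls = agreement_gate(calls, DEFAULT_SCHEMA)
    morphos = [m if d.kind == "nucleus" else None
               for m, d in zip(morphos, dets)]
    return dets, calls, morphos


def slide_features(tiles, models: PipelineModels,
                   config: RunConfig | None = None):
    """Aggregate pipeline outputs of all tiles into the 104-feature vector.

    Returns ``(features, audit)`` where audit conserves objects per stage:
    detections == accepted + rejected.
    """
    config = config or RunConfig()
    all_dets, all_calls, all_morphos = [], [], []
    offset = 0
    for tile in tiles:
        dets, calls, morphos = process_tile(tile, models, config)
        for c in calls:
            c.detection_id += offset
        all_dets.extend(dets)
        all_calls.extend(calls)
        all_morphos.extend(morphos)
        offset += len(dets)
    rule = DecisionRuleParams(avg_a=config.diagnose.avg_a,
                              avg_b=config.diagnose.avg_b,
                              glob_cell=config.diagnose.glob_cell)
    feats = aggregate_slide_features(all_calls, all_dets, all_morphos,
                                     registry_default(), rule)
    n_rej = sum(1 for c in all_calls if c.final_class == REJECTED)
    audit = {"tiles": len(tiles), "detections": len(all_dets),
             "accepted": len(all_dets) - n_rej, "rejected": n_rej}
    return feats, audit


def run_pipeline(manifest, models: PipelineModels,
                 config: RunConfig | None = None,
                 reference_profile=None) -> dict:
    """Full per-slide report. ``manifest`` is a SlideManifest (tiles read
    from disk) or a list of in-memory RGB tiles with an id."""
    config = config or RunConfig()
    if isinstance(manifest, SlideManifest):
        import imageio.v3 as iio
        tiles = [np.asarray(iio.imread(p)) for p in manifest.tiles]
        slide_id = manifest.slide_id
    else:
        slide_id, tiles = manifest
    if config.iam.enabled and reference_profile is not None:
        tiles, src_profile = iam_mod.migrate_slide(
            tiles, reference_profile, seed=config.seed,
            feather_radius=config.iam.feather_radius)
        log.info("stage=iam slide=%s migrated=%d", slide_id, len(tiles))
    feats, audit = slide_features(tiles, models, config)
    rule = DecisionRuleParams(avg_a=config.diagnose.avg_a,
                              avg_b=config.diagnose.avg_b,
                              glob_cell=config.diagnose.glob_cell)
    result = predict_tbs(feats, models.wsi, rule_params=rule,
                         gene_model=models.gene)
    log.info("stage=diagnose slide=%s final=%s counts=%s",
             slide_id, result.final, audit)
    return {
        "slide_id": slide_id,
        "config_hash": config_hash(config),
        "stage1": result.stage1,
        "wsi_pred": result.wsi_pred,
        "probs": result.probs,
        "gene_pred": result.gene_pred,
        "final": result.final,
        "adeq_lhs": result.adeq_lhs,
        "audit": audit,
    }


# ---------------------------------------------------------------------------
# desk-scale training fixtures

def harvest_training_crops(classes, per_class: int, crop_size: int = 72,
                           seed: int = 0, patch_size: int = 128,
                           clean_fraction: float = 0.5):
    """Labelled crops for classifier training.

    Half (``clean_fraction``) are clean single-cell renders; the rest are
    harvested from dense rendered patches around ground-truth centroids, so
    the training distribution includes neighbouring cells and off-centre
    context exactly as the detector produces at inference time.
    """
    rng = np.random.default_rng(seed)
    crops, labels = [], []
    n_clean = int(per_class * clean_fraction)
    for ci, cls in enumerate(classes):
        for s in range(n_clean):
            img, _ = render_cell_crop(cls, size=crop_size, stain="pap",
                                      seed=int(seed) * 100003 + ci * 1009 + s)
            crops.append(img)
            labels.append(cls)
    quota = {c: per_class - n_clean for c in classes}
    guard = 0
    while any(v > 0 for v in quota.values()) and guard < 4000:
        guard += 1
        focus = max(quota, key=quota.get)
        mix = np.zeros(17)
        mix[int(focus[1:]) - 1] = 0.6
        others = [c for c in classes if c != focus]
        for c in others:
            mix[int(c[1:]) - 1] = 0.4 / len(others)
        cfg = SynthConfig(patch_size=patch_size, nuclei_per_patch=(5, 9),
                          class_mix=tuple(mix), cluster_rate=0.05)
        p = render_patch(cfg, int(rng.integers(0, 2 ** 31 - 1)))
        for _, row in p.class_table.iterrows():
            cls = row["class"]
            if quota.get(cls, 0) <= 0:
                continue
            det = Detection(bbox=(int(row.cx), int(row.cy),
                                  int(row.cx) + 1, int(row.cy) + 1),
                            instance_mask=np.ones((1, 1), bool),
                            kind="nucleus", score=1.0)
            crops.append(extract_crop(p.image, det, crop_size))
            labels.append(cls)
            quota[cls] -= 1
    return np.asarray(crops), labels


def train_fixture_models(seed: int = 0, n_seg_patches: int = 50,
                         seg_epochs: int = 30, crops_per_class: int = 80,
                         cell_epochs: int = 40,
                         morpho_per_class: int = 60) -> PipelineModels:
    """Train the segmentation net, cell net and morphology GBT on the
    synthetic generator. Deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    # segmentation: mixed-style patches at the tiny input size
    seg_cfg = SynthConfig(patch_size=TINY_SEG.input_size,
                          nuclei_per_patch=(6, 14),
                          class_mix=tuple(_train_mix()), cluster_rate=0.1)
    patches = [render_patch(seg_cfg, int(s))
               for s in rng.integers(0, 2 ** 31 - 1, n_seg_patches)]
    seg = build_seg_net(TINY_SEG, init_seed=seed)
    seg, _ = train_seg_net(seg, patches,
                           SegTrainConfig(epochs=seg_epochs, seed=seed))
    # cell classifier: clean single-cell renders + crops harvested from
    # dense patches (matches the detector's inference-time crop statistics)
    crops, labels = harvest_training_crops(PIPELINE_CLASSES, crops_per_class,
                                           seed=seed)
    cell = build_cell_net(TINY_CELL, init_seed=seed)
    cell, _ = train_cell_net(cell, crops, labels,
                             CellTrainConfig(lr=2e-3, epochs=cell_epochs,
                                             seed=seed))
    # morphology GBT on ground-truth instances, labelled by role
    feats, roles = [], []
    for ci, cls in enumerate(PIPELINE_CLASSES):
        for s in range(morpho_per_class):
            img, m = render_cell_crop(cls, size=72, stain="pap",
                                      seed=int(seed) * 77003 + ci * 2003 + s)
            ys, xs = np.nonzero(m)
            bbox = (int(xs.min()), int(ys.min()),
                    int(xs.max()) + 1, int(ys.max()) + 1)
            det = Detection(bbox=bbox,
                            instance_mask=m[bbox[1]:bbox[3], bbox[0]:bbox[2]],
                            kind="nucleus", score=1.0)
            feats.append(nuclear_morphometry(img, det))
            roles.append(DEFAULT_SCHEMA.role(cls))
    morpho, _ = train_morpho_gbt(feats, roles, seed=seed)
    return PipelineModels(seg=seg, cell=cell, morpho=morpho)


def _train_mix():
    """Class mix covering the pipeline classes for segmentation training."""
    mix = np.zeros(17)
    for cls, p in (("C1", 0.15), ("C4", 0.1), ("C5", 0.1),
                   ("C6", 0.35), ("C9", 0.05), ("C10", 0.25)):
        mix[int(cls[1:]) - 1] = p
    return mix


def cohort_features(slides, models: PipelineModels,
                    config: RunConfig | None = None):
    """Pipeline features for a list of SynthSlide; returns
    ``(DataFrame, tbs labels, braf labels)``."""
    rows, labels, braf = [], [], []
    for s in slides:
        feats, _ = slide_features([t.image for t in s.tiles], models, config)
        rows.append(feats)
        labels.append(s.true_tbs)
        braf.append(s.braf)
    return pd.DataFrame(rows).reset_index(drop=True), labels, braf
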