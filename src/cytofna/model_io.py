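"""Model persistence.

Neural networks are stored as a single ``.npz`` archive whose ``__header__``
entry is a JSON string (config + format version); parameters and batch-norm
running statistics are flat arrays keyed by module index. Gradient-boosted
models use the XGBoost JSON format plus a sidecar metadata header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .cellclass import CellNet, CellNetConfig, build_cell_net
from .segdetect import SegNet, SegNetConfig, build_seg_net
from .segdetect.gbt import MorphoGbt
from .nn import BatchNorm2d

__all__ = ["save_seg_net", "load_seg_net", "save_cell_net", "load_cell_net",
           "save_gbt", "load_gbt"]

_FORMAT = 1


def _collect(model):
    arrays, meta = {}, []
    for i, mod in enumerate(model.modules()):
        for k, v in getattr(mod, "params", {}).items():
            arrays[f"m{i}.{k}"] = v
        if isinstance(mod, BatchNorm2d):
            arrays[f"m{i}.running_mean"] = mod.running_mean
            arrays[f"m{i}.running_var"] = mod.running_var
        meta.append(type(mod).__name__)
    return arrays, meta


def _restore(model, data):
    for i, mod in enumerate(model.modules()):
        for k in getattr(mod, "params", {}):
            mod.params[k][...] = data[f"m{i}.{k}"]
        if isinstance(mod, BatchNorm2d):
            mod.running_mean = data[f"m{i}.running_mean"]
            mod.running_var = data[f"m{i}.running_var"]


def _save_net(model, config_dict, kind, path):
    arrays, meta = _collect(model)
    header = json.dumps({"format": _FORMAT, "kind": kind,
                         "config": config_dict, "modules": meta})
    np.savez(path, __header__=np.array(header), **arrays)


def save_seg_net(model: SegNet, path):
    cfg = model.config
    _save_net(model, {"depth": cfg.depth, "base_width": cfg.base_width,
                      "pyramid_fusion": cfg.pyramid_fusion,
                      "input_size": cfg.input_size}, "seg", path)


def load_seg_net(path) -> SegNet:
    data = np.load(path, allow_pickle=False)
    header = json.loads(str(data["__header__"]))
    if header["kind"] != "seg":
        raise ValueError(f"not a segmentation model archive: {path}")
    model = build_seg_net(SegNetConfig(**header["config"]))
    _restore(model, data)
    model.eval()
    return model


def save_cell_net(model: CellNet, path):
    cfg = model.config
    _save_net(model, {"stage_depths": list(cfg.stage_depths),
                      "stage_widths": list(cfg.stage_widths),
                      "lka_kernel": cfg.lka_kernel,
                      "lka_dilated_kernel": cfg.lka_dilated_kernel,
                      "lka_dilation": cfg.lka_dilation,
                      "input_size": cfg.input_size,
                      "num_classes": cfg.num_classes}, "cell", path)


def load_cell_net(path) -> CellNet:
    data = np.load(path, allow_pickle=False)
    header = json.loads(str(data["__header__"]))
    if header["kind"] != "cell":
        raise ValueError(f"not a cell-classifier archive: {path}")
    c = header["config"]
    c["stage_depths"] = tuple(c["stage_depths"])
    c["stage_widths"] = tuple(c["stage_widths"])
    model = build_cell_net(CellNetConfig(**c))
    _restore(model, data)
    model.eval()
    return model


def save_gbt(model, path):
    """MorphoGbt / WsiClassifier / GeneClassifier -> XGBoost JSON + header."""
    path = Path(path)
    model.booster.save_model(path)
    meta = {"type": type(model).__name__}
    for attr in ("classes", "registry_version", "best_params",
                 "fold_accuracies", "cv_accuracy"):
        if hasattr(model, attr):
            meta[attr] = getattr(model, attr)
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))


def load_gbt(path):
    from xgboost import XGBClassifier
    from .diagnose import GeneClassifier, WsiClassifier
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    booster = XGBClassifier()
    booster.load_model(path)
    t = meta["type"]
    if t == "MorphoGbt":
        return MorphoGbt(booster, meta["classes"])
    if t == "WsiClassifier":
        return WsiClassifier(booster=booster, classes=meta["classes"],
                             registry_version=meta["registry_version"],
                             best_params=meta.get("best_params", {}),
                             fold_accuracies=meta.get("fold_accuracies", []),
                             cv_accuracy=meta.get("cv_accuracy", float("nan")))
    if t == "GeneClassifier":
        return GeneClassifier(booster=booster,
                              registry_version=meta["registry_version"])
    raise ValueError(f"unknown model type {t}")
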