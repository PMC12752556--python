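"""Cytology-specific image appearance migration (IAM).

Cross-site stain and scanner variability is quantified per *domain* as the
per-channel mean/std of cell-foreground pixels in a perceptual colour space
(CIELAB: luminance + two chroma channels), then compensated by an affine
statistics-matching map applied to foreground pixels only. Cytology smears
are dispersed cells on bare glass, so — unlike tissue sections — a dedicated
foreground mask is required: glass background must not enter the statistics
or the mapping, or the migration distorts the stain.

The source profile is always estimated at slide level (one profile from all
tiles) and applied tile-by-tile, which prevents tile-to-tile flicker. The
mapping function is pluggable; the default is the Reinhard-style per-channel
affine match. Stored 1st/99th percentiles support alternative clipping maps
but are unused by the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.color import lab2rgb, rgb2hsv, rgb2lab
from skimage.filters import gaussian
from skimage.measure import label as cc_label
from skimage.morphology import disk

__all__ = ["MaskParams", "AppearanceProfile", "extract_cell_mask",
           "estimate_profile", "migrate_image", "migrate_slide",
           "HE_MASK_PRESET"]


class DataError(ValueError):
    pass


@dataclass(frozen=True)
class MaskParams:
    """Foreground extraction controls.

    The glass background is estimated adaptively as the tile-median
    luminance and saturation (cells are assumed to be the minority of
    pixels), which keeps the mask stable under global stain/scanner tints.
    ``saturation_threshold``: how far above the glass saturation estimate a
    pixel must be; ``luminance_margin``: how far below the glass luminance;
    ``min_object_size`` px; ``closing_radius`` px of the morphological
    closing.
    """
    saturation_threshold: float = 0.12
    luminance_margin: float = 0.12
    min_object_size: int = 20
    closing_radius: int = 2

    def __post_init__(self):
        if not 0.0 < self.saturation_threshold < 1.0:
            raise ValueError("saturation_threshold must be in (0,1)")


#: H&E smears carry fainter eosin background; adaptation is a preset, not a
#: separate algorithm.
HE_MASK_PRESET = MaskParams(saturation_threshold=0.16, luminance_margin=0.10)


@dataclass
class AppearanceProfile:
    color_space: str            # 'lab'
    mean: np.ndarray            # (3,)
    std: np.ndarray             # (3,)
    p1: np.ndarray              # (3,) 1st percentiles
    p99: np.ndarray             # (3,) 99th percentiles
    n_pixels: int
    source: str = ""

    def to_json(self):
        return {"color_space": self.color_space,
                "mean": self.mean.tolist(), "std": self.std.tolist(),
                "p1": self.p1.tolist(), "p99": self.p99.tolist(),
                "n_pixels": int(self.n_pixels), "source": self.source}

    @classmethod
    def from_json(cls, d):
        return cls(color_space=d["color_space"],
                   mean=np.asarray(d["mean"], float),
                   std=np.asarray(d["std"], float),
                   p1=np.asarray(d["p1"], float),
                   p99=np.asarray(d["p99"], float),
                   n_pixels=int(d["n_pixels"]), source=d.get("source", ""))


def extract_cell_mask(image: np.ndarray,
                      params: MaskParams | None = None) -> np.ndarray:
    """Cell-foreground mask: saturated OR darker-than-glass pixels,
    morphologically closed, small objects removed. Pure glass yields an
    empty mask (flagged by the caller, not an error)."""
    params = params or MaskParams()
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image")
    x = image.astype(np.float32) / 255.0
    hsv = rgb2hsv(x)
    lum = x.mean(axis=2)
    glass_lum = float(np.median(lum))
    glass_sat = float(np.median(hsv[..., 1]))
    fg = (hsv[..., 1] > glass_sat + params.saturation_threshold) \
        | (lum < glass_lum - params.luminance_margin)
    fg = ndi.binary_closing(fg, structure=disk(params.closing_radius))
    lab = cc_label(fg, connectivity=2)
    sizes = np.bincount(lab.ravel())
    keep = sizes >= params.min_object_size
    keep[0] = False
    return keep[lab]


def estimate_profile(images, masks, max_pixels: int = 200_000,
                     seed: int = 0, source: str = "") -> AppearanceProfile:
    """Pooled foreground colour statistics of a domain.

    Pixels from all images are pooled, then subsampled to ``max_pixels`` with
    a seeded generator. Deterministic given ``seed``.
    """
    chunks = []
    for img, m in zip(images, masks):
        if m.any():
            chunks.append(rgb2lab(img.astype(np.float32) / 255.0)[m])
    if not chunks:
        raise DataError("no foreground to profile")
    px = np.concatenate(chunks, axis=0)
    if len(px) > max_pixels:
        rng = np.random.default_rng(seed)
        px = px[rng.choice(len(px), size=max_pixels, replace=False)]
    return AppearanceProfile(
        color_space="lab",
        mean=px.mean(axis=0).astype(float),
        std=px.std(axis=0).astype(float),
        p1=np.percentile(px, 1, axis=0).astype(float),
        p99=np.percentile(px, 99, axis=0).astype(float),
        n_pixels=len(px), source=source)


def _feather(mask: np.ndarray, radius: float) -> np.ndarray:
    if radius <= 0:
        return mask.astype(np.float32)
    w = gaussian(mask.astype(np.float32), sigma=radius, preserve_range=True)
    # keep full weight inside the mask; feather only the outside fringe
    return np.maximum(w, mask.astype(np.float32)).clip(0.0, 1.0)


def migrate_image(image: np.ndarray, source: AppearanceProfile,
                  reference: AppearanceProfile, mask: np.ndarray,
                  feather_radius: float = 3.0) -> np.ndarray:
    """Map foreground statistics of ``image`` onto the reference profile.

    Per channel c in LAB: ``x -> (x - mu_src_c) * (sigma_ref_c / sigma_src_c)
    + mu_ref_c``; a zero source sigma uses gain 1. Background pixels are
    blended through a feathered mask to avoid halo artifacts.
    """
    if source.color_space != reference.color_space:
        raise ValueError("profiles use different colour spaces")
    lab = rgb2lab(image.astype(np.float32) / 255.0)
    gain = np.where(source.std > 0, reference.std / np.where(source.std == 0, 1, source.std), 1.0)
    mapped = (lab - source.mean) * gain + reference.mean
    w = _feather(mask, feather_radius)[..., None]
    out_lab = w * mapped + (1.0 - w) * lab
    rgb = lab2rgb(out_lab)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def migrate_slide(tiles, reference: AppearanceProfile,
                  mask_params: MaskParams | None = None, seed: int = 0,
                  feather_radius: float = 3.0):
    """Slide-level adaptive migration: ONE source profile from all tiles,
    applied tile-by-tile. Returns ``(migrated tiles, profile or None)``;
    slides with no foreground anywhere are returned unchanged with a None
    profile (warning flag)."""
    if not len(tiles):
        raise ValueError("need at least one tile")
    masks = [extract_cell_mask(t, mask_params) for t in tiles]
    if not any(m.any() for m in masks):
        return [t.copy() for t in tiles], None
    profile = estimate_profile(tiles, masks, seed=seed, source="slide")
    out = [migrate_image(t, profile, reference, m, feather_radius)
           for t, m in zip(tiles, masks)]
    return out, profile
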