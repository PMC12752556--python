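"""Synthetic liquid-based thyroid-FNA smear generator.

Renders Papanicolaou- or H&E-styled RGB patches with known instance masks and
per-instance class labels, groups patches into slides with a deterministic
Bethesda (TBS) ground-truth label, and applies controlled stain/scanner
appearance shifts. Every downstream stage of the pipeline (segmentation,
debris filtering, cell classification, slide aggregation, diagnosis,
appearance migration) is trained and validated against this generator.

Phenotype conventions (schematic, not photorealistic):

* benign follicular cells (C6-C8): small, round, darkly stained nuclei;
* papillary-carcinoma classes (C1-C3): larger, paler nuclei with irregular
  membrane outlines;
* nuclear-groove class (C4): a dark linear fold across the nucleus;
* pseudo-inclusion class (C5): a sharp bright intranuclear disk;
* red-blood-cell debris: small saturated-red disks that carry **no** mask
  label (they are non-targets and give the HSV filter a true-negative
  population); faint colloid smears are likewise unlabelled.

All randomness flows through a single ``numpy.random.Generator`` per call, so
identical ``(config, seed)`` pairs produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.ndimage import gaussian_filter

from .schema import (ATYPICAL_CLASSES, CLASS_IDS, EPITHELIAL_CLASSES)

__all__ = [
    "SynthConfig", "SynthPatch", "SynthSlide", "AppearanceShift",
    "render_patch", "render_cell_crop", "render_slide", "perturb_appearance",
    "sample_cohort", "write_patch", "write_slide", "default_class_mix",
]


class ConfigurationError(ValueError):
    """Raised for invalid generator configuration."""


# ---------------------------------------------------------------------------
# configuration

def default_class_mix(atypical_fraction: float = 0.3) -> np.ndarray:
    """Probability vector over C1..C17 with a given atypical fraction among
    epithelial cells.

    Epithelial mass is fixed at 0.8 (atypical share split over C1/C4/C5,
    benign share on C6) plus 0.2 lymphocytes (C10), so the expected realized
    atypical fraction equals ``atypical_fraction``. Papillary-carcinoma
    cells dominate the atypical share; the groove and pseudo-inclusion
    phenotypes are the minority, as on real malignant smears.
    """
    f = float(atypical_fraction)
    if not 0.0 <= f <= 1.0:
        raise ConfigurationError("atypical_fraction must be in [0,1]")
    mix = np.zeros(17)
    mix[[0, 3, 4]] = 0.8 * f * np.array([0.7, 0.15, 0.15])
    mix[5] = 0.8 * (1.0 - f)
    mix[9] = 0.2
    return mix


@dataclass(frozen=True)
class SynthConfig:
    patch_size: int = 256
    nuclei_per_patch: tuple[int, int] = (8, 16)
    class_mix: tuple = tuple(default_class_mix(0.3))
    cluster_rate: float = 0.15
    debris_rate: float = 0.3
    stain_style: str = "pap"
    seed: int = 0
    # slide-level ground-truth rule parameters (config-exposed fixture rule)
    adequacy_weight_a: float = 10.0   # per large epithelial group (PTCA/TFECA)
    adequacy_weight_b: float = 5.0    # per small epithelial group (PTCB/TFECB)
    adequacy_threshold: float = 60.0
    tbs_v_lo: float = 0.1             # atypical fraction (lo, hi] -> TBS V
    tbs_v_hi: float = 0.5             # atypical fraction > hi -> TBS VI
    braf_slope: float = 10.0          # logistic link of BRAF on atypical frac.
    braf_center: float = 0.5

    def __post_init__(self):
        mix = np.asarray(self.class_mix, dtype=float)
        if mix.shape != (17,) or abs(mix.sum() - 1.0) > 1e-9 or (mix < 0).any():
            raise ConfigurationError("class_mix must be 17 non-negative "
                                     "probabilities summing to 1")
        if self.patch_size < 64:
            raise ConfigurationError("patch_size must be >= 64")
        for r in (self.cluster_rate, self.debris_rate):
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError("rates must be in [0,1]")
        if self.stain_style not in ("pap", "he"):
            raise ConfigurationError("stain_style must be 'pap' or 'he'")
        lo, hi = self.nuclei_per_patch
        if lo < 0 or hi < lo:
            raise ConfigurationError("invalid nuclei_per_patch range")


@dataclass
class SynthPatch:
    image: np.ndarray          # uint8 HxWx3
    instance_mask: np.ndarray  # uint16 HxW, 0 = background
    class_table: pd.DataFrame  # instance_id, class, cx, cy, is_cluster, n_members


@dataclass
class SynthSlide:
    tiles: list
    true_counts: pd.Series     # index C1..C17
    true_tbs: str              # 'I', 'II', 'V', 'VI'
    braf: int
    atypical_fraction: float


# ---------------------------------------------------------------------------
# class rendering styles

# (radius_lo, radius_hi, aspect_hi, base RGB (pap), pallor, irregularity)
_STYLES = {
    "C1": (9, 13, 1.6, (118, 100, 158), 0.22, 0.18),   # PTC single: large pale
    "C2": (8, 11, 1.5, (110, 92, 150), 0.20, 0.15),
    "C3": (9, 12, 1.5, (112, 95, 152), 0.20, 0.16),
    "C4": (7, 10, 1.4, (95, 80, 140), 0.12, 0.08),     # groove drawn on top
    "C5": (8, 11, 1.3, (100, 84, 142), 0.12, 0.06),    # bright inclusion disk
    "C6": (5, 7, 1.2, (62, 52, 118), 0.0, 0.03),       # benign: small, dark
    "C7": (5, 7, 1.3, (70, 60, 124), 0.04, 0.04),
    "C8": (6, 8, 1.3, (66, 56, 120), 0.04, 0.04),
    "C9": (12, 16, 1.2, (152, 128, 118), 0.25, 0.10),  # macrophage: big, tan
    "C10": (3, 4, 1.1, (38, 34, 84), 0.0, 0.02),       # lymphocyte: tiny, dark
    "C11": (4, 6, 1.4, (80, 70, 130), 0.05, 0.12),
    "C12": (10, 13, 1.3, (140, 120, 130), 0.18, 0.08),
    "C13": (14, 18, 1.6, (190, 172, 150), 0.35, 0.25),
    "C14": (8, 10, 1.2, (120, 85, 110), 0.10, 0.06),
    "C15": (9, 12, 1.5, (90, 110, 140), 0.15, 0.10),
    "C16": (4, 6, 1.2, (150, 60, 70), 0.05, 0.05),
    "C17": (6, 9, 1.8, (130, 130, 110), 0.20, 0.20),
}

_BG = {"pap": (224, 232, 236), "he": (246, 232, 236)}
_RBC = {"pap": (205, 42, 48), "he": (210, 70, 75)}


def _nucleus_polygon_mask(shape, cx, cy, r0, aspect, angle, irregularity, rng):
    """Boolean mask of one (possibly irregular) rotated ellipse."""
    theta = np.linspace(0.0, 2 * np.pi, 72, endpoint=False)
    mod = np.ones_like(theta)
    if irregularity > 0:
        for k in (2, 3, 5):
            mod += irregularity * rng.uniform(0.2, 1.0) * np.sin(
                k * theta + rng.uniform(0, 2 * np.pi)) / 2.0
    rx = r0 * aspect * mod
    ry = r0 * mod
    x = rx * np.cos(theta)
    y = ry * np.sin(theta)
    ca, sa = np.cos(angle), np.sin(angle)
    xs = cx + ca * x - sa * y
    ys = cy + sa * x + ca * y
    from skimage.draw import polygon
    rr, cc = polygon(ys, xs, shape=shape)
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    return m


def _textured_fill(image, mask, base_rgb, pallor, rng, stain):
    """Paint a nucleus with chromatin-like low-frequency texture."""
    base = np.array(base_rgb, dtype=float)
    if stain == "he":
        base = base * np.array([1.15, 0.85, 0.95])
    base = base * (1.0 + pallor)
    h, w = mask.shape
    noise = gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), 1.5)
    nstd = noise.std() or 1.0
    tex = 1.0 + 0.18 * noise / nstd
    for c in range(3):
        image[..., c][mask] = np.clip(base[c] * tex[mask], 0, 255)


def _draw_instance(image, inst_mask, label, class_id, cfg, rng):
    """Place one labelled object; returns (ok, cx, cy, n_members)."""
    size = cfg.patch_size
    rlo, rhi, ahi, rgb, pallor, irr = _STYLES[class_id]
    is_cluster = label is not None and rng.random() < cfg.cluster_rate
    n_members = int(rng.integers(2, 5)) if is_cluster else 1
    r0 = rng.uniform(rlo, rhi)
    margin = int(np.ceil(r0 * ahi * (2.2 if is_cluster else 1.3))) + 2
    margin = min(margin, size // 2 - 1)
    for _ in range(60):
        cx = rng.uniform(margin, size - margin)
        cy = rng.uniform(margin, size - margin)
        if inst_mask[int(cy), int(cx)] == 0:
            break
    obj = np.zeros_like(inst_mask, dtype=bool)
    for m_i in range(n_members):
        if m_i == 0:
            mx, my = cx, cy
        else:
            ang = rng.uniform(0, 2 * np.pi)
            dist = rng.uniform(0.8, 1.4) * r0
            mx, my = cx + dist * np.cos(ang), cy + dist * np.sin(ang)
        aspect = rng.uniform(1.0, ahi)
        angle = rng.uniform(0, np.pi)
        m = _nucleus_polygon_mask(inst_mask.shape, mx, my,
                                  rng.uniform(rlo, rhi) if m_i else r0,
                                  aspect, angle, irr, rng)
        obj |= m
    obj &= inst_mask == 0   # earlier instances keep their pixels
    if not obj.any():
        return False, 0.0, 0.0, n_members, is_cluster
    _textured_fill(image, obj, rgb, pallor, rng, cfg.stain_style)
    if class_id == "C4":  # nuclear groove: dark fold along the long axis
        _draw_groove(image, obj, rng)
    elif class_id == "C5":  # pseudo-inclusion: bright intranuclear disk
        _draw_inclusion(image, obj, rng, cfg.stain_style)
    inst_mask[obj] = label
    cy_f, cx_f = ndi.center_of_mass(obj)
    return True, float(cx_f), float(cy_f), n_members, is_cluster


def _draw_groove(image, obj, rng):
    ys, xs = np.nonzero(obj)
    cy, cx = ys.mean(), xs.mean()
    ang = rng.uniform(0, np.pi)
    d = np.abs(-np.sin(ang) * (xs - cx) + np.cos(ang) * (ys - cy))
    line = d < 1.2
    for c in range(3):
        ch = image[..., c]
        ch[ys[line], xs[line]] = ch[ys[line], xs[line]] * 0.35


def _draw_inclusion(image, obj, rng, stain):
    ys, xs = np.nonzero(obj)
    cy, cx = ys.mean(), xs.mean()
    rad = max(2.0, 0.35 * np.sqrt(obj.sum() / np.pi))
    d2 = (xs - cx) ** 2 + (ys - cy) ** 2
    disk = d2 < rad ** 2
    bright = np.array(_BG[stain], dtype=float) * 0.92
    for c in range(3):
        image[..., c][ys[disk], xs[disk]] = bright[c]


def _draw_debris(image, inst_mask, cfg, rng):
    """Unlabelled RBC disks and colloid smears."""
    size = cfg.patch_size
    n_rbc = rng.poisson(cfg.debris_rate * 12)
    from skimage.draw import disk as draw_disk
    for _ in range(n_rbc):
        r = rng.uniform(2.0, 4.0)
        cy = rng.uniform(r + 1, size - r - 1)
        cx = rng.uniform(r + 1, size - r - 1)
        rr, cc = draw_disk((cy, cx), r, shape=inst_mask.shape)
        keep = inst_mask[rr, cc] == 0
        rr, cc = rr[keep], cc[keep]
        col = np.array(_RBC[cfg.stain_style], float) * rng.uniform(0.9, 1.05)
        for c in range(3):
            image[rr, cc, c] = np.clip(col[c], 0, 255)
    if rng.random() < cfg.debris_rate:
        # one faint colloid smear, alpha-blended, unlabelled
        m = _nucleus_polygon_mask(inst_mask.shape, rng.uniform(0, size),
                                  rng.uniform(0, size), rng.uniform(20, 40),
                                  rng.uniform(1.0, 2.0), rng.uniform(0, np.pi),
                                  0.3, rng)
        m &= inst_mask == 0
        colloid = np.array((208, 190, 160), float)
        for c in range(3):
            image[..., c][m] = 0.65 * image[..., c][m] + 0.35 * colloid[c]


def render_patch(config: SynthConfig, seed: int | None = None) -> SynthPatch:
    """Render one patch; deterministic given ``(config, seed)``."""
    seed = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    size = config.patch_size
    image = np.empty((size, size, 3), dtype=float)
    bg = _BG[config.stain_style]
    for c in range(3):
        image[..., c] = bg[c]
    image += rng.normal(0.0, 2.5, size=image.shape)
    inst_mask = np.zeros((size, size), dtype=np.uint16)

    _draw_debris(image, inst_mask, config, rng)

    lo, hi = config.nuclei_per_patch
    n = int(rng.integers(lo, hi + 1))
    mix = np.asarray(config.class_mix, dtype=float)
    rows = []
    label = 1
    for _ in range(n):
        class_id = CLASS_IDS[rng.choice(17, p=mix)] if mix.sum() else "C6"
        ok, cx, cy, n_members, is_cluster = _draw_instance(
            image, inst_mask, label, class_id, config, rng)
        if ok:
            rows.append(dict(instance_id=label, **{"class": class_id},
                             cx=cx, cy=cy, is_cluster=bool(is_cluster),
                             n_members=int(n_members if is_cluster else 1)))
            label += 1
    table = pd.DataFrame(rows, columns=["instance_id", "class", "cx", "cy",
                                        "is_cluster", "n_members"])
    img8 = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return SynthPatch(image=img8, instance_mask=inst_mask, class_table=table)


def render_cell_crop(class_id: str, size: int = 64, stain: str = "pap",
                     seed: int = 0):
    """One centred cell of a given class on clean background.

    Returns ``(image uint8, mask bool)``; used to build classifier training
    sets mirroring the ROI crops a detector would produce.
    """
    rng = np.random.default_rng(seed)
    image = np.empty((size, size, 3), dtype=float)
    bg = _BG[stain]
    for c in range(3):
        image[..., c] = bg[c]
    image += rng.normal(0.0, 2.5, size=image.shape)
    rlo, rhi, ahi, rgb, pallor, irr = _STYLES[class_id]
    m = _nucleus_polygon_mask((size, size),
                              size / 2 + rng.uniform(-3, 3),
                              size / 2 + rng.uniform(-3, 3),
                              rng.uniform(rlo, rhi), rng.uniform(1.0, ahi),
                              rng.uniform(0, np.pi), irr, rng)
    _textured_fill(image, m, rgb, pallor, rng, stain)
    if class_id == "C4":
        _draw_groove(image, m, rng)
    elif class_id == "C5":
        _draw_inclusion(image, m, rng, stain)
    return np.clip(np.rint(image), 0, 255).astype(np.uint8), m


# ---------------------------------------------------------------------------
# slides

def true_tbs_from_counts(counts: pd.Series, config: SynthConfig) -> str:
    """Deterministic ground-truth TBS label from per-class object counts.

    TBS I when the weighted epithelial-group count falls below the adequacy
    threshold; otherwise the label follows the atypical-object fraction:
    > ``tbs_v_hi`` -> VI, in (``tbs_v_lo``, ``tbs_v_hi``] -> V, else II.
    """
    lhs = (config.adequacy_weight_a * (counts.get("C1", 0) + counts.get("C6", 0))
           + config.adequacy_weight_b * (counts.get("C2", 0) + counts.get("C7", 0)))
    if lhs < config.adequacy_threshold:
        return "I"
    epithelial = sum(int(counts.get(c, 0)) for c in EPITHELIAL_CLASSES)
    atypical = sum(int(counts.get(c, 0)) for c in ATYPICAL_CLASSES)
    frac = atypical / epithelial if epithelial else 0.0
    if frac > config.tbs_v_hi:
        return "VI"
    if frac > config.tbs_v_lo:
        return "V"
    return "II"


def render_slide(config: SynthConfig, n_tiles: int, seed: int | None = None) -> SynthSlide:
    """Render a multi-tile slide with ground-truth TBS label and BRAF status."""
    if n_tiles < 1:
        raise ConfigurationError("n_tiles must be >= 1")
    seed = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    tile_seeds = rng.integers(0, 2 ** 31 - 1, size=n_tiles)
    tiles = [render_patch(config, int(s)) for s in tile_seeds]
    counts = pd.Series(0, index=list(CLASS_IDS))
    for t in tiles:
        if len(t.class_table):
            counts = counts.add(t.class_table["class"].value_counts(),
                                fill_value=0)
    counts = counts.reindex(list(CLASS_IDS)).fillna(0).astype(int)
    tbs = true_tbs_from_counts(counts, config)
    epithelial = sum(int(counts[c]) for c in EPITHELIAL_CLASSES)
    atypical = sum(int(counts[c]) for c in ATYPICAL_CLASSES)
    frac = atypical / epithelial if epithelial else 0.0
    p_braf = 0.5 * (1.0 + np.tanh(0.5 * config.braf_slope * (frac - config.braf_center)))
    braf = int(rng.random() < p_braf)
    return SynthSlide(tiles=tiles, true_counts=counts, true_tbs=tbs,
                      braf=braf, atypical_fraction=frac)


def sample_cohort(n_slides: int, seed: int, patch_size: int = 128,
                  n_tiles: int = 3, nuclei_per_tile: tuple[int, int] = (6, 10),
                  sparse_rate: float = 0.15, stain_style: str = "pap"):
    """A cohort of slides spanning all four TBS labels.

    With probability ``sparse_rate`` a slide is rendered nearly acellular
    (TBS I regime); otherwise the intended atypical mass is drawn uniformly
    on [0,1], producing II/V/VI labels through the deterministic counts rule.
    """
    rng = np.random.default_rng(seed)
    slides = []
    for _ in range(n_slides):
        if rng.random() < sparse_rate:
            mix = np.zeros(17)
            mix[[9, 12]] = (0.7, 0.3)  # lymphocytes and colloid only
            cfg = SynthConfig(patch_size=patch_size, nuclei_per_patch=(0, 3),
                              class_mix=tuple(mix), cluster_rate=0.0,
                              stain_style=stain_style)
        else:
            f = rng.uniform(0.0, 1.0)
            cfg = SynthConfig(patch_size=patch_size,
                              nuclei_per_patch=nuclei_per_tile,
                              class_mix=tuple(default_class_mix(f)),
                              cluster_rate=0.1, stain_style=stain_style)
        slides.append(render_slide(cfg, n_tiles, int(rng.integers(0, 2 ** 31 - 1))))
    return slides


# ---------------------------------------------------------------------------
# appearance perturbation

@dataclass(frozen=True)
class AppearanceShift:
    """Per-channel affine gain/offset plus gamma, applied in [0,1] units."""
    gain: tuple = (1.0, 1.0, 1.0)
    offset: tuple = (0.0, 0.0, 0.0)   # in intensity levels (0..255)
    gamma: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if any(g <= 0 for g in self.gain) or any(g <= 0 for g in self.gamma):
            raise ConfigurationError("gains and gammas must be positive")


def perturb_appearance(patch: SynthPatch, shift: AppearanceShift) -> SynthPatch:
    """Stain/scanner shift: only the image changes; mask and table are shared."""
    x = patch.image.astype(float) / 255.0
    out = np.empty_like(x)
    for c in range(3):
        out[..., c] = (x[..., c] ** shift.gamma[c]) * shift.gain[c] \
            + shift.offset[c] / 255.0
    img8 = np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)
    return SynthPatch(image=img8, instance_mask=patch.instance_mask,
                      class_table=patch.class_table)


# ---------------------------------------------------------------------------
# on-disk formats: PNG image, 16-bit PNG mask, CSV table, JSON manifest

def write_patch(patch: SynthPatch, out_dir, stem: str):
    import imageio.v3 as iio
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out_dir / f"{stem}.png", patch.image)
    iio.imwrite(out_dir / f"{stem}_mask.png", patch.instance_mask)
    patch.class_table.to_csv(out_dir / f"{stem}_cells.csv", index=False)


def write_slide(slide: SynthSlide, out_dir, slide_id: str,
                magnification: str = "20x", stain: str = "pap"):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tile_paths = []
    for i, tile in enumerate(slide.tiles):
        stem = f"{slide_id}_t{i:03d}"
        write_patch(tile, out_dir, stem)
        tile_paths.append(f"{stem}.png")
    manifest = {
        "slide_id": slide_id,
        "tiles": tile_paths,
        "magnification": magnification,
        "stain": stain,
        "true_tbs": slide.true_tbs,
        "braf": int(slide.braf),
    }
    with open(out_dir / f"{slide_id}.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out_dir / f"{slide_id}.json"
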