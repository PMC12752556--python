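"""19-feature nuclear morphometry.

Eleven geometry features from the instance mask and eight intensity/texture
features from the masked image region, in a fixed documented order. Geometry
follows scikit-image region properties (0-based, row-major rasters);
orientation is mapped into (-pi/2, pi/2] measured from the x axis.
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb2gray, rgb2hsv
from skimage.filters import sobel
from skimage.measure import regionprops

from .postprocess import Detection

__all__ = ["MORPHO_FEATURE_NAMES", "nuclear_morphometry"]

MORPHO_FEATURE_NAMES = (
    "area", "perimeter", "equivalent_diameter", "major_axis", "minor_axis",
    "aspect_ratio", "eccentricity", "circularity", "solidity", "extent",
    "orientation", "gray_mean", "gray_std", "gray_min", "gray_max",
    "hue_mean", "saturation_mean", "value_mean", "gradient_energy",
)


def nuclear_morphometry(image: np.ndarray, detection: Detection) -> np.ndarray:
    """The 19 features of one detected nucleus, ordered as
    :data:`MORPHO_FEATURE_NAMES`.

    ``image`` is the full RGB tile; the detection's mask/bbox select the
    object. Degenerate 1-pixel masks use a perimeter >= 1 convention and
    aspect ratio 1.
    """
    x0, y0, x1, y1 = detection.bbox
    m = detection.instance_mask
    if not m.any():
        raise ValueError("empty detection mask")
    crop = image[y0:y1, x0:x1]
    props = regionprops(m.astype(np.uint8))[0]

    area = float(props.area)
    perimeter = max(float(props.perimeter), 1.0)
    eq_diam = float(props.equivalent_diameter_area)
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    aspect = major / minor if minor > 0 else 1.0
    ecc = float(props.eccentricity)
    circularity = 4.0 * np.pi * area / perimeter ** 2
    solidity = float(props.solidity)
    extent = float(props.extent)
    # regionprops orientation is measured from the vertical (row) axis;
    # convert to angle from the x axis in (-pi/2, pi/2]
    theta = np.pi / 2.0 - float(props.orientation)
    if theta > np.pi / 2.0:
        theta -= np.pi

    gray = rgb2gray(crop) * 255.0
    gv = gray[m]
    hsv = rgb2hsv(crop)
    hv = hsv[m]
    grad = sobel(gray / 255.0)
    grad_energy = float(np.mean(grad[m] ** 2))

    return np.array([
        area, perimeter, eq_diam, major, minor, aspect, ecc, circularity,
        solidity, extent, theta,
        float(gv.mean()), float(gv.std()), float(gv.min()), float(gv.max()),
        float(hv[:, 0].mean()), float(hv[:, 1].mean()), float(hv[:, 2].mean()),
        grad_energy,
    ], dtype=float)
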