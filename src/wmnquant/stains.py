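"""Beer–Lambert stain model shared by the slide renderer and stain separation.

Brightfield immunohistochemistry obeys Beer–Lambert absorption: each stain
contributes optical density OD = -log10(I / I0) along a fixed RGB absorption
direction. We use the Ruifrok–Johnston haematoxylin / eosin / DAB vectors (as
shipped with scikit-image) and express all optical densities in base-10 units
against a pure-white illuminant (255, 255, 255). Because the renderer and the
unmixer share one matrix, stain separation is exactly invertible on noiseless
images, up to 8-bit quantisation.
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb_from_hed

# Rows: haematoxylin, eosin, DAB absorption unit vectors in RGB-OD space.
STAIN_MATRIX = np.asarray(rgb_from_hed, dtype=float)
STAIN_MATRIX_INV = np.linalg.inv(STAIN_MATRIX)

HAEM = 0
EOSIN = 1
DAB = 2

#: Intensity floor used before taking logs, in units of transmitted fraction.
_EPS = 1e-6


def stains_to_rgb(stain_od: np.ndarray) -> np.ndarray:
    """Convert per-pixel stain optical densities to an RGB image.

    Parameters
    ----------
    stain_od
        Array of shape (..., 3) holding (haematoxylin, eosin, DAB) base-10
        optical densities.

    Returns
    -------
    Float RGB image in [0, 255] (not quantised).
    """
    od_rgb = stain_od @ STAIN_MATRIX
    return 255.0 * np.power(10.0, -od_rgb)


def rgb_to_stains(rgb: np.ndarray) -> np.ndarray:
    """Unmix an RGB image into (haematoxylin, eosin, DAB) optical densities.

    Accepts uint8 or float images on a 0–255 scale. Exact inverse of
    :func:`stains_to_rgb` for in-gamut optical densities.
    """
    trans = np.maximum(np.asarray(rgb, dtype=np.float32) / np.float32(255.0), np.float32(_EPS))
    od_rgb = -np.log10(trans)
    return od_rgb @ STAIN_MATRIX_INV.astype(np.float32)


def neutral_grey_stains(level: float, white: float = 255.0) -> np.ndarray:
    """Stain coordinates of a neutral grey of the given 8-bit level.

    The three stain vectors span RGB-OD space, so any neutral offset (such as
    the light grey slide background) has exact stain coordinates; adding them
    to every pixel keeps the forward/backward transform an exact round trip.
    """
    od = -np.log10(level / white) * np.ones(3)
    return od @ STAIN_MATRIX_INV
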