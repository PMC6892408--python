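"""Brightfield stain separation for dual Iba1 (purple) / Pu.1 (brown) IHC.

Chromogen absorbances combine linearly in optical-density (OD) space
(Beer-Lambert), so a two-stain brightfield image can be unmixed by
least-squares projection of each pixel's OD vector onto the two stain
vectors.  The module converts calibrated RGB images to OD, unmixes them
into per-stain concentration maps, and thresholds those maps into binary
masks for downstream segmentation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

#: Default optical-density unit vectors, rows = (Iba1, Pu.1).
#: Iba1 is developed with a purple (alkaline-phosphatase-type) chromogen that
#: absorbs mostly green; Pu.1 with a brown DAB-type chromogen (the classical
#: Ruifrok & Johnston DAB vector).  Instrument/chromogen dependent: always
#: overridable wherever stain vectors are accepted.
DEFAULT_STAIN_VECTORS = np.array(
    [
        [0.40, 0.80, 0.45],  # Iba1, purple
        [0.27, 0.57, 0.78],  # Pu.1, brown (DAB)
    ]
)
DEFAULT_STAIN_VECTORS /= np.linalg.norm(DEFAULT_STAIN_VECTORS, axis=1, keepdims=True)
DEFAULT_STAIN_VECTORS.setflags(write=False)

#: Small transmittance offset avoiding log(0) for saturated pixels.
OD_EPS = 1.0 / 255.0

#: Unmixing refuses stain matrices whose condition number exceeds this.
MAX_CONDITION_NUMBER = 1e4


class StainVectorError(ValueError):
    """Raised when the stain matrix is too close to singular to unmix."""


@dataclass
class CalibratedImage:
    """An 8-bit RGB brightfield image with a physical scale and region label.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` uint8 array.
    microns_per_pixel
        Physical pixel pitch in micrometres; must be finite and positive.
    region
        Anatomical label, e.g. ``"cortex"`` or ``"cerebellum"``.
    metadata
        Free-form animal/slide annotations (genotype, age, ...).
    """

    pixels: np.ndarray
    microns_per_pixel: float
    region: str = "other"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) RGB pixels, got {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must contain at least one pixel")
        if not (np.isfinite(self.microns_per_pixel) and self.microns_per_pixel > 0):
            raise ValueError("microns_per_pixel must be finite and > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class StainMaps:
    """Per-stain concentration maps (in OD units) plus the unexplained residual."""

    iba1_od: np.ndarray
    pu1_od: np.ndarray
    residual_od: np.ndarray
    microns_per_pixel: float = 1.0


@dataclass
class BinaryMask:
    """A boolean mask sharing the source image's grid and physical scale."""

    mask: np.ndarray
    microns_per_pixel: float
    threshold: Optional[float] = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def area_um2(self) -> float:
        """Total mask area in square micrometres."""
        return float(self.mask.sum()) * self.microns_per_pixel**2


def rgb_to_od(image, i0: float = 255.0, eps: float = OD_EPS) -> np.ndarray:
    """Convert RGB pixel intensities to optical densities per channel.

    ``OD_c = -log10((pixel_c + eps) / (i0 + eps))`` so that a pixel at the
    illumination level ``i0`` maps exactly to OD 0 and OD is non-negative
    for all pixels ``<= i0``.

    ``image`` may be a :class:`CalibratedImage` or a bare array.
    """
    if i0 <= 0:
        raise ValueError("i0 must be > 0")
    pixels = image.pixels if isinstance(image, CalibratedImage) else np.asarray(image)
    od = -np.log10((pixels.astype(np.float64) + eps) / (i0 + eps))
    return od


def od_to_rgb(od: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Invert :func:`rgb_to_od` (up to uint8 quantisation)."""
    transmitted = i0 * np.power(10.0, -np.asarray(od, dtype=np.float64))
    return np.clip(np.rint(transmitted), 0, 255).astype(np.uint8)


def unmix_stains(
    od: np.ndarray,
    stain_vectors: np.ndarray = DEFAULT_STAIN_VECTORS,
    microns_per_pixel: float = 1.0,
) -> StainMaps:
    """Least-squares decomposition of each pixel's OD vector onto two stains.

    Negative concentrations are clipped to zero; the OD mass the clipped
    fit fails to explain (including any out-of-plane component) is reported
    per pixel as the L2 norm in ``residual_od``.

    Raises
    ------
    StainVectorError
        If the two stain vectors are near-collinear (condition number of
        the stain matrix above :data:`MAX_CONDITION_NUMBER`).
    """
    vectors = np.asarray(stain_vectors, dtype=np.float64)
    if vectors.shape != (2, 3):
        raise ValueError(f"expected two 3-vectors, got shape {vectors.shape}")
    a = vectors.T  # 3 x 2 stain matrix
    cond = np.linalg.cond(a)
    if not np.isfinite(cond) or cond > MAX_CONDITION_NUMBER:
        raise StainVectorError(
            f"stain vectors are near-collinear (condition number {cond:.3g} > "
            f"{MAX_CONDITION_NUMBER:.3g}); provide linearly independent vectors"
        )
    od = np.asarray(od, dtype=np.float64)
    flat = od.reshape(-1, 3)
    conc = flat @ np.linalg.pinv(a).T  # (N, 2) least-squares coefficients
    conc = np.maximum(conc, 0.0)
    residual = np.linalg.norm(flat - conc @ a.T, axis=1)
    shape = od.shape[:2]
    return StainMaps(
        iba1_od=conc[:, 0].reshape(shape),
        pu1_od=conc[:, 1].reshape(shape),
        residual_od=residual.reshape(shape),
        microns_per_pixel=microns_per_pixel,
    )


def threshold_channel(
    channel: np.ndarray,
    method: str = "otsu",
    value: Optional[float] = None,
    microns_per_pixel: float = 1.0,
) -> BinaryMask:
    """Binarise a per-stain OD map by a global threshold.

    ``method="otsu"`` picks the threshold maximising between-class variance;
    ``method="fixed"`` requires ``value``.  The mask is ``channel > t``
    (strictly above), so raising the threshold never adds pixels.  A
    constant map under Otsu yields an empty mask with a warning rather than
    an error.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if method == "fixed":
        if value is None:
            raise ValueError("fixed thresholding requires a value")
        t = float(value)
    elif method == "otsu":
        if np.ptp(channel) == 0:
            warnings.warn(
                "constant channel: Otsu threshold undefined, returning empty mask",
                stacklevel=2,
            )
            return BinaryMask(
                np.zeros(channel.shape, dtype=bool), microns_per_pixel, threshold=None
            )
        t = float(threshold_otsu(channel))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    logger.info("threshold_channel: method=%s threshold=%.6g", method, t)
    return BinaryMask(channel > t, microns_per_pixel, threshold=t)
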