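"""Fundus image conditioning: ROI extraction, denoising, calibration, CLAHE.

The conditioning chain mirrors standard fundus-photography practice: the
camera aperture (the circular "effective imaging area") is found by
thresholding the red channel, the image is median-denoised, brightness/colour
is calibrated to reference channel means and resampled to a working size, and
contrast is enhanced with CLAHE before any intensity-based segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure, morphology, transform
from skimage.measure import label

__all__ = [
    "PreprocessConfig",
    "PAPER_GRAY_COEFFS",
    "CONVENTIONAL_GRAY_COEFFS",
    "to_grayscale",
    "extract_roi",
    "median_denoise",
    "normalize",
    "clahe_enhance",
    "preprocess",
]

#: Grayscale weights as used by this pipeline (note blue weight 0.144; the
#: conventional ITU-R 601 triple uses 0.114).
PAPER_GRAY_COEFFS = (0.299, 0.587, 0.144)
CONVENTIONAL_GRAY_COEFFS = (0.299, 0.587, 0.114)


class EmptyRoiError(ValueError):
    """No pixel passed the ROI brightness threshold."""


@dataclass
class PreprocessConfig:
    """Parameters of the conditioning chain.

    Attributes
    ----------
    roi_threshold_fraction:
        The aperture is the largest connected region where the red channel is
        at least this fraction of the red-channel mean. Default 1/3.
    median_kernel:
        Odd side length of the median filter window, pixels.
    target_size:
        Working size (height == width) images are resampled to.
    reference_means:
        Per-channel (R, G, B) intensity means the image is calibrated to.
        ``None`` leaves brightness/colour untouched (single-image mode with
        no external reference).
    calibration:
        ``"additive"`` (shift each channel) or ``"multiplicative"`` (gain).
    clahe_clip:
        Contrast limit; 2.0 is a mild, conventional setting. Internally
        mapped to ``equalize_adapthist``'s normalized clip as ``clip / 100``.
    clahe_tiles:
        Number of CLAHE tiles per image side.
    gray_coeffs:
        RGB weights for grayscale conversion.
    roi_opening_radius:
        Disk radius (px) of the boundary-smoothing opening at a 1024-px
        working size; scaled proportionally for other sizes.
    """

    roi_threshold_fraction: float = 1.0 / 3.0
    median_kernel: int = 3
    target_size: int = 1024
    reference_means: tuple[float, float, float] | None = None
    calibration: str = "additive"
    clahe_clip: float = 2.0
    clahe_tiles: int = 8
    gray_coeffs: tuple[float, float, float] = PAPER_GRAY_COEFFS
    roi_opening_radius: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.roi_threshold_fraction < 1.0:
            raise ValueError("roi_threshold_fraction must lie in (0, 1)")
        if self.median_kernel < 3 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and >= 3")
        if any(c <= 0 for c in self.gray_coeffs):
            raise ValueError("gray_coeffs must be positive")
        if self.calibration not in ("additive", "multiplicative"):
            raise ValueError("calibration must be 'additive' or 'multiplicative'")


def _require_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected HxWx3 RGB image, got shape {image.shape}")
    return image


def to_grayscale(image: np.ndarray, coeffs: tuple[float, float, float] = PAPER_GRAY_COEFFS) -> np.ndarray:
    """Weighted-sum grayscale conversion, Gray = R*cr + G*cg + B*cb.

    Returns a float array; values are NOT clipped (with the default weights
    the coefficient sum is 1.03, so a white pixel maps to 262.65).
    """
    image = _require_rgb(image).astype(np.float64)
    cr, cg, cb = coeffs
    return image[..., 0] * cr + image[..., 1] * cg + image[..., 2] * cb


def extract_roi(image: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Segment the effective fundus imaging area (camera aperture).

    Thresholds the red channel at ``roi_threshold_fraction`` of its mean,
    keeps the largest connected component, and smooths the boundary with a
    morphological opening. The result is a single connected boolean mask.

    Raises
    ------
    EmptyRoiError
        If no pixel exceeds the (strictly positive) threshold, e.g. on an
        all-zero image.
    """
    cfg = cfg or PreprocessConfig()
    image = _require_rgb(image)
    red = image[..., 0].astype(np.float64)
    thresh = cfg.roi_threshold_fraction * red.mean()
    candidates = red >= thresh
    if thresh <= 0 or not candidates.any():
        raise EmptyRoiError("no pixel passes the ROI brightness threshold")

    labels = label(candidates, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    roi = labels == counts.argmax()

    radius = max(1, round(cfg.roi_opening_radius * min(image.shape[:2]) / 1024))
    roi = morphology.opening(roi, morphology.disk(radius))
    if not roi.any():
        raise EmptyRoiError("ROI vanished under morphological opening")
    # opening can split thin necks; keep the largest piece so the mask stays
    # a single component
    labels = label(roi, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def median_denoise(image: np.ndarray, kernel: int = 3) -> np.ndarray:
    """Median filter (per channel for RGB), reflecting at the borders."""
    if kernel < 3 or kernel % 2 == 0:
        raise ValueError("kernel must be odd and >= 3")
    image = np.asarray(image)
    if image.ndim == 2:
        return ndi.median_filter(image, size=kernel, mode="reflect")
    if image.ndim == 3:
        return ndi.median_filter(image, size=(kernel, kernel, 1), mode="reflect")
    raise ValueError(f"expected 2-D or 3-D image, got shape {image.shape}")


def normalize(
    image: np.ndarray,
    reference_means: tuple[float, float, float] | None,
    target_size: int | tuple[int, int] | None,
    calibration: str = "additive",
) -> np.ndarray:
    """Mean-calibrate each channel and resample to the working size.

    Calibration shifts (default) or scales each channel so its mean matches
    the reference mean, then clips to [0, 255]. Resampling is bilinear.
    Either step may be skipped by passing ``None``.
    """
    image = _require_rgb(image).astype(np.float64)
    if reference_means is not None:
        ref = np.asarray(reference_means, dtype=np.float64)
        if np.any(ref <= 0) or np.any(ref >= 255):
            raise ValueError("reference means must lie in (0, 255)")
        means = image.reshape(-1, 3).mean(axis=0)
        if calibration == "additive":
            image = image + (ref - means)
        elif calibration == "multiplicative":
            if np.any(means == 0):
                raise ValueError("multiplicative calibration undefined for zero-mean channel")
            image = image * (ref / means)
        else:
            raise ValueError("calibration must be 'additive' or 'multiplicative'")
        image = np.clip(image, 0.0, 255.0)
    if target_size is not None:
        if np.isscalar(target_size):
            target_size = (int(target_size), int(target_size))
        if min(target_size) < 2:
            raise ValueError("degenerate target size")
        image = transform.resize(
            image, target_size, order=1, mode="edge", anti_aliasing=False, preserve_range=True
        )
    return image


def clahe_enhance(image: np.ndarray, clip: float = 2.0, tiles: int = 8) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a [0, 255] image.

    ``clip`` follows the common contrast-limit convention (2.0 is mild); it
    is mapped to the normalized clip fraction ``clip / 100`` used by
    ``skimage.exposure.equalize_adapthist``.
    """
    if clip <= 0:
        raise ValueError("clip must be positive")
    if tiles < 1:
        raise ValueError("tiles must be >= 1")
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("clahe_enhance expects a single-channel image")
    h, w = image.shape
    kernel = (max(1, h // tiles), max(1, w // tiles))
    out = exposure.equalize_adapthist(
        np.clip(image, 0, 255) / 255.0, kernel_size=kernel, clip_limit=clip / 100.0
    )
    return out * 255.0


def preprocess(image: np.ndarray, cfg: PreprocessConfig | None = None):
    """Run the full conditioning chain: ROI -> denoise -> normalize -> CLAHE.

    Returns ``(enhanced_gray, rgb_normalized, roi)`` at the working size.
    CLAHE is applied to the grayscale conversion of the normalized image.
    """
    cfg = cfg or PreprocessConfig()
    roi = extract_roi(image, cfg)
    denoised = median_denoise(np.asarray(image, dtype=np.float64), cfg.median_kernel)
    rgb = normalize(denoised, cfg.reference_means, cfg.target_size, cfg.calibration)
    roi_resized = (
        transform.resize(
            roi.astype(float), rgb.shape[:2], order=0, mode="edge", preserve_range=True
        )
        > 0.5
    )
    gray = to_grayscale(rgb, cfg.gray_coeffs)
    enhanced = clahe_enhance(np.clip(gray, 0, 255), cfg.clahe_clip, cfg.clahe_tiles)
    return enhanced, rgb, roi_resized
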