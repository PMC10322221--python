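"""Optic disc localization, polar boundary tracing, and size calibration.

The optic disc is the bright, roughly circular region where the optic nerve
exits the eye. Its boundary is traced by a polar transform around a seed
point: along each radial direction the strongest bright-to-dark transition
marks the disc edge. The minimum enclosing circle of the traced boundary
defines the disc center and the papillary diameter (PD). An anatomical PD of
1.5 mm converts pixel measurements to physical units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label
from skimage.transform import warp_polar

__all__ = [
    "DiscSeed",
    "DiscBoundary",
    "OpticDisc",
    "locate_disc",
    "trace_boundary_polar",
    "min_enclosing_circle",
    "calibrate",
    "segment_disc",
]

#: Assumed physical papillary diameter used for pixel-to-mm calibration.
PD_MM = 1.5


class SeedNotFoundError(ValueError):
    """No bright candidate region for the optic disc."""


class BoundaryNotFoundError(ValueError):
    """Radial profiles carry no edge signal."""


@dataclass(frozen=True)
class DiscSeed:
    """Starting point for boundary tracing; x = column, y = row."""

    x: float
    y: float
    source: str = "heuristic"  # or "user"


@dataclass
class DiscBoundary:
    """Per-angle boundary radii around ``center`` (uniform angles over [0, 2pi))."""

    center: tuple[float, float]
    radii: np.ndarray

    @property
    def n_angles(self) -> int:
        return len(self.radii)

    def points(self) -> np.ndarray:
        """Boundary as (n, 2) array of (x, y) image coordinates."""
        theta = np.linspace(0.0, 2.0 * np.pi, self.n_angles, endpoint=False)
        cx, cy = self.center
        return np.column_stack([cx + self.radii * np.cos(theta), cy + self.radii * np.sin(theta)])


@dataclass(frozen=True)
class OpticDisc:
    """Disc geometry plus the mm-per-pixel calibration (PD = 1.5 mm)."""

    center: tuple[float, float]
    diameter_px: float

    @property
    def mm_per_px(self) -> float:
        return PD_MM / self.diameter_px

    @property
    def radius_px(self) -> float:
        return self.diameter_px / 2.0

    def distance_pd(self, x: float, y: float) -> float:
        """Distance from (x, y) to the disc BORDER, in PD units (negative inside)."""
        d = float(np.hypot(x - self.center[0], y - self.center[1]))
        return (d - self.radius_px) / self.diameter_px


def locate_disc(
    image: np.ndarray,
    roi: np.ndarray | None = None,
    seed: tuple[float, float] | None = None,
    percentile: float = 99.0,
    smooth_sigma: float = 5.0,
) -> DiscSeed:
    """Heuristic disc seed: centroid of the brightest smoothed region.

    A user-supplied ``seed`` is returned verbatim. Otherwise the image is
    Gaussian-smoothed, thresholded at the given intensity percentile inside
    the ROI, and the centroid of the largest component is returned.
    """
    if seed is not None:
        return DiscSeed(float(seed[0]), float(seed[1]), source="user")
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 3:
        image = image.mean(axis=2)
    smoothed = ndi.gaussian_filter(image, smooth_sigma)
    mask = np.asarray(roi, bool) if roi is not None else np.ones_like(smoothed, bool)
    vals = smoothed[mask]
    if vals.size == 0:
        raise SeedNotFoundError("empty ROI")
    if np.ptp(vals) < 1e-6:
        raise SeedNotFoundError("image has no bright structure; supply a seed")
    thresh = np.percentile(vals, percentile)
    candidates = (smoothed >= thresh) & mask
    if not candidates.any():
        raise SeedNotFoundError("no pixel exceeds the brightness percentile")
    labels = label(candidates, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    rows, cols = np.nonzero(labels == counts.argmax())
    return DiscSeed(float(cols.mean()), float(rows.mean()), source="heuristic")


def trace_boundary_polar(
    gray: np.ndarray,
    seed: DiscSeed,
    n_angles: int = 360,
    r_max: float | None = None,
    edge_sigma: float = 2.0,
    smooth_window: int = 9,
    r_min: float = 3.0,
    edge_fraction: float = 0.3,
) -> DiscBoundary:
    """Trace the disc edge along each radial direction.

    The image is unwrapped to polar coordinates about the seed and each
    angular row is filtered with a 1-D derivative of Gaussian (sigma
    ``edge_sigma``) along the radius; negative responses mark bright-to-dark
    transitions. Because dark vessels beyond the disc rim also produce
    strong drops, the boundary at each angle is the INNERMOST drop whose
    strength reaches ``edge_fraction`` of the strongest drop anywhere (the
    disc rim is the first strong edge met going outward from a seed inside
    the disc), refined to the local response minimum. The radius profile is
    then median-smoothed across angles with a circular window.
    """
    gray = np.asarray(gray, dtype=np.float64)
    h, w = gray.shape
    if r_max is None:
        r_max = 0.4 * min(h, w)
    if not (r_max <= seed.x <= w - 1 - r_max and r_max <= seed.y <= h - 1 - r_max):
        raise ValueError("seed too close to the image border for radius r_max")
    n_radii = int(np.ceil(2.0 * r_max))  # 2x radial oversampling
    polar = warp_polar(
        gray, center=(seed.y, seed.x), radius=r_max, output_shape=(n_angles, n_radii)
    )
    # derivative of Gaussian along the radial axis; boundary = steepest drop
    dog = ndi.gaussian_filter1d(polar, sigma=edge_sigma, axis=1, order=1, mode="nearest")
    scale = r_max / n_radii  # column index -> radius in pixels
    lo = max(1, int(np.ceil(r_min / scale)))
    window = dog[:, lo:]
    if np.ptp(polar) < 1e-9 or np.abs(window).max() < 1e-9:
        raise BoundaryNotFoundError("flat radial profiles; no disc edge signal")
    threshold = edge_fraction * window.min()  # negative
    radii = np.empty(n_angles, dtype=np.float64)
    for i in range(n_angles):
        row = window[i]
        strong = np.nonzero(row <= threshold)[0]
        if strong.size == 0:
            j = int(row.argmin())
        else:
            # walk to the local minimum of the first strong contiguous run
            j = int(strong[0])
            while j + 1 < len(row) and row[j + 1] < row[j]:
                j += 1
        # sub-pixel refinement: parabola through the response minimum
        frac = 0.0
        if 0 < j < len(row) - 1:
            denom = row[j - 1] - 2.0 * row[j] + row[j + 1]
            if abs(denom) > 1e-12:
                frac = float(np.clip(0.5 * (row[j - 1] - row[j + 1]) / denom, -0.5, 0.5))
        radii[i] = (j + frac + lo) * scale
    if smooth_window > 1:
        radii = ndi.median_filter(radii, size=smooth_window, mode="wrap")
    return DiscBoundary(center=(seed.x, seed.y), radii=radii)


def _circle_two(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, float]:
    center = (p + q) / 2.0
    return center, float(np.linalg.norm(p - center))


def _circle_three(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, float] | None:
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        return None  # collinear
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx) + (cx**2 + cy**2) * (bx - ax)) / d
    center = np.array([ux, uy])
    return center, float(np.linalg.norm(a - center))


def _in_circle(p: np.ndarray, center: np.ndarray, radius: float, eps: float = 1e-7) -> bool:
    return np.linalg.norm(p - center) <= radius * (1 + eps) + eps


def min_enclosing_circle(points: np.ndarray) -> tuple[tuple[float, float], float]:
    """Smallest circle containing all points (Welzl's algorithm).

    Points are pre-shuffled with a fixed seed, so the result is deterministic
    and the expected running time linear. Returns ``((cx, cy), radius)``.
    """
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    rng = np.random.default_rng(0)
    pts = pts[rng.permutation(len(pts))]

    center, radius = _circle_two(pts[0], pts[1])
    for i in range(2, len(pts)):
        if _in_circle(pts[i], center, radius):
            continue
        # pts[i] must lie on the boundary
        center, radius = _circle_two(pts[0], pts[i])
        for j in range(1, i):
            if _in_circle(pts[j], center, radius):
                continue
            center, radius = _circle_two(pts[i], pts[j])
            for k in range(j):
                if _in_circle(pts[k], center, radius):
                    continue
                res = _circle_three(pts[i], pts[j], pts[k])
                if res is not None:
                    center, radius = res
    return (float(center[0]), float(center[1])), float(radius)


def calibrate(center: tuple[float, float], diameter_px: float) -> OpticDisc:
    """Build the calibrated disc; mm_per_px = 1.5 / diameter_px."""
    if diameter_px <= 0:
        raise ValueError("disc diameter must be positive")
    return OpticDisc(center=(float(center[0]), float(center[1])), diameter_px=float(diameter_px))


def segment_disc(
    gray: np.ndarray,
    roi: np.ndarray | None = None,
    seed: tuple[float, float] | None = None,
    n_angles: int = 360,
    r_max: float | None = None,
) -> OpticDisc:
    """Full disc pipeline: seed -> polar boundary -> min enclosing circle -> calibration."""
    s = locate_disc(gray, roi=roi, seed=seed)
    boundary = trace_boundary_polar(gray, s, n_angles=n_angles, r_max=r_max)
    center, radius = min_enclosing_circle(boundary.points())
    return calibrate(center, 2.0 * radius)
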