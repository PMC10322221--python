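"""Synthetic phantoms with analytic ground truth.

Every measurement in this package is validated against phantoms whose
geometry is known in closed form: bars of exact width, circular arcs of
exact curvature, Y-junctions with designed branching angles, Sierpinski
carpets with known fractal dimension, discs of known diameter, and composite
"fundus" scenes combining a bright optic disc with dark vessels inside a
circular aperture — mirroring the contrast of real fundus photographs so the
classical segmentation stages can be exercised end to end.

Masks are rasterized by pixel-center inclusion (no anti-aliasing) and are
bit-reproducible; Gaussian noise (seeded) is applied to the rendered image
only, never to the masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

__all__ = ["PhantomSpec", "GroundTruth", "Phantom", "generate", "generate_cohort"]

# render colours (R, G, B)
_BACKGROUND = (180, 120, 90)  # fundus-like orange
_DISC_COLOR = (235, 215, 175)
_VEIN_COLOR = (90, 30, 30)
_ARTERY_COLOR = (150, 60, 60)
_OUTSIDE = (0, 0, 0)

AV_ARTERY, AV_VEIN, AV_UNKNOWN = 1, 2, 3


@dataclass
class PhantomSpec:
    """Parameters of one synthetic scene.

    ``kind`` selects the geometry: ``bar``, ``arc``, ``y_junction``,
    ``tree``, ``sierpinski``, ``disc``, or ``composite_fundus``. Unused
    fields are ignored by kinds that do not need them.
    """

    kind: str = "bar"
    size: int = 512
    width: float = 11.0  # vessel width, px
    length: float = 200.0  # bar length, px
    angle_deg: float = 0.0  # bar orientation / branch angle
    radius: float = 100.0  # arc radius, px
    theta_range: tuple[float, float] = (0.0, 180.0)  # arc angular extent, degrees
    branch_length: float = 90.0
    branch_width: float | None = None
    iterations: int = 5  # sierpinski
    disc_diameter: float = 96.0
    n_vessels: int = 4  # composite: number of standalone vessels
    noise_sd: float = 0.0
    seed: int = 0
    center: tuple[float, float] | None = None  # (x, y); default image center

    def __post_init__(self) -> None:
        if self.kind not in (
            "bar", "arc", "y_junction", "tree", "sierpinski", "disc", "composite_fundus",
        ):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.kind not in ("sierpinski", "disc") and self.width < 3:
            raise ValueError("vessel width must be >= 3 px")
        if self.kind == "arc" and not self.radius > self.width:
            raise ValueError("arc radius must exceed the vessel width")


@dataclass
class GroundTruth:
    """Analytic truth implied by a spec; only applicable fields are set."""

    true_width_px: float | None = None
    true_curvature_per_px: float | None = None
    true_angle_deg: float | None = None
    true_density: float | None = None
    true_fd: float | None = None
    disc_center_xy: tuple[float, float] | None = None
    disc_diameter_px: float | None = None
    extras: dict[str, Any] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class Phantom:
    spec: PhantomSpec
    image: np.ndarray  # HxWx3 uint8
    vessel_mask: np.ndarray  # HxW bool
    av_mask: np.ndarray  # HxW uint8 in {0,1,2,3}
    roi: np.ndarray  # HxW bool
    truth: GroundTruth


def _grid(size: int) -> tuple[np.ndarray, np.ndarray]:
    y, x = np.mgrid[0:size, 0:size]
    return x.astype(np.float64), y.astype(np.float64)


def bar_mask(
    size: int, center: tuple[float, float], length: float, width: float, angle_deg: float
) -> np.ndarray:
    """Axis-rotated solid bar; a pixel belongs iff its center lies inside."""
    x, y = _grid(size)
    th = np.radians(angle_deg)
    u = (x - center[0]) * np.cos(th) + (y - center[1]) * np.sin(th)
    v = -(x - center[0]) * np.sin(th) + (y - center[1]) * np.cos(th)
    return (np.abs(u) <= length / 2.0) & (np.abs(v) <= width / 2.0)


def arc_mask(
    size: int,
    center: tuple[float, float],
    radius: float,
    width: float,
    theta_range: tuple[float, float],
) -> np.ndarray:
    """Annular sector: radius within width/2 of ``radius``, angle in range."""
    x, y = _grid(size)
    dx, dy = x - center[0], y - center[1]
    r = np.hypot(dx, dy)
    if theta_range[1] - theta_range[0] >= 360.0:
        in_angle = np.ones_like(r, bool)
    else:
        theta = np.degrees(np.arctan2(dy, dx)) % 360.0
        t0, t1 = theta_range[0] % 360.0, theta_range[1] % 360.0
        in_angle = (theta >= t0) & (theta <= t1) if t0 <= t1 else (theta >= t0) | (theta <= t1)
    return (np.abs(r - radius) <= width / 2.0) & in_angle


def disc_mask(size: int, center: tuple[float, float], diameter: float) -> np.ndarray:
    x, y = _grid(size)
    return np.hypot(x - center[0], y - center[1]) <= diameter / 2.0


def sierpinski_carpet(iterations: int) -> np.ndarray:
    """Boolean Sierpinski carpet on a 3**iterations per-side grid."""
    cells = np.ones((1, 1), bool)
    for _ in range(iterations):
        n = cells.shape[0]
        tiled = np.tile(cells, (3, 3)).reshape(3, n, 3, n).swapaxes(1, 2)
        tiled[1, 1] = False
        cells = tiled.swapaxes(1, 2).reshape(3 * n, 3 * n)
    return cells


def _segment_endpoint(start: np.ndarray, angle_deg: float, length: float) -> np.ndarray:
    th = np.radians(angle_deg)
    return start + length * np.array([np.cos(th), np.sin(th)])


def _bar_between(size: int, p: np.ndarray, q: np.ndarray, width: float) -> np.ndarray:
    center = ((p + q) / 2.0)
    d = q - p
    length = float(np.hypot(*d))
    angle = float(np.degrees(np.arctan2(d[1], d[0])))
    return bar_mask(size, (center[0], center[1]), length, width, angle)


def _check_in_frame(mask: np.ndarray) -> None:
    border = np.concatenate([mask[0], mask[-1], mask[:, 0], mask[:, -1]])
    if border.any():
        raise ValueError("phantom geometry exceeds the image frame")


def _render(
    size: int,
    vessel_mask: np.ndarray,
    av_mask: np.ndarray,
    roi: np.ndarray,
    disc: np.ndarray | None,
    noise_sd: float,
    seed: int,
) -> np.ndarray:
    img = np.zeros((size, size, 3), np.float64)
    img[:] = _OUTSIDE
    img[roi] = _BACKGROUND
    if disc is not None:
        img[disc & roi] = _DISC_COLOR
    img[(av_mask == AV_VEIN) | (av_mask == AV_UNKNOWN)] = _VEIN_COLOR
    img[av_mask == AV_ARTERY] = _ARTERY_COLOR
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate(spec: PhantomSpec) -> Phantom:
    """Rasterize a phantom and its exact ground truth."""
    size = spec.size
    center = spec.center or (size / 2.0, size / 2.0)
    truth = GroundTruth()
    disc = None
    roi = np.ones((size, size), bool)
    av = None

    if spec.kind == "bar":
        mask = bar_mask(size, center, spec.length, spec.width, spec.angle_deg)
        truth.true_width_px = spec.width
        truth.true_curvature_per_px = 0.0
    elif spec.kind == "arc":
        mask = arc_mask(size, center, spec.radius, spec.width, spec.theta_range)
        truth.true_width_px = spec.width
        truth.true_curvature_per_px = 1.0 / spec.radius
    elif spec.kind == "y_junction":
        c = np.asarray(center)
        main = bar_mask(size, center, spec.length, spec.width, 0.0)
        bw = spec.branch_width or spec.width
        tip = _segment_endpoint(c, spec.angle_deg, spec.branch_length)
        branch = _bar_between(size, c, tip, bw)
        mask = main | branch
        truth.true_width_px = spec.width
        truth.true_angle_deg = spec.angle_deg
    elif spec.kind == "tree":
        c = np.asarray(center)
        half = spec.length / 2.0
        trunk = bar_mask(size, center, spec.length, spec.width, 90.0)
        bw = spec.branch_width or max(3.0, spec.width * 0.6)
        up = c + np.array([0.0, -half / 2.0])
        dn = c + np.array([0.0, half / 2.0])
        b1 = _bar_between(size, up, _segment_endpoint(up, -spec.angle_deg, spec.branch_length), bw)
        b2 = _bar_between(size, dn, _segment_endpoint(dn, spec.angle_deg, spec.branch_length), bw)
        mask = trunk | b1 | b2
        truth.true_width_px = spec.width
        truth.true_angle_deg = spec.angle_deg
    elif spec.kind == "sierpinski":
        cells = sierpinski_carpet(spec.iterations)
        cell_px = max(1, size // cells.shape[0])
        mask = np.zeros((size, size), bool)
        carpet = np.kron(cells, np.ones((cell_px, cell_px), bool))
        mask[: carpet.shape[0], : carpet.shape[1]] = carpet
        truth.true_fd = float(np.log(8) / np.log(3))
        truth.extras["filled_cells"] = int(cells.sum())
    elif spec.kind == "disc":
        mask = np.zeros((size, size), bool)
        disc = disc_mask(size, center, spec.disc_diameter)
        truth.disc_center_xy = (float(center[0]), float(center[1]))
        truth.disc_diameter_px = spec.disc_diameter
        truth.true_fd = 2.0
    elif spec.kind == "composite_fundus":
        return _composite(spec)
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(spec.kind)

    if spec.kind not in ("sierpinski", "disc"):
        _check_in_frame(mask)
    av = np.where(mask, AV_UNKNOWN, 0).astype(np.uint8)
    image = _render(size, mask, av, roi, disc, spec.noise_sd, spec.seed)
    return Phantom(spec, image, mask, av, roi, truth)


def _composite(spec: PhantomSpec) -> Phantom:
    """Fundus-like scene: aperture, bright disc, dark vessel tree + arcs.

    Two thick vertical "veins" leave the disc upward and downward, each with
    an oblique thinner "artery" branch; additional standalone arcs provide
    curved vessels in the peripapillary annuli. Vein width is ``spec.width``;
    arteries are 0.7x as wide (rounded to an odd integer).
    """
    size = spec.size
    cx, cy = spec.center or (size / 2.0, size / 2.0)
    pd = spec.disc_diameter
    w_vein = spec.width
    w_art = max(3.0, 0.7 * spec.width)

    roi = disc_mask(size, (cx, cy), 2 * 0.47 * size)
    disc = disc_mask(size, (cx, cy), pd)

    vein = np.zeros((size, size), bool)
    artery = np.zeros((size, size), bool)

    margin = 0.06 * size
    top, bot = margin, size - margin
    # upper and lower mains (veins), vertical through the disc center column;
    # even rasterized widths need a half-pixel column offset to stay exact
    x_main = cx if round(w_vein) % 2 else cx + 0.5
    vein |= _bar_between(size, np.array([x_main, cy - pd / 2]), np.array([x_main, top]), w_vein)
    vein |= _bar_between(size, np.array([x_main, cy + pd / 2]), np.array([x_main, bot]), w_vein)
    # artery branches off each main, both at a designed 45 degrees from the
    # downstream (away-from-disc) main direction
    up_node = np.array([x_main, cy - pd * 1.6])
    dn_node = np.array([x_main, cy + pd * 1.6])
    artery |= _bar_between(
        size, up_node, _segment_endpoint(up_node, -45.0, 0.22 * size), w_art
    )
    artery |= _bar_between(
        size, dn_node, _segment_endpoint(dn_node, 135.0, 0.22 * size), w_art
    )
    # standalone curved vessels (veins), alternating sides, radius from spec;
    # peripheral vessels run thinner than the main arcades
    w_arc = 0.85 * w_vein
    for i in range(max(0, spec.n_vessels - 4)):
        side = 1 if i % 2 == 0 else -1
        r = spec.radius * (1.0 + 0.15 * (i // 2))
        c_arc = (cx + side * (pd * 1.2 + r), cy)
        sweep = (140.0, 220.0) if side > 0 else (-40.0, 40.0)
        m = arc_mask(size, c_arc, r, w_arc, sweep)
        m &= disc_mask(size, (cx, cy), 2 * (0.47 * size - 2))  # keep inside aperture
        vein |= m

    artery &= ~vein  # veins occlude arteries at crossings
    mask = vein | artery
    av = np.zeros((size, size), np.uint8)
    av[vein] = AV_VEIN
    av[artery] = AV_ARTERY

    truth = GroundTruth(
        true_width_px=w_vein,
        disc_center_xy=(float(cx), float(cy)),
        disc_diameter_px=float(pd),
        extras={
            "vein_width_px": float(w_vein),
            "artery_width_px": float(w_art),
            "branch_angle_deg": 45.0,
            "n_vessels": spec.n_vessels,
            "arc_radius_px": float(spec.radius),
        },
    )
    image = _render(size, mask, av, roi, disc, spec.noise_sd, spec.seed)
    return Phantom(spec, image, mask, av, roi, truth)


def generate_cohort(n: int, seed: int = 0, size: int = 640) -> list[Phantom]:
    """``n`` composite fundus phantoms with systematically graded geometry.

    Vein width ramps 8 -> 16 px and the standalone-vessel count ramps 4 -> 8
    across the cohort, so measured mean diameter and vascular density must
    increase monotonically with the index. Fully deterministic for a seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    phantoms = []
    for i in range(n):
        f = i / max(1, n - 1)
        spec = PhantomSpec(
            kind="composite_fundus",
            size=size,
            width=8.0 + 8.0 * f,
            n_vessels=4 + int(round(4 * f)),
            radius=150.0 + 40.0 * f,
            disc_diameter=96.0,
            noise_sd=4.0,
            seed=seed + i,
        )
        phantoms.append(generate(spec))
    return phantoms
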