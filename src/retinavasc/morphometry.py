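"""Quantitative vascular morphometry on centerline graphs and masks.

The measurement suite:

* **Diameter** — at a centerline point, the straight line orthogonal to the
  local tangent crosses the vessel boundary at two points; their Euclidean
  distance is the diameter. Sampled every 5 px along each vessel and
  converted to micrometres through the papillary-diameter calibration.
* **Tortuosity** — pointwise curvature from the circumradius of the triangle
  A-B-C, where B and C sit a fixed arc length either side of A on the
  centerline: R = a / (2 sin A), curvature C = 1/R. Tortuosity is the mean
  curvature over all measurable centerline points (the 25 px at each vessel
  end are excluded — the construction needs both neighbors).
* **Fractal dimension** — box counting: slope of log N(eps) against
  log(1/eps) over a dyadic box-size schedule.
* **Density** — vessel pixel area over fundus ROI area.
* **Branching angle** — at each branch point on a main vessel, lines are
  fitted to the first 10 centerline pixels of the main and branch vessels
  leaving the node; the angle between them is the branching angle.
* **AVR** — mean arteriolar diameter over mean venular diameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .centerline import CenterlineGraph, VesselSegment
from .optic_disc import OpticDisc

__all__ = [
    "CrossSection",
    "CurvatureSample",
    "BoxCountSeries",
    "DensityResult",
    "BranchAngleResult",
    "diameter_at",
    "sample_diameters",
    "average_diameter",
    "avr",
    "curvature_at",
    "sample_curvatures",
    "tortuosity",
    "fractal_dimension",
    "box_count",
    "vascular_density",
    "select_main_vessels",
    "branching_angles",
]


@dataclass
class CrossSection:
    """One diameter measurement at a centerline point."""

    center: tuple[float, float]  # (x, y)
    tangent: tuple[float, float]  # unit vector
    d_px: float
    d_um: float  # NaN when no calibration is available
    segment_id: int
    av_label: str = "unknown"


@dataclass
class CurvatureSample:
    """Three-point curvature at a centerline point A (B, C arc-equidistant)."""

    point: tuple[float, float]  # A, (x, y)
    chord_a: float  # |BC| in px
    angle_a: float  # interior angle at A, radians
    curvature: float  # 1/R_A, px^-1 (0 for collinear)
    segment_id: int
    av_label: str = "unknown"


@dataclass
class BoxCountSeries:
    epsilons: np.ndarray
    counts: np.ndarray
    slope: float


@dataclass
class DensityResult:
    vessel_area_px: int
    roi_area_px: int

    @property
    def rho(self) -> float:
        return self.vessel_area_px / self.roi_area_px


@dataclass
class BranchAngleResult:
    branch_xy: tuple[float, float]
    angle_deg: float
    main_segment_id: int
    branch_segment_id: int


# ---------------------------------------------------------------------------
# diameter


def _fit_tangent(points: np.ndarray) -> np.ndarray:
    """Unit direction of the total-least-squares line through points."""
    pts = np.asarray(points, float)
    centered = pts - pts.mean(axis=0)
    # principal axis of the 2x2 scatter matrix
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    t = v[:, np.argmax(w)]
    return t / np.linalg.norm(t)


def _bilinear(mask_f: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Bilinear samples of a float mask at (x, y); out-of-bounds -> NaN."""
    h, w = mask_f.shape
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    valid = (x0 >= 0) & (y0 >= 0) & (x0 < w - 1) & (y0 < h - 1)
    out = np.full(x.shape, np.nan)
    if valid.any():
        xv, yv, x0v, y0v = x[valid], y[valid], x0[valid], y0[valid]
        fx, fy = xv - x0v, yv - y0v
        out[valid] = (
            mask_f[y0v, x0v] * (1 - fx) * (1 - fy)
            + mask_f[y0v, x0v + 1] * fx * (1 - fy)
            + mask_f[y0v + 1, x0v] * (1 - fx) * fy
            + mask_f[y0v + 1, x0v + 1] * fx * fy
        )
    return out


def _ray_exit(mask: np.ndarray, origin: np.ndarray, direction: np.ndarray, step: float = 0.1):
    """March along ``direction`` until leaving the mask; return the exit point.

    The mask is sampled bilinearly (inside = interpolated indicator >= 0.5),
    which places the boundary sub-pixel even for oblique vessels. Returns
    None if the ray leaves the image while still inside the mask
    (unmeasurable).
    """
    mask_f = mask.astype(np.float64)
    max_t = float(np.hypot(*mask.shape))
    chunk = 256
    t0 = 0.0
    while t0 < max_t:
        ts = t0 + step * np.arange(1, chunk + 1)
        x = origin[0] + ts * direction[0]
        y = origin[1] + ts * direction[1]
        vals = _bilinear(mask_f, x, y)
        outside = np.nonzero(~(vals >= 0.5))[0]
        if outside.size:
            i = int(outside[0])
            if np.isnan(vals[i]):
                return None  # left the image while still inside the mask
            t_out = ts[i]
            t_in = ts[i - 1] if i > 0 else t0
            # refine: linear crossing of the 0.5 level between the samples
            v_in = vals[i - 1] if i > 0 else _bilinear(mask_f, *[np.array([v]) for v in origin])[0]
            v_out = vals[i]
            frac = (v_in - 0.5) / (v_in - v_out) if v_in != v_out else 0.5
            t_cross = t_in + frac * (t_out - t_in)
            return origin + t_cross * direction
        t0 = ts[-1]
    return None


def diameter_at(
    mask: np.ndarray,
    path: np.ndarray,
    idx: int,
    tangent_window: int = 7,
    mm_per_px: float | None = None,
    segment_id: int = -1,
    av_label: str = "unknown",
) -> CrossSection | None:
    """Diameter at path point ``idx``; None when the section is unmeasurable."""
    mask = np.asarray(mask, bool)
    path = np.asarray(path, float)
    lo, hi = max(0, idx - tangent_window), min(len(path), idx + tangent_window + 1)
    tangent = _fit_tangent(path[lo:hi])
    normal = np.array([-tangent[1], tangent[0]])
    origin = path[idx]
    r, c = int(round(origin[1])), int(round(origin[0]))
    if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]) or not mask[r, c]:
        return None
    p1 = _ray_exit(mask, origin, normal)
    p2 = _ray_exit(mask, origin, -normal)
    if p1 is None or p2 is None:
        return None
    d_px = float(np.linalg.norm(p1 - p2))
    d_um = d_px * mm_per_px * 1000.0 if mm_per_px else float("nan")
    return CrossSection(
        center=(float(origin[0]), float(origin[1])),
        tangent=(float(tangent[0]), float(tangent[1])),
        d_px=d_px,
        d_um=d_um,
        segment_id=segment_id,
        av_label=av_label,
    )


def sample_diameters(
    mask: np.ndarray,
    graph: CenterlineGraph,
    step: int = 5,
    tangent_window: int = 7,
    disc: OpticDisc | None = None,
) -> list[CrossSection]:
    """Diameters every ``step`` path pixels, skipping node-adjacent points."""
    mm_per_px = disc.mm_per_px if disc is not None else None
    sections: list[CrossSection] = []
    for seg in graph.segments.values():
        n = seg.n_pixels
        for idx in range(tangent_window, n - tangent_window, step):
            cs = diameter_at(
                mask,
                seg.path,
                idx,
                tangent_window=tangent_window,
                mm_per_px=mm_per_px,
                segment_id=seg.id,
                av_label=seg.av_label,
            )
            if cs is not None:
                sections.append(cs)
    return sections


def average_diameter(sections: list[CrossSection], label: str | None = None, unit: str = "um") -> float:
    """Mean diameter over (optionally label-filtered) cross sections; NaN if empty."""
    vals = [
        s.d_um if unit == "um" else s.d_px
        for s in sections
        if label is None or s.av_label == label
    ]
    return float(np.mean(vals)) if vals else float("nan")


def avr(artery_mean: float, vein_mean: float) -> float:
    """Arteriole-to-venule diameter ratio."""
    if not vein_mean > 0:
        raise ValueError("vein mean diameter must be positive")
    return artery_mean / vein_mean


# ---------------------------------------------------------------------------
# curvature / tortuosity

_SIN_COLLINEAR = 1e-6


def curvature_at(
    path: np.ndarray, idx: int, arc_half: int = 25, segment_id: int = -1, av_label: str = "unknown"
) -> CurvatureSample | None:
    """Circumradius curvature at path point ``idx``.

    B and C are ``arc_half`` path steps either side of A; with a = |BC| and
    the interior angle at A, the circumradius is R = a / (2 sin A) and the
    curvature 1/R = 2 sin A / a. Collinear triples have zero curvature.
    Returns None when the point is within ``arc_half`` of a segment end.
    """
    path = np.asarray(path, float)
    if idx < arc_half or idx >= len(path) - arc_half:
        return None
    a_pt = path[idx]
    b_pt = path[idx - arc_half]
    c_pt = path[idx + arc_half]
    ab = b_pt - a_pt
    ac = c_pt - a_pt
    a_len = float(np.linalg.norm(c_pt - b_pt))
    if a_len < 1e-9:
        return None
    cosang = np.clip(ab @ ac / (np.linalg.norm(ab) * np.linalg.norm(ac)), -1.0, 1.0)
    angle = float(np.arccos(cosang))
    sin_a = float(np.sin(angle))
    curv = 0.0 if sin_a < _SIN_COLLINEAR else 2.0 * sin_a / a_len
    return CurvatureSample(
        point=(float(a_pt[0]), float(a_pt[1])),
        chord_a=a_len,
        angle_a=angle,
        curvature=curv,
        segment_id=segment_id,
        av_label=av_label,
    )


def sample_curvatures(
    graph: CenterlineGraph, arc_half: int = 25, step: int = 1
) -> list[CurvatureSample]:
    """Curvature at every ``step``-th measurable centerline point."""
    samples: list[CurvatureSample] = []
    for seg in graph.segments.values():
        for idx in range(arc_half, seg.n_pixels - arc_half, step):
            cs = curvature_at(seg.path, idx, arc_half, segment_id=seg.id, av_label=seg.av_label)
            if cs is not None:
                samples.append(cs)
    return samples


def tortuosity(
    samples: list[CurvatureSample], pooling: str = "pooled", per_mm: float | None = None
) -> float:
    """Mean curvature over samples, in px^-1 (or mm^-1 via ``per_mm`` = mm_per_px).

    ``pooled`` averages all samples together; ``per_vessel_mean`` averages
    within each vessel segment first, then across segments. Reported table
    values conventionally multiply this by 1000.
    """
    if not samples:
        return float("nan")
    if pooling == "pooled":
        value = float(np.mean([s.curvature for s in samples]))
    elif pooling == "per_vessel_mean":
        by_seg: dict[int, list[float]] = {}
        for s in samples:
            by_seg.setdefault(s.segment_id, []).append(s.curvature)
        value = float(np.mean([np.mean(v) for v in by_seg.values()]))
    else:
        raise ValueError("pooling must be 'pooled' or 'per_vessel_mean'")
    if per_mm:
        value = value / per_mm  # px^-1 -> mm^-1
    return value


# ---------------------------------------------------------------------------
# fractal dimension / density


def box_count(mask: np.ndarray, epsilons: np.ndarray | None = None) -> BoxCountSeries:
    """Occupied-box counts over a dyadic box-size schedule and the fitted slope.

    The grid is anchored at the image origin; N(eps) counts eps-by-eps boxes
    containing at least one foreground pixel. The fractal dimension is the
    least-squares slope of log N against log(1/eps).
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask has no fractal dimension")
    h, w = mask.shape
    if epsilons is None:
        eps_max = min(h, w) // 4
        eps_list = []
        e = 4
        while e <= eps_max:
            eps_list.append(e)
            e *= 2
        if len(eps_list) < 2:
            eps_list = [2, 4]
        epsilons = np.array(eps_list)
    counts = []
    for eps in epsilons:
        nh, nw = -(-h // eps), -(-w // eps)
        padded = np.zeros((nh * eps, nw * eps), bool)
        padded[:h, :w] = mask
        blocks = padded.reshape(nh, eps, nw, eps).any(axis=(1, 3))
        counts.append(int(blocks.sum()))
    counts = np.array(counts)
    slope = float(np.polyfit(np.log(1.0 / epsilons), np.log(counts), 1)[0])
    return BoxCountSeries(epsilons=np.asarray(epsilons), counts=counts, slope=slope)


def fractal_dimension(mask: np.ndarray) -> float:
    """Box-counting fractal dimension of a vessel mask."""
    return box_count(mask).slope


def vascular_density(mask: np.ndarray, roi: np.ndarray) -> DensityResult:
    """rho = vessel area / fundus ROI area (exact pixel counts)."""
    mask = np.asarray(mask, bool)
    roi = np.asarray(roi, bool)
    roi_area = int(np.count_nonzero(roi))
    if roi_area == 0:
        raise ValueError("empty ROI")
    return DensityResult(int(np.count_nonzero(mask & roi)), roi_area)


# ---------------------------------------------------------------------------
# main vessels / branching angle


def _segment_mean_diameters(sections: list[CrossSection]) -> dict[int, float]:
    by_seg: dict[int, list[float]] = {}
    for s in sections:
        by_seg.setdefault(s.segment_id, []).append(s.d_px)
    return {k: float(np.mean(v)) for k, v in by_seg.items()}


def _segment_centroid(seg: VesselSegment) -> np.ndarray:
    return seg.path.mean(axis=0)


def select_main_vessels(
    graph: CenterlineGraph,
    sections: list[CrossSection],
    disc: OpticDisc,
    max_border_pd: float = 2.0,
) -> dict[str, list[int]]:
    """Thickest vessel chain in the upper and lower retinal halves.

    Only segments whose centroid lies within ``max_border_pd`` PD of the
    disc border are eligible. Within each half (centroid above/below the
    disc center), the segment with the largest mean diameter seeds the main
    vessel; the chain is extended through branch nodes by repeatedly adding
    the thickest eligible incident segment. Ties break toward the lower
    segment id. Returns ``{"upper": [...ids], "lower": [...ids]}`` (a half
    with no eligible segment maps to an empty list).
    """
    diam = _segment_mean_diameters(sections)
    cy = disc.center[1]

    def eligible(seg: VesselSegment) -> bool:
        cx_, cy_ = _segment_centroid(seg)
        return seg.id in diam and disc.distance_pd(cx_, cy_) <= max_border_pd

    halves: dict[str, list[int]] = {"upper": [], "lower": []}
    for half, pred in (("upper", lambda y: y < cy), ("lower", lambda y: y >= cy)):
        cands = [s for s in graph.segments.values() if eligible(s) and pred(_segment_centroid(s)[1])]
        if not cands:
            continue
        seed = max(cands, key=lambda s: (diam[s.id], -s.id))
        chain = [seed.id]
        # grow from both ends through branch nodes
        for end_attr in ("start_node", "end_node"):
            current = seed
            nid = getattr(seed, end_attr)
            while nid is not None and graph.nodes[nid].kind == "branch":
                incident = [
                    graph.segments[s]
                    for s in graph.node_segments(nid)
                    if s not in chain and s in diam
                ]
                if not incident:
                    break
                nxt = max(incident, key=lambda s: (diam[s.id], -s.id))
                chain.append(nxt.id)
                nid = nxt.end_node if nxt.start_node == nid else nxt.start_node
                current = nxt
        halves[half] = chain
    return halves


def _direction_from_node(
    seg: VesselSegment, node_id: int, offset: int = 10, skip: int = 0
) -> np.ndarray | None:
    """Unit direction of the line fitted to ``offset`` path pixels leaving
    ``node_id`` along this segment, directed outward from the node.

    ``skip`` discards that many pixels nearest the node before fitting:
    topology-preserving thinning bends the centerline toward the junction
    bisector within roughly one vessel radius of a branch point, so the fit
    starts where the centerline again tracks the true vessel axis.
    """
    if seg.start_node == node_id:
        run = seg.path[skip : skip + offset]
    elif seg.end_node == node_id:
        run = seg.path[::-1][skip : skip + offset]
    else:
        return None
    if len(run) < offset:
        return None
    d = _fit_tangent(run)
    # orient outward: along increasing distance from the node
    if d @ (run[-1] - run[0]) < 0:
        d = -d
    return d


def branching_angles(
    graph: CenterlineGraph,
    mains: dict[str, list[int]],
    disc: OpticDisc,
    mask: np.ndarray | None = None,
    offset: int = 10,
    max_border_pd: float = 2.0,
) -> tuple[list[BranchAngleResult], float]:
    """Angles between each main vessel and its branches at branch points.

    At each branch node on a main chain within ``max_border_pd`` PD of the
    disc border, a line is fitted to the ``offset`` centerline pixels leaving
    the node along the main vessel (downstream: away from the disc) and along
    each branch; the angle between the two fitted directions, in degrees, is
    one branching-angle measurement. When the vessel ``mask`` is given, the
    pixels within one local vessel radius of the node (junction-distorted by
    thinning) are excluded before fitting. Returns all measurements and
    their mean (NaN when there are none).
    """
    main_ids = set(mains.get("upper", [])) | set(mains.get("lower", []))
    edt = ndi.distance_transform_edt(np.asarray(mask, bool)) if mask is not None else None
    results: list[BranchAngleResult] = []
    for node in graph.branch_points():
        if disc.distance_pd(*node.xy) > max_border_pd:
            continue
        incident = graph.node_segments(node.id)
        incident_main = [s for s in incident if s in main_ids]
        if not incident_main:
            continue
        skip = 0
        if edt is not None:
            r, c = node.pixels[0]
            skip = int(np.ceil(edt[r, c]))

        # downstream main arm: far end farther from the disc center
        def _far_dist(sid: int) -> float:
            seg = graph.segments[sid]
            far = seg.path[-1] if seg.start_node == node.id else seg.path[0]
            return float(np.hypot(far[0] - disc.center[0], far[1] - disc.center[1]))

        down_id = max(incident_main, key=lambda s: (_far_dist(s), -s))
        main_dir = _direction_from_node(graph.segments[down_id], node.id, offset, skip)
        if main_dir is None:
            continue
        for sid in incident:
            if sid in main_ids:
                continue
            branch_dir = _direction_from_node(graph.segments[sid], node.id, offset, skip)
            if branch_dir is None:
                continue  # branch arm shorter than the fit window
            cosang = np.clip(main_dir @ branch_dir, -1.0, 1.0)
            angle = float(np.degrees(np.arccos(cosang)))
            results.append(BranchAngleResult(node.xy, angle, down_id, sid))
    mean = float(np.mean([r.angle_deg for r in results])) if results else float("nan")
    return results, mean
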