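"""End-to-end analysis: image -> vessel mask -> centerline -> metric bundle.

``analyze_arrays`` orchestrates the pipeline on in-memory arrays; ``analyze``
wraps it for files on disk. The pipeline degrades gracefully: a failed stage
records a warning and leaves its metrics missing rather than aborting, so
population runs always produce a (possibly partial) row per image.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io as rio
from .centerline import CenterlineGraph, build_graph
from .morphometry import (
    average_diameter,
    avr,
    branching_angles,
    fractal_dimension,
    sample_curvatures,
    sample_diameters,
    select_main_vessels,
    tortuosity,
    vascular_density,
)
from .optic_disc import OpticDisc, calibrate, segment_disc
from .preprocessing import PreprocessConfig, preprocess, to_grayscale
from .segmentation import (
    VesselFilterConfig,
    average_scores,
    confusion_counts,
    otsu_threshold,
    preselect_vessels,
    scores_from_counts,
)
from .zones import ZoneSpec, aggregate_zones

__all__ = ["AnalysisConfig", "MetricsBundle", "analyze", "analyze_arrays", "evaluate", "CSV_COLUMNS"]


@dataclass
class AnalysisConfig:
    """All pipeline knobs in one round-trippable record."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    vessel_rules: VesselFilterConfig = field(default_factory=VesselFilterConfig)
    zone_spec: ZoneSpec = field(default_factory=ZoneSpec)
    diameter_step: int = 5
    tangent_window: int = 7
    arc_half: int = 25
    curvature_step: int = 1
    spur_px: float = 10.0
    tortuosity_pooling: str = "pooled"
    tortuosity_unit: str = "px"  # "px" (px^-1) or "mm" (mm^-1)
    exclude_disc_interior: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["zone_spec"] = [list(z) for z in self.zone_spec.zones]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        pp = d.pop("preprocess", {})
        if isinstance(pp.get("gray_coeffs"), list):
            pp["gray_coeffs"] = tuple(pp["gray_coeffs"])
        if isinstance(pp.get("reference_means"), list):
            pp["reference_means"] = tuple(pp["reference_means"])
        rules = d.pop("vessel_rules", {})
        zones = d.pop("zone_spec", None)
        cfg = cls(
            preprocess=PreprocessConfig(**pp),
            vessel_rules=VesselFilterConfig(**rules),
            zone_spec=ZoneSpec(tuple(tuple(z) for z in zones)) if zones else ZoneSpec(),
            **d,
        )
        return cfg


@dataclass
class MetricsBundle:
    """The full morphometric parameter vector for one image."""

    image_id: str = ""
    disc_center_x: float = float("nan")
    disc_center_y: float = float("nan")
    disc_diameter_px: float = float("nan")
    mm_per_px: float = float("nan")
    diameter_um: float = float("nan")
    diameter_artery_um: float = float("nan")
    diameter_vein_um: float = float("nan")
    diameter_px: float = float("nan")
    avr: float = float("nan")
    fractal_dimension: float = float("nan")
    branching_angle_deg: float = float("nan")
    tortuosity: float = float("nan")  # mean curvature, px^-1 (or mm^-1 per config)
    tortuosity_x1000: float = float("nan")  # conventional table scaling
    density: float = float("nan")
    n_diameter_samples: int = 0
    n_curvature_samples: int = 0
    n_branch_angles: int = 0
    zones: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_flat_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items() if k not in ("zones", "warnings")}
        for zname, zvals in self.zones.items():
            for key, val in zvals.items():
                d[f"{key}_{zname}"] = val
        d["warnings"] = ";".join(self.warnings)
        return d


_ZONE_KEYS = ["diameter_um", "diameter_artery_um", "diameter_vein_um", "avr", "tortuosity_x1000"]
CSV_COLUMNS: list[str] = (
    [
        "image_id",
        "disc_center_x",
        "disc_center_y",
        "disc_diameter_px",
        "mm_per_px",
        "diameter_um",
        "diameter_artery_um",
        "diameter_vein_um",
        "diameter_px",
        "avr",
        "fractal_dimension",
        "branching_angle_deg",
        "tortuosity",
        "tortuosity_x1000",
        "density",
        "n_diameter_samples",
        "n_curvature_samples",
        "n_branch_angles",
    ]
    + [f"{k}_{z}" for z in ("C1", "C2", "C3", "C4") for k in _ZONE_KEYS]
    + ["warnings"]
)


def assign_av_labels(graph: CenterlineGraph, av_mask: np.ndarray | None) -> None:
    """Label each segment artery/vein by majority vote over its pixels."""
    if av_mask is None:
        return
    av_mask = np.asarray(av_mask)
    names = {1: "artery", 2: "vein", 3: "unknown"}
    for seg in graph.segments.values():
        cols = seg.path[:, 0].astype(int)
        rows = seg.path[:, 1].astype(int)
        labels = av_mask[rows, cols]
        labels = labels[labels > 0]
        if labels.size:
            seg.av_label = names.get(int(np.bincount(labels).argmax()), "unknown")


def _classical_segmentation(image: np.ndarray, cfg: AnalysisConfig):
    """Preprocess an RGB fundus image and extract a classical vessel mask."""
    enhanced, rgb, roi = preprocess(image, cfg.preprocess)
    thr = otsu_threshold(enhanced, roi)
    dark = (enhanced < thr) & roi
    mask = preselect_vessels(dark, roi, cfg.vessel_rules)
    return mask, roi, enhanced


def analyze_arrays(
    image: np.ndarray | None,
    mask: np.ndarray | None = None,
    av_mask: np.ndarray | None = None,
    roi: np.ndarray | None = None,
    disc: OpticDisc | None = None,
    disc_seed: tuple[float, float] | None = None,
    config: AnalysisConfig | None = None,
    image_id: str = "",
) -> MetricsBundle:
    """Run the morphometry pipeline on in-memory inputs.

    Either an RGB ``image`` (classical segmentation + disc detection) or an
    externally produced vessel ``mask`` must be given; with both, the mask is
    ingested and the image is used only for disc geometry. A pre-calibrated
    ``disc`` bypasses disc segmentation entirely.
    """
    cfg = config or AnalysisConfig()
    bundle = MetricsBundle(image_id=image_id)
    if image is None and mask is None:
        raise ValueError("need an image or a vessel mask")
    if image is not None and mask is not None and image.shape[:2] != np.asarray(mask).shape:
        raise ValueError("image and mask dimensions differ")
    if mask is not None and av_mask is not None and np.asarray(av_mask).shape != np.asarray(mask).shape:
        raise ValueError("mask and A/V mask dimensions differ")

    if mask is None:
        mask, roi_auto, _ = _classical_segmentation(image, cfg)
        bundle.warnings.append("classical segmentation used (no vessel mask supplied)")
        if roi is None:
            roi = roi_auto
    mask = np.asarray(mask, bool)
    if roi is None:
        roi = np.ones_like(mask)
        bundle.warnings.append("no ROI supplied; using the full frame")
    mask = mask & roi

    if disc is None and image is not None:
        try:
            gray = to_grayscale(image) if image.ndim == 3 else np.asarray(image, float)
            disc = segment_disc(gray, roi=roi, seed=disc_seed)
        except Exception as exc:  # disc failure is non-fatal
            bundle.warnings.append(f"disc segmentation failed: {exc}")
            disc = None
    if disc is not None:
        bundle.disc_center_x, bundle.disc_center_y = disc.center
        bundle.disc_diameter_px = disc.diameter_px
        bundle.mm_per_px = disc.mm_per_px
    else:
        bundle.warnings.append("no disc geometry; micrometre and zonal metrics unavailable")

    if not mask.any():
        bundle.warnings.append("empty vessel mask; no morphometry computed")
        return bundle

    skel, graph = build_graph(mask, min_spur_px=cfg.spur_px)
    assign_av_labels(graph, av_mask)

    analysis_mask = mask
    if cfg.exclude_disc_interior and disc is not None:
        yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
        inside = np.hypot(xx - disc.center[0], yy - disc.center[1]) <= disc.radius_px
        analysis_mask = mask & ~inside

    sections = sample_diameters(
        analysis_mask, graph, step=cfg.diameter_step, tangent_window=cfg.tangent_window, disc=disc
    )
    curvatures = sample_curvatures(graph, arc_half=cfg.arc_half, step=cfg.curvature_step)

    bundle.n_diameter_samples = len(sections)
    bundle.n_curvature_samples = len(curvatures)
    bundle.diameter_px = average_diameter(sections, unit="px")
    bundle.diameter_um = average_diameter(sections)
    a = average_diameter(sections, label="artery")
    v = average_diameter(sections, label="vein")
    bundle.diameter_artery_um = a
    bundle.diameter_vein_um = v
    if np.isfinite(a) and np.isfinite(v) and v > 0:
        bundle.avr = avr(a, v)

    per_mm = disc.mm_per_px if (disc is not None and cfg.tortuosity_unit == "mm") else None
    tort = tortuosity(curvatures, pooling=cfg.tortuosity_pooling, per_mm=per_mm)
    bundle.tortuosity = tort
    bundle.tortuosity_x1000 = tort * 1000.0

    try:
        bundle.fractal_dimension = fractal_dimension(analysis_mask)
    except ValueError as exc:
        bundle.warnings.append(f"fractal dimension failed: {exc}")
    bundle.density = vascular_density(analysis_mask, roi).rho

    if disc is not None:
        mains = select_main_vessels(graph, sections, disc)
        angles, mean_angle = branching_angles(graph, mains, disc, mask=mask)
        bundle.n_branch_angles = len(angles)
        bundle.branching_angle_deg = mean_angle
        zm = aggregate_zones(sections, curvatures, disc, cfg.zone_spec)
        for z in cfg.zone_spec.names:
            bundle.zones[z] = {
                "diameter_um": zm.diameter_um[z],
                "diameter_artery_um": zm.diameter_artery_um[z],
                "diameter_vein_um": zm.diameter_vein_um[z],
                "avr": zm.avr[z],
                "tortuosity_x1000": zm.tortuosity[z] * 1000.0,
                "n_diameter": zm.n_diameter[z],
                "n_curvature": zm.n_curvature[z],
            }
    return bundle


def analyze(
    image_path: str | Path | None,
    mask_path: str | Path | None = None,
    av_path: str | Path | None = None,
    disc_seed: tuple[float, float] | None = None,
    disc_diameter_px: float | None = None,
    config: AnalysisConfig | None = None,
) -> MetricsBundle:
    """File-based pipeline entry point; see ``analyze_arrays``."""
    image = rio.read_image(image_path) if image_path else None
    mask = rio.read_mask(mask_path) if mask_path else None
    av = rio.read_av_mask(av_path) if av_path else None
    disc = None
    if disc_seed is not None and disc_diameter_px is not None:
        disc = calibrate(disc_seed, disc_diameter_px)
        disc_seed = None
    name = Path(image_path or mask_path).stem
    return analyze_arrays(
        image, mask, av, disc=disc, disc_seed=disc_seed, config=config, image_id=name
    )


def evaluate(
    pred_path: str | Path,
    truth_path: str | Path,
    roi_path: str | Path | None = None,
) -> dict:
    """Score a predicted mask file against ground truth; see segmentation module."""
    pred = rio.read_mask(pred_path)
    truth = rio.read_mask(truth_path)
    roi = rio.read_mask(roi_path) if roi_path else None
    counts = confusion_counts(pred, truth, roi)
    scores = scores_from_counts(counts)
    return {
        "tp": counts.tp,
        "tn": counts.tn,
        "fp": counts.fp,
        "fn": counts.fn,
        **scores.as_dict(),
    }
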