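"""Peripapillary zonal analysis: the C1-C4 annuli around the optic disc.

Measurements are binned by the distance of their centerline point from the
optic disc BORDER, expressed in papillary diameters (PD): C1 spans
0.5-1.0 PD, C2 1.0-1.5 PD, C3 1.5-2.0 PD, C4 2.0-2.5 PD. Intervals are
half-open [inner, outer), so a point at exactly 1.0 PD belongs to C2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .morphometry import CrossSection, CurvatureSample, average_diameter, avr, tortuosity
from .optic_disc import OpticDisc

__all__ = ["ZoneSpec", "ZoneMetrics", "zone_of", "aggregate_zones", "DEFAULT_ZONES"]

DEFAULT_ZONES: tuple[tuple[str, float, float], ...] = (
    ("C1", 0.5, 1.0),
    ("C2", 1.0, 1.5),
    ("C3", 1.5, 2.0),
    ("C4", 2.0, 2.5),
)


@dataclass(frozen=True)
class ZoneSpec:
    """Annular zones as (name, inner_pd, outer_pd) from the disc border."""

    zones: tuple[tuple[str, float, float], ...] = DEFAULT_ZONES

    def __post_init__(self) -> None:
        prev_outer = -np.inf
        for name, inner, outer in self.zones:
            if not inner < outer:
                raise ValueError(f"zone {name}: inner must be < outer")
            if inner < prev_outer:
                raise ValueError(f"zone {name} overlaps its predecessor")
            prev_outer = outer

    @property
    def names(self) -> list[str]:
        return [z[0] for z in self.zones]


@dataclass
class ZoneMetrics:
    """Per-zone aggregates; zones without samples report NaN."""

    diameter_um: dict[str, float] = field(default_factory=dict)
    diameter_artery_um: dict[str, float] = field(default_factory=dict)
    diameter_vein_um: dict[str, float] = field(default_factory=dict)
    avr: dict[str, float] = field(default_factory=dict)
    tortuosity: dict[str, float] = field(default_factory=dict)
    n_diameter: dict[str, int] = field(default_factory=dict)
    n_curvature: dict[str, int] = field(default_factory=dict)


def zone_of(point: tuple[float, float], disc: OpticDisc, spec: ZoneSpec | None = None) -> str | None:
    """Zone name containing ``point`` or None (inside/outside all annuli).

    The distance from the disc border in PD units is
    ``(||point - center|| - PD/2) / PD``; the point falls in the zone whose
    half-open interval [inner, outer) contains it.
    """
    spec = spec or ZoneSpec()
    d = disc.distance_pd(point[0], point[1])
    for name, inner, outer in spec.zones:
        if inner <= d < outer:
            return name
    return None


def aggregate_zones(
    sections: list[CrossSection],
    curvatures: list[CurvatureSample],
    disc: OpticDisc,
    spec: ZoneSpec | None = None,
) -> ZoneMetrics:
    """Per-zone mean diameter (all/artery/vein), AVR and tortuosity.

    A cross-section belongs to the zone of its centerline point; curvature
    samples to the zone of point A.
    """
    spec = spec or ZoneSpec()
    zm = ZoneMetrics()
    sec_by_zone: dict[str, list[CrossSection]] = {n: [] for n in spec.names}
    cur_by_zone: dict[str, list[CurvatureSample]] = {n: [] for n in spec.names}
    for s in sections:
        z = zone_of(s.center, disc, spec)
        if z is not None:
            sec_by_zone[z].append(s)
    for c in curvatures:
        z = zone_of(c.point, disc, spec)
        if z is not None:
            cur_by_zone[z].append(c)
    for name in spec.names:
        secs = sec_by_zone[name]
        zm.n_diameter[name] = len(secs)
        zm.n_curvature[name] = len(cur_by_zone[name])
        zm.diameter_um[name] = average_diameter(secs) if secs else float("nan")
        a = average_diameter(secs, label="artery") if secs else float("nan")
        v = average_diameter(secs, label="vein") if secs else float("nan")
        zm.diameter_artery_um[name] = a
        zm.diameter_vein_um[name] = v
        zm.avr[name] = avr(a, v) if np.isfinite(a) and np.isfinite(v) and v > 0 else float("nan")
        zm.tortuosity[name] = tortuosity(cur_by_zone[name]) if cur_by_zone[name] else float("nan")
    return zm
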