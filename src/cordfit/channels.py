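"""Guiding-channel layout and clearance checking.

A guiding device is an elliptical cylinder of a chosen length whose straight
cylindrical channels carry peripheral nerve grafts obliquely from a white
matter tract anchor on one end face to a gray matter target on the other:
descending channels run from cranial tract anchors (for example the lateral
corticospinal tract) to caudal ventral-horn gray, ascending channels from
caudal dorsal-column anchors to cranial dorsal gray.

Coordinates: x transverse (+right), y anteroposterior (+dorsal), z from the
cranial face (0) to the caudal face (device length); all mm.  Feasibility
requires a minimum material wall between any two channels and between each
channel and the outer ellipse; because the device is a convex cylinder and
channels are straight, checking both end faces bounds every intermediate
cross-section.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
import numpy as np
from scipy.optimize import brentq
from shapely.geometry import LineString, Point, Polygon, box

from .catalog import EllipseInterface, InterfaceCatalog
from .contours import CrossSection
from .fit import assign_best_device

__all__ = [
    "DEVICE_LENGTHS",
    "TractSpec",
    "ChannelLayoutConfig",
    "AnchorSet",
    "Channel",
    "DeviceModel",
    "ClearanceReport",
    "ClearanceError",
    "derive_anchor_set",
    "plan_channels",
    "check_clearance",
    "channel_deviation",
    "segment_segment_distance",
    "point_to_ellipse_edge",
]

#: Manufactured device lengths, mm (5-mm increments over the short thoracic range).
DEVICE_LENGTHS: tuple[int, ...] = (15, 20, 25, 30, 35, 40)

DEFAULT_WALL_MM = 0.4


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------


def segment_segment_distance(p1: np.ndarray, q1: np.ndarray, p2: np.ndarray, q2: np.ndarray) -> float:
    """Minimum distance between 3D segments [p1, q1] and [p2, q2].

    Closed-form clamped quadratic minimization (no sampling).
    """
    p1, q1, p2, q2 = (np.asarray(v, dtype=float) for v in (p1, q1, p2, q2))
    d1, d2 = q1 - p1, q2 - p2
    r = p1 - p2
    a, e, f = d1 @ d1, d2 @ d2, d2 @ r
    eps = 1e-14
    if a <= eps and e <= eps:
        return float(np.linalg.norm(r))
    if a <= eps:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = d1 @ r
        if e <= eps:
            t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
        else:
            b = d1 @ d2
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > eps else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t, s = 1.0, np.clip((b - c) / a, 0.0, 1.0)
    closest1 = p1 + s * d1
    closest2 = p2 + t * d2
    return float(np.linalg.norm(closest1 - closest2))


def point_to_ellipse_edge(x: float, y: float, transverse_mm: float, ap_mm: float) -> float:
    """Signed distance from a point to the ellipse boundary (positive inside).

    The ellipse has diameters ``transverse_mm`` (x) and ``ap_mm`` (y) and is
    centered at the origin.  Uses the standard one-dimensional root-finding
    formulation of the closest-point problem.
    """
    a, b = transverse_mm / 2.0, ap_mm / 2.0
    px, py = abs(x), abs(y)
    inside = (px / a) ** 2 + (py / b) ** 2 <= 1.0
    if px < 1e-12 and py < 1e-12:
        return min(a, b)
    # order axes so a_ >= b_ with matching coordinates
    if a >= b:
        a_, b_, u, v = a, b, px, py
    else:
        a_, b_, u, v = b, a, py, px
    if v < 1e-12:
        # point on the major axis: the nearest point can be off-axis
        if u < (a_ * a_ - b_ * b_) / a_:
            xc = a_ * a_ * u / (a_ * a_ - b_ * b_)
            yc = b_ * math.sqrt(max(0.0, 1.0 - (xc / a_) ** 2))
            d = math.hypot(u - xc, yc)
        else:
            d = abs(a_ - u)
        return d if inside else -d
    if u < 1e-12:
        # on the minor axis the co-vertex is nearest (for interior points)
        d = abs(b_ - v) if inside else abs(v - b_)
        return d if inside else -d

    def f(t: float) -> float:
        return (a_ * u / (t + a_ * a_)) ** 2 + (b_ * v / (t + b_ * b_)) ** 2 - 1.0

    t_lo = -b_ * b_ + 1e-12
    t_hi = max(a_ * u, b_ * v) + a_ * a_  # f(t_hi) < 0 for this bracket
    while f(t_hi) > 0:
        t_hi *= 2.0
    t = brentq(f, t_lo, t_hi, xtol=1e-13)
    xc = a_ * a_ * u / (t + a_ * a_)
    yc = b_ * b_ * v / (t + b_ * b_)
    d = math.hypot(u - xc, v - yc)
    return d if inside else -d


# ---------------------------------------------------------------------------
# Layout configuration and anchor derivation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TractSpec:
    """A white-matter tract anchor given relative to the cord anatomy.

    ``angle_deg`` is the polar angle from the dorsal midline (+y axis)
    toward the right; the anchor sits on that ray at ``radial_fraction`` of
    the way from the gray-matter boundary to the outer contour.  A mirrored
    left-side anchor is always added.
    """

    name: str
    angle_deg: float
    radial_fraction: float
    direction: str  # "descending" | "ascending"

    def __post_init__(self) -> None:
        if not 0.0 <= self.radial_fraction <= 1.0:
            raise ValueError("radial_fraction must be in [0, 1]")
        if self.direction not in ("descending", "ascending"):
            raise ValueError("direction must be 'descending' or 'ascending'")


@dataclass(frozen=True)
class ChannelLayoutConfig:
    """Channel layout: tract anchors, channel radius, wall thickness.

    Default tracts are illustrative rather than clinically prescriptive:
    the lateral corticospinal tract in the dorsolateral funiculus
    (descending) and the dorsal columns flanking the dorsal midline
    (ascending), one channel per side each.
    """

    tracts: tuple[TractSpec, ...] = (
        TractSpec("corticospinal", angle_deg=55.0, radial_fraction=0.5, direction="descending"),
        TractSpec("dorsal_column", angle_deg=20.0, radial_fraction=0.45, direction="ascending"),
    )
    channel_radius_mm: float = 0.4
    wall_min_mm: float = DEFAULT_WALL_MM
    #: ascending channels exit into the dorsal-intermediate gray: the dorsal
    #: target is the centroid of the dorsal gray clipped to this fraction of
    #: the gray half-width, keeping it medial to the descending channels
    dorsal_target_medial_frac: float = 0.55

    def __post_init__(self) -> None:
        if self.channel_radius_mm <= 0:
            raise ValueError("channel radius must be positive")
        if self.wall_min_mm < 0:
            raise ValueError("wall thickness cannot be negative")
        if not 0.0 < self.dorsal_target_medial_frac <= 1.0:
            raise ValueError("dorsal_target_medial_frac must be in (0, 1]")


@dataclass(frozen=True)
class AnchorSet:
    """Labeled tract anchors and gray-matter targets on both end faces.

    Keys are ``"<tract>_left"`` / ``"<tract>_right"``; values (x, y) mm.
    Descending channels pair ``cranial_anchors`` with ``caudal_targets``;
    ascending channels pair ``caudal_anchors`` with ``cranial_targets``.
    """

    cranial_anchors: dict[str, tuple[float, float]]
    caudal_targets: dict[str, tuple[float, float]]
    caudal_anchors: dict[str, tuple[float, float]]
    cranial_targets: dict[str, tuple[float, float]]
    pairs: tuple[tuple[str, str, str], ...]  # (direction, anchor_label, target_label)

    def all_points(self) -> dict[str, tuple[float, float]]:
        out: dict[str, tuple[float, float]] = {}
        for d in (self.cranial_anchors, self.caudal_targets, self.caudal_anchors, self.cranial_targets):
            out.update(d)
        return out


def _ray_crossings(poly: Polygon, angle_deg: float, reach: float) -> tuple[float, float]:
    """(entry, exit) distances of the ray from the origin through a polygon."""
    u = np.array([math.sin(math.radians(angle_deg)), math.cos(math.radians(angle_deg))])
    ray = LineString([(0.0, 0.0), tuple(u * reach)])
    hit = ray.intersection(poly.exterior)
    if hit.is_empty:
        raise ValueError(f"ray at {angle_deg} deg does not reach the contour")
    pts = [hit] if hit.geom_type == "Point" else list(hit.geoms)
    dists = sorted(math.hypot(p.x, p.y) for p in pts)
    return dists[0], dists[-1]


def _side_region_centroid(poly: Polygon, dorsal: bool, reach: float,
                          max_x: float | None = None) -> tuple[float, float]:
    ymin, ymax = (0.0, reach) if dorsal else (-reach, 0.0)
    region = poly.intersection(box(0.0, ymin, max_x if max_x is not None else reach, ymax))
    if region.is_empty:
        raise ValueError("gray matter has no area in the requested quadrant")
    c = region.centroid
    return float(c.x), float(c.y)


def derive_anchor_set(cs: CrossSection, layout: ChannelLayoutConfig = ChannelLayoutConfig()) -> AnchorSet:
    """Place tract anchors and gray targets on a symmetric cross-section.

    Each tract anchor lies on its configured ray at the configured fraction
    between the gray boundary and the outer contour, guaranteeing a white
    matter position; descending targets are the ventral-horn centroids and
    ascending targets the dorsal gray centroids.  The right side is
    computed and mirrored, so anchor pairs are exactly symmetric.
    """
    outer_poly, gray_poly = cs.outer.polygon, cs.gray.polygon
    reach = max(cs.outer.width_height()) * 2.0
    cranial_anchors: dict[str, tuple[float, float]] = {}
    caudal_anchors: dict[str, tuple[float, float]] = {}
    pairs: list[tuple[str, str, str]] = []

    vh = _side_region_centroid(gray_poly, dorsal=False, reach=reach)
    gray_halfwidth = gray_poly.bounds[2]
    dg = _side_region_centroid(gray_poly, dorsal=True, reach=reach,
                               max_x=layout.dorsal_target_medial_frac * gray_halfwidth)
    if not gray_poly.contains(Point(vh)):
        raise ValueError("ventral-horn centroid fell outside the gray contour")
    if not gray_poly.contains(Point(dg)):
        raise ValueError("dorsal gray centroid fell outside the gray contour")
    caudal_targets = {"ventral_horn_right": vh, "ventral_horn_left": (-vh[0], vh[1])}
    cranial_targets = {"dorsal_gray_right": dg, "dorsal_gray_left": (-dg[0], dg[1])}

    for tract in layout.tracts:
        _, r_gray = _ray_crossings(gray_poly, tract.angle_deg, reach)
        _, r_outer = _ray_crossings(outer_poly, tract.angle_deg, reach)
        if r_outer <= r_gray:
            raise ValueError(f"tract {tract.name!r}: ray leaves no white matter at {tract.angle_deg} deg")
        r = r_gray + tract.radial_fraction * (r_outer - r_gray)
        u = (math.sin(math.radians(tract.angle_deg)), math.cos(math.radians(tract.angle_deg)))
        pt = (r * u[0], r * u[1])
        if not outer_poly.contains(Point(pt)) or gray_poly.contains(Point(pt)):
            raise ValueError(f"tract {tract.name!r}: anchor is not in white matter")
        for side, p in (("right", pt), ("left", (-pt[0], pt[1]))):
            label = f"{tract.name}_{side}"
            if tract.direction == "descending":
                cranial_anchors[label] = p
                pairs.append(("descending", label, f"ventral_horn_{side}"))
            else:
                caudal_anchors[label] = p
                pairs.append(("ascending", label, f"dorsal_gray_{side}"))
    return AnchorSet(
        cranial_anchors=cranial_anchors,
        caudal_targets=caudal_targets,
        caudal_anchors=caudal_anchors,
        cranial_targets=cranial_targets,
        pairs=tuple(pairs),
    )


# ---------------------------------------------------------------------------
# Channels and devices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Channel:
    """One straight cylindrical graft channel through the device."""

    label: str
    direction: str
    entry_xy: tuple[float, float]  # on the face where axons enter
    exit_xy: tuple[float, float]
    radius_mm: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("channel radius must be positive")
        if self.direction not in ("descending", "ascending"):
            raise ValueError("direction must be 'descending' or 'ascending'")

    def axis(self, length_mm: float) -> tuple[np.ndarray, np.ndarray]:
        """3D axis endpoints (cranial point first)."""
        if self.direction == "descending":
            return (np.array([*self.entry_xy, 0.0]), np.array([*self.exit_xy, length_mm]))
        return (np.array([*self.exit_xy, 0.0]), np.array([*self.entry_xy, length_mm]))


@dataclass(frozen=True)
class DeviceModel:
    """An interface ellipse extruded to a device length, with its channels."""

    interface: EllipseInterface
    length_mm: float
    channels: tuple[Channel, ...] = ()

    def __post_init__(self) -> None:
        if self.length_mm not in DEVICE_LENGTHS:
            raise ValueError(f"device length must be one of {DEVICE_LENGTHS} mm")

    @property
    def id(self) -> str:
        return f"{self.interface.id} L{self.length_mm:g}"


@dataclass(frozen=True)
class ClearanceReport:
    """Result of the wall-thickness check for one device."""

    wall_min_mm: float
    min_wall_mm: float
    violating_pairs: tuple[tuple[str, str, float], ...]
    boundary_margins_mm: dict[str, float]
    passed: bool

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "wall_min_mm": self.wall_min_mm,
            "min_wall_mm": self.min_wall_mm,
            "violating_pairs": [list(v) for v in self.violating_pairs],
            "boundary_margins_mm": self.boundary_margins_mm,
            "passed": self.passed,
        }, indent=2))


class ClearanceError(ValueError):
    """Raised when a channel layout violates the wall constraints."""

    def __init__(self, report: ClearanceReport):
        self.report = report
        super().__init__(
            f"channel layout infeasible: min wall {report.min_wall_mm:.3f} mm "
            f"(required {report.wall_min_mm} mm), "
            f"{len(report.violating_pairs)} violating pair(s)"
        )


def check_clearance(device: DeviceModel, wall_min: float = DEFAULT_WALL_MM) -> ClearanceReport:
    """Check pairwise channel walls and channel-to-boundary margins.

    The wall between two channels is the minimum distance between their 3D
    axis segments minus both radii.  The boundary margin of a channel is
    the distance from its axis to the interface ellipse, evaluated at both
    end faces minus the radius — conservative and exact for a straight
    channel in a convex elliptical cylinder.
    """
    channels = device.channels
    axes = [c.axis(device.length_mm) for c in channels]
    min_wall = math.inf
    violating = []
    for i in range(len(channels)):
        for j in range(i + 1, len(channels)):
            d = segment_segment_distance(*axes[i], *axes[j])
            wall = d - channels[i].radius_mm - channels[j].radius_mm
            min_wall = min(min_wall, wall)
            if wall < wall_min:
                violating.append((channels[i].label, channels[j].label, wall))
    margins = {}
    for c in channels:
        m = min(
            point_to_ellipse_edge(*c.entry_xy, device.interface.transverse_mm, device.interface.ap_mm),
            point_to_ellipse_edge(*c.exit_xy, device.interface.transverse_mm, device.interface.ap_mm),
        ) - c.radius_mm
        margins[c.label] = m
    ok = not violating and all(m >= wall_min for m in margins.values())
    return ClearanceReport(
        wall_min_mm=wall_min,
        min_wall_mm=min_wall if channels else math.inf,
        violating_pairs=tuple(violating),
        boundary_margins_mm=margins,
        passed=bool(ok),
    )


def build_channels(anchors: AnchorSet, layout: ChannelLayoutConfig) -> tuple[Channel, ...]:
    """One straight channel per configured (anchor, target) pair, unvalidated."""
    channels = []
    for direction, anchor_label, target_label in anchors.pairs:
        if direction == "descending":
            entry = anchors.cranial_anchors[anchor_label]
            exit_ = anchors.caudal_targets[target_label]
        else:
            entry = anchors.caudal_anchors[anchor_label]
            exit_ = anchors.cranial_targets[target_label]
        channels.append(Channel(
            label=f"{anchor_label}->{target_label}",
            direction=direction,
            entry_xy=entry,
            exit_xy=exit_,
            radius_mm=layout.channel_radius_mm,
        ))
    return tuple(channels)


def plan_channels(
    anchors: AnchorSet,
    interface: EllipseInterface,
    length_mm: float,
    layout: ChannelLayoutConfig = ChannelLayoutConfig(),
) -> DeviceModel:
    """Build the straight-channel device and verify its clearance.

    One channel per configured (anchor, target) pair: descending channels
    enter at cranial tract anchors and exit at caudal gray targets,
    ascending channels the reverse.  Raises :class:`ClearanceError`
    carrying the full report when the layout is infeasible.
    """
    device = DeviceModel(interface=interface, length_mm=length_mm,
                         channels=build_channels(anchors, layout))
    report = check_clearance(device, layout.wall_min_mm)
    if not report.passed:
        raise ClearanceError(report)
    return device


def channel_deviation(
    transverse_mm: float,
    ap_mm: float,
    catalog: InterfaceCatalog,
    anchors: AnchorSet,
    device_id: str | None = None,
) -> tuple[str, dict[str, float]]:
    """Deviation (mm) of each anchor between the device and a scaled cord.

    The anchors live on a cross-section scaled to the best-fitting device's
    diameters; overlaying the same anatomy on a simulated cord of size
    (T_s, AP_s) moves an anchor at (x, y) to (x * T_s/T_d, y * AP_s/AP_d).
    The reported deviation is the Euclidean distance between the two, a
    quantitative form of channel-to-anatomy alignment: it vanishes at the
    device midpoint and is bounded by half the sample's Euclidean
    error-of-fit for anchors inside the ellipse.
    """
    if device_id is None:
        device_id = assign_best_device(transverse_mm, ap_mm, catalog)
    device = catalog[device_id]
    fx = transverse_mm / device.transverse_mm
    fy = ap_mm / device.ap_mm
    deviations = {
        label: math.hypot(x * (fx - 1.0), y * (fy - 1.0))
        for label, (x, y) in anchors.all_points().items()
    }
    return device_id, deviations
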