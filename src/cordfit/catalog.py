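"""Elliptical device interface catalogs.

A guiding device meets the cord with an elliptical cross-section described
by its transverse and anteroposterior (AP) diameters.  The analysis set
holds seven interfaces in three shape classes — three "normal" ellipses at
the mean thoracic RAPT, two "round" (higher RAPT) and two "flat" (lower
RAPT) — plus one oversized safety ellipse per class that is carried in the
catalog but excluded from error-of-fit statistics.

Two construction routes are provided:

* :func:`build_configured_catalog` places the ellipses from explicit
  configuration (defaulting to percentiles of a simulated thoracic
  population), mirroring a by-hand centered placement; and
* :func:`optimize_catalog` chooses the seven ellipses by direct multi-restart
  minimization of one of the four error-of-fit summary statistics on a
  simulated sample, which makes the placement reproducible and auditable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.cluster.vq import kmeans2
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from .morphometry import mean_thoracic_rapt

__all__ = [
    "SHAPE_CLASSES",
    "EllipseInterface",
    "InterfaceCatalog",
    "CatalogConfig",
    "ellipse_area",
    "build_configured_catalog",
    "optimize_catalog",
]

SHAPE_CLASSES = ("normal", "round", "flat")

_RAPT_CLASS_TOL = 1e-6


@dataclass(frozen=True)
class EllipseInterface:
    """One elliptical device cross-section."""

    id: str
    shape_class: str
    transverse_mm: float
    ap_mm: float
    oversized: bool = False

    def __post_init__(self) -> None:
        if self.shape_class not in SHAPE_CLASSES:
            raise ValueError(f"unknown shape class {self.shape_class!r}")
        if not (self.transverse_mm > 0 and self.ap_mm > 0):
            raise ValueError(f"interface {self.id!r}: diameters must be positive")

    @property
    def rapt(self) -> float:
        return self.ap_mm / self.transverse_mm

    @property
    def area_mm2(self) -> float:
        return ellipse_area(self)


def ellipse_area(interface: EllipseInterface) -> float:
    """Ellipse area pi * T * AP / 4 in mm^2."""
    return math.pi * interface.transverse_mm * interface.ap_mm / 4.0


@dataclass(frozen=True)
class InterfaceCatalog:
    """A set of device interfaces: 7 analysis sizes plus 3 oversized ones.

    Shape-class structure (3 normal + 2 round + 2 flat among the analysis
    sizes, exactly one oversized ellipse per class) and id uniqueness are
    enforced at construction.
    """

    interfaces: tuple[EllipseInterface, ...]

    def __post_init__(self) -> None:
        ids = [i.id for i in self.interfaces]
        if len(set(ids)) != len(ids):
            raise ValueError("interface ids must be unique")
        keyed = {(i.transverse_mm, i.ap_mm, i.oversized) for i in self.interfaces}
        if len(keyed) != len(self.interfaces):
            raise ValueError("duplicate interface geometry in catalog")
        analysis = [i for i in self.interfaces if not i.oversized]
        oversized = [i for i in self.interfaces if i.oversized]
        counts = {c: sum(1 for i in analysis if i.shape_class == c) for c in SHAPE_CLASSES}
        if counts != {"normal": 3, "round": 2, "flat": 2}:
            raise ValueError(f"analysis set must be 3 normal / 2 round / 2 flat, got {counts}")
        over_counts = {c: sum(1 for i in oversized if i.shape_class == c) for c in SHAPE_CLASSES}
        if over_counts != {"normal": 1, "round": 1, "flat": 1}:
            raise ValueError("need exactly one oversized interface per shape class")

    def analysis_interfaces(self) -> tuple[EllipseInterface, ...]:
        return tuple(i for i in self.interfaces if not i.oversized)

    def __len__(self) -> int:
        return len(self.interfaces)

    def __getitem__(self, device_id: str) -> EllipseInterface:
        for i in self.interfaces:
            if i.id == device_id:
                return i
        raise KeyError(device_id)

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "id": i.id,
                "shape_class": i.shape_class,
                "transverse_mm": i.transverse_mm,
                "ap_mm": i.ap_mm,
                "oversized": i.oversized,
            }
            for i in self.interfaces
        ]
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "InterfaceCatalog":
        payload = json.loads(Path(path).read_text())
        return cls(tuple(EllipseInterface(**item) for item in payload))


@dataclass(frozen=True)
class CatalogConfig:
    """Configuration of the explicitly placed catalog.

    ``normal_transverse_mm`` gives the three normal-class transverse
    diameters; if None they default to the ``normal_percentiles`` of the
    pooled thoracic transverse diameters of ``population`` (default
    15/50/85 — wide enough that the central size keeps the dominant
    assignment basin, i.e. the catalog stays visibly centered).  Round and
    flat ellipses sit at the two outer normal sizes with the class RAPT
    obtained by multiplying the mean thoracic RAPT by ``rapt_round`` /
    ``rapt_flat``.  Oversized safety ellipses scale the largest member of
    each class by ``oversized_scale`` on both diameters.
    """

    normal_transverse_mm: tuple[float, float, float] | None = None
    normal_percentiles: tuple[float, float, float] = (15.0, 50.0, 85.0)
    rapt_round: float = 1.12
    rapt_flat: float = 0.88
    oversized_scale: float = 1.15

    def __post_init__(self) -> None:
        if self.rapt_round <= 0 or self.rapt_flat <= 0:
            raise ValueError("RAPT multipliers must be positive")
        if not self.rapt_flat <= 1.0 <= self.rapt_round:
            raise ValueError("require rapt_flat <= 1 <= rapt_round")
        if self.oversized_scale <= 1.0:
            raise ValueError("oversized_scale must exceed 1")


def _add_oversized(analysis: Sequence[EllipseInterface], scale: float) -> tuple[EllipseInterface, ...]:
    out = list(analysis)
    for cls in SHAPE_CLASSES:
        largest = max((i for i in analysis if i.shape_class == cls), key=lambda i: i.area_mm2)
        out.append(EllipseInterface(
            id=f"{cls} large",
            shape_class=cls,
            transverse_mm=largest.transverse_mm * scale,
            ap_mm=largest.ap_mm * scale,
            oversized=True,
        ))
    return tuple(out)


def build_configured_catalog(table, config: CatalogConfig = CatalogConfig(), population=None) -> InterfaceCatalog:
    """Build the 7 + 3 interface catalog from explicit configuration.

    Parameters
    ----------
    table : pandas.DataFrame
        Morphometry table (fixes the mean thoracic RAPT).
    config : CatalogConfig
        Placement parameters; see :class:`CatalogConfig`.
    population : SimulatedPopulation, optional
        Thoracic sample used to derive default normal sizes when
        ``config.normal_transverse_mm`` is None.
    """
    rapt_normal = mean_thoracic_rapt(table)
    if config.normal_transverse_mm is not None:
        t_normals = tuple(sorted(config.normal_transverse_mm))
    else:
        if population is None:
            raise ValueError("need either explicit normal sizes or a population for percentile defaults")
        pooled = population.samples["transverse_mm"].to_numpy(float)
        t_normals = tuple(np.percentile(pooled, list(config.normal_percentiles)))

    interfaces = [
        EllipseInterface(f"normal {k + 1}", "normal", t, t * rapt_normal)
        for k, t in enumerate(t_normals)
    ]
    t_lo, t_hi = t_normals[0], t_normals[-1]
    for k, t in enumerate((t_lo, t_hi)):
        interfaces.append(EllipseInterface(f"round {k + 1}", "round", t, t * rapt_normal * config.rapt_round))
        interfaces.append(EllipseInterface(f"flat {k + 1}", "flat", t, t * rapt_normal * config.rapt_flat))
    return InterfaceCatalog(_add_oversized(interfaces, config.oversized_scale))


# ---------------------------------------------------------------------------
# Direct optimization of the seven analysis ellipses
# ---------------------------------------------------------------------------

OBJECTIVES = ("mean_euclid", "median_euclid", "p95_euclid", "mean_area")


def _objective_value(points: np.ndarray, centers: np.ndarray, objective: str) -> float:
    """Error-of-fit statistic for nearest-Euclidean assignment to ``centers``.

    ``points`` and ``centers`` are (n, 2) / (k, 2) arrays of (transverse, AP)
    diameters.  Assignment always minimizes Euclidean distance in diameter
    space; the area objective then scores the assigned pairs by absolute
    ellipse-area mismatch.
    """
    d = cdist(points, centers)
    lab = np.argmin(d, axis=1)
    if objective == "mean_euclid":
        return float(d[np.arange(len(points)), lab].mean())
    if objective == "median_euclid":
        return float(np.median(d[np.arange(len(points)), lab]))
    if objective == "p95_euclid":
        return float(np.percentile(d[np.arange(len(points)), lab], 95))
    if objective == "mean_area":
        area_pts = math.pi * points[:, 0] * points[:, 1] / 4.0
        area_dev = math.pi * centers[:, 0] * centers[:, 1] / 4.0
        return float(np.abs(area_pts - area_dev[lab]).mean())
    raise ValueError(f"unknown objective {objective!r}")


def _geometric_median(pts: np.ndarray, iters: int = 64, tol: float = 1e-10) -> np.ndarray:
    """Weiszfeld iteration for the 2D geometric median."""
    x = pts.mean(axis=0)
    for _ in range(iters):
        d = np.linalg.norm(pts - x, axis=1)
        d = np.where(d < 1e-12, 1e-12, d)
        x_new = (pts / d[:, None]).sum(axis=0) / (1.0 / d).sum()
        if np.linalg.norm(x_new - x) < tol:
            return x_new
        x = x_new
    return x


def _kmedian_refine(points: np.ndarray, centers: np.ndarray, iters: int = 40) -> np.ndarray:
    """Alternate nearest assignment with per-cluster geometric medians.

    Each step does not increase the mean Euclidean assignment distance, so
    this is a fast local descent for the mean-distance objective and a good
    warm start for the others.
    """
    centers = centers.copy()
    prev = np.inf
    for _ in range(iters):
        lab = np.argmin(cdist(points, centers), axis=1)
        for k in range(len(centers)):
            members = points[lab == k]
            if len(members):
                centers[k] = _geometric_median(members)
        cur = _objective_value(points, centers, "mean_euclid")
        if prev - cur < 1e-9:
            break
        prev = cur
    return centers


def _tail_weighted_refine(points: np.ndarray, centers: np.ndarray, quantile: float = 0.90,
                          weight: float = 4.0, iters: int = 40) -> np.ndarray:
    """Weighted k-median descent emphasizing the worst-served samples.

    Samples beyond the given distance quantile get extra weight in the
    per-cluster weighted geometric median, pulling centers toward the tail.
    Used to seed the 95th-percentile objective, which plain k-median
    ignores.
    """
    centers = centers.copy()
    for _ in range(iters):
        d = cdist(points, centers)
        lab = d.argmin(axis=1)
        nearest = d[np.arange(len(points)), lab]
        thr = np.quantile(nearest, quantile)
        w = np.where(nearest >= thr, weight, 1.0)
        for k in range(len(centers)):
            mask = lab == k
            if not mask.any():
                continue
            p, wk = points[mask], w[mask]
            x = np.average(p, axis=0, weights=wk)
            for _ in range(40):
                dist = np.linalg.norm(p - x, axis=1)
                dist = np.where(dist < 1e-12, 1e-12, dist)
                x = (p * (wk / dist)[:, None]).sum(axis=0) / (wk / dist).sum()
            centers[k] = x
    return centers


def _polish(points: np.ndarray, centers: np.ndarray, objective: str, maxfev: int) -> tuple[np.ndarray, float]:
    flat0 = centers.ravel()

    def f(flat: np.ndarray) -> float:
        c = flat.reshape(-1, 2)
        if np.any(c <= 0):
            return 1e6
        return _objective_value(points, c, objective)

    res = minimize(f, flat0, method="Nelder-Mead",
                   options={"maxfev": maxfev, "xatol": 1e-4, "fatol": 1e-7})
    best = res.x.reshape(-1, 2)
    val = f(res.x)
    start_val = f(flat0)
    if start_val < val:
        return centers, start_val
    return best, val


def _centers_to_catalog(centers: np.ndarray, oversized_scale: float) -> InterfaceCatalog:
    """Label seven free ellipses with shape classes by RAPT ranking.

    The two lowest-RAPT ellipses become "flat", the two highest "round" and
    the middle three "normal"; within a class, ids are numbered by
    increasing transverse diameter.  Duplicate geometries are nudged apart
    so the catalog remains valid after a degenerate optimization.
    """
    centers = centers.copy()
    # separate exactly coincident ellipses (can happen on degenerate samples)
    for i in range(len(centers)):
        for j in range(i):
            if np.allclose(centers[i], centers[j], atol=1e-12):
                centers[i] *= 1.0 + 1e-9 * (i + 1)
    rapt = centers[:, 1] / centers[:, 0]
    order = np.argsort(rapt, kind="stable")
    cls_of = {}
    for pos, idx in enumerate(order):
        cls_of[idx] = "flat" if pos < 2 else ("round" if pos >= 5 else "normal")
    interfaces = []
    for cls in SHAPE_CLASSES:
        members = sorted((i for i in range(7) if cls_of[i] == cls), key=lambda i: centers[i, 0])
        for k, i in enumerate(members):
            interfaces.append(EllipseInterface(f"{cls} {k + 1}", cls, float(centers[i, 0]), float(centers[i, 1])))
    return InterfaceCatalog(_add_oversized(interfaces, oversized_scale))


def optimize_catalog(
    population,
    objective: str = "mean_euclid",
    constraints: str = "free",
    seed: int = 0,
    table=None,
    n_restarts: int = 4,
    maxfev: int = 4000,
    oversized_scale: float = 1.15,
) -> InterfaceCatalog:
    """Choose the seven analysis ellipses by direct optimization.

    Runs a multi-restart derivative-free search (k-median alternation for
    warm starts, Nelder-Mead polish) over the seven (transverse, AP) pairs,
    minimizing the requested error-of-fit statistic on ``population``.
    Warm starts include the configured catalog when a morphometry ``table``
    is supplied, so the result never scores worse than that catalog.

    ``constraints="free"`` optimizes all 14 diameters independently; shape
    classes are assigned afterwards by RAPT ranking (2 flat / 3 normal /
    2 round).  ``constraints="shape_class_structured"`` ties every ellipse's
    RAPT to one of three class values and optimizes 7 transverse diameters
    plus the 3 class RAPTs (10 parameters).
    """
    if objective not in OBJECTIVES:
        raise ValueError(f"objective must be one of {OBJECTIVES}")
    if constraints not in ("free", "shape_class_structured"):
        raise ValueError(f"unknown constraint mode {constraints!r}")
    points = population.diameters()
    if len(points) == 0:
        raise ValueError("empty sample")
    rng = np.random.default_rng(seed)

    starts: list[np.ndarray] = []
    if len(points) >= 7:
        for _ in range(max(1, n_restarts - 1)):
            km, _ = kmeans2(points, 7, minit="++", seed=rng.integers(2**31 - 1))
            refined = _kmedian_refine(points, km)
            starts.append(refined)
            if objective == "p95_euclid":
                starts.append(_tail_weighted_refine(points, refined))
    else:
        base = points[rng.integers(0, len(points), size=7)].astype(float)
        base += rng.normal(scale=1e-3, size=base.shape)
        base = np.maximum(np.abs(base), 1e-9)
        base[0] = points[0]  # keep one ellipse exactly on a sample point
        starts.append(base)
    if table is not None:
        cfg_catalog = build_configured_catalog(table, CatalogConfig(), population=population)
        starts.append(np.array([[i.transverse_mm, i.ap_mm] for i in cfg_catalog.analysis_interfaces()]))

    best_centers, best_val = None, np.inf
    for start in starts:
        centers, val = _polish(points, start, objective, maxfev)
        # a second simplex pass from the solution often escapes a collapsed simplex
        centers, val = _polish(points, centers, objective, maxfev)
        if val < best_val:
            best_centers, best_val = centers, val

    if constraints == "shape_class_structured":
        best_centers, _ = _polish_structured(points, best_centers, objective, maxfev)
    return _centers_to_catalog(best_centers, oversized_scale)


def _polish_structured(points: np.ndarray, centers: np.ndarray, objective: str,
                       maxfev: int) -> tuple[np.ndarray, float]:
    """Re-optimize with class-tied RAPTs: 7 transverse diameters + 3 RAPTs."""
    rapt = centers[:, 1] / centers[:, 0]
    order = np.argsort(rapt, kind="stable")
    cls_idx = np.empty(7, dtype=int)
    for pos, idx in enumerate(order):
        cls_idx[idx] = 0 if pos < 2 else (1 if pos < 5 else 2)
    x0 = np.concatenate([
        centers[:, 0],
        [rapt[cls_idx == 0].mean(), rapt[cls_idx == 1].mean(), rapt[cls_idx == 2].mean()],
    ])

    def unpack(x: np.ndarray) -> np.ndarray:
        t = x[:7]
        r = x[7:]
        return np.column_stack([t, t * r[cls_idx]])

    def f(x: np.ndarray) -> float:
        if np.any(x[:7] <= 0) or np.any(x[7:] <= 0) or not (x[7] < x[8] < x[9]):
            return 1e6
        return _objective_value(points, unpack(x), objective)

    res = minimize(f, x0, method="Nelder-Mead",
                   options={"maxfev": maxfev, "xatol": 1e-4, "fatol": 1e-7})
    x = res.x if f(res.x) <= f(x0) else x0
    return unpack(x), f(x)
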