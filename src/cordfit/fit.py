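"""Error-of-fit between simulated cord sizes and device interfaces.

Each simulated (transverse, AP) pair is assigned to the analysis interface
minimizing the Euclidean distance in diameter space; four error metrics are
then computed per sample — transverse error, AP error, their Euclidean
combination, and the absolute ellipse-area mismatch — and summarized as
mean / median / 95th percentile (linear order-statistic interpolation, the
"type 7" quantile convention).

Oversized safety interfaces are excluded from assignment by default; they
exist as intraoperative head-room, not as sizing options.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .catalog import EllipseInterface, InterfaceCatalog

__all__ = [
    "assign_best_device",
    "compute_fit_record",
    "evaluate_population_fit",
    "summarize_fit",
    "FitSummary",
]

METRICS = ("euclid", "transverse", "ap", "area")


def _effective_interfaces(catalog: InterfaceCatalog, include_oversized: bool) -> list[EllipseInterface]:
    ifaces = list(catalog.interfaces) if include_oversized else list(catalog.analysis_interfaces())
    if not ifaces:
        raise ValueError("no interfaces available for assignment")
    # ties between equidistant devices resolve to the larger area (safety margin)
    return sorted(ifaces, key=lambda i: -i.area_mm2)


def assign_best_device(transverse_mm: float, ap_mm: float, catalog: InterfaceCatalog,
                       include_oversized: bool = False) -> str:
    """Id of the interface minimizing Euclidean distance in diameter space."""
    ifaces = _effective_interfaces(catalog, include_oversized)
    d = [math.hypot(transverse_mm - i.transverse_mm, ap_mm - i.ap_mm) for i in ifaces]
    return ifaces[int(np.argmin(d))].id


def compute_fit_record(transverse_mm: float, ap_mm: float, device: EllipseInterface) -> dict:
    """The four error-of-fit components between a cord size and one interface."""
    e_t = abs(transverse_mm - device.transverse_mm)
    e_ap = abs(ap_mm - device.ap_mm)
    e_euclid = math.hypot(e_t, e_ap)
    e_area = abs(math.pi * transverse_mm * ap_mm / 4.0 - device.area_mm2)
    return {
        "device_id": device.id,
        "e_transverse_mm": e_t,
        "e_ap_mm": e_ap,
        "e_euclid_mm": e_euclid,
        "e_area_mm2": e_area,
    }


def evaluate_population_fit(population, catalog: InterfaceCatalog,
                            include_oversized: bool = False) -> pd.DataFrame:
    """Assign every sample to its best interface and tabulate all four errors.

    Returns one row per sample with columns ``segment``, ``draw_index``,
    ``device_id``, ``e_transverse_mm``, ``e_ap_mm``, ``e_euclid_mm``,
    ``e_area_mm2``.
    """
    ifaces = _effective_interfaces(catalog, include_oversized)
    centers = np.array([[i.transverse_mm, i.ap_mm] for i in ifaces])
    pts = population.diameters()
    if len(pts) == 0:
        raise ValueError("empty population")
    dist = cdist(pts, centers)
    lab = np.argmin(dist, axis=1)  # first of ties = largest area (sorted order)
    chosen = centers[lab]
    e = np.abs(pts - chosen)
    area_pts = math.pi * pts[:, 0] * pts[:, 1] / 4.0
    area_dev = math.pi * centers[:, 0] * centers[:, 1] / 4.0
    records = population.samples[["segment", "draw_index"]].copy()
    records["device_id"] = [ifaces[k].id for k in lab]
    records["e_transverse_mm"] = e[:, 0]
    records["e_ap_mm"] = e[:, 1]
    records["e_euclid_mm"] = dist[np.arange(len(pts)), lab]
    records["e_area_mm2"] = np.abs(area_pts - area_dev[lab])
    return records


@dataclass(frozen=True)
class FitSummary:
    """Mean/median/95th-percentile grid of the four error metrics."""

    grid: pd.DataFrame  # index: euclid/transverse/ap/area; columns: median/mean/p95
    n_records: int
    device_counts: pd.Series

    def __getitem__(self, key: tuple[str, str]) -> float:
        metric, stat = key
        return float(self.grid.at[metric, stat])


def summarize_fit(records: pd.DataFrame) -> FitSummary:
    """Summarize fit records into the 4-metric x 3-statistic grid.

    Percentiles use linear interpolation of order statistics; per-device
    assignment counts are carried alongside and sum to the record count.
    """
    if len(records) == 0:
        raise ValueError("cannot summarize an empty record set")
    cols = {
        "euclid": "e_euclid_mm",
        "transverse": "e_transverse_mm",
        "ap": "e_ap_mm",
        "area": "e_area_mm2",
    }
    rows = {}
    for metric, col in cols.items():
        v = records[col].to_numpy(float)
        rows[metric] = {
            "median": float(np.median(v)),
            "mean": float(v.mean()),
            "p95": float(np.percentile(v, 95)),  # type-7 linear interpolation
        }
    grid = pd.DataFrame.from_dict(rows, orient="index")[["median", "mean", "p95"]]
    counts = records["device_id"].value_counts()
    return FitSummary(grid=grid, n_records=len(records), device_counts=counts)
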