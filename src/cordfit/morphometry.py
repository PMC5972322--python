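"""Segmental morphometry of the human spinal cord.

Houses the published per-segment population estimates of transverse and
anteroposterior (AP) cord diameter (mean +/- SD, mm) for the 30 neuronal
segments C1-S5, together with two derived scalar quantities used throughout
the device-sizing analysis:

* a per-segment correlation schedule for bivariate size simulation, varying
  continuously with mean transverse diameter between a high correlation in
  the smallest (sacral) segments and a low correlation in the largest
  (cervical) segments; and
* the mean thoracic RAPT (ratio of AP to transverse diameter) over the
  analysis range T2-T12, which fixes the aspect ratio of "normal"-shaped
  device interfaces.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "SEGMENTS",
    "THORACIC_SEGMENTS",
    "ANALYSIS_SEGMENTS",
    "segment_index",
    "is_thoracic",
    "load_morphometry_table",
    "correlation_for_segment",
    "mean_thoracic_rapt",
]

#: The 30 spinal cord segments in craniocaudal order.
SEGMENTS: tuple[str, ...] = tuple(
    [f"C{i}" for i in range(1, 9)]
    + [f"T{i}" for i in range(1, 13)]
    + [f"L{i}" for i in range(1, 6)]
    + [f"S{i}" for i in range(1, 6)]
)

#: Thoracic segments T1-T12.
THORACIC_SEGMENTS: tuple[str, ...] = tuple(f"T{i}" for i in range(1, 13))

#: The thoracic analysis range for device sizing: T2-T12 (11 levels).
ANALYSIS_SEGMENTS: tuple[str, ...] = tuple(f"T{i}" for i in range(2, 13))

_SEGMENT_RANK = {s: i for i, s in enumerate(SEGMENTS)}

_TABLE_COLUMNS = [
    "mean_transverse_mm",
    "sd_transverse_mm",
    "mean_ap_mm",
    "sd_ap_mm",
    "n_subjects",
]


def segment_index(segment: str) -> int:
    """Craniocaudal rank of a segment label (C1 -> 0, ..., S5 -> 29)."""
    try:
        return _SEGMENT_RANK[segment]
    except KeyError:
        raise ValueError(f"unknown spinal cord segment {segment!r}") from None


def is_thoracic(segment: str) -> bool:
    """True exactly for T1-T12."""
    segment_index(segment)
    return segment in THORACIC_SEGMENTS


def load_morphometry_table() -> pd.DataFrame:
    """Load the packaged segmental diameter table.

    Returns
    -------
    pandas.DataFrame
        Indexed by segment label in craniocaudal order, with columns
        ``mean_transverse_mm``, ``sd_transverse_mm``, ``mean_ap_mm``,
        ``sd_ap_mm`` (all mm) and ``n_subjects``.

    Raises
    ------
    ValueError
        If the packaged data are corrupted (missing or duplicated segments,
        non-positive means or SDs, AP mean exceeding transverse mean),
        naming the offending row.
    """
    with resources.files("cordfit.data").joinpath("morphometry_table.csv").open() as fh:
        table = pd.read_csv(fh, index_col="segment")
    _validate_table(table)
    return table.loc[list(SEGMENTS)]


def _validate_table(table: pd.DataFrame) -> None:
    missing = set(SEGMENTS) - set(table.index)
    if missing:
        raise ValueError(f"morphometry table is missing segments: {sorted(missing)}")
    if table.index.duplicated().any():
        dupes = table.index[table.index.duplicated()].tolist()
        raise ValueError(f"morphometry table has duplicate segments: {dupes}")
    unknown = set(table.index) - set(SEGMENTS)
    if unknown:
        raise ValueError(f"morphometry table has unknown segments: {sorted(unknown)}")
    for col in _TABLE_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"morphometry table lacks column {col!r}")
    for seg, row in table.iterrows():
        if not (row["mean_transverse_mm"] > 0 and row["mean_ap_mm"] > 0):
            raise ValueError(f"segment {seg}: non-positive mean diameter")
        if not (row["sd_transverse_mm"] > 0 and row["sd_ap_mm"] > 0):
            raise ValueError(f"segment {seg}: non-positive SD")
        if row["mean_ap_mm"] > row["mean_transverse_mm"]:
            raise ValueError(f"segment {seg}: AP mean exceeds transverse mean")
        if row["n_subjects"] < 1:
            raise ValueError(f"segment {seg}: invalid subject count")


def correlation_for_segment(
    table: pd.DataFrame,
    segment: str,
    rho_min: float = 0.4,
    rho_max: float = 0.9,
) -> float:
    """Transverse/AP correlation assigned to ``segment`` for simulation.

    The correlation decreases linearly with mean transverse diameter, from
    ``rho_max`` at the smallest segment in the table to ``rho_min`` at the
    largest.  This encodes the anatomical shape constraint: small cords are
    tightly proportioned (high correlation) while large cervical cords vary
    more freely in aspect ratio.
    """
    if not (0.0 < rho_min < rho_max < 1.0):
        raise ValueError("require 0 < rho_min < rho_max < 1")
    mu = table["mean_transverse_mm"]
    mu_min, mu_max = float(mu.min()), float(mu.max())
    if mu_max == mu_min:
        raise ValueError("degenerate table: all segments share one transverse mean")
    mu_seg = float(table.at[segment, "mean_transverse_mm"]) if segment in table.index else None
    if mu_seg is None:
        raise ValueError(f"segment {segment!r} not in table")
    rho = rho_max - (rho_max - rho_min) * (mu_seg - mu_min) / (mu_max - mu_min)
    return float(np.clip(rho, rho_min, rho_max))


def mean_thoracic_rapt(table: pd.DataFrame, segments: tuple[str, ...] = ANALYSIS_SEGMENTS) -> float:
    """Mean RAPT (AP/transverse ratio of segment means) over T2-T12.

    Computed as the arithmetic mean of the 11 per-segment ratios of means;
    the alternative (ratio of pooled means) differs by under 1%.
    """
    sub = table.loc[list(segments)]
    return float((sub["mean_ap_mm"] / sub["mean_transverse_mm"]).mean())
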