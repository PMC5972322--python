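"""Seeded simulation of a population of spinal cord cross-sectional sizes.

Each segment's (transverse, AP) diameter pair is drawn from a bivariate
Gaussian with the published per-segment means and SDs, and a correlation
from the segment's position on the linear correlation schedule (high in
small segments, low in large ones).  Sampling uses a Cholesky transform of
independent standard normals from a named, seedable NumPy generator, so the
draw stream is fully reproducible given the seed.

Diameters are physical lengths; by default any draw with a non-positive
coordinate is redrawn and the number of redraws recorded (negligible for
thoracic segments, where means sit 3-4 SDs above zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphometry import SEGMENTS, correlation_for_segment, segment_index

__all__ = ["SimulationConfig", "SimulatedPopulation", "simulate_population", "summarize_population"]

_MAX_RESAMPLE_ROUNDS = 1000


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulation run.

    Attributes
    ----------
    n_per_segment : int
        Draws per requested segment (default 200).
    seed : int
        Seed for the ``numpy.random.default_rng`` (PCG64) generator.
    rho_min, rho_max : float
        Endpoints of the linear correlation schedule (defaults 0.4, 0.9).
    truncation : str
        ``"resample_nonpositive"`` (default) redraws non-positive diameters;
        ``"none"`` keeps them (flagged via the population's summary).
    segments : tuple of str
        Segments to simulate (default all 30).
    """

    n_per_segment: int = 200
    seed: int = 0
    rho_min: float = 0.4
    rho_max: float = 0.9
    truncation: str = "resample_nonpositive"
    segments: tuple[str, ...] = field(default_factory=lambda: SEGMENTS)

    def __post_init__(self) -> None:
        if self.n_per_segment < 1:
            raise ValueError("n_per_segment must be >= 1")
        if self.truncation not in ("resample_nonpositive", "none"):
            raise ValueError(f"unknown truncation policy {self.truncation!r}")
        for seg in self.segments:
            segment_index(seg)  # raises on unknown labels


@dataclass(frozen=True)
class SimulatedPopulation:
    """A simulated population of per-segment (transverse, AP) diameter pairs.

    ``samples`` has columns ``segment``, ``draw_index``, ``transverse_mm``,
    ``ap_mm``; ``resample_count`` counts redrawn non-positive draws so that
    ``len(samples) + resample_count`` equals the total draws taken.
    """

    samples: pd.DataFrame
    config: SimulationConfig
    resample_count: int

    def __len__(self) -> int:
        return len(self.samples)

    def restrict(self, segments) -> "SimulatedPopulation":
        """Sub-population containing only the given segments."""
        keep = self.samples["segment"].isin(list(segments))
        return SimulatedPopulation(self.samples.loc[keep].reset_index(drop=True), self.config, self.resample_count)

    def diameters(self) -> np.ndarray:
        """(n, 2) array of (transverse, AP) pairs in mm."""
        return self.samples[["transverse_mm", "ap_mm"]].to_numpy(float)


def _draw_segment(rng: np.random.Generator, n: int, mu: np.ndarray, sd: np.ndarray, rho: float,
                  resample: bool) -> tuple[np.ndarray, int]:
    cov = np.array([
        [sd[0] ** 2, rho * sd[0] * sd[1]],
        [rho * sd[0] * sd[1], sd[1] ** 2],
    ])
    chol = np.linalg.cholesky(cov) if np.all(sd > 0) else np.zeros((2, 2))
    draws = mu + rng.standard_normal((n, 2)) @ chol.T
    if not resample:
        return draws, 0
    redrawn = 0
    for _ in range(_MAX_RESAMPLE_ROUNDS):
        bad = np.any(draws <= 0.0, axis=1)
        n_bad = int(bad.sum())
        if n_bad == 0:
            return draws, redrawn
        redrawn += n_bad
        draws[bad] = mu + rng.standard_normal((n_bad, 2)) @ chol.T
    raise RuntimeError("resampling failed to produce positive diameters")


def simulate_population(table: pd.DataFrame, config: SimulationConfig) -> SimulatedPopulation:
    """Draw ``n_per_segment`` (transverse, AP) pairs for every configured segment.

    Segments are processed in craniocaudal order with a single generator, so
    identical config and seed reproduce the sample stream exactly.
    """
    rng = np.random.default_rng(config.seed)
    ordered = sorted(config.segments, key=segment_index)
    frames = []
    resampled = 0
    resample = config.truncation == "resample_nonpositive"
    for seg in ordered:
        row = table.loc[seg]
        mu = row[["mean_transverse_mm", "mean_ap_mm"]].to_numpy(float)
        sd = row[["sd_transverse_mm", "sd_ap_mm"]].to_numpy(float)
        rho = correlation_for_segment(table, seg, config.rho_min, config.rho_max)
        draws, redrawn = _draw_segment(rng, config.n_per_segment, mu, sd, rho, resample)
        resampled += redrawn
        frames.append(pd.DataFrame({
            "segment": seg,
            "draw_index": np.arange(config.n_per_segment),
            "transverse_mm": draws[:, 0],
            "ap_mm": draws[:, 1],
        }))
    samples = pd.concat(frames, ignore_index=True)
    return SimulatedPopulation(samples=samples, config=config, resample_count=resampled)


def summarize_population(pop: SimulatedPopulation) -> pd.DataFrame:
    """Per-segment summary: mean/SD of each diameter, their correlation, RAPT quantiles.

    The correlation is reported as missing when either SD is zero.
    """
    if len(pop) == 0:
        raise ValueError("empty population")

    def _one(g: pd.DataFrame) -> pd.Series:
        t, a = g["transverse_mm"], g["ap_mm"]
        rapt = a / t
        if t.std(ddof=1) > 0 and a.std(ddof=1) > 0:
            corr = float(np.corrcoef(t, a)[0, 1])
        else:
            corr = np.nan
        return pd.Series({
            "n": len(g),
            "mean_transverse_mm": t.mean(),
            "sd_transverse_mm": t.std(ddof=1),
            "mean_ap_mm": a.mean(),
            "sd_ap_mm": a.std(ddof=1),
            "correlation": corr,
            "rapt_median": rapt.median(),
            "rapt_q05": rapt.quantile(0.05),
            "rapt_q95": rapt.quantile(0.95),
        })

    out = pop.samples.groupby("segment", sort=False).apply(_one, include_groups=False)
    out.index.name = "segment"
    return out.loc[sorted(out.index, key=segment_index)]
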