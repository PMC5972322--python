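"""End-to-end orchestration of the device sizing analysis.

Runs simulate -> catalog -> error-of-fit -> averaged contour model ->
channel planning -> device enumeration, writing every stage's artifact
(CSV/JSON/GeoJSON/SVG) plus a manifest with the configuration, the seed and
content hashes, so a rerun with the same config and seed is reproducible
bit for bit.

Per-stage seeds are derived from the pipeline seed and a CRC of the stage
name, so individual stages can be reproduced in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .catalog import CatalogConfig, InterfaceCatalog, build_configured_catalog, optimize_catalog
from .channels import (
    DEVICE_LENGTHS,
    ChannelLayoutConfig,
    DeviceModel,
    build_channels,
    channel_deviation,
    check_clearance,
    derive_anchor_set,
)
from .contours import build_average_thoracic_model, scale_cross_section, write_contours_csv, write_geojson
from .fit import evaluate_population_fit, summarize_fit
from .morphometry import ANALYSIS_SEGMENTS, load_morphometry_table
from .simulate import SimulationConfig, simulate_population, summarize_population

__all__ = ["PipelineConfig", "DeviceCatalog", "enumerate_devices", "run_pipeline", "stage_seed"]

logger = logging.getLogger("cordfit")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    n_per_segment: int = 200
    rho_min: float = 0.4
    rho_max: float = 0.9
    catalog_mode: str = "configured"  # "configured" | "optimize"
    objective: str = "mean_euclid"
    catalog: CatalogConfig = field(default_factory=CatalogConfig)
    layout: ChannelLayoutConfig = field(default_factory=ChannelLayoutConfig)
    lengths: tuple[int, ...] = DEVICE_LENGTHS
    contour_points: int = 256
    channel_interface_id: str = "normal 2"
    channel_length_mm: float = 25.0

    def __post_init__(self) -> None:
        if self.catalog_mode not in ("configured", "optimize"):
            raise ValueError("catalog_mode must be 'configured' or 'optimize'")
        if list(self.lengths) != sorted(self.lengths) or any(l <= 0 for l in self.lengths):
            raise ValueError("lengths must be sorted and positive")


@dataclass(frozen=True)
class DeviceCatalog:
    """All manufactured devices: every interface at every length."""

    devices: tuple[DeviceModel, ...]
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.devices)

    def to_json(self, path: str | Path) -> None:
        payload = []
        for d in self.devices:
            payload.append({
                "id": d.id,
                "interface": {
                    "id": d.interface.id,
                    "shape_class": d.interface.shape_class,
                    "transverse_mm": d.interface.transverse_mm,
                    "ap_mm": d.interface.ap_mm,
                    "oversized": d.interface.oversized,
                },
                "length_mm": d.length_mm,
                "channels": [
                    {
                        "label": c.label,
                        "direction": c.direction,
                        "entry_xy": list(c.entry_xy),
                        "exit_xy": list(c.exit_xy),
                        "radius_mm": c.radius_mm,
                    }
                    for c in d.channels
                ],
            })
        Path(path).write_text(json.dumps({"seed": self.seed, "devices": payload}, indent=1))


def enumerate_devices(catalog, lengths=DEVICE_LENGTHS) -> DeviceCatalog:
    """Cartesian product of interfaces and lengths, ordered by (id, length).

    ``catalog`` may be a full :class:`InterfaceCatalog` or any iterable of
    interfaces (e.g. the analysis subset).
    """
    if not lengths:
        raise ValueError("no device lengths given")
    interfaces = catalog.interfaces if isinstance(catalog, InterfaceCatalog) else tuple(catalog)
    devices = tuple(
        DeviceModel(interface=iface, length_mm=length)
        for iface in sorted(interfaces, key=lambda i: i.id)
        for length in lengths
    )
    return DeviceCatalog(devices=devices)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _render_overlay_svg(path: Path, interface, device: DeviceModel, cord_cs) -> None:
    """Fig-style SVG overlay: interface ellipse, channel end disks, cord contours."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle, Ellipse

    plt.rcParams["svg.hashsalt"] = "cordfit"  # reproducible SVG ids

    fig, axes = plt.subplots(1, 2, figsize=(8, 4), sharex=True, sharey=True)
    for ax, face in zip(axes, ("cranial", "caudal")):
        ax.add_patch(Ellipse((0, 0), interface.transverse_mm, interface.ap_mm,
                             fill=False, color="black", lw=1.2))
        ax.plot(*cord_cs.outer.vertices.T, color="tab:blue", lw=0.8)
        ax.plot(*cord_cs.gray.vertices.T, color="tab:gray", lw=0.8)
        for c in device.channels:
            cranial, caudal = c.axis(device.length_mm)
            xy = cranial[:2] if face == "cranial" else caudal[:2]
            ax.add_patch(Circle(xy, c.radius_mm, fill=False, color="tab:red", lw=1.0))
        ax.set_title(f"{face} face — {interface.id}")
        ax.set_aspect("equal")
        ax.set_xlabel("transverse (mm)")
    axes[0].set_ylabel("anteroposterior (mm)")
    fig.tight_layout()
    fig.savefig(path, format="svg", metadata={"Date": None})
    plt.close(fig)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and write the artifact bundle; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "artifacts": {}, "stages": {}}
    table = load_morphometry_table()

    logger.info("stage 1: population simulation")
    sim_cfg = SimulationConfig(
        n_per_segment=config.n_per_segment,
        seed=stage_seed(config.seed, "simulate"),
        rho_min=config.rho_min,
        rho_max=config.rho_max,
    )
    pop = simulate_population(table, sim_cfg)
    thoracic = pop.restrict(ANALYSIS_SEGMENTS)
    pop.samples.to_csv(outdir / "population.csv", index=False)
    summarize_population(pop).to_csv(outdir / "population_summary.csv")
    manifest["stages"]["simulate"] = {
        "seed": sim_cfg.seed, "n_samples": len(pop), "n_thoracic": len(thoracic),
        "resample_count": pop.resample_count,
    }

    logger.info("stage 2: interface catalog (%s)", config.catalog_mode)
    if config.catalog_mode == "optimize":
        catalog = optimize_catalog(thoracic, objective=config.objective,
                                   seed=stage_seed(config.seed, "catalog"), table=table)
    else:
        catalog = build_configured_catalog(table, config.catalog, population=thoracic)
    catalog.to_json(outdir / "catalog.json")

    logger.info("stage 3: error-of-fit")
    records = evaluate_population_fit(thoracic, catalog)
    summary = summarize_fit(records)
    records.to_csv(outdir / "fit_records.csv", index=False)
    summary.grid.to_csv(outdir / "fit_summary.csv")
    manifest["stages"]["fit"] = {
        "n_records": summary.n_records,
        "summary": summary.grid.to_dict(),
        "device_counts": summary.device_counts.to_dict(),
    }

    logger.info("stage 4: averaged thoracic contour model")
    model = build_average_thoracic_model(
        table, seed=stage_seed(config.seed, "contour"), n_points=config.contour_points
    )
    write_geojson(model.values(), outdir / "cross_sections.geojson")
    write_contours_csv(model.values(), outdir / "contours.csv")

    logger.info("stage 5: channel planning on %s", config.channel_interface_id)
    iface = catalog[config.channel_interface_id]
    device_cs = scale_cross_section(model["combined"], iface.transverse_mm, iface.ap_mm)
    anchors = derive_anchor_set(device_cs, config.layout)
    # an infeasible layout is recorded in the manifest, not a pipeline failure
    device = DeviceModel(interface=iface, length_mm=config.channel_length_mm,
                         channels=build_channels(anchors, config.layout))
    report = check_clearance(device, config.layout.wall_min_mm)
    if not report.passed:
        logger.warning("channel layout infeasible on %s: min wall %.3f mm",
                       iface.id, report.min_wall_mm)
    report.to_json(outdir / "clearance.json")
    _render_overlay_svg(outdir / "overlay.svg", iface, device, device_cs)
    manifest["stages"]["channels"] = {
        "interface": iface.id, "length_mm": device.length_mm,
        "min_wall_mm": report.min_wall_mm, "passed": report.passed,
    }

    logger.info("stage 6: channel-to-anatomy deviation across the population")
    dev_rows = []
    for row in thoracic.samples.itertuples(index=False):
        device_id, devs = channel_deviation(row.transverse_mm, row.ap_mm, catalog, anchors)
        for label, d in devs.items():
            dev_rows.append((row.segment, row.draw_index, device_id, label, d))
    pd.DataFrame(dev_rows, columns=["segment", "draw_index", "device_id", "anchor_label", "deviation_mm"]) \
        .to_csv(outdir / "deviations.csv", index=False)

    logger.info("stage 7: device enumeration")
    device_catalog = DeviceCatalog(enumerate_devices(catalog, config.lengths).devices, seed=config.seed)
    device_catalog.to_json(outdir / "device_catalog.json")
    manifest["stages"]["devices"] = {"n_devices": len(device_catalog)}

    for artifact in sorted(outdir.iterdir()):
        if artifact.name != "manifest.json":
            manifest["artifacts"][artifact.name] = _sha256(artifact)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
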