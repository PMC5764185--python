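"""Orchestration: simulate -> quantify -> localize -> summarize.

A single YAML configuration drives both simulation and quantification so a
whole run is reproducible from one file and one seed.  Every run writes a
manifest (config hash, seed, package version, output checksums) and a plain
run log; outputs are deterministic given fixed inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from sc2wb import __version__ as _pkg_version
from sc2wb.errors import ConfigError, DataError
from sc2wb.layout import ArrayLayout, extract_profile, lane_rois, read_scan, write_scan
from sc2wb.localize import (
    localization,
    migration_cv,
    normalize_expression,
    peak_capacity,
    separation_resolution,
)
from sc2wb.peaks import PeakFit, call_peaks
from sc2wb.simulate import TargetSpec, TransportParams, nfkb_pulse, simulate_array, simulate_timecourse
from sc2wb.stats import summarize, timecourse

__all__ = ["RunConfig", "run_simulate", "run_quantify", "run_stats", "quantify_images"]


@dataclass
class RunConfig:
    """Full configuration of one simulate+quantify run."""

    layout: ArrayLayout = field(default_factory=ArrayLayout)
    panel: list[TargetSpec] = field(default_factory=list)
    transport: TransportParams = field(default_factory=TransportParams)
    n_cells: int | None = None
    noise_sd: float = 10.0
    migration_cv: float = 6.4
    tau_loss: float | None = None
    fraction_model: str = "normal"
    snr_min: float = 3.0
    r2_min: float = 0.7
    east_is_cytoplasmic: bool = True
    seed: int = 0
    output_dir: str = "results/run"
    timepoints: list[float] | None = None
    n_cells_per_timepoint: int = 100
    curve: dict | None = None  # nfkb_pulse kwargs for time-course scenarios

    def __post_init__(self) -> None:
        if self.snr_min <= 0 or self.r2_min <= 0:
            raise ConfigError("thresholds snr_min and r2_min must be positive")
        if not self.panel:
            raise ConfigError("panel must list at least one target")

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        try:
            layout = ArrayLayout.from_dict(d.pop("layout", {}))
            panel = [TargetSpec(**t) for t in d.pop("panel", [])]
            transport = TransportParams(**d.pop("transport", {}))
            sim = d.pop("simulation", {})
            thr = d.pop("thresholds", {})
            orient = d.pop("orientation", {})
            tc = d.pop("timecourse", {})
        except TypeError as exc:
            raise ConfigError(f"invalid configuration field: {exc}") from exc
        known = {
            "n_cells": sim.get("n_cells"),
            "noise_sd": sim.get("noise_sd", 10.0),
            "migration_cv": sim.get("migration_cv", 6.4),
            "tau_loss": sim.get("tau_loss"),
            "fraction_model": sim.get("fraction_model", "normal"),
            "seed": sim.get("seed", d.pop("seed", 0)),
            "snr_min": thr.get("snr_min", 3.0),
            "r2_min": thr.get("r2_min", 0.7),
            "east_is_cytoplasmic": orient.get("east_is_cytoplasmic", True),
            "output_dir": d.pop("output_dir", "results/run"),
            "timepoints": tc.get("timepoints"),
            "n_cells_per_timepoint": tc.get("n_cells_per_timepoint", 100),
            "curve": tc.get("curve"),
        }
        unknown = set(d) - {"seed", "output_dir"}
        if unknown:
            raise ConfigError(f"unknown configuration sections: {sorted(unknown)}")
        return cls(layout=layout, panel=panel, transport=transport, **known)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(asdict(self)), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _expected_center(target: TargetSpec, transport: TransportParams,
                     east_is_cytoplasmic: bool) -> list[float]:
    """Signed expected band centers of a target (east-positive axis)."""
    m = target.migration_um if target.migration_um is not None else transport.migration_um
    cyt_sign = 1.0 if east_is_cytoplasmic else -1.0
    if target.expected_compartment == "cytoplasmic":
        return [cyt_sign * m]
    if target.expected_compartment == "nuclear":
        return [-cyt_sign * m]
    return [m, -m]


def assign_peaks(
    peaks: Sequence[PeakFit],
    targets: Sequence[TargetSpec],
    transport: TransportParams,
    east_is_cytoplasmic: bool = True,
) -> None:
    """Label each peak with the channel target whose expected center is nearest.

    With a single target on the channel every peak belongs to it; with several
    (multiplexed channel) each peak goes to the target minimizing the distance
    between the fitted center and the target's expected signed center(s).
    """
    if len(targets) == 1:
        for p in peaks:
            p.target = targets[0].name
        return
    centers = {
        t.name: _expected_center(t, transport, east_is_cytoplasmic) for t in targets
    }
    for p in peaks:
        p.target = min(
            centers, key=lambda name: min(abs(p.x - c) for c in centers[name])
        )


def quantify_images(
    images: Mapping[str, np.ndarray],
    layout: ArrayLayout,
    panel: Sequence[TargetSpec],
    transport: TransportParams | None = None,
    snr_min: float = 3.0,
    r2_min: float = 0.7,
    east_is_cytoplasmic: bool = True,
    log: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Quantify every lane of a multi-channel array scan.

    For each lane and channel: extract the background-subtracted axial
    profile, call peaks on both sides (SNR and R2 thresholds), integrate each
    called band over its 4-sigma window, assign peaks to panel targets and
    form per-cell localization records.  A failing lane is logged and skipped;
    the run continues.

    Returns ``(peaks_df, cells_df, metrics)`` where ``metrics`` holds the
    per-pair separation resolution table, peak capacity and per-target
    migration CV.
    """
    transport = transport or TransportParams()
    by_channel: dict[str, list[TargetSpec]] = {}
    for t in panel:
        by_channel.setdefault(t.channel, []).append(t)
    missing = set(by_channel) - set(images)
    if missing:
        raise DataError(
            f"image stack lacks configured channel(s): {sorted(missing)}; "
            f"available: {sorted(images)}"
        )
    log = log if log is not None else []

    peak_rows: list[PeakFit] = []
    cell_rows = []
    rs_rows = []
    for roi in lane_rois(layout):
        for channel, targets in by_channel.items():
            try:
                profile = extract_profile(images[channel], roi, layout, channel=channel)
                peaks = call_peaks(profile, "east", snr_min=snr_min, r2_min=r2_min)
                peaks += call_peaks(profile, "west", snr_min=snr_min, r2_min=r2_min)
            except (DataError, ValueError) as exc:
                log.append(f"lane cell_id={roi.cell_id} channel={channel}: skipped ({exc})")
                continue
            assign_peaks(peaks, targets, transport, east_is_cytoplasmic)
            peak_rows.extend(peaks)
            for t in targets:
                rec = localization(
                    [p for p in peaks if p.target == t.name],
                    cell_id=roi.cell_id,
                    target=t.name,
                    east_is_cytoplasmic=east_is_cytoplasmic,
                )
                rec.channel = channel
                cell_rows.append(rec)
            # adjacent-pair separation resolution along the full signed axis
            called = sorted([p for p in peaks if p.called], key=lambda p: p.x)
            for p1, p2 in zip(called, called[1:]):
                rs_rows.append(
                    {
                        "cell_id": roi.cell_id,
                        "channel": channel,
                        "target_1": p1.target,
                        "target_2": p2.target,
                        "rs": separation_resolution(p1, p2),
                    }
                )

    peaks_df = pd.DataFrame(
        [
            {
                "cell_id": p.cell_id,
                "channel": p.channel,
                "target": p.target,
                "x_um": p.x,
                "sigma_um": p.sigma,
                "w_um": p.w,
                "amplitude": p.amplitude,
                "snr": p.snr,
                "r2": p.r2,
                "auc": p.auc,
                "called": p.called,
                "compartment": p.compartment,
            }
            for p in peak_rows
        ],
        columns=[
            "cell_id", "channel", "target", "x_um", "sigma_um", "w_um",
            "amplitude", "snr", "r2", "auc", "called", "compartment",
        ],
    )
    cells_df = pd.DataFrame(
        [r.as_dict() for r in cell_rows],
        columns=[
            "cell_id", "target", "channel", "auc_east", "auc_west",
            "n_peaks_east", "n_peaks_west", "detected", "east_is_cytoplasmic",
            "flags", "auc_total", "nuc_fraction", "cyt_fraction",
        ],
    )
    if not cells_df.empty:
        cells_df = normalize_expression(cells_df)

    called_peaks = [p for p in peak_rows if p.called]
    metrics: dict = {
        "separation_resolution": pd.DataFrame(
            rs_rows, columns=["cell_id", "channel", "target_1", "target_2", "rs"]
        ),
        "peak_capacity": peak_capacity(layout.separation_length, called_peaks)
        if called_peaks
        else float("nan"),
        "migration_cv": {},
    }
    for t in panel:
        t_peaks = [p for p in called_peaks if p.target == t.name]
        cells_with = {p.cell_id for p in t_peaks}
        if len(cells_with) >= 2:
            metrics["migration_cv"][t.name] = migration_cv(t_peaks, t.name)
    return peaks_df, cells_df, metrics


def _write_manifest(outdir: Path, config: RunConfig, outputs: list[Path]) -> None:
    manifest = {
        "package_version": _pkg_version,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "outputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in outputs
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_simulate(config: RunConfig, output_dir: str | Path | None = None,
                 seed: int | None = None) -> dict:
    """Simulate the configured scenario and write scans + truth + manifest.

    A plain array scenario writes ``scan.tif`` and ``truth.csv``; a
    time-course scenario (``timepoints`` configured) writes one
    ``scan_t{minutes}.tif`` per timepoint and a combined ``truth.csv``.
    """
    outdir = Path(output_dir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    outputs = []
    if config.timepoints:
        curve = nfkb_pulse(**(config.curve or {}))
        sims = simulate_timecourse(
            config.layout,
            config.panel,
            config.timepoints,
            curve,
            config.n_cells_per_timepoint,
            transport=config.transport,
            seed=seed,
            noise_sd=config.noise_sd,
            migration_cv=config.migration_cv,
            tau_loss=config.tau_loss,
            fraction_model=config.fraction_model,
        )
        truths = []
        for tp, (images, truth) in sims.items():
            p = outdir / f"scan_t{int(tp):03d}.tif"
            write_scan(images, p)
            outputs.append(p)
            truths.append(truth)
        truth = pd.concat(truths, ignore_index=True)
    else:
        images, truth = simulate_array(
            config.layout,
            config.panel,
            transport=config.transport,
            n_cells=config.n_cells,
            noise_sd=config.noise_sd,
            seed=seed,
            migration_cv=config.migration_cv,
            tau_loss=config.tau_loss,
            fraction_model=config.fraction_model,
        )
        p = outdir / "scan.tif"
        write_scan(images, p)
        outputs.append(p)
    truth_path = outdir / "truth.csv"
    truth.to_csv(truth_path, index=False)
    outputs.append(truth_path)
    _write_manifest(outdir, config, outputs)
    return {"output_dir": str(outdir), "n_truth_rows": len(truth)}


def run_quantify(
    config: RunConfig,
    images: Mapping[str, np.ndarray] | str | Path | None = None,
    output_dir: str | Path | None = None,
) -> dict:
    """Quantify a scan (or the scenario's simulated scan) and write tables.

    Writes ``peaks.csv``, ``cells.csv``, ``metrics.csv``, ``run.log`` and a
    manifest.  ``images`` may be an in-memory channel dict or a TIFF path;
    when omitted, ``scan.tif`` under the output directory is used.
    """
    outdir = Path(output_dir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    channels = []
    for t in config.panel:
        if t.channel not in channels:
            channels.append(t.channel)
    if images is None:
        images = outdir / "scan.tif"
    if isinstance(images, (str, Path)):
        images = read_scan(images, channels)

    log: list[str] = [
        f"sc2wb {_pkg_version}",
        f"config_hash {config.config_hash()}",
        f"seed {config.seed}",
        f"channels {channels}",
    ]
    peaks_df, cells_df, metrics = quantify_images(
        images,
        config.layout,
        config.panel,
        transport=config.transport,
        snr_min=config.snr_min,
        r2_min=config.r2_min,
        east_is_cytoplasmic=config.east_is_cytoplasmic,
        log=log,
    )
    log.append(f"lanes {config.layout.n_wells}  peaks {len(peaks_df)}  cells {len(cells_df)}")

    peaks_path = outdir / "peaks.csv"
    cells_path = outdir / "cells.csv"
    metrics_path = outdir / "metrics.csv"
    peaks_df.to_csv(peaks_path, index=False)
    cells_df.to_csv(cells_path, index=False)
    rows = [
        {"metric": "peak_capacity", "target": "", "value": metrics["peak_capacity"]}
    ]
    rows += [
        {"metric": "migration_cv", "target": name, "value": cv}
        for name, cv in metrics["migration_cv"].items()
    ]
    rs = metrics["separation_resolution"]
    if not rs.empty:
        for (t1, t2), grp in rs.groupby(["target_1", "target_2"]):
            rows.append(
                {"metric": "rs_mean", "target": f"{t1}|{t2}", "value": grp["rs"].mean()}
            )
    pd.DataFrame(rows).to_csv(metrics_path, index=False)
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    _write_manifest(outdir, config, [peaks_path, cells_path, metrics_path])
    return {
        "output_dir": str(outdir),
        "n_peaks": len(peaks_df),
        "n_cells": len(cells_df),
        "peaks": peaks_df,
        "cells": cells_df,
        "metrics": metrics,
    }


def run_stats(cells: pd.DataFrame | str | Path, output_dir: str | Path) -> dict:
    """Summarize per-cell records: per-target distribution summaries and,
    when a ``timepoint_min`` column is present, the time course of the median
    nuclear fraction with its time-to-peak."""
    if isinstance(cells, (str, Path)):
        cells = pd.read_csv(cells)
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    det = cells[cells["detected"].astype(bool)]
    out: dict = {"targets": {}}
    rows = []
    for target, grp in det.groupby("target"):
        entry = {}
        for col in ("nuc_fraction", "auc_total"):
            vals = grp[col].dropna()
            if len(vals) >= 2:
                s = summarize(vals)
                entry[col] = s.as_dict()
                rows.append({"target": target, "metric": col, **s.as_dict()})
        out["targets"][str(target)] = entry
    if "timepoint_min" in det.columns:
        records = {
            float(tp): grp["nuc_fraction"].dropna().to_numpy()
            for tp, grp in det.groupby("timepoint_min")
        }
        tc = timecourse(records)
        out["timecourse"] = {
            "timepoints": list(tc.timepoints),
            "median_nuc_fraction": [s.median for s in tc.summaries],
            "time_to_peak_min": tc.time_to_peak,
        }
    pd.DataFrame(rows).to_csv(outdir / "summary.csv", index=False)
    (outdir / "summary.json").write_text(json.dumps(_jsonable(out), indent=2, sort_keys=True))
    return out
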