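"""CSV/JSON readers and writers, run configuration, and the two pipelines.

File conventions are fixed: comma-separated UTF-8 CSV with a header row and
"." decimals, units embedded in column names (``thickness_cm``,
``kerma_mGy_min``, ``x_px`` ...), no dialect sniffing.  All outputs are
deterministic given (inputs, config, seed); timestamps appear only in the
run log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import attenuation as att
from . import beam_sim, perp_geometry

__all__ = [
    "RunConfig",
    "AttenuationResults",
    "read_measurement_csv",
    "write_measurement_csv",
    "read_marker_csv",
    "write_marker_csv",
    "write_report",
    "run_pipeline",
]

logger = logging.getLogger("radqc")

MEASUREMENT_COLUMNS = ["kV", "thickness_cm", "repeat_index", "kerma_mGy_min"]
MARKER_COLUMNS = ["pair_label", "end", "x_px", "y_px"]


# ---------------------------------------------------------------------------
# Measurement tables
# ---------------------------------------------------------------------------

def read_measurement_csv(
    path: str | Path,
    areal_density_per_article: float | None = None,
    article_thickness_cm: float = 0.5,
) -> list[att.TransmissionSeries]:
    """Parse a transmission-measurement CSV into per-kV series.

    Expected columns: ``kV, thickness_cm, repeat_index, kerma_mGy_min`` plus
    an optional ``hvl_al_mm`` column constant within each kV.  Row order is
    irrelevant; duplicate (kV, thickness, repeat) keys, missing columns, and
    non-numeric or non-positive kerma values raise with row numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    for col in MEASUREMENT_COLUMNS:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna() | df[col].isna()
        if bad.any():
            rows = (df.index[bad] + 2).tolist()  # +2: header + 1-based
            raise ValueError(f"non-numeric or missing {col} at file rows {rows}")
        df[col] = pd.to_numeric(df[col])
    neg = df["kerma_mGy_min"] <= 0
    if neg.any():
        rows = (df.index[neg] + 2).tolist()
        raise ValueError(f"non-positive kerma at file rows {rows}")
    dup = df.duplicated(subset=["kV", "thickness_cm", "repeat_index"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()
        raise ValueError(f"duplicate (kV, thickness, repeat) keys at file rows {rows}")

    series = []
    for kv, grp in df.groupby("kV"):
        hvl_al = None
        if "hvl_al_mm" in grp.columns:
            vals = pd.to_numeric(grp["hvl_al_mm"], errors="coerce").dropna().unique()
            if len(vals) > 1:
                raise ValueError(f"hvl_al_mm not constant within {kv} kV")
            if len(vals) == 1:
                hvl_al = float(vals[0])
        pivot = grp.pivot(
            index="thickness_cm", columns="repeat_index", values="kerma_mGy_min"
        ).sort_index()
        if pivot.isna().any().any():
            raise ValueError(f"ragged repeats at {kv} kV")
        series.append(
            att.TransmissionSeries(
                tube_voltage=float(kv),
                thicknesses_cm=pivot.index.to_numpy(),
                kerma_rates=pivot.to_numpy(),
                hvl_al_reported_mm=hvl_al,
                areal_density_per_article=areal_density_per_article,
                article_thickness_cm=article_thickness_cm,
            )
        )
    return sorted(series, key=lambda s: s.tube_voltage)


def write_measurement_csv(
    experiment: beam_sim.SimulatedExperiment, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write a simulated experiment as ``measurements.csv`` plus a
    ``ground_truth.json`` sidecar holding the seed and per-kV true HVLs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in experiment.series:
        for i, t in enumerate(s.thicknesses_cm):
            for r in range(s.n_repeats):
                rows.append(
                    {
                        "kV": s.tube_voltage,
                        "thickness_cm": t,
                        "repeat_index": r,
                        "kerma_mGy_min": s.kerma_rates[i, r],
                        "hvl_al_mm": s.hvl_al_reported_mm,
                    }
                )
    csv_path = out_dir / "measurements.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    sidecar = out_dir / "ground_truth.json"
    sidecar.write_text(
        json.dumps(
            {
                "seed": experiment.seed,
                "ground_truth_hvl_mm": {
                    str(k): v for k, v in experiment.ground_truth_hvl_mm.items()
                },
            },
            indent=2,
        )
    )
    return csv_path, sidecar


# ---------------------------------------------------------------------------
# Marker tables
# ---------------------------------------------------------------------------

def write_marker_csv(
    observations: list[perp_geometry.MarkerPairObservation],
    path: str | Path,
    pixel_spacing: float,
) -> Path:
    """Write marker observations in pixel units with a metadata header line.

    The first line is ``# pixel_spacing_mm=<value>``; coordinates are pixels
    relative to the image center (mm / spacing), so they may be negative.
    """
    path = Path(path)
    lines = [f"# pixel_spacing_mm={pixel_spacing!r}", ",".join(MARKER_COLUMNS)]
    for obs in observations:
        for end, xy in (("top", obs.top), ("bottom", obs.bottom)):
            x_px, y_px = (float(v) / pixel_spacing for v in xy)
            lines.append(f"{obs.label},{end},{x_px!r},{y_px!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_marker_csv(
    path: str | Path,
) -> tuple[list[perp_geometry.MarkerPairObservation], float]:
    """Read a marker CSV; returns (observations in mm, pixel spacing)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("# pixel_spacing_mm="):
        raise ValueError("missing '# pixel_spacing_mm=' metadata line")
    spacing = float(first.split("=", 1)[1])
    if spacing <= 0:
        raise ValueError("pixel spacing must be positive")
    df = pd.read_csv(path, comment="#", header=0, skiprows=1)
    missing = [c for c in MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    observations = []
    for label, grp in df.groupby("pair_label", sort=True):
        ends = dict(zip(grp["end"], zip(grp["x_px"], grp["y_px"])))
        if set(ends) != {"top", "bottom"}:
            raise ValueError(f"pair {label!r} must have exactly one top and one bottom row")
        top = tuple(np.asarray(ends["top"], dtype=float) * spacing)
        bottom = tuple(np.asarray(ends["bottom"], dtype=float) * spacing)
        observations.append(
            perp_geometry.MarkerPairObservation(label=str(label), top=top, bottom=bottom)
        )
    return observations, spacing


# ---------------------------------------------------------------------------
# Results and reports
# ---------------------------------------------------------------------------

@dataclass
class AttenuationResults:
    """Everything the attenuation pipeline produces for one measurement set."""

    records: list[att.BeamQualityRecord]
    fits: dict[float, att.DoubleExpFit]
    trend_hvl: att.QuadraticTrend | None = None
    trend_hvd: att.QuadraticTrend | None = None
    cross_fit: att.LinearCrossFit | None = None


def _records_frame(records: list[att.BeamQualityRecord]) -> pd.DataFrame:
    cols = [
        "tube_voltage", "hvl_specimen_mm", "mu_specimen_per_mm",
        "hvl_al_mm", "mu_al_per_mm", "hvd_g_cm2",
    ]
    return pd.DataFrame([dataclasses.asdict(r) for r in records], columns=cols)


def write_report(
    results: AttenuationResults | perp_geometry.PerpendicularityResult,
    out_dir: str | Path,
    config_echo: dict | None = None,
) -> list[Path]:
    """Write a deterministic report file set and a run log.

    Attenuation results produce ``beam_quality.csv``, ``fits.json`` and
    ``trend.json``; a perpendicularity result produces ``perp_result.json``.
    ``run.log`` echoes the configuration (timestamps live only there).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if isinstance(results, AttenuationResults):
        csv_path = out_dir / "beam_quality.csv"
        _records_frame(results.records).to_csv(csv_path, index=False)
        written.append(csv_path)

        fits_path = out_dir / "fits.json"
        fits_path.write_text(
            json.dumps(
                {str(kv): dataclasses.asdict(f) for kv, f in results.fits.items()},
                indent=2,
                sort_keys=True,
            )
        )
        written.append(fits_path)

        trend_path = out_dir / "trend.json"
        payload = {}
        for name, trend in (("hvl", results.trend_hvl), ("hvd", results.trend_hvd)):
            if trend is not None:
                payload[name] = dataclasses.asdict(trend)
        if results.cross_fit is not None:
            payload["cross_material"] = dataclasses.asdict(results.cross_fit)
        trend_path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        written.append(trend_path)
    elif isinstance(results, perp_geometry.PerpendicularityResult):
        perp_path = out_dir / "perp_result.json"
        perp_path.write_text(json.dumps(dataclasses.asdict(results), indent=2))
        written.append(perp_path)
    else:
        raise TypeError(f"unsupported results type {type(results).__name__}")

    log_path = out_dir / "run.log"
    stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
    log_path.write_text(
        f"{stamp} radqc report\nconfig: {json.dumps(config_echo or {}, sort_keys=True)}\n"
    )
    written.append(log_path)
    return written


# ---------------------------------------------------------------------------
# Pipelines
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end run configuration for one of the three pipelines."""

    pipeline: str  # "attenuation" | "perpendicularity" | "simulate"
    inputs: dict[str, str] = field(default_factory=dict)
    out_dir: str = "radqc_out"
    seed: int = 0
    method: str = "least_squares"
    areal_density_per_article: float | None = None
    article_thickness_cm: float = 0.5
    detector_center: tuple[float, float] = (0.0, 0.0)
    light_field_center: tuple[float, float] | None = None
    central_ray: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.pipeline not in ("attenuation", "perpendicularity", "simulate"):
            raise ValueError(f"unknown pipeline {self.pipeline!r}")


def analyze_attenuation(
    series_list: list[att.TransmissionSeries],
) -> AttenuationResults:
    """Average, fit, and extract HVL/HVD/mu and trend fits for a series set."""
    records = att.build_beam_quality_table(series_list)
    fits = {}
    for s in series_list:
        t, means = att.average_repeats(s)
        fits[s.tube_voltage] = att.fit_double_exponential(t, means)
    trend_hvl = trend_hvd = cross = None
    if len(records) >= 3:
        kv = np.array([r.tube_voltage for r in records])
        trend_hvl = att.fit_quadratic_trend(
            kv, np.array([r.hvl_specimen_mm for r in records]) / 10.0, "HVL-cm"
        )
        if all(r.hvd_g_cm2 is not None for r in records):
            trend_hvd = att.fit_quadratic_trend(
                kv, np.array([r.hvd_g_cm2 for r in records]), "HVD-g/cm2"
            )
    with_al = [(r.hvl_al_mm, r.hvl_specimen_mm) for r in records if r.hvl_al_mm]
    if len({p[0] for p in with_al}) >= 2:
        cross = att.fit_cross_material_line(with_al)
    return AttenuationResults(
        records=records, fits=fits, trend_hvl=trend_hvl,
        trend_hvd=trend_hvd, cross_fit=cross,
    )


def run_pipeline(config: RunConfig) -> int:
    """Execute a configured pipeline end to end; returns a process exit status.

    Stage errors are logged with the stage name and yield a non-zero status
    without partial report output.
    """
    stage = "configure"
    try:
        if config.pipeline == "attenuation":
            stage = "read"
            series = read_measurement_csv(
                config.inputs["measurements"],
                areal_density_per_article=config.areal_density_per_article,
                article_thickness_cm=config.article_thickness_cm,
            )
            stage = "fit"
            results = analyze_attenuation(series)
            stage = "report"
            write_report(results, config.out_dir, dataclasses.asdict(config))
        elif config.pipeline == "perpendicularity":
            stage = "read"
            observations, _ = read_marker_csv(config.inputs["markers"])
            stage = "locate"
            lines = []
            on_axis = []
            for obs in observations:
                try:
                    lines.append(perp_geometry.line_through_pair(obs))
                except perp_geometry.OnAxisPairError as e:
                    on_axis.append(e.point)
            if on_axis and len(lines) < 2:
                result = perp_geometry.PerpendicularityResult(
                    perp_ray=tuple(np.mean(on_axis, axis=0)),
                    method="on_axis", per_line_residuals=[],
                )
            else:
                result = perp_geometry.locate_perpendicular_ray(lines, config.method)
            stage = "deviations"
            perp_geometry.deviation_report(
                result, config.detector_center,
                config.light_field_center, config.central_ray,
            )
            stage = "report"
            write_report(result, config.out_dir, dataclasses.asdict(config))
        else:  # simulate
            stage = "simulate"
            protocol = beam_sim.TransmissionProtocol(seed=config.seed)
            experiment = beam_sim.simulate_transmission_experiment(protocol)
            write_measurement_csv(experiment, config.out_dir)
    except Exception as exc:  # noqa: BLE001 - pipeline boundary
        logger.error("stage %s failed: %s", stage, exc)
        return 1
    logger.info("pipeline %s completed", config.pipeline)
    return 0
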