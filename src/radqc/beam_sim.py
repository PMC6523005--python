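"""Seeded synthetic-data generators for the two bench experiments.

Two generators live here:

* a transmission-experiment simulator that emulates the HVL/HVD measurement
  protocol — stepped absorber thicknesses, repeated air-kerma-rate readings,
  polyenergetic (beam-hardening) transmission and multiplicative measurement
  noise — with the ground-truth half-value layer recorded for oracle tests;

* a projection-scene simulator for the perpendicularity test tool — a square
  platform carrying vertically aligned fiducial-marker pairs at its top and
  bottom corners, projected through a point x-ray source onto the detector
  plane, with optional Gaussian localization noise.

Both are fully deterministic given a seed.  The global seed splits into
independent substreams (per tube voltage, per marker) so that subsetting a
protocol never shifts the draws of the remaining entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .attenuation import TransmissionSeries
from .perp_geometry import MarkerPairObservation

__all__ = [
    "SpectrumModel",
    "TransmissionProtocol",
    "SceneConfig",
    "SceneTruth",
    "SimulatedExperiment",
    "spectrum_transmission",
    "reference_transmission",
    "ground_truth_hvl_mm",
    "simulate_transmission_experiment",
    "simulate_scene",
    "default_spectra",
    "CLEAR_PLA_HVL_MM",
    "ALUMINUM_HVL_MM",
    "CLEAR_PLA_AREAL_DENSITY",
]

# Reference beam-quality data for clear PLA measured on a portable
# fluoroscopic c-arm, 50-120 kV: specimen HVL (mm of PLA, nominal thickness)
# and the dosimeter-reported beam HVL (mm of aluminum).  Used to calibrate
# the default synthetic spectra and as worked-example inputs.
CLEAR_PLA_HVL_MM: dict[int, float] = {
    50: 20.1, 60: 21.6, 70: 22.4, 80: 23.9,
    90: 24.8, 100: 25.8, 110: 26.6, 120: 27.0,
}
ALUMINUM_HVL_MM: dict[int, float] = {
    50: 2.6, 60: 3.3, 70: 3.9, 80: 4.4,
    90: 4.9, 100: 5.4, 110: 5.8, 120: 6.2,
}
# mean areal density of one 0.5 cm clear-PLA article, g/cm^2
CLEAR_PLA_AREAL_DENSITY: float = 0.590


# ---------------------------------------------------------------------------
# Spectrum model and transmission
# ---------------------------------------------------------------------------

@dataclass
class SpectrumModel:
    """Discrete effective spectrum: weighted exponential components.

    Each component is ``(weight, mu_specimen per-cm, mu_reference per-mm)``.
    A two-component model produces exactly double-exponential transmission,
    the physical basis of the fit form used by the analysis, and exhibits
    beam hardening whenever the rates differ.
    """

    components: list[tuple[float, float, float]]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("at least one component required")
        w = np.array([c[0] for c in self.components], dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")
        for _, mu_s, mu_r in self.components:
            if mu_s < 0 or mu_r < 0:
                raise ValueError("attenuation coefficients must be non-negative")

    @property
    def weights(self) -> np.ndarray:
        return np.array([c[0] for c in self.components], dtype=float)

    @property
    def mu_specimen(self) -> np.ndarray:
        return np.array([c[1] for c in self.components], dtype=float)

    @property
    def mu_reference(self) -> np.ndarray:
        return np.array([c[2] for c in self.components], dtype=float)


def spectrum_transmission(model: SpectrumModel, thickness_cm: float) -> float:
    """Fractional transmission sum(w_i * exp(-mu_i * t)) through the specimen.

    Equals 1 at t = 0 and lies in (0, 1] for t >= 0.
    """
    if np.any(np.asarray(thickness_cm) < 0):
        raise ValueError("thickness must be non-negative")
    return float(np.sum(model.weights * np.exp(-model.mu_specimen * thickness_cm)))


def reference_transmission(model: SpectrumModel, thickness_mm: float) -> float:
    """Fractional transmission through the reference material (aluminum, mm)."""
    if thickness_mm < 0:
        raise ValueError("thickness must be non-negative")
    return float(np.sum(model.weights * np.exp(-model.mu_reference * thickness_mm)))


def _bisect_half(trans, lo: float = 0.0) -> float:
    hi = 1.0
    while trans(hi) > 0.5:
        hi *= 2.0
        if hi > 1e9:
            raise ValueError("transmission never reaches 0.5")
    return brentq(lambda t: trans(t) - 0.5, lo, hi, xtol=1e-12)


def ground_truth_hvl_mm(model: SpectrumModel) -> float:
    """Exact specimen HVL (mm) of a spectrum model, by bisection on the
    transmission curve.  For a single component this equals 10*ln2/mu."""
    return 10.0 * _bisect_half(lambda t: spectrum_transmission(model, t))


def ground_truth_hvl_reference_mm(model: SpectrumModel) -> float:
    """Exact reference-material (aluminum) HVL in mm, by bisection."""
    return _bisect_half(lambda t: reference_transmission(model, t))


# ---------------------------------------------------------------------------
# Default spectra
# ---------------------------------------------------------------------------

def _two_component_for_hvl(hvl: float, ratio: float) -> tuple[float, float]:
    """Rates (mu_hi, mu_lo) = (ratio*m, m) of an equal-weight two-component
    mixture whose half-value thickness equals ``hvl`` (same unit as 1/m)."""

    def half_residual(m: float) -> float:
        return 0.5 * np.exp(-ratio * m * hvl) + 0.5 * np.exp(-m * hvl) - 0.5

    # the single-rate solution ln2/hvl brackets the mixture solution from above
    m = brentq(half_residual, 1e-9, np.log(2) / hvl, xtol=1e-15)
    return ratio * m, m


def default_spectra(
    tube_voltages: list[int] | None = None, mu_ratio: float = 2.5
) -> dict[int, SpectrumModel]:
    """Built-in per-kV spectra calibrated to the reference beam qualities.

    Each tube voltage gets an equal-weight two-component model whose
    hard/soft rate ratio is ``mu_ratio`` and whose exact specimen and
    aluminum HVLs match the bundled clear-PLA reference table, so simulated
    HVLs span ~20-27 mm of specimen across 50-120 kV.
    """
    if tube_voltages is None:
        tube_voltages = sorted(CLEAR_PLA_HVL_MM)
    out: dict[int, SpectrumModel] = {}
    for kv in tube_voltages:
        if kv not in CLEAR_PLA_HVL_MM:
            raise KeyError(f"no reference beam quality for {kv} kV")
        mu_s_hi, mu_s_lo = _two_component_for_hvl(CLEAR_PLA_HVL_MM[kv] / 10.0, mu_ratio)
        mu_r_hi, mu_r_lo = _two_component_for_hvl(ALUMINUM_HVL_MM[kv], mu_ratio)
        out[kv] = SpectrumModel(
            components=[(0.5, mu_s_hi, mu_r_hi), (0.5, mu_s_lo, mu_r_lo)],
            description=f"two-component beam-hardening model, {kv} kV",
        )
    return out


# ---------------------------------------------------------------------------
# Transmission experiment simulator
# ---------------------------------------------------------------------------

@dataclass
class TransmissionProtocol:
    """Measurement protocol for a simulated transmission experiment.

    Defaults mirror the bench protocol: thicknesses 0-5 cm in 0.5 cm steps,
    tube voltages 50-120 kV in 10 kV steps, three repeats per point, and 1%
    multiplicative measurement noise on the kerma-rate readings (the
    repeat-to-repeat variability of the dosimeter is not published; 1% is a
    realistic default for a modern solid-state reference-class instrument).
    """

    thicknesses_cm: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 5.01, 0.5)
    )
    tube_voltages: list[int] = field(
        default_factory=lambda: list(range(50, 121, 10))
    )
    repeats: int = 3
    kerma_at_zero: float = 30.0
    noise_cv: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        self.thicknesses_cm = np.asarray(self.thicknesses_cm, dtype=float)
        t = self.thicknesses_cm
        if np.any(t < 0) or np.any(np.diff(t) <= 0) or t[0] != 0.0:
            raise ValueError("thicknesses must be non-negative, strictly increasing, and include 0")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


@dataclass
class SimulatedExperiment:
    """Simulator output: series per kV plus per-kV ground-truth HVLs (mm)."""

    series: list[TransmissionSeries]
    ground_truth_hvl_mm: dict[int, float]
    seed: int


def _kv_rng(seed: int, kv: int) -> np.random.Generator:
    # keyed substream: independent of which other kVs are simulated
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(int(kv),)))


def _multiplicative_noise(
    rng: np.random.Generator, cv: float, size: int
) -> np.ndarray:
    """1 + eps with eps ~ N(0, cv); eps < -0.99 resampled so readings stay
    strictly positive."""
    eps = rng.normal(0.0, cv, size=size)
    bad = eps < -0.99
    while np.any(bad):
        eps[bad] = rng.normal(0.0, cv, size=int(bad.sum()))
        bad = eps < -0.99
    return 1.0 + eps


def simulate_transmission_experiment(
    protocol: TransmissionProtocol,
    model_per_kv: dict[int, SpectrumModel] | None = None,
    areal_density_per_article: float | None = CLEAR_PLA_AREAL_DENSITY,
) -> SimulatedExperiment:
    """Generate repeated kerma-rate readings for every (kV, thickness) point.

    Each reading is ``kerma_at_zero * transmission * (1 + eps)`` with seeded
    multiplicative Gaussian noise.  The dosimeter-reported aluminum HVL and
    the ground-truth specimen HVL are both derived from the spectrum model by
    bisection.  Identical seeds yield bit-identical output.
    """
    if model_per_kv is None:
        model_per_kv = default_spectra(protocol.tube_voltages)
    missing = [kv for kv in protocol.tube_voltages if kv not in model_per_kv]
    if missing:
        raise KeyError(f"no spectrum model for tube voltages {missing}")

    series: list[TransmissionSeries] = []
    truth: dict[int, float] = {}
    for kv in protocol.tube_voltages:
        model = model_per_kv[kv]
        rng = _kv_rng(protocol.seed, kv)
        trans = np.array(
            [spectrum_transmission(model, t) for t in protocol.thicknesses_cm]
        )
        clean = protocol.kerma_at_zero * trans
        noise = _multiplicative_noise(
            rng, protocol.noise_cv, clean.size * protocol.repeats
        ).reshape(clean.size, protocol.repeats)
        kerma = clean[:, None] * noise
        series.append(
            TransmissionSeries(
                tube_voltage=kv,
                thicknesses_cm=protocol.thicknesses_cm.copy(),
                kerma_rates=kerma,
                hvl_al_reported_mm=ground_truth_hvl_reference_mm(model),
                areal_density_per_article=areal_density_per_article,
            )
        )
        truth[kv] = ground_truth_hvl_mm(model)
    return SimulatedExperiment(series=series, ground_truth_hvl_mm=truth, seed=protocol.seed)


# ---------------------------------------------------------------------------
# Perpendicularity-tool scene simulator
# ---------------------------------------------------------------------------

@dataclass
class SceneConfig:
    """Geometry of a perpendicularity-tool exposure.

    The detector plane is z = 0 with x/y in mm; the source sits at height
    ``sid`` above ``source_foot`` (the true perpendicular-ray point).  The
    tool is a 10 cm square, 20 cm tall marker platform (half_width 50 mm,
    height 200 mm); the bottom markers sit on a thin base plate, default
    2 mm above the detector.
    """

    source_foot: tuple[float, float] = (0.0, 0.0)
    sid: float = 1000.0
    platform_center: tuple[float, float] = (0.0, 0.0)
    platform_half_width: float = 50.0
    platform_height: float = 200.0
    bottom_marker_height: float = 2.0
    pixel_spacing: float = 0.143
    localization_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.sid > self.platform_height > self.bottom_marker_height >= 0):
            raise ValueError("require sid > platform_height > bottom_marker_height >= 0")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if self.localization_noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


@dataclass
class SceneTruth:
    """Ground truth accompanying a simulated scene."""

    source_foot: tuple[float, float]
    sid: float
    central_fiducial_projection: tuple[float, float]
    top_magnification: float


_CORNER_SIGNS = [(-1, -1), (-1, 1), (1, 1), (1, -1)]
_CORNER_LABELS = ["A", "B", "C", "D"]


def _project(point_xy: np.ndarray, height: float, foot: np.ndarray, sid: float) -> np.ndarray:
    if height >= sid:
        raise ValueError("marker at or above source height")
    return foot + sid / (sid - height) * (point_xy - foot)


def simulate_scene(
    config: SceneConfig,
) -> tuple[list[MarkerPairObservation], SceneTruth]:
    """Project the eight corner markers and central top fiducial onto the
    detector through the point source, with seeded localization noise.

    Returns the four vertical-pair observations (labels A-D, corner order
    (-,-), (-,+), (+,+), (+,-)) and the scene's ground truth.  Noise is an
    independent Gaussian per coordinate with its own substream per marker,
    so adding or removing pairs does not reshuffle the rest.
    """
    foot = np.asarray(config.source_foot, dtype=float)
    center = np.asarray(config.platform_center, dtype=float)
    hw = config.platform_half_width

    observations: list[MarkerPairObservation] = []
    for i, (sx, sy) in enumerate(_CORNER_SIGNS):
        corner = center + np.array([sx * hw, sy * hw])
        top = _project(corner, config.platform_height, foot, config.sid)
        bottom = _project(corner, config.bottom_marker_height, foot, config.sid)
        if config.localization_noise_sd > 0:
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(i,))
            )
            top = top + rng.normal(0.0, config.localization_noise_sd, 2)
            bottom = bottom + rng.normal(0.0, config.localization_noise_sd, 2)
        observations.append(
            MarkerPairObservation(
                label=_CORNER_LABELS[i],
                top=(float(top[0]), float(top[1])),
                bottom=(float(bottom[0]), float(bottom[1])),
            )
        )

    central = _project(center, config.platform_height, foot, config.sid)
    truth = SceneTruth(
        source_foot=(float(foot[0]), float(foot[1])),
        sid=config.sid,
        central_fiducial_projection=(float(central[0]), float(central[1])),
        top_magnification=config.sid / (config.sid - config.platform_height),
    )
    return observations, truth
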