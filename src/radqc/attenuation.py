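"""Half-value layer and half-value density extraction from transmission data.

The measurement protocol records air-kerma rate (mGy/min) at stepped absorber
thicknesses for a set of tube voltages.  Because a radiographic beam is
polyenergetic, the transmission curve is not a single exponential: low-energy
photons are removed preferentially (beam hardening) and the effective
attenuation rate decreases with depth.  A two-term ("second order")
exponential decay,

    K(t) = a1 * exp(-m1 * t) + a2 * exp(-m2 * t),

captures this and is the fit form used throughout.  The half-value layer
(HVL) is the thickness at which the fitted curve falls to half its fitted
zero-thickness value; the half-value density (HVD) is the same quantity on an
areal-density axis (g/cm^2), which removes the dependence on physical density.

Attenuation coefficients are reported as mu = ln 2 / HVL, a positive number
(some sources write ln(0.5)/t_half; the magnitude is identical and positive
values are the reporting convention here).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "TransmissionSeries",
    "DoubleExpFit",
    "BeamQualityRecord",
    "QuadraticTrend",
    "LinearCrossFit",
    "NonAttenuatingFitError",
    "average_repeats",
    "fit_double_exponential",
    "solve_hvl",
    "compute_mu",
    "compute_hvd",
    "hvd_from_hvl",
    "fit_quadratic_trend",
    "fit_cross_material_line",
    "build_beam_quality_table",
]


class NonAttenuatingFitError(ValueError):
    """Raised when a fitted curve never falls to half its initial value."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class TransmissionSeries:
    """One tube voltage's kerma-vs-thickness measurement block.

    Parameters
    ----------
    tube_voltage : float
        Nominal tube potential in kV.
    thicknesses_cm : ndarray
        Nominal absorber thicknesses in cm; must include 0 and be strictly
        increasing with at least 5 distinct values.
    kerma_rates : ndarray, shape (n_thickness, n_repeats)
        Air-kerma-rate readings in mGy/min, all strictly positive.
    hvl_al_reported_mm : float or None
        Beam HVL in mm of aluminum as reported by the dosimeter with no
        absorber in the beam.
    areal_density_per_article : float or None
        Areal density (g/cm^2) of one absorber article, required for HVD.
    article_thickness_cm : float
        Nominal thickness of one article (default 0.5 cm).
    """

    tube_voltage: float
    thicknesses_cm: np.ndarray
    kerma_rates: np.ndarray
    hvl_al_reported_mm: float | None = None
    areal_density_per_article: float | None = None
    article_thickness_cm: float = 0.5

    def __post_init__(self) -> None:
        self.thicknesses_cm = np.asarray(self.thicknesses_cm, dtype=float)
        self.kerma_rates = np.atleast_2d(np.asarray(self.kerma_rates, dtype=float))
        t = self.thicknesses_cm
        if t.ndim != 1 or len(np.unique(t)) < 5:
            raise ValueError("need at least 5 distinct thicknesses")
        if not np.any(t == 0.0):
            raise ValueError("thickness grid must include 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("thicknesses must be strictly increasing")
        if self.kerma_rates.shape[0] != len(t):
            raise ValueError("kerma matrix rows must match thickness count")
        if np.any(self.kerma_rates <= 0):
            raise ValueError("all kerma rates must be positive")
        means = self.kerma_rates.mean(axis=1)
        if np.any(np.diff(means) > 0):
            warnings.warn(
                f"mean kerma not non-increasing with thickness at {self.tube_voltage} kV",
                stacklevel=2,
            )

    @property
    def n_repeats(self) -> int:
        return self.kerma_rates.shape[1]


@dataclass
class DoubleExpFit:
    """Fitted two-term exponential attenuation model.

    Canonical ordering m1 >= m2 is enforced so that (a1, m1) is always the
    fast (soft-beam) component.  ``rmse`` is in the units of the ordinate
    (mGy/min); ``converged`` is False when the relative RMSE exceeds 5% of
    the fitted zero-thickness value.
    """

    a1: float
    m1: float
    a2: float
    m2: float
    rmse: float
    converged: bool

    def __post_init__(self) -> None:
        if min(self.a1, self.a2, self.m1, self.m2) < 0:
            raise ValueError("amplitudes and rates must be non-negative")
        if self.m1 < self.m2:  # canonical ordering
            self.a1, self.a2 = self.a2, self.a1
            self.m1, self.m2 = self.m2, self.m1

    @property
    def zero_value(self) -> float:
        """Fitted ordinate at zero thickness, a1 + a2."""
        return self.a1 + self.a2

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        out = self.a1 * np.exp(-self.m1 * t) + self.a2 * np.exp(-self.m2 * t)
        return out if out.ndim else float(out)


@dataclass
class BeamQualityRecord:
    """Per-kV derived beam-quality quantities (one table row)."""

    tube_voltage: float
    hvl_specimen_mm: float
    mu_specimen_per_mm: float
    hvl_al_mm: float | None = None
    mu_al_per_mm: float | None = None
    hvd_g_cm2: float | None = None

    def __post_init__(self) -> None:
        if self.hvl_specimen_mm <= 0:
            raise ValueError("HVL must be positive")
        if abs(self.mu_specimen_per_mm * self.hvl_specimen_mm - np.log(2)) > 1e-9:
            raise ValueError("mu * HVL must equal ln 2")
        if self.hvl_al_mm is not None and self.mu_al_per_mm is not None:
            if abs(self.mu_al_per_mm * self.hvl_al_mm - np.log(2)) > 1e-9:
                raise ValueError("aluminum mu * HVL must equal ln 2")


@dataclass
class QuadraticTrend:
    """Quadratic trend y = a*kV^2 + b*kV + c of HVL or HVD vs tube voltage."""

    a: float
    b: float
    c: float
    y_kind: str = "HVL-cm"

    def __call__(self, kv: np.ndarray | float) -> np.ndarray | float:
        return np.polyval([self.a, self.b, self.c], kv)


@dataclass
class LinearCrossFit:
    """Line relating specimen HVL (mm) to the beam's aluminum HVL (mm)."""

    slope: float
    intercept: float

    def __call__(self, hvl_al_mm: np.ndarray | float) -> np.ndarray | float:
        return self.slope * np.asarray(hvl_al_mm, dtype=float) + self.intercept


# ---------------------------------------------------------------------------
# Curve fitting
# ---------------------------------------------------------------------------

def average_repeats(series: TransmissionSeries) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic mean of the repeat readings at each thickness.

    Returns ``(thicknesses_cm, mean_kerma)``, both 1-D of equal length.
    Averaging precedes fitting: the model is fit to the mean curve, not to
    the pooled repeats.
    """
    if series.kerma_rates.shape[1] < 1:
        raise ValueError("no repeats to average")
    return series.thicknesses_cm, series.kerma_rates.mean(axis=1)


def _double_exp_residuals(params: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    a1, m1, a2, m2 = params
    return a1 * np.exp(-m1 * t) + a2 * np.exp(-m2 * t) - y


def fit_double_exponential(
    thicknesses: np.ndarray, values: np.ndarray
) -> DoubleExpFit:
    """Least-squares fit of ``a1*exp(-m1*t) + a2*exp(-m2*t)`` with all
    parameters bound to be non-negative.

    Starting values come from a log-linear single-exponential fit; the rate
    is split across three multi-start ratios (0.5x, 1x, 2x) and the
    lowest-SSR solution wins.  A constant curve resolves to m1 = m2 = 0.
    """
    t = np.asarray(thicknesses, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(t) < 5:
        raise ValueError("need at least 5 points for a 4-parameter fit")
    if np.any(y <= 0):
        raise ValueError("ordinate values must be positive")

    # log-linear seed for the single-exponential rate
    slope, logk0 = np.polyfit(t, np.log(y), 1)
    m0 = max(-slope, 0.0)
    k0 = float(np.exp(logk0))

    best = None
    for split in (0.5, 1.0, 2.0):
        # spread the two rates around the seeded single rate
        m_hi = max(m0 * split * 2.0, 1e-6)
        m_lo = m0 * split * 0.5
        x0 = np.array([0.5 * k0, m_hi, 0.5 * k0, m_lo])
        try:
            sol = least_squares(
                _double_exp_residuals,
                x0,
                args=(t, y),
                bounds=(0.0, np.inf),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=5000,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("no multi-start converged")

    a1, m1, a2, m2 = best.x
    rmse = float(np.sqrt(np.mean(_double_exp_residuals(best.x, t, y) ** 2)))
    zero = a1 + a2
    converged = bool(zero > 0 and rmse <= 0.05 * zero)
    return DoubleExpFit(a1=a1, m1=m1, a2=a2, m2=m2, rmse=rmse, converged=converged)


# ---------------------------------------------------------------------------
# Half-value quantities
# ---------------------------------------------------------------------------

def solve_hvl(
    fit: DoubleExpFit,
    *,
    reference_value: float | None = None,
    unit_scale: float = 10.0,
) -> float:
    """Thickness at which the fitted curve reaches half its reference value.

    The reference level defaults to the *fitted* zero-thickness value
    ``a1 + a2``; pass ``reference_value`` (e.g. the measured t=0 mean) to use
    the measured-reference alternative.  The root is bracketed and bisected
    to |dt| < 1e-9 in the fit's abscissa unit, then scaled by ``unit_scale``
    (10 converts a cm-axis fit to mm; use 1.0 for an areal-density axis).
    """
    if fit.zero_value <= 0:
        raise NonAttenuatingFitError("fit has zero amplitude")
    if fit.m1 + fit.m2 <= 0:
        raise NonAttenuatingFitError("fit does not attenuate (m1 = m2 = 0)")
    ref = fit.zero_value if reference_value is None else float(reference_value)
    half = 0.5 * ref

    def f(t: float) -> float:
        return fit(t) - half

    if f(0.0) <= 0:
        raise NonAttenuatingFitError("curve already below half value at t = 0")
    hi = 1.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e9:
            raise NonAttenuatingFitError("no half-value crossing found")
    t_half = brentq(f, 0.0, hi, xtol=1e-9)
    return float(t_half * unit_scale)


def compute_mu(hvl: float) -> float:
    """Linear attenuation coefficient from a half-value layer.

    mu = ln 2 / t_half, in the reciprocal of HVL's unit (mm in -> per-mm
    out).  Reported positive by convention.
    """
    if hvl <= 0:
        raise ValueError("HVL must be positive")
    return float(np.log(2) / hvl)


def hvd_from_hvl(
    hvl_mm: float, areal_density_per_article: float, article_thickness_cm: float = 0.5
) -> float:
    """Convert an HVL (mm, nominal) to a half-value density (g/cm^2).

    For uniform articles the areal density accumulates linearly with nominal
    thickness, so HVD = (HVL_cm / article_thickness_cm) * areal_density.
    """
    if hvl_mm <= 0 or areal_density_per_article <= 0 or article_thickness_cm <= 0:
        raise ValueError("all inputs must be positive")
    return hvl_mm / 10.0 / article_thickness_cm * areal_density_per_article


def compute_hvd(series: TransmissionSeries) -> float:
    """Half-value density (g/cm^2) by refitting on an areal-density axis.

    The averaged kerma curve is refit against cumulative areal density
    (thickness / article thickness x per-article areal density) and the 50%
    point solved as for HVL.  For uniform articles this agrees with the
    nominal scaling of :func:`hvd_from_hvl` to high precision.
    """
    if series.areal_density_per_article is None:
        raise ValueError("series carries no areal density metadata")
    t, means = average_repeats(series)
    rho = t / series.article_thickness_cm * series.areal_density_per_article
    fit = fit_double_exponential(rho, means)
    return solve_hvl(fit, unit_scale=1.0)


# ---------------------------------------------------------------------------
# Trend fits
# ---------------------------------------------------------------------------

def fit_quadratic_trend(
    tube_voltages: np.ndarray, y: np.ndarray, y_kind: str = "HVL-cm"
) -> QuadraticTrend:
    """Unweighted OLS fit of y = a*kV^2 + b*kV + c.

    Exact on data lying on a quadratic; requires >= 3 distinct tube voltages.
    """
    kv = np.asarray(tube_voltages, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(kv)) < 3:
        raise ValueError("need at least 3 distinct tube voltages")
    a, b, c = np.polyfit(kv, y, 2)
    return QuadraticTrend(a=float(a), b=float(b), c=float(c), y_kind=y_kind)


def fit_cross_material_line(
    pairs: np.ndarray | list[tuple[float, float]]
) -> LinearCrossFit:
    """Unweighted OLS of specimen HVL (mm) on aluminum HVL (mm).

    ``pairs`` holds (hvl_al_mm, hvl_specimen_mm) rows; at least two distinct
    aluminum HVLs are required.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (n, 2): aluminum HVL, specimen HVL")
    x, y = arr[:, 0], arr[:, 1]
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct aluminum HVLs")
    slope, intercept = np.polyfit(x, y, 1)
    return LinearCrossFit(slope=float(slope), intercept=float(intercept))


# ---------------------------------------------------------------------------
# Table assembly
# ---------------------------------------------------------------------------

def build_beam_quality_table(
    series_list: list[TransmissionSeries],
) -> list[BeamQualityRecord]:
    """Fit each series and assemble per-kV beam-quality records, sorted by kV.

    Each record carries the specimen HVL from the double-exponential fit, the
    dosimeter-reported aluminum HVL if present, attenuation coefficients for
    both, and the HVD when areal-density metadata is available.
    """
    kvs = [s.tube_voltage for s in series_list]
    if len(set(kvs)) != len(kvs):
        raise ValueError("duplicate tube voltages in input")
    records = []
    for s in series_list:
        t, means = average_repeats(s)
        fit = fit_double_exponential(t, means)
        if not fit.converged:
            raise NonAttenuatingFitError(
                f"fit did not converge at {s.tube_voltage} kV (rmse={fit.rmse:.3g})"
            )
        hvl_mm = solve_hvl(fit)
        rec = BeamQualityRecord(
            tube_voltage=s.tube_voltage,
            hvl_specimen_mm=hvl_mm,
            mu_specimen_per_mm=compute_mu(hvl_mm),
            hvl_al_mm=s.hvl_al_reported_mm,
            mu_al_per_mm=(
                compute_mu(s.hvl_al_reported_mm)
                if s.hvl_al_reported_mm is not None
                else None
            ),
            hvd_g_cm2=(
                compute_hvd(s) if s.areal_density_per_article is not None else None
            ),
        )
        records.append(rec)
    return sorted(records, key=lambda r: r.tube_voltage)
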