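"""Specimen and filament metrology: areal densities and summary statistics.

The absorber articles are nominally 5 x 5 x 0.5 cm printed slabs; their
measured mass and face area give the per-article areal density (g/cm^2)
that the HVD computation consumes.  Filament diameters are compared between
spools with an unequal-variance two-sample test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TestArticle",
    "FilamentSample",
    "areal_density",
    "summarize",
    "two_sample_compare",
]


@dataclass
class TestArticle:
    """One printed slab: length/width/thickness in cm, mass in g."""

    length: float
    width: float
    thickness: float
    mass: float

    def __post_init__(self) -> None:
        if min(self.length, self.width, self.thickness, self.mass) <= 0:
            raise ValueError("all dimensions and mass must be strictly positive")
        if not (4.0 <= self.length <= 6.0 and 4.0 <= self.width <= 6.0):
            warnings.warn(
                "article footprint outside the nominal 5 x 5 cm protocol range",
                stacklevel=2,
            )


@dataclass
class FilamentSample:
    """Repeated filament diameter readings (mm) from one spool."""

    diameters: np.ndarray

    def __post_init__(self) -> None:
        self.diameters = np.asarray(self.diameters, dtype=float)
        if self.diameters.size < 2:
            raise ValueError("need at least two diameter readings")
        if np.any(self.diameters <= 0):
            raise ValueError("diameters must be positive")
        if np.any((self.diameters < 1.5) | (self.diameters > 2.0)):
            warnings.warn("diameter outside the usual 1.5-2.0 mm filament range",
                          stacklevel=2)


def areal_density(article: TestArticle) -> float:
    """Mass per unit face area, g/cm^2: mass / (length * width)."""
    return article.mass / (article.length * article.width)


def summarize(values: np.ndarray | list[float]) -> tuple[float, float, int]:
    """(mean, sample standard deviation with n-1 denominator, n)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need n >= 2 for a standard deviation")
    return float(v.mean()), float(v.std(ddof=1)), int(v.size)


def two_sample_compare(
    a: np.ndarray | list[float], b: np.ndarray | list[float]
) -> tuple[float, float, float]:
    """Welch (unequal-variance) two-sided t comparison.

    Returns (statistic, degrees of freedom, p-value).  Degenerate input —
    both samples constant and identical — yields statistic 0, p = 1 with a
    warning rather than a NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        warnings.warn("zero-variance identical samples; reporting p = 1",
                      stacklevel=2)
        return 0.0, float(a.size + b.size - 2), 1.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
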