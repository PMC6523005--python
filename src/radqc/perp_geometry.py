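"""Perpendicular-ray localization from projected fiducial-marker pairs.

A point x-ray source at height SID above the detector projects each
vertically aligned marker pair onto the detector plane; the line through the
two projections necessarily passes through the foot of the perpendicular
from the source (the perpendicular ray).  With two or more non-parallel
marker pairs, the perpendicular ray is recovered as the common point of the
pair lines — independent of SID and of where the tool sits on the detector.

All estimation is two-dimensional in the detector plane: marker heights
never enter the inverse problem.  Two estimators are provided: a
least-squares common point (default) and the centroid of pairwise line
intersections, which mirrors the manual draw-lines-and-mark-overlaps
procedure used at a PACS workstation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MarkerPairObservation",
    "DetectorLine",
    "PerpendicularityResult",
    "OnAxisPairError",
    "DegenerateGeometryError",
    "InsufficientDataError",
    "pixels_to_mm",
    "mm_to_pixels",
    "line_through_pair",
    "locate_perpendicular_ray",
    "deviation_report",
    "estimate_sid",
]


class OnAxisPairError(ValueError):
    """Marker pair projects to (nearly) a single point: the pair is on the
    perpendicular ray, and the shared point itself estimates it."""

    def __init__(self, point: tuple[float, float]):
        super().__init__(f"marker pair on axis at {point}")
        self.point = point


class DegenerateGeometryError(ValueError):
    """All line pairs (near-)parallel; no crossing to locate."""


class InsufficientDataError(ValueError):
    """Fewer than two usable lines."""


@dataclass
class MarkerPairObservation:
    """Detector-plane projections (mm) of one vertical fiducial pair."""

    label: str
    top: tuple[float, float]
    bottom: tuple[float, float]

    def __post_init__(self) -> None:
        for p in (self.top, self.bottom):
            if not np.all(np.isfinite(p)):
                raise ValueError("marker coordinates must be finite")


@dataclass
class DetectorLine:
    """Line in the detector plane: a point and a unit direction."""

    point: tuple[float, float]
    direction: tuple[float, float]

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-12:
            raise ValueError("direction must be a unit vector")

    def distance_to(self, xy: np.ndarray | tuple[float, float]) -> float:
        """Perpendicular point-to-line distance in mm."""
        p = np.asarray(self.point, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        v = np.asarray(xy, dtype=float) - p
        return float(abs(v[0] * d[1] - v[1] * d[0]))


@dataclass
class PerpendicularityResult:
    """Estimated perpendicular-ray point with diagnostics.

    ``per_line_residuals`` are point-to-line distances (mm) from the
    estimate to each pair line; ``intersection_cloud`` holds the pairwise
    crossing points when the centroid method is used; ``deviations`` maps
    reference names (detector_center, light_field_center, central_ray) to
    Euclidean distances in mm.
    """

    perp_ray: tuple[float, float]
    method: str
    per_line_residuals: list[float]
    intersection_cloud: list[tuple[float, float]] = field(default_factory=list)
    deviations: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Coordinate conversion
# ---------------------------------------------------------------------------

def pixels_to_mm(
    coords: np.ndarray, pixel_spacing: float, image_center: tuple[float, float]
) -> np.ndarray:
    """Convert pixel coordinates to mm relative to the image center."""
    if pixel_spacing <= 0:
        raise ValueError("pixel_spacing must be positive")
    return (np.asarray(coords, dtype=float) - np.asarray(image_center, dtype=float)) * pixel_spacing


def mm_to_pixels(
    coords_mm: np.ndarray, pixel_spacing: float, image_center: tuple[float, float]
) -> np.ndarray:
    """Inverse of :func:`pixels_to_mm`."""
    if pixel_spacing <= 0:
        raise ValueError("pixel_spacing must be positive")
    return np.asarray(coords_mm, dtype=float) / pixel_spacing + np.asarray(
        image_center, dtype=float
    )


# ---------------------------------------------------------------------------
# Line construction and intersection
# ---------------------------------------------------------------------------

def line_through_pair(
    obs: MarkerPairObservation, eps_sep: float = 0.05
) -> DetectorLine:
    """Detector line through a pair's two projections.

    The direction is normalized with a canonical sign (positive x, tie-break
    positive y) so results do not depend on which end was listed first.
    Raises :class:`OnAxisPairError` when the projections are separated by
    less than ``eps_sep`` mm — then the shared point itself marks the
    perpendicular ray.
    """
    top = np.asarray(obs.top, dtype=float)
    bottom = np.asarray(obs.bottom, dtype=float)
    d = top - bottom
    norm = np.linalg.norm(d)
    if norm <= eps_sep:
        mid = 0.5 * (top + bottom)
        raise OnAxisPairError((float(mid[0]), float(mid[1])))
    d = d / norm
    if d[0] < 0 or (d[0] == 0 and d[1] < 0):
        d = -d
    return DetectorLine(point=(float(bottom[0]), float(bottom[1])),
                        direction=(float(d[0]), float(d[1])))


def _intersect(l1: DetectorLine, l2: DetectorLine) -> np.ndarray | None:
    p1, d1 = np.asarray(l1.point), np.asarray(l1.direction)
    p2, d2 = np.asarray(l2.point), np.asarray(l2.direction)
    cross = d1[0] * d2[1] - d1[1] * d2[0]
    if cross == 0:
        return None
    s = ((p2 - p1)[0] * d2[1] - (p2 - p1)[1] * d2[0]) / cross
    return p1 + s * d1


def locate_perpendicular_ray(
    lines: list[DetectorLine],
    method: str = "least_squares",
    theta_min_deg: float = 0.5,
) -> PerpendicularityResult:
    """Estimate the perpendicular-ray point from two or more pair lines.

    ``least_squares`` minimizes the sum of squared point-to-line distances
    via the normal equations ``sum(I - d_i d_i^T)(x - p_i) = 0`` — the
    default, and the more precise estimator under localization noise.
    ``pairwise_centroid`` intersects every line pair whose crossing angle
    exceeds ``theta_min_deg`` and returns the centroid of the intersection
    cloud, mirroring the manual center-of-the-overlap-points procedure.
    Both agree exactly on noiseless, non-degenerate input.
    """
    if len(lines) < 2:
        raise InsufficientDataError("need at least two lines")
    if method not in ("least_squares", "pairwise_centroid"):
        raise ValueError(f"unknown method {method!r}")

    if method == "least_squares":
        A = np.zeros((2, 2))
        b = np.zeros(2)
        for ln in lines:
            d = np.asarray(ln.direction)
            P = np.eye(2) - np.outer(d, d)
            A += P
            b += P @ np.asarray(ln.point)
        # A is singular iff all directions are identical
        if np.linalg.matrix_rank(A, tol=1e-10) < 2:
            raise DegenerateGeometryError("all lines are (near-)parallel")
        x = np.linalg.solve(A, b)
        cloud: list[tuple[float, float]] = []
    else:
        sin_min = np.sin(np.deg2rad(theta_min_deg))
        pts = []
        for i in range(len(lines)):
            for j in range(i + 1, len(lines)):
                d1 = np.asarray(lines[i].direction)
                d2 = np.asarray(lines[j].direction)
                if abs(d1[0] * d2[1] - d1[1] * d2[0]) <= sin_min:
                    continue
                p = _intersect(lines[i], lines[j])
                if p is not None:
                    pts.append(p)
        if not pts:
            raise DegenerateGeometryError("no line pair crosses above the angle threshold")
        x = np.mean(pts, axis=0)
        cloud = [(float(p[0]), float(p[1])) for p in pts]

    residuals = [ln.distance_to(x) for ln in lines]
    return PerpendicularityResult(
        perp_ray=(float(x[0]), float(x[1])),
        method=method,
        per_line_residuals=residuals,
        intersection_cloud=cloud,
    )


def deviation_report(
    result: PerpendicularityResult,
    detector_center: tuple[float, float],
    light_field_center: tuple[float, float] | None = None,
    central_ray: tuple[float, float] | None = None,
) -> PerpendicularityResult:
    """Fill in Euclidean deviation distances (mm) to the provided references.

    The detector center is required; the light-field center (the central top
    fiducial's projection) and the central-ray location are optional manual
    inputs and are skipped when absent.
    """
    p = np.asarray(result.perp_ray)
    result.deviations["detector_center"] = float(
        np.linalg.norm(p - np.asarray(detector_center))
    )
    if light_field_center is not None:
        result.deviations["light_field_center"] = float(
            np.linalg.norm(p - np.asarray(light_field_center))
        )
    if central_ray is not None:
        result.deviations["central_ray"] = float(
            np.linalg.norm(p - np.asarray(central_ray))
        )
    return result


# ---------------------------------------------------------------------------
# SID recovery from magnification
# ---------------------------------------------------------------------------

def estimate_sid(
    observations: list[MarkerPairObservation],
    platform_height: float,
    platform_half_width: float,
) -> float:
    """Recover the source-image distance from top-marker magnification.

    The projected top square is magnified by m = SID / (SID - h), so
    SID = h * m / (m - 1).  The magnification is estimated from projected
    pairwise distances among the top markers against the true square
    geometry (side 2*half_width): with four markers the four shortest
    projected distances are sides and the two longest are diagonals; with
    two or three markers all pairs are assumed adjacent corners.
    """
    tops = np.array([obs.top for obs in observations], dtype=float)
    if len(tops) < 2:
        raise InsufficientDataError("need at least two top markers")
    side = 2.0 * platform_half_width
    dists = []
    for i in range(len(tops)):
        for j in range(i + 1, len(tops)):
            dists.append(np.linalg.norm(tops[i] - tops[j]))
    dists = np.sort(np.array(dists))
    if len(tops) == 4:
        true = np.array([side] * 4 + [side * np.sqrt(2)] * 2)
    else:
        true = np.full(len(dists), side)
    m = float(np.sum(dists) / np.sum(true))
    if m <= 1.0 + 1e-6:
        raise ValueError("magnification <= 1: parallel-beam or non-physical geometry")
    return platform_height * m / (m - 1.0)
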