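"""Vector-based anisotropy statistic, rotation scan, sinusoidal fit and
three-class topography classification of tracer-coupled networks.

The statistic works on the vectors from the patched astrocyte to each
coupled cell.  The plane is divided into four 90° sectors — two straddling
the y axis (1A around +y, 1B around −y) and two straddling the x axis
(2A around +x, 2B around −x).  For each sector the vector sum is taken and
its magnitude normalised by the sector's cell count; the anisotropy ratio
is

    R = (|v_1A|/n_1A + |v_1B|/n_1B) / (|v_2A|/n_2A + |v_2B|/n_2B)

so R > 1 means the tracer extends further along y than along x.  Rotating
the coordinate frame in 15° steps over a full turn and refitting

    R(θ) = A0 + A · sin(ω·θ + φ + 3π/4)

yields the maximal ratio R_max = A0 + A and the orientation α ∈ [0°, 180°)
of maximal tracer extent (measured from the mediolateral +x axis).  For an
elliptical network the ratio oscillates twice per full turn (ω ≈ 2).
Networks are then classified:

* class 1 — anisotropic, orthogonal to the tonotopic axis:
  R_max > 1.1 and 45° < α ≤ 135°;
* class 2 — isotropic ("round"): R_max ≤ 1.1;
* class 3 — anisotropic, parallel to the tonotopic axis:
  R_max > 1.1 and α ≤ 45° or α > 135°.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import ConvexHull, QhullError

from .datatypes import NetworkPointSet

__all__ = [
    "SectorDecomposition",
    "RotationScan",
    "SinusoidFitResult",
    "NetworkClassification",
    "NetworkMetrics",
    "sector_ratio",
    "rotation_scan",
    "fit_sinusoid",
    "classify_network",
    "network_metrics",
    "analyze_network",
    "CLASS_ORTHOGONAL",
    "CLASS_ISOTROPIC",
    "CLASS_PARALLEL",
]

CLASS_ORTHOGONAL = "class1_orthogonal_anisotropic"
CLASS_ISOTROPIC = "class2_isotropic"
CLASS_PARALLEL = "class3_parallel_anisotropic"

_PHASE_OFFSET = 0.75 * np.pi  # fixed phase offset of the sinusoid model


@dataclass
class SectorDecomposition:
    """Per-sector sum vectors, magnitudes and counts at one frame rotation."""

    theta_deg: float
    sum_vectors: dict[str, np.ndarray]
    magnitudes: dict[str, float]
    counts: dict[str, int]

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


@dataclass
class RotationScan:
    """Anisotropy ratios over a full turn of the coordinate frame."""

    angles_deg: np.ndarray
    ratios: np.ndarray  # NaN where the ratio is undefined

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.ratios)

    @property
    def n_defined(self) -> int:
        return int(self.defined.sum())


@dataclass
class SinusoidFitResult:
    """Fitted sinusoid R(θ) = A0 + A·sin(ω·θ + φ + 3π/4) and derived values.

    ``omega`` is in cycles per full turn, ``phi`` in radians (wrapped to
    [0, 2π)), ``alpha_deg`` the orientation of maximal tracer extent in
    [0°, 180°) measured from the mediolateral (+x) axis.
    """

    a0: float
    amplitude: float
    omega: float
    phi: float
    r_max: float
    alpha_deg: float
    rmse: float
    converged: bool = True

    def predict(self, theta_deg: np.ndarray) -> np.ndarray:
        th = np.deg2rad(np.asarray(theta_deg, dtype=float))
        return self.a0 + self.amplitude * np.sin(self.omega * th + self.phi + _PHASE_OFFSET)


@dataclass
class NetworkClassification:
    network_class: str
    r_max: float
    alpha_deg: float
    r_max_threshold: float = 1.1
    alpha_bounds_deg: tuple[float, float] = (45.0, 135.0)


@dataclass
class NetworkMetrics:
    """Cell count, convex-hull area and density of a network.

    ``n_cells`` counts the patched cell as part of the network.  ``area_mm2``
    is None (flagged) for degenerate, e.g. collinear, configurations.
    """

    n_cells: int
    area_mm2: float | None
    density_per_mm2: float | None


_SECTORS = ("1A", "1B", "2A", "2B")


def _sector_of(angles_deg: np.ndarray) -> np.ndarray:
    """Sector label index per polar angle (deg, any range).

    1A = [45°, 135°), 1B = [225°, 315°), 2A = [315°, 360°) ∪ [0°, 45°),
    2B = [135°, 225°); half-open boundaries.
    """
    a = np.mod(angles_deg, 360.0)
    out = np.empty(a.shape, dtype=int)
    out[(a >= 45.0) & (a < 135.0)] = 0
    out[(a >= 225.0) & (a < 315.0)] = 1
    out[(a >= 315.0) | (a < 45.0)] = 2
    out[(a >= 135.0) & (a < 225.0)] = 3
    return out


def sector_ratio(
    points: NetworkPointSet, theta_deg: float = 0.0
) -> tuple[float, SectorDecomposition]:
    """Anisotropy ratio R at a frame rotation of ``theta_deg``.

    Each coupled cell's vector from the patched cell is assigned to one of
    four 90° sectors by its polar angle in the rotated frame.  An empty
    sector contributes 0 to its side of the quotient; if the whole
    denominator (x sectors) vanishes the ratio is undefined and NaN is
    returned with the decomposition.
    """
    vectors = points.cells - points.patched
    angles = np.rad2deg(np.arctan2(vectors[:, 1], vectors[:, 0]))
    sector_idx = _sector_of(angles - theta_deg)

    sums: dict[str, np.ndarray] = {}
    mags: dict[str, float] = {}
    counts: dict[str, int] = {}
    for k, name in enumerate(_SECTORS):
        mask = sector_idx == k
        v = vectors[mask].sum(axis=0) if mask.any() else np.zeros(2)
        sums[name] = v
        mags[name] = float(np.hypot(*v))
        counts[name] = int(mask.sum())

    def term(name: str) -> float:
        return mags[name] / counts[name] if counts[name] > 0 else 0.0

    num = term("1A") + term("1B")
    den = term("2A") + term("2B")
    decomp = SectorDecomposition(theta_deg, sums, mags, counts)
    if den == 0.0:
        return float("nan"), decomp
    return num / den, decomp


def rotation_scan(points: NetworkPointSet, step_deg: float = 15.0) -> RotationScan:
    """Recompute the anisotropy ratio while rotating the frame over a full turn."""
    if step_deg <= 0 or not np.isclose(360.0 % step_deg, 0.0):
        raise ValueError("step_deg must evenly divide 360")
    angles = np.arange(0.0, 360.0, step_deg)
    ratios = np.array([sector_ratio(points, th)[0] for th in angles])
    return RotationScan(angles, ratios)


def _fit_once(theta_rad, y, a0_0, a_0, omega_0, phi_0):
    def resid(p):
        a0, a, w, phi = p
        return a0 + a * np.sin(w * theta_rad + phi + _PHASE_OFFSET) - y

    return least_squares(
        resid,
        x0=[a0_0, a_0, omega_0, phi_0],
        bounds=([-np.inf, 0.0, 0.5, -2.0 * np.pi], [np.inf, np.inf, 6.0, 4.0 * np.pi]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )


def fit_sinusoid(scan: RotationScan, n_phase_starts: int = 8) -> SinusoidFitResult:
    """Fit the sinusoid to the defined ratios of a rotation scan.

    Nonlinear least squares over (A0, A, ω, φ) with A ≥ 0 and ω bounded to
    [0.5, 6] cycles per turn.  Initialisation: A0 = mean(R),
    A = (max − min)/2, ω = 2, and φ grid-searched over ``n_phase_starts``
    equally spaced starts in [0, 2π); the best-cost solution wins.
    """
    mask = scan.defined
    if mask.sum() < 8:
        raise ValueError("need at least 8 defined ratios to fit the sinusoid")
    theta = np.deg2rad(scan.angles_deg[mask])
    y = scan.ratios[mask]

    a0_0 = float(np.mean(y))
    a_0 = max(float(np.max(y) - np.min(y)) / 2.0, 1e-9)
    best = None
    for phi_0 in np.linspace(0.0, 2.0 * np.pi, n_phase_starts, endpoint=False):
        try:
            res = _fit_once(theta, y, a0_0, a_0, 2.0, phi_0)
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        return SinusoidFitResult(
            a0=float("nan"), amplitude=float("nan"), omega=float("nan"),
            phi=float("nan"), r_max=float("nan"), alpha_deg=float("nan"),
            rmse=float("nan"), converged=False,
        )

    a0, a, omega, phi = best.x
    phi = float(np.mod(phi, 2.0 * np.pi))
    rmse = float(np.sqrt(np.mean(best.fun**2)))
    alpha = _alpha_from_fit(a, omega, phi)
    return SinusoidFitResult(
        a0=float(a0), amplitude=float(a), omega=float(omega), phi=phi,
        r_max=float(a0 + a), alpha_deg=alpha, rmse=rmse, converged=True,
    )


def _alpha_from_fit(amplitude: float, omega: float, phi: float) -> float:
    """Orientation (deg in [0, 180)) of maximal tracer extent.

    The fitted R(θ) is maximal where the sine equals 1, i.e. at frame
    rotations θ* = (π/2 − φ − 3π/4 + 2πk)/ω.  At rotation θ the ratio's
    numerator axis (the rotated y axis) points along θ + 90° in network
    coordinates, so the orientation of maximal extent is θ* + 90°, reduced
    to [0°, 180°).  The smallest non-negative θ* is used; for ω = 2 all
    maxima give the same orientation modulo 180°.
    """
    if not np.isfinite(omega) or omega == 0 or amplitude == 0:
        # a flat fit has no preferred orientation; report the convention 0
        return 0.0
    base = (np.pi / 2.0 - phi - _PHASE_OFFSET) / omega
    period = 2.0 * np.pi / omega
    theta_star = np.mod(base, period)
    alpha = np.rad2deg(theta_star) + 90.0
    return float(np.mod(alpha, 180.0))


def classify_network(
    fit: SinusoidFitResult,
    r_max_threshold: float = 1.1,
    alpha_bounds_deg: tuple[float, float] = (45.0, 135.0),
) -> NetworkClassification:
    """Assign one of the three topography classes from R_max and α.

    Class 2 (isotropic) iff R_max ≤ threshold; otherwise class 1
    (orthogonal) iff 45° < α ≤ 135°, else class 3 (parallel).  A failed
    fit raises.
    """
    if not fit.converged or not np.isfinite(fit.r_max):
        raise ValueError("cannot classify a network whose sinusoid fit failed")
    lo, hi = alpha_bounds_deg
    if fit.r_max <= r_max_threshold:
        cls = CLASS_ISOTROPIC
    elif lo < fit.alpha_deg <= hi:
        cls = CLASS_ORTHOGONAL
    else:
        cls = CLASS_PARALLEL
    return NetworkClassification(cls, fit.r_max, fit.alpha_deg, r_max_threshold, alpha_bounds_deg)


def network_metrics(points: NetworkPointSet) -> NetworkMetrics:
    """Cell count, convex-hull area (mm²) and cell density of a network.

    The patched cell is counted and included in the hull.  Collinear or
    otherwise degenerate configurations get a flagged (None) area and no
    density.
    """
    pts = points.all_points()
    n = len(pts)  # patched + coupled
    try:
        hull = ConvexHull(pts)
        area_mm2 = float(hull.volume) / 1e6  # 2-D "volume" is the area, µm² → mm²
    except QhullError:
        return NetworkMetrics(n, None, None)
    if area_mm2 <= 0:
        return NetworkMetrics(n, None, None)
    return NetworkMetrics(n, area_mm2, n / area_mm2)


def analyze_network(points: NetworkPointSet, step_deg: float = 15.0) -> dict:
    """Full per-network analysis: scan → fit → classification → metrics.

    Returns a JSON-serialisable record.
    """
    scan = rotation_scan(points, step_deg)
    fit = fit_sinusoid(scan)
    record: dict = {
        "angles_deg": scan.angles_deg.tolist(),
        "ratios": [r if np.isfinite(r) else None for r in scan.ratios],
        "fit": {
            "a0": fit.a0, "amplitude": fit.amplitude, "omega": fit.omega,
            "phi": fit.phi, "r_max": fit.r_max, "alpha_deg": fit.alpha_deg,
            "rmse": fit.rmse, "converged": fit.converged,
        },
    }
    if fit.converged:
        cls = classify_network(fit)
        record["network_class"] = cls.network_class
    else:
        record["network_class"] = None
    metrics = network_metrics(points)
    record["metrics"] = {
        "n_cells": metrics.n_cells,
        "area_mm2": metrics.area_mm2,
        "density_per_mm2": metrics.density_per_mm2,
    }
    return record
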