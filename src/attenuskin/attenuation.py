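"""Per-A-scan attenuation-coefficient estimation for OCT B-scans.

Each A-scan is modelled as a two-way Lambert-Beer decay from the tissue
surface, ``I(z) = a * exp(-2 b z)`` with ``z`` in pixels from the surface
peak.  The fitted ``b`` is an effective attenuation (attenuation times
refractive index) and is dimensionless per pixel-depth unit; multiply by
``1 / pixel_spacing`` to express it per millimetre.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "AScan",
    "BScan",
    "FitResult",
    "AttenuationMap",
    "SurfaceError",
    "WindowError",
    "detect_surface",
    "fit_attenuation",
    "fit_bscan",
    "attenuation_map",
]


class SurfaceError(ValueError):
    """No unambiguous surface peak could be located."""


class WindowError(ValueError):
    """The requested fit window has too few usable points."""


@dataclass(frozen=True)
class AScan:
    """A single depth-resolved intensity profile (one B-scan column)."""

    intensities: np.ndarray
    pixel_spacing: float
    column_index: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError("A-scan needs a 1-D intensity vector of length >= 2")
        if not self.pixel_spacing > 0:
            raise ValueError("pixel_spacing must be positive")
        object.__setattr__(self, "intensities", arr)

    def __len__(self) -> int:
        return self.intensities.size


@dataclass
class BScan:
    """Laterally ordered collection of A-scans with sample metadata.

    ``matrix`` is depth x n_ascans; ``true_mu`` (when produced by the
    simulator) records the generating attenuation per column.
    """

    matrix: np.ndarray
    pixel_spacing: float
    sample_label: str
    sample_id: str = ""
    true_mu: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ValueError("B-scan matrix must be 2-D (depth x A-scans)")
        if not self.pixel_spacing > 0:
            raise ValueError("pixel_spacing must be positive")
        self.matrix = m
        if self.true_mu is not None:
            self.true_mu = np.asarray(self.true_mu, dtype=float)
            if self.true_mu.size != m.shape[1]:
                raise ValueError("true_mu length must match number of A-scans")

    @property
    def n_ascans(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_depth(self) -> int:
        return self.matrix.shape[0]

    def ascan(self, column: int) -> AScan:
        return AScan(self.matrix[:, column], self.pixel_spacing, column)


@dataclass
class FitResult:
    """Exponential-decay fit of one A-scan plus quality metrics."""

    amplitude_a: float
    attenuation_b: float
    r_squared: float
    rmse: float
    max_intensity: float
    surface_index: int
    converged: bool
    column_index: int = 0


@dataclass
class AttenuationMap:
    """Fitted attenuation per A-scan column, in acquisition order."""

    values: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return self.values.size


def detect_surface(ascan: AScan) -> int:
    """Locate the tissue surface as the global intensity maximum.

    Ties are broken toward the shallowest index.  A flat (all-equal)
    signal has no surface and raises :class:`SurfaceError`.
    """
    y = ascan.intensities
    if np.all(y == y[0]):
        raise SurfaceError("flat A-scan: no surface peak")
    return int(np.argmax(y))


def _model(z: np.ndarray, a: float, b: float) -> np.ndarray:
    # clip the exponent so wild intermediate (a, b) trials cannot overflow
    return a * np.exp(np.clip(-2.0 * b * z, -745.0, 700.0))


def _loglinear_seed(z: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Ordinary regression on log intensities above a small floor estimate."""
    floor = max(float(np.min(y)), 0.0)
    # subtracting the full floor can zero the tail; back off to half
    shifted = y - 0.5 * floor
    eps = max(1e-12, 1e-9 * float(np.max(np.abs(y)) or 1.0))
    logy = np.log(np.clip(shifted, eps, None))
    slope, intercept = np.polyfit(z, logy, 1)
    a0 = float(np.exp(intercept))
    b0 = float(-slope / 2.0)
    if not np.isfinite(a0) or a0 <= 0:
        a0 = max(float(y[0]), eps)
    if not np.isfinite(b0):
        b0 = 0.0
    return a0, b0


def _fit_metrics(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float]:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res <= 1e-24 * max(1.0, float(np.abs(y).max()) ** 2) else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(ss_res / y.size))
    return r2, rmse


def fit_attenuation(
    ascan: AScan,
    surface_index: int | None = None,
    fit_depth: int = 150,
) -> FitResult:
    """Least-squares fit of ``a * exp(-2 b z)`` from the surface peak.

    The fit window is ``[surface_index, surface_index + fit_depth)``
    clipped to the A-scan.  Nonlinear least squares on linear intensities
    is seeded by a log-domain regression; if the nonlinear step fails or
    does not improve the seed, the log-linear estimates are returned with
    ``converged=False`` / ``converged=True`` respectively (the better SSE
    always wins).
    """
    if surface_index is None:
        surface_index = detect_surface(ascan)
    y_full = ascan.intensities
    if not 0 <= surface_index < y_full.size:
        raise WindowError("surface_index outside the A-scan")
    stop = min(surface_index + int(fit_depth), y_full.size)
    y = y_full[surface_index:stop]
    if y.size < 3:
        raise WindowError(f"fit window has {y.size} points; need >= 3")
    z = np.arange(y.size, dtype=float)

    a0, b0 = _loglinear_seed(z, y)
    seed_sse = float(np.sum((y - _model(z, a0, b0)) ** 2))

    converged = True
    a_hat, b_hat = a0, b0
    try:
        sol = least_squares(
            lambda p: _model(z, p[0], p[1]) - y,
            x0=[a0, b0],
            method="lm",
            max_nfev=200,
        )
        nls_sse = float(2.0 * sol.cost)
        if sol.success and np.all(np.isfinite(sol.x)) and nls_sse <= seed_sse:
            a_hat, b_hat = float(sol.x[0]), float(sol.x[1])
        elif not sol.success:
            converged = False
    except Exception:
        converged = False

    yhat = _model(z, a_hat, b_hat)
    r2, rmse = _fit_metrics(y, yhat)
    return FitResult(
        amplitude_a=a_hat,
        attenuation_b=b_hat,
        r_squared=r2,
        rmse=rmse,
        max_intensity=float(y_full[surface_index]),
        surface_index=int(surface_index),
        converged=converged,
        column_index=ascan.column_index,
    )


def fit_bscan(
    bscan: BScan,
    roi: tuple[int, int] | None = None,
    fit_depth: int = 150,
) -> list[FitResult]:
    """Fit every A-scan column in ``roi`` (half-open column range).

    Per-column failures (flat signal, short window) are recorded as
    non-converged NaN results rather than aborting the scan.
    """
    lo, hi = (0, bscan.n_ascans) if roi is None else roi
    if not (0 <= lo < hi <= bscan.n_ascans):
        raise ValueError(f"roi {lo}:{hi} outside B-scan width {bscan.n_ascans}")
    results: list[FitResult] = []
    for col in range(lo, hi):
        ascan = bscan.ascan(col)
        try:
            results.append(fit_attenuation(ascan, fit_depth=fit_depth))
        except (SurfaceError, WindowError):
            results.append(
                FitResult(
                    amplitude_a=np.nan,
                    attenuation_b=np.nan,
                    r_squared=np.nan,
                    rmse=np.nan,
                    max_intensity=float(np.max(ascan.intensities)),
                    surface_index=-1,
                    converged=False,
                    column_index=col,
                )
            )
    return results


def attenuation_map(fits: Sequence[FitResult], sample_id: str = "") -> AttenuationMap:
    """Collect fitted ``b`` values in input order for heatmap export."""
    if len(fits) == 0:
        raise ValueError("no fits supplied")
    return AttenuationMap(
        values=np.array([f.attenuation_b for f in fits], dtype=float),
        sample_id=sample_id,
    )
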