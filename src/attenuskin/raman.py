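"""Raman spectral preprocessing and group statistics.

Pipeline: cosmic-ray removal (modified z-score of second differences),
Savitzky-Golay smoothing, area normalization over the 800-1800 cm^-1
fingerprint region, and autofluorescence baseline removal by
asymmetrically reweighted penalized least squares (arPLS).  Group-level
outputs are pointwise means with t-based 95% confidence intervals and
Welch-style difference spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve
from scipy.stats import t as student_t

__all__ = [
    "RamanSpectrum",
    "ArplsConfig",
    "GroupSpectra",
    "remove_cosmic_rays",
    "smooth",
    "normalize_fingerprint",
    "arpls_baseline",
    "group_statistics",
    "difference_spectrum",
    "regrid",
]


@dataclass
class RamanSpectrum:
    """Wavenumber axis (cm^-1, strictly increasing) plus intensities."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    processing_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if w.shape != y.shape or w.ndim != 1:
            raise ValueError("wavenumbers and intensities must be equal-length vectors")
        if np.any(np.diff(w) <= 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        self.wavenumbers = w
        self.intensities = y

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_intensities(self, y: np.ndarray, step: str) -> "RamanSpectrum":
        return RamanSpectrum(
            self.wavenumbers.copy(),
            np.asarray(y, dtype=float),
            [*self.processing_log, step],
        )


@dataclass(frozen=True)
class ArplsConfig:
    """arPLS parameters: smoothness penalty, weight-change tolerance, cap."""

    lambda_smooth: float = 1e5
    ratio_tol: float = 1e-6
    max_iter: int = 50

    def validate(self) -> None:
        if not self.lambda_smooth > 0:
            raise ValueError("lambda_smooth must be positive")
        if not self.ratio_tol > 0:
            raise ValueError("ratio_tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class GroupSpectra:
    """Group mean spectrum with per-channel 95% CI half-widths."""

    group: str
    wavenumbers: np.ndarray
    matrix: np.ndarray  # n_spectra x n_channels
    mean: np.ndarray
    ci_half_width: np.ndarray
    ci_points: np.ndarray  # indices of the display subsample
    confidence: float = 0.95


def remove_cosmic_rays(s: RamanSpectrum, z_threshold: float = 8.0) -> RamanSpectrum:
    """Replace cosmic-ray spikes by linear interpolation of clean neighbors.

    Spikes are channels whose modified z-score (median/MAD based) of the
    second difference exceeds ``z_threshold``.  Boundary spikes fall back
    to the nearest clean value (one-sided rule).
    """
    if len(s) < 5:
        raise ValueError("need at least 5 channels to despike")
    y = s.intensities
    dd = np.diff(y, n=2)
    dd_full = np.concatenate([[dd[0]], dd, [dd[-1]]])
    med = np.median(dd_full)
    mad = np.median(np.abs(dd_full - med))
    if mad == 0:
        scale = np.mean(np.abs(dd_full - med))
        if scale == 0:
            return s.with_intensities(y.copy(), f"despike(z={z_threshold}): 0 spikes")
        z = np.abs(dd_full - med) / scale
    else:
        z = 0.6745 * np.abs(dd_full - med) / mad
    bad = z > z_threshold
    if not np.any(bad):
        return s.with_intensities(y.copy(), f"despike(z={z_threshold}): 0 spikes")
    good = ~bad
    idx = np.arange(y.size)
    cleaned = y.copy()
    # np.interp clamps outside the good range -> one-sided boundary rule
    cleaned[bad] = np.interp(idx[bad], idx[good], y[good])
    return s.with_intensities(
        cleaned, f"despike(z={z_threshold}): {int(bad.sum())} spikes"
    )


def smooth(s: RamanSpectrum, window: int = 11, order: int = 3) -> RamanSpectrum:
    """Savitzky-Golay polynomial smoothing; axis unchanged."""
    if window % 2 == 0 or window <= order:
        raise ValueError("window must be odd and greater than order")
    if window >= len(s):
        raise ValueError("window must be shorter than the spectrum")
    y = savgol_filter(s.intensities, window_length=window, polyorder=order)
    return s.with_intensities(y, f"savgol(window={window}, order={order})")


def normalize_fingerprint(
    s: RamanSpectrum, lo: float = 800.0, hi: float = 1800.0
) -> RamanSpectrum:
    """Divide by the trapezoidal integral over [lo, hi] (area = 1 after)."""
    w = s.wavenumbers
    if w[0] > lo or w[-1] < hi:
        raise ValueError(f"axis [{w[0]}, {w[-1]}] does not cover [{lo}, {hi}]")
    mask = (w >= lo) & (w <= hi)
    area = float(np.trapezoid(s.intensities[mask], w[mask]))
    if area <= 0:
        raise ValueError("non-positive integral over the normalization range")
    return s.with_intensities(
        s.intensities / area, f"normalize_area({lo}-{hi})"
    )


def _second_difference(n: int) -> sparse.csc_matrix:
    d = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    return d.tocsc()


def whittaker_baseline(y: np.ndarray, lam: float) -> np.ndarray:
    """Unweighted second-difference penalized fit (oracle for arPLS)."""
    y = np.asarray(y, dtype=float)
    n = y.size
    d = _second_difference(n)
    a = sparse.eye(n, format="csc") + lam * (d.T @ d)
    return spsolve(a, y)


def arpls_baseline(
    s: RamanSpectrum, cfg: ArplsConfig | None = None
) -> tuple[np.ndarray, RamanSpectrum]:
    """Estimate the autofluorescence baseline by arPLS.

    Iterates ``(W + lam * D'D) z = W y`` with the asymmetric logistic
    reweighting of channels by their negative-side residual statistics;
    stops when the relative weight change drops below ``ratio_tol``.
    Returns ``(baseline, corrected_spectrum)``.
    """
    cfg = cfg or ArplsConfig()
    cfg.validate()
    y = s.intensities
    n = y.size
    d = _second_difference(n)
    h = cfg.lambda_smooth * (d.T @ d)
    w = np.ones(n)
    z = y.copy()
    converged = False
    for _ in range(cfg.max_iter):
        W = sparse.diags(w, format="csc")
        z = spsolve(W + h, w * y)
        resid = y - z
        neg = resid[resid < 0]
        if neg.size == 0:
            converged = True
            break
        m = float(np.mean(neg))
        sd = float(np.std(neg))
        if sd == 0:
            converged = True
            break
        arg = np.clip(2.0 * (resid - (2.0 * sd - m)) / sd, -500, 500)
        w_new = 1.0 / (1.0 + np.exp(arg))
        change = float(np.linalg.norm(w - w_new) / max(np.linalg.norm(w), 1e-300))
        w = w_new
        if change < cfg.ratio_tol:
            converged = True
            break
    if not converged:
        warnings.warn("arPLS did not converge within max_iter", RuntimeWarning)
    corrected = s.with_intensities(
        y - z, f"arpls(lambda={cfg.lambda_smooth:g}, converged={converged})"
    )
    return np.asarray(z, dtype=float), corrected


def regrid(s: RamanSpectrum, axis: np.ndarray) -> RamanSpectrum:
    """Linear interpolation of a spectrum onto a common axis."""
    axis = np.asarray(axis, dtype=float)
    y = np.interp(axis, s.wavenumbers, s.intensities)
    return RamanSpectrum(axis.copy(), y, [*s.processing_log, "regrid"])


def _common_matrix(spectra: Sequence[RamanSpectrum]) -> tuple[np.ndarray, np.ndarray]:
    axis = spectra[0].wavenumbers
    rows = []
    for sp in spectra:
        if sp.wavenumbers.shape == axis.shape and np.allclose(sp.wavenumbers, axis):
            rows.append(sp.intensities)
        else:
            rows.append(regrid(sp, axis).intensities)
    return axis, np.vstack(rows)


def group_statistics(
    spectra: Sequence[RamanSpectrum],
    group: str,
    confidence: float = 0.95,
    n_ci_points: int = 20,
) -> GroupSpectra:
    """Pointwise mean and t-based CI half-width for a group of spectra."""
    if len(spectra) < 2:
        raise ValueError("need at least 2 spectra for a confidence interval")
    axis, mat = _common_matrix(spectra)
    n = mat.shape[0]
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    tcrit = float(student_t.ppf(0.5 + confidence / 2.0, df=n - 1))
    hw = tcrit * sd / np.sqrt(n)
    ci_points = np.unique(
        np.linspace(0, axis.size - 1, n_ci_points).round().astype(int)
    )
    return GroupSpectra(
        group=group,
        wavenumbers=axis,
        matrix=mat,
        mean=mean,
        ci_half_width=hw,
        ci_points=ci_points,
        confidence=confidence,
    )


def difference_spectrum(
    a: GroupSpectra, b: GroupSpectra, confidence: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """``mean_a - mean_b`` with per-channel Welch (unpooled) CI half-width."""
    if a.wavenumbers.shape != b.wavenumbers.shape or not np.allclose(
        a.wavenumbers, b.wavenumbers
    ):
        raise ValueError("group spectra are not on a common axis")
    na, nb = a.matrix.shape[0], b.matrix.shape[0]
    va = a.matrix.var(axis=0, ddof=1)
    vb = b.matrix.var(axis=0, ddof=1)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        df = se2**2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    df = np.where(np.isfinite(df), df, 1.0)
    tcrit = student_t.ppf(0.5 + confidence / 2.0, df=df)
    diff = a.mean - b.mean
    hw = tcrit * np.sqrt(se2)
    hw = np.where(se2 == 0, 0.0, hw)
    return diff, np.asarray(hw, dtype=float)
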