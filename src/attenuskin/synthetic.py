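"""Seeded simulators for OCT B-scans and Raman spectra.

Stand-ins for clinical data: A-scans follow the two-way exponential decay
forward model with multiplicative log-normal speckle and an additive noise
floor; Raman spectra are Gaussian bands over a smooth autofluorescence
background with Poisson-count cosmic-ray spikes.  Every generator is a
pure function of its config (including the seed) and emits ground truth
alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .attenuation import AScan, BScan
from .raman import RamanSpectrum

__all__ = [
    "OctSimConfig",
    "RamanSimConfig",
    "ConfigError",
    "default_oct_config",
    "default_raman_config",
    "generate_ascan",
    "generate_bscan",
    "generate_raman_spectrum",
    "CLASS_MU",
]


class ConfigError(ValueError):
    """Simulation config violates an invariant."""


# Default effective-mu distributions (mean, sd), truncated positive.
# Benign nevi sit higher than melanoma; with the sd below, fitted maxima
# approach the ~1.6 ceiling seen for in-vivo skin.
CLASS_MU: dict[str, tuple[float, float]] = {
    "BN": (1.2, 0.15),
    "MM": (0.8, 0.15),
}


@dataclass(frozen=True)
class OctSimConfig:
    n_ascans: int = 1000
    n_depth: int = 400
    pixel_spacing: float = 0.0029  # mm per pixel
    surface_index_mean: int = 40
    surface_jitter_sd: float = 3.0
    amplitude_mean: float = 2.0
    mu_mean: float = 1.0
    mu_sd: float = 0.15
    refractive_index: float = 1.4
    speckle_sd: float = 0.08  # log-intensity units
    noise_floor_sd: float = 0.002  # intensity units
    seed: int = 0

    def validate(self) -> None:
        if self.n_ascans < 1:
            raise ConfigError("n_ascans must be >= 1")
        if self.n_depth <= self.surface_index_mean:
            raise ConfigError("n_depth must exceed surface_index_mean")
        if not self.mu_mean > 0:
            raise ConfigError("mu_mean must be positive")
        for name in ("surface_jitter_sd", "mu_sd", "speckle_sd", "noise_floor_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 1.33 <= self.refractive_index <= 1.55:
            raise ConfigError("refractive_index must lie in [1.33, 1.55]")
        if not self.pixel_spacing > 0:
            raise ConfigError("pixel_spacing must be positive")


@dataclass(frozen=True)
class RamanSimConfig:
    wavenumber_grid: tuple[float, ...] = ()
    band_centers: tuple[float, ...] = ()
    band_amplitudes: tuple[float, ...] = ()
    band_widths: tuple[float, ...] = ()
    background_control_points: tuple[tuple[float, float], ...] = ()
    noise_sd: float = 5.0
    cosmic_ray_rate: float = 0.5
    cosmic_ray_amplitude: float = 5000.0
    seed: int = 0

    def validate(self) -> None:
        grid = np.asarray(self.wavenumber_grid, dtype=float)
        if grid.size < 2 or np.any(np.diff(grid) <= 0):
            raise ConfigError("wavenumber grid must be strictly increasing, length >= 2")
        n = len(self.band_centers)
        if len(self.band_amplitudes) != n or len(self.band_widths) != n:
            raise ConfigError("band centers/amplitudes/widths must align")
        if any(w <= 0 for w in self.band_widths):
            raise ConfigError("band widths must be positive")
        if self.cosmic_ray_rate < 0:
            raise ConfigError("cosmic_ray_rate must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


def default_oct_config(class_label: str, seed: int = 0, **overrides) -> OctSimConfig:
    """Per-class OCT config with the default BN-over-MM mu ordering."""
    mu_mean, mu_sd = CLASS_MU[class_label.upper()]
    cfg = OctSimConfig(mu_mean=mu_mean, mu_sd=mu_sd, seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


# Band placement: carotenoids (~1008, 1158, 1525 cm-1) stronger in MM;
# CH2-CH3 (~1450) and amide-I (~1655) stronger in BN.
_BAND_CENTERS = (1008.0, 1158.0, 1525.0, 1450.0, 1655.0)
_BAND_WIDTHS = (8.0, 9.0, 10.0, 14.0, 16.0)
_BAND_AMPLITUDES = {
    "BN": (120.0, 100.0, 150.0, 260.0, 300.0),
    "MM": (220.0, 190.0, 280.0, 150.0, 180.0),
}
_BACKGROUND_POINTS = {
    "BN": ((700.0, 900.0), (1000.0, 1250.0), (1300.0, 1450.0), (1600.0, 1200.0), (1900.0, 850.0)),
    "MM": ((700.0, 1300.0), (1000.0, 1800.0), (1300.0, 2100.0), (1600.0, 1750.0), (1900.0, 1250.0)),
}


def default_raman_config(group: str, seed: int = 0, **overrides) -> RamanSimConfig:
    group = group.upper()
    grid = tuple(np.arange(700.0, 1900.0 + 1e-9, 1.0))
    cfg = RamanSimConfig(
        wavenumber_grid=grid,
        band_centers=_BAND_CENTERS,
        band_amplitudes=_BAND_AMPLITUDES[group],
        band_widths=_BAND_WIDTHS,
        background_control_points=_BACKGROUND_POINTS[group],
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def _rng(seed: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *extra]))


def _ascan_signal(
    cfg: OctSimConfig,
    class_mu: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    surface = int(round(cfg.surface_index_mean + rng.normal(0.0, cfg.surface_jitter_sd)))
    surface = int(np.clip(surface, 0, cfg.n_depth - 3))
    z = np.arange(cfg.n_depth - surface, dtype=float)
    decay = cfg.amplitude_mean * np.exp(-2.0 * class_mu * z)
    if cfg.speckle_sd > 0:
        decay = decay * rng.lognormal(0.0, cfg.speckle_sd, size=decay.size)
    signal = np.zeros(cfg.n_depth)
    signal[surface:] = decay
    if cfg.noise_floor_sd > 0:
        signal += np.abs(rng.normal(0.0, cfg.noise_floor_sd, size=cfg.n_depth))
    # keep the surface peak the global maximum even under speckle
    peak = signal[surface]
    cap = np.max(signal)
    if cap > peak:
        signal[signal > peak] = peak * (1.0 - 1e-6)
        signal[surface] = peak
    return signal, surface


def generate_ascan(cfg: OctSimConfig, class_mu: float) -> AScan:
    """One synthetic A-scan at attenuation ``class_mu`` (seeded by cfg)."""
    cfg.validate()
    if not class_mu > 0:
        raise ConfigError("class_mu must be positive")
    signal, _ = _ascan_signal(cfg, class_mu, _rng(cfg.seed))
    return AScan(signal, cfg.pixel_spacing, 0)


def generate_bscan(cfg: OctSimConfig, class_label: str, sample_id: str = "") -> BScan:
    """Synthetic B-scan with per-column mu drawn from the class distribution.

    True per-column mu values are stored on the result for recovery tests.
    """
    cfg.validate()
    label = class_label.upper()
    if label not in CLASS_MU:
        raise ConfigError(f"unknown class label {class_label!r}")
    rng = _rng(cfg.seed)
    mus = rng.normal(cfg.mu_mean, cfg.mu_sd, size=cfg.n_ascans)
    while np.any(mus <= 0):  # truncate positive by redraw
        bad = mus <= 0
        mus[bad] = rng.normal(cfg.mu_mean, cfg.mu_sd, size=int(bad.sum()))
    matrix = np.empty((cfg.n_depth, cfg.n_ascans))
    for j in range(cfg.n_ascans):
        matrix[:, j], _ = _ascan_signal(cfg, mus[j], _rng(cfg.seed, 1, j))
    return BScan(
        matrix=matrix,
        pixel_spacing=cfg.pixel_spacing,
        sample_label=label,
        sample_id=sample_id or f"{label.lower()}_sim",
        true_mu=mus,
    )


def _background_curve(cfg: RamanSimConfig, grid: np.ndarray) -> np.ndarray:
    pts = np.asarray(cfg.background_control_points, dtype=float)
    if pts.size == 0:
        return np.zeros_like(grid)
    if pts.shape[0] == 1:
        return np.full_like(grid, pts[0, 1])
    spline = CubicSpline(pts[:, 0], pts[:, 1])
    return np.asarray(spline(grid), dtype=float)


def generate_raman_spectrum(
    cfg: RamanSimConfig,
    group: str = "BN",
) -> tuple[RamanSpectrum, dict]:
    """Synthetic spectrum plus ground truth.

    Returns ``(spectrum, truth)`` where ``truth`` holds the clean
    background vector, the band-only signal, and the spiked channel
    indices.
    """
    cfg.validate()
    grid = np.asarray(cfg.wavenumber_grid, dtype=float)
    group_key = sum(ord(ch) for ch in group.upper())  # stable across processes
    rng = _rng(cfg.seed, group_key)
    background = _background_curve(cfg, grid)
    bands = np.zeros_like(grid)
    for c, a, w in zip(cfg.band_centers, cfg.band_amplitudes, cfg.band_widths):
        bands += a * np.exp(-0.5 * ((grid - c) / w) ** 2)
    intens = background + bands
    if cfg.noise_sd > 0:
        intens = intens + rng.normal(0.0, cfg.noise_sd, size=grid.size)
    n_spikes = int(rng.poisson(cfg.cosmic_ray_rate))
    spike_idx = np.sort(rng.choice(grid.size, size=min(n_spikes, grid.size), replace=False))
    intens = intens.copy()
    intens[spike_idx] += cfg.cosmic_ray_amplitude * (0.5 + rng.random(spike_idx.size))
    spectrum = RamanSpectrum(grid.copy(), intens, processing_log=["simulated"])
    truth = {
        "background": background,
        "bands": bands,
        "spike_indices": spike_idx,
    }
    return spectrum, truth
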