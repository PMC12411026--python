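"""Delimited-text readers and writers for B-scans, fits, and spectra.

B-scan files carry one ``# key=value`` metadata header line (at minimum
``pixel_spacing`` and ``label``) followed by a numeric matrix with rows as
depth and columns as A-scans.  Spectra are two-column text (wavenumber,
intensity); ``#`` comment lines are tolerated.
"""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .attenuation import BScan, FitResult
from .raman import RamanSpectrum

__all__ = [
    "ParseError",
    "read_bscan",
    "write_bscan",
    "read_spectrum",
    "write_spectrum",
    "fits_to_frame",
    "frame_to_fits",
    "file_digest",
    "derive_seed",
]

_FIT_COLUMNS = (
    "column_index",
    "a",
    "b",
    "r2",
    "rmse",
    "max_intensity",
    "surface_index",
    "converged",
)


class ParseError(ValueError):
    """Malformed input file."""


def _parse_header(line: str, path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    for token in line.lstrip("#").split():
        if "=" not in token:
            raise ParseError(f"{path}: bad header token {token!r}")
        key, value = token.split("=", 1)
        meta[key] = value
    return meta


def read_bscan(path: str | Path) -> BScan:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ParseError(f"{path}: missing '#' metadata header line")
        meta = _parse_header(header, path)
        if "pixel_spacing" not in meta:
            raise ParseError(f"{path}: header lacks pixel_spacing")
        rows: list[list[float]] = []
        width = None
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cells = line.replace(",", " ").split()
            try:
                row = [float(c) for c in cells]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric cell") from exc
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise ParseError(
                    f"{path}:{lineno}: ragged row ({len(row)} cells, expected {width})"
                )
            rows.append(row)
    if not rows:
        raise ParseError(f"{path}: no matrix rows")
    true_mu = None
    if "true_mu_file" in meta:
        mu_path = path.parent / meta["true_mu_file"]
        if mu_path.exists():
            true_mu = np.loadtxt(mu_path, ndmin=1)
    return BScan(
        matrix=np.asarray(rows, dtype=float),
        pixel_spacing=float(meta["pixel_spacing"]),
        sample_label=meta.get("label", ""),
        sample_id=meta.get("sample_id", path.stem),
        true_mu=true_mu,
    )


def write_bscan(bscan: BScan, path: str | Path) -> None:
    path = Path(path)
    header = (
        f"pixel_spacing={bscan.pixel_spacing!r} "
        f"label={bscan.sample_label} sample_id={bscan.sample_id}"
    )
    np.savetxt(path, bscan.matrix, header=header, comments="# ", fmt="%.17g")


def read_spectrum(path: str | Path) -> RamanSpectrum:
    path = Path(path)
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] != 2:
        raise ParseError(f"{path}: expected two columns, got {data.shape[1]}")
    w, y = data[:, 0], data[:, 1]
    if np.unique(w).size != w.size:
        raise ParseError(f"{path}: duplicate wavenumbers")
    if np.any(np.diff(w) < 0):
        warnings.warn(f"{path}: axis not ascending; sorting", RuntimeWarning)
        order = np.argsort(w)
        w, y = w[order], y[order]
    return RamanSpectrum(w, y, [f"read({path.name})"])


def write_spectrum(s: RamanSpectrum, path: str | Path) -> None:
    np.savetxt(
        Path(path),
        np.column_stack([s.wavenumbers, s.intensities]),
        header="wavenumber intensity",
        comments="# ",
        fmt="%.17g",
    )


def fits_to_frame(fits: list[FitResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "column_index": [f.column_index for f in fits],
            "a": [f.amplitude_a for f in fits],
            "b": [f.attenuation_b for f in fits],
            "r2": [f.r_squared for f in fits],
            "rmse": [f.rmse for f in fits],
            "max_intensity": [f.max_intensity for f in fits],
            "surface_index": [f.surface_index for f in fits],
            "converged": [bool(f.converged) for f in fits],
        },
        columns=list(_FIT_COLUMNS),
    )


def frame_to_fits(frame: pd.DataFrame) -> list[FitResult]:
    return [
        FitResult(
            amplitude_a=float(r.a),
            attenuation_b=float(r.b),
            r_squared=float(r.r2),
            rmse=float(r.rmse),
            max_intensity=float(r.max_intensity),
            surface_index=int(r.surface_index),
            converged=bool(r.converged),
            column_index=int(r.column_index),
        )
        for r in frame.itertuples()
    ]


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SeedSequence on (global, stage-hash).

    The stage hash is the SHA-256 of the stage name truncated to 8 bytes,
    so the derivation is stable across processes and platforms.
    """
    stage_key = int.from_bytes(
        hashlib.sha256(stage.encode()).digest()[:8], "big"
    )
    return int(np.random.SeedSequence([global_seed, stage_key]).generate_state(1)[0])
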