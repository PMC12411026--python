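"""Aggregate per-A-scan fit results into fixed-size bins of feature vectors.

Every ``bin_size`` consecutive converged fits yield one instance with the
mean and sample standard deviation (n-1) of the four fit quantities:
attenuation b, R^2, RMSE, and maximum intensity — 8 features total.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .attenuation import FitResult

__all__ = ["FEATURE_NAMES", "bin_features", "assemble_dataset"]

FEATURE_NAMES: tuple[str, ...] = (
    "mean_b",
    "sd_b",
    "mean_r2",
    "sd_r2",
    "mean_rmse",
    "sd_rmse",
    "mean_maxI",
    "sd_maxI",
)

_QUANTITIES = ("attenuation_b", "r_squared", "rmse", "max_intensity")


def bin_features(
    fits: Sequence[FitResult],
    bin_size: int = 5,
    label: str = "",
    sample_id: str = "",
    ddof: int = 1,
) -> pd.DataFrame:
    """Bin converged fits into consecutive non-overlapping groups.

    Non-converged fits are dropped first and bin boundaries recomputed on
    the surviving sequence; an incomplete trailing bin is discarded, so
    ``n_bins = floor(n_converged / bin_size)``.  ``ddof=1`` gives the
    sample standard deviation; set ``ddof=0`` for the population form.
    """
    if len(fits) == 0:
        raise ValueError("no fits supplied")
    if bin_size < 2:
        raise ValueError("bin_size must be >= 2")
    kept = [f for f in fits if f.converged]
    n_bins = len(kept) // bin_size
    if n_bins == 0:
        warnings.warn(
            f"fewer than bin_size={bin_size} converged fits; empty output",
            RuntimeWarning,
        )
        return pd.DataFrame(
            columns=[*FEATURE_NAMES, "label", "sample_id", "bin_index"]
        )
    values = np.array(
        [[getattr(f, q) for q in _QUANTITIES] for f in kept[: n_bins * bin_size]]
    )
    blocks = values.reshape(n_bins, bin_size, len(_QUANTITIES))
    means = blocks.mean(axis=1)
    sds = blocks.std(axis=1, ddof=ddof)
    data = {}
    for k in range(len(_QUANTITIES)):
        data[FEATURE_NAMES[2 * k]] = means[:, k]
        data[FEATURE_NAMES[2 * k + 1]] = sds[:, k]
    frame = pd.DataFrame(data, columns=list(FEATURE_NAMES))
    frame["label"] = label
    frame["sample_id"] = sample_id
    frame["bin_index"] = np.arange(n_bins)
    return frame


def assemble_dataset(binned: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-sample binned feature tables, preserving sample ids."""
    frames = [b for b in binned if len(b)]
    if not frames:
        raise ValueError("no binned features to assemble")
    out = pd.concat(frames, ignore_index=True)
    missing = [c for c in FEATURE_NAMES if c not in out.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    return out[[*FEATURE_NAMES, "label", "sample_id", "bin_index"]]
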