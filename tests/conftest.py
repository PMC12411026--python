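import numpy as np
import pytest

import attenuskin as ak


@pytest.fixture(scope="session")
def small_bscan():
    """60-column noisy BN B-scan with ground-truth mu."""
    cfg = ak.default_oct_config("BN", seed=11, n_ascans=60, n_depth=300)
    return ak.generate_bscan(cfg, "BN", "bn_small")


@pytest.fixture(scope="session")
def small_fits(small_bscan):
    return ak.fit_bscan(small_bscan, fit_depth=150)


@pytest.fixture(scope="session")
def noiseless_cfg():
    return ak.default_oct_config(
        "BN",
        seed=5,
        n_ascans=40,
        n_depth=300,
        speckle_sd=0.0,
        noise_floor_sd=0.0,
        surface_jitter_sd=0.0,
    )


@pytest.fixture(scope="session")
def raman_pair():
    """A simulated BN spectrum plus its ground truth."""
    cfg = ak.default_raman_config("BN", seed=3)
    return ak.generate_raman_spectrum(cfg, "BN")


def make_feature_table(
    n_per_class: int = 300,
    shift: float = 4.0,
    n_features: int = 8,
    seed: int = 0,
    informative: tuple[int, ...] = (0,),
):
    """Gaussian feature table: ``informative`` columns shifted by
    ``shift`` SDs between classes, the rest pure noise."""
    import pandas as pd

    from attenuskin.binning import FEATURE_NAMES

    rng = np.random.default_rng(seed)
    names = list(FEATURE_NAMES[:n_features])
    rows = []
    for label, sign in (("BN", 0.0), ("MM", 1.0)):
        x = rng.normal(0.0, 1.0, size=(n_per_class, n_features))
        for j in informative:
            x[:, j] += sign * shift
        frame = pd.DataFrame(x, columns=names)
        frame["label"] = label
        frame["sample_id"] = [
            f"{label}_{i % 3}" for i in range(n_per_class)
        ]
        frame["bin_index"] = np.arange(n_per_class)
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)
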