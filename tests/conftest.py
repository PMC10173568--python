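import numpy as np
import pandas as pd
import pytest

from dyadlds.sem import ModelSpec


def one_factor_spec(cols, marker_fixed=True, label_prefix=None):
    """Single-factor CFA spec with marker identification."""
    spec = ModelSpec(list(cols), ["f"])
    for pos, col in enumerate(cols):
        if pos == 0 and marker_fixed:
            spec.add("lambda", col, "f", free=False, value=1.0)
            spec.add("nu", col, free=False, value=0.0)
        else:
            spec.add("lambda", col, "f", free=True, value=1.0)
            spec.add("nu", col, free=True, value=0.0)
        spec.add("theta", col, col, free=True, value=0.5)
    spec.add("psi", "f", "f", free=True, value=1.0)
    spec.add("alpha", "f", free=True, value=0.0)
    return spec


def simulate_factor_data(rng, n, loadings, intercepts, resid_sd,
                         factor_mean=0.0, factor_sd=1.0):
    eta = rng.normal(factor_mean, factor_sd, n)
    cols = [f"y{j+1}" for j in range(len(loadings))]
    data = {
        c: intercepts[j] + loadings[j] * eta + rng.normal(0, resid_sd[j], n)
        for j, c in enumerate(cols)
    }
    return pd.DataFrame(data), eta


@pytest.fixture(scope="session")
def factor_frame():
    rng = np.random.default_rng(123)
    frame, _ = simulate_factor_data(
        rng, 2000, [1.0, 0.8, 1.3], [0.0, 0.5, -0.3], [0.7, 0.7, 0.7],
        factor_mean=1.0, factor_sd=1.2,
    )
    return frame


@pytest.fixture(scope="session")
def small_dyad_frame():
    from dyadlds import synthetic

    cfg = synthetic.default_config(n_dyads=1200, seed=77, constructs=("conduct",))
    frame, truth = synthetic.generate_dyads(cfg)
    return frame, truth, cfg
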