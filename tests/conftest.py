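import numpy as np
import pytest

from mumri import pgse_twitch as pt
from mumri import synthetic as syn


@pytest.fixture(scope="session")
def pgse_noiseless():
    """Default noiseless latency-scan phantom: (series, mask, truth)."""
    return syn.simulate_pgse_latency_series(syn.default_phantom_config())


@pytest.fixture(scope="session")
def pgse_noisy():
    """Same phantom with gaussian noise at 2% of baseline signal."""
    return syn.simulate_pgse_latency_series(
        syn.default_phantom_config(noise_sd=2.0, rng_seed=7)
    )


@pytest.fixture(scope="session")
def noiseless_maps(pgse_noiseless):
    series, mask, _ = pgse_noiseless
    return pt.map_metrics(series, mask, pt.DetectionConfig(smoothing_window=1))


def make_metric_map(values, name="t_contract"):
    """Build a MetricMap from a 2D array (NaN marks invalid voxels)."""
    values = np.asarray(values, dtype=float)
    valid = np.isfinite(values)
    vals = values[valid]
    return pt.MetricMap(
        values=values,
        valid=valid,
        name=name,
        mean=float(vals.mean()) if vals.size else float("nan"),
        sd=float(vals.std(ddof=0)) if vals.size else float("nan"),
        n_valid=int(valid.sum()),
        excluded_fraction=0.0,
    )
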