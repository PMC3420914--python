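import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cnsnv import (
    SimConfig,
    default_hyperparams,
    fit_em,
    simulate_dataset,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def hyper():
    return default_hyperparams()


@pytest.fixture(scope="session")
def small_dataset():
    """150 positions per copy-number state, fixed seed."""
    return simulate_dataset(SimConfig(n_per_state=150, seed=7))


@pytest.fixture(scope="session")
def fitted(small_dataset, hyper):
    counts, _ = small_dataset
    return fit_em(counts, hyper)


@pytest.fixture(scope="session")
def training_params(hyper):
    """Parameters fitted on a full-size simulated training set."""
    counts, _ = simulate_dataset(SimConfig(n_per_state=1000, seed=11))
    params, _ = fit_em(counts, hyper)
    return params


# Deep-amplicon germline sites showing allelic skew between the normal and
# metastatic tumour samples: (chrom, pos, normal depth, normal non-reference
# frequency, metastatic depth, metastatic non-reference frequency).
# Counts are reconstructed as round(freq * depth).
GERMLINE_SKEW_SITES = [
    ("1", 144932587, 17928, 0.3169, 18017, 0.2164),
    ("1", 149999951, 5387, 0.2046, 8770, 0.0409),
    ("1", 150543396, 61790, 0.6191, 78410, 0.3981),
    ("8", 146033676, 92012, 0.4499, 147007, 0.2683),
    ("9", 33375641, 24722, 0.2781, 22104, 0.1985),
    ("10", 29823914, 128591, 0.3867, 110884, 0.4808),
    ("11", 390124, 37172, 0.4601, 57560, 0.2907),
    ("11", 17499485, 101208, 0.5595, 58749, 0.1548),
    ("11", 65860057, 75400, 0.4044, 97848, 0.1738),
    ("11", 116569101, 260320, 0.5342, 237372, 0.1390),
    ("11", 124827464, 249388, 0.5259, 171924, 0.1372),
    ("12", 122455439, 208542, 0.3071, 175257, 0.4182),
    ("17", 36549887, 1774, 0.3207, 4409, 0.1851),
    ("19", 40691038, 209119, 0.5478, 247223, 0.1696),
    ("19", 42074256, 6402, 0.4531, 10867, 0.1214),
    ("19", 50869860, 70793, 0.4878, 90262, 0.1843),
    ("19", 59415177, 34753, 0.1592, 46500, 0.0642),
]


@pytest.fixture(scope="session")
def germline_skew_rows():
    rows = []
    for chrom, pos, nd, nf, td, tf in GERMLINE_SKEW_SITES:
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "normal_nonref": round(nf * nd),
                "normal_depth": nd,
                "tumor_nonref": round(tf * td),
                "tumor_depth": td,
            }
        )
    return pd.DataFrame(rows)
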