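import dataclasses

import numpy as np
import pandas as pd
import pytest

from cardiomir import SimConfig, generate_expression, screen
from cardiomir.energetics import EchoRecord
from cardiomir.preprocess import preprocess


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """One deterministic noise-free cohort: (matrix, design, truth)."""
    return generate_expression(SimConfig(noise_cv=0.0, seed=1))


@pytest.fixture(scope="session")
def zero_noise_screens(zero_noise_cohort):
    """Screen results for every comparison on the noise-free cohort."""
    matrix, design, _ = zero_noise_cohort
    normed = preprocess(matrix)
    return {
        case: screen(normed, design, ("NHF", case))
        for case in ("AMNHF", "OMHF", "AMHF")
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def random_echo_record(rng) -> EchoRecord:
    """A random physiologically valid echocardiographic record."""
    lvedv = rng.uniform(60, 250)
    lvidd = rng.uniform(3.5, 7.5)
    return EchoRecord(
        lvedv=lvedv,
        lvesv=lvedv * rng.uniform(0.2, 0.9),
        ivs=rng.uniform(0.6, 1.8),
        pwts=rng.uniform(0.7, 2.2),
        lvidd=lvidd,
        lvids=lvidd * rng.uniform(0.5, 0.95),
        sbp=rng.uniform(80, 200),
        lvet=rng.uniform(0.2, 0.4),
        lvsv=rng.uniform(30, 120),
        heart_rate=rng.uniform(45, 130),
        height=rng.uniform(145, 195),
        weight=rng.uniform(40, 100),
    )


@pytest.fixture
def small_matrix():
    return pd.DataFrame(
        {
            "s1": [100.0, 60.0, 49.999, 50.0],
            "s2": [200.0, 80.0, 300.0, 55.0],
            "s3": [150.0, 70.0, 120.0, 52.0],
        },
        index=pd.Index(["mA", "mB", "mC", "mD"], name="miRNA"),
    )
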