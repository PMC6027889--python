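import logging

import numpy as np
import pytest

from mintcoloc import NOISE_FREE, SimParams

logging.disable(logging.INFO)  # keep per-nucleus INFO logging out of test output


@pytest.fixture
def noise_free_params() -> SimParams:
    """Deterministic nucleus with noise and expression variability off."""
    return SimParams(
        noise_model=NOISE_FREE,
        expression_scale_sd=0.0,
        seed=7,
    )


def iou(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    return np.logical_and(a, b).sum() / np.logical_or(a, b).sum()


def pcc_bruteforce(y: np.ndarray, c: np.ndarray) -> float:
    """Direct elementwise evaluation of the correlation sum-formula."""
    y = [float(v) for v in np.asarray(y).ravel()]
    c = [float(v) for v in np.asarray(c).ravel()]
    n = len(y)
    ybar = sum(y) / n
    cbar = sum(c) / n
    num = sum((yi - ybar) * (ci - cbar) for yi, ci in zip(y, c))
    den = (sum((yi - ybar) ** 2 for yi in y) * sum((ci - cbar) ** 2 for ci in c)) ** 0.5
    return num / den
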