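import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rdnafoot.fragmatrix import FragMatrix
from rdnafoot.regions import GenomicInterval, default_landmarks
from rdnafoot.simulate import (
    sir2_g1_model,
    simulate_mnase_fragments,
    terminator_model,
    wt_g1_model,
    wt_g2_model,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def lm():
    return default_landmarks()


def _sim(model_factory, seed, n=30_000):
    lm_ = default_landmarks()
    return simulate_mnase_fragments(model_factory(lm_), n, seed)


@pytest.fixture(scope="session")
def wt_g1_sim():
    return _sim(wt_g1_model, 101)


@pytest.fixture(scope="session")
def wt_g2_sim():
    return _sim(wt_g2_model, 102)


@pytest.fixture(scope="session")
def sir2_g1_sim():
    return _sim(sir2_g1_model, 103)


@pytest.fixture(scope="session")
def terminator_sim():
    return _sim(terminator_model, 104)


def perbase_matrix_oracle(
    fragments, window: GenomicInterval, len_range=(40, 250), mode="span"
):
    """Independent nested-loop per-base counting oracle for FragMatrix
    (1 bp position and length bins)."""
    len_min, len_max = len_range
    counts = np.zeros((window.length, len_max - len_min + 1))
    contributing = 0
    for f in fragments:
        length = f.end - f.start
        if f.chrom != window.chrom or not (len_min <= length <= len_max):
            continue
        j = length - len_min
        if mode == "midpoint":
            mid = (f.start + f.end) // 2
            if window.start <= mid < window.end:
                counts[mid - window.start, j] += 1
                contributing += 1
        else:
            s = max(f.start, window.start)
            e = min(f.end, window.end)
            if s < e:
                for p in range(s, e):
                    counts[p - window.start, j] += 1
                contributing += 1
    return counts, contributing


@pytest.fixture(scope="session")
def matrix_oracle():
    return perbase_matrix_oracle


def assert_matrix_matches_oracle(matrix: FragMatrix, oracle_counts, oracle_n):
    assert matrix.counts.shape == oracle_counts.shape
    np.testing.assert_array_equal(matrix.counts, oracle_counts)
    assert matrix.n_fragments == oracle_n
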