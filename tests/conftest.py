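import numpy as np
import pytest

from popcaim.synthetic import MovieConfig, simulate_movie

MOVIE_SEED = 42


@pytest.fixture(scope="session")
def standard_movie():
    """The standard imaging fixture: 10 neurons + 3 astrocytes at SNR 5.

    SNR is peak transient signal over pixel noise sd: amplitude 0.5 on a
    baseline of 100 gives a 50-count signal over 10-count pixel noise.
    """
    cfg = MovieConfig(n_neurons=10, n_astrocytes=3, noise_sd=0.1, amplitude=0.5)
    return simulate_movie(cfg, seed=MOVIE_SEED)


@pytest.fixture(scope="session")
def clean_movie():
    """Noise-free variant of the standard movie for extraction checks."""
    cfg = MovieConfig(n_neurons=10, n_astrocytes=3, noise_sd=0.0, amplitude=0.5)
    return simulate_movie(cfg, seed=MOVIE_SEED)


def sliding_median_oracle(trace, fps, half_window_s):
    """Naive per-sample sort-and-median dF/F baseline, independent of the
    vectorized implementation."""
    import statistics

    trace = list(map(float, trace))
    n = len(trace)
    out = []
    for i in range(n):
        window = [trace[j] for j in range(n) if abs(j - i) <= half_window_s * fps]
        f0 = statistics.median(sorted(window))
        out.append((trace[i] - f0) / f0)
    return np.array(out)
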