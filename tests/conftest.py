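import numpy as np
import pytest

from spectarget.ism import EIIPTable


@pytest.fixture(scope="session")
def eiip_table() -> EIIPTable:
    return EIIPTable.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def oracle_dft_amplitudes(values: np.ndarray, n_fft: int) -> np.ndarray:
    """Independent O(N^2) direct-summation DFT amplitude oracle.

    Mean-subtracts, zero-pads to n_fft, and returns |X_k| for k = 1..n_fft/2
    by explicit summation — no FFT anywhere.
    """
    x = np.asarray(values, dtype=float) - np.mean(values)
    amps = np.empty(n_fft // 2)
    for k in range(1, n_fft // 2 + 1):
        re = sum(x[n] * np.cos(-2 * np.pi * k * n / n_fft) for n in range(len(x)))
        im = sum(x[n] * np.sin(-2 * np.pi * k * n / n_fft) for n in range(len(x)))
        amps[k - 1] = np.hypot(re, im)
    return amps
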