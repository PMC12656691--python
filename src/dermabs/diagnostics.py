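"""MCMC diagnostics: effective sample size and highest-posterior-density intervals."""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["effective_sample_size", "hpdi"]


def effective_sample_size(draws) -> float:
    """Effective sample size via Geyer's initial-positive-sequence estimator.

    Autocovariances are summed in adjacent pairs until the first pair sum
    turns non-positive; the truncated sum gives the integrated
    autocorrelation time. For positively autocorrelated chains the result
    is below the draw count; a constant chain is reported as the draw count
    with a warning (there is no autocorrelation to estimate).
    """
    x = np.asarray(draws, dtype=float).ravel()
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 draws to estimate ESS")
    x = x - x.mean()
    var = float(x @ x) / n
    if var == 0.0:
        warnings.warn("constant chain: ESS reported as the draw count", stacklevel=2)
        return float(n)
    # autocovariance via FFT
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    rho = acov / acov[0]
    # Geyer initial positive sequence: sum Gamma_m = rho[2m] + rho[2m+1] while > 0
    tau = 1.0
    m_idx = 1
    while m_idx + 1 < n:
        gamma = rho[m_idx] + rho[m_idx + 1]
        if gamma <= 0:
            break
        tau += 2.0 * gamma
        m_idx += 2
    return float(n / tau)


def hpdi(draws, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the sorted draws."""
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 20:
        raise ValueError("need at least 20 draws for an HPDI")
    m = int(np.ceil(mass * n))
    m = min(m, n)
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])
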