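"""Independent oracles shared across the suite.

These deliberately avoid the library code paths they are used to check.
"""

import numpy as np

from holoperf import MultiEchoSeries, default_echo_times


def brute_force_dp(doses, p):
    """Independent oracle for Dp%: sort ascending, take the (100 - p)-th
    percentile position k = (n - 1) q, linear interpolation between the
    bracketing order statistics."""
    doses = np.sort(np.asarray(doses, float))
    q = (100.0 - p) / 100.0
    k = (doses.size - 1) * q
    lo, hi = int(np.floor(k)), int(np.ceil(k))
    return doses[lo] + (doses[hi] - doses[lo]) * (k - lo)


def pearson_oracle(x, y):
    """From-scratch covariance-formula Pearson coefficient."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def decay_series(r2star_s, s0=1000.0, n_echoes=10, noise_sd=0.0,
                 shape=(5, 5, 4), seed=0):
    """Mono-exponential multi-echo magnitude series with optional Rician
    noise, built directly from the closed form."""
    tes = default_echo_times(n_echoes)
    r2 = np.broadcast_to(np.asarray(r2star_s, float), shape)
    signal = s0 * np.exp(-r2[..., None] * tes / 1000.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = np.sqrt(
            (signal + rng.normal(0, noise_sd, signal.shape)) ** 2
            + rng.normal(0, noise_sd, signal.shape) ** 2
        )
    return MultiEchoSeries.from_array(signal, tes)
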