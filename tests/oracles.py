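"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the library code paths (and numpy's FFT where the
check is about the transform itself): spectra are computed with explicit
DFT sums, distances with explicit loops, so agreement is evidence rather
than tautology.
"""

import math

import numpy as np


def dft_onesided_power(x):
    """One-sided power spectrum of a real vector via explicit DFT sums."""
    n = len(x)
    n_freq = n // 2 + 1
    out = []
    for k in range(n_freq):
        re = sum(x[t] * math.cos(-2 * math.pi * k * t / n) for t in range(n))
        im = sum(x[t] * math.sin(-2 * math.pi * k * t / n) for t in range(n))
        out.append(re**2 + im**2)
    return np.array(out)


def full_dft(x):
    """Full complex DFT via explicit sums."""
    n = len(x)
    return np.array(
        [
            sum(x[t] * np.exp(-2j * math.pi * k * t / n) for t in range(n))
            for k in range(n)
        ]
    )


def inverse_dft(X):
    n = len(X)
    return np.array(
        [
            sum(X[k] * np.exp(2j * math.pi * k * t / n) for k in range(n)) / n
            for t in range(n)
        ]
    )


def spectral_nd_bruteforce(dff, sample_rate, window_seconds=1.0, normalize=True):
    """Spectral differentiation by enumeration: explicit DFTs, explicit pairwise
    Euclidean distances, explicit median."""
    dff = np.atleast_2d(dff)
    n_cells, n_samples = dff.shape
    win = int(round(window_seconds * sample_rate))
    n_win = n_samples // win
    states = []
    for w in range(n_win):
        concat = []
        for c in range(n_cells):
            seg = dff[c, w * win : (w + 1) * win]
            concat.extend(dft_onesided_power(seg))
        states.append(np.array(concat))
    dists = []
    for i in range(n_win):
        for j in range(i + 1, n_win):
            dists.append(math.sqrt(float(((states[i] - states[j]) ** 2).sum())))
    dists = sorted(dists)
    m = len(dists)
    median = (
        dists[m // 2] if m % 2 == 1 else 0.5 * (dists[m // 2 - 1] + dists[m // 2])
    )
    return median / math.sqrt(n_cells) if normalize else median


def temporal_scramble_pixel_bruteforce(series, random_phases):
    """Phase-scramble one pixel's 30-sample window with explicit DFTs.

    ``random_phases`` are the free phases (len n//2 - 1 for even n); the new
    phase vector is [DC phase, r, Nyquist phase, -reversed r].
    """
    n = len(series)
    X = full_dft(np.asarray(series, dtype=float))
    mag = np.abs(X)
    phase = np.angle(X)
    r = np.asarray(random_phases)
    new_phase = np.concatenate(
        [[phase[0]], r, [phase[n // 2]], -r[::-1]]
    )
    rebuilt = mag * np.exp(1j * new_phase)
    return inverse_dft(rebuilt).real
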