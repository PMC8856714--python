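"""Synthetic calcium-imaging sessions and cohorts.

The generator emulates the statistical structure the differentiation analysis
assumes: a cohort of sessions spanning 3 cortical layers x 5 visual areas,
each session presenting 12 movie stimuli (2 tagged unscrambled, 3 scrambled,
7 other) in 10 randomized blocks of 30-s trials separated by 4-s gray gaps at
30 Hz.  Cellular activity is a doubly-stochastic point process (Poisson events
plus Poisson-triggered bursts) convolved with an idealized GCaMP6f impulse
response (difference of exponentials, 0.6 s decay / 0.05 s rise) and corrupted
by i.i.d. Gaussian noise.

The category effect is a shared slow latent modulator: within each trial a
multiplicative response gain, constant within each 1-s window and redrawn
across windows, scales the population's event rates, burst-trigger rates, and
event magnitudes together.  In designated responsive (layer, area)
populations, unscrambled trials draw window gains with variance exceeding the
scrambled trials' by ``effect_delta``, producing the across-window state
variability that the spectral measure detects (a separate ``rate_effect_delta``
knob adds a pure mean-rate component).  With ``effect_delta = 0`` the two
categories are statistically exchangeable, which downstream permutation tests
rely on for null calibration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from scipy.ndimage import gaussian_filter1d

from .core import AREAS, LAYERS, BehaviorTraces, FluorescenceSession

#: Window-gain variance increment at which the per-session permutation test on
#: spectral differentiation rejects in >= 80% of responsive-population sessions
#: (established by the power-calibration test in the suite).
EFFECT_DELTA_STAR = 0.29


@dataclass
class KernelParams:
    """Difference-of-exponentials calcium impulse response (GCaMP6f-like)."""

    tau_decay: float = 0.6  # s
    tau_rise: float = 0.05  # s
    peak_amplitude: float = 1.0

    def __post_init__(self):
        if not (self.tau_decay > self.tau_rise > 0):
            raise ValueError(
                f"require tau_decay > tau_rise > 0, got {self.tau_decay}, {self.tau_rise}"
            )


def gcamp_kernel(
    params: KernelParams, sample_rate: float, duration: float
) -> np.ndarray:
    """Sampled difference-of-exponentials kernel, normalized to ``peak_amplitude``.

    k(t) = A (exp(-t/tau_d) - exp(-t/tau_r)); k(0) = 0, single interior maximum
    at t* = ln(tau_d/tau_r) * tau_d tau_r / (tau_d - tau_r), decaying toward 0.
    """
    if duration < 5 * params.tau_decay:
        raise ValueError("kernel duration must cover at least 5 decay time constants")
    t = np.arange(0.0, duration, 1.0 / sample_rate)
    k = np.exp(-t / params.tau_decay) - np.exp(-t / params.tau_rise)
    return params.peak_amplitude * k / k.max()


def kernel_peak_time(params: KernelParams) -> float:
    """Closed-form mode of the difference of exponentials."""
    td, tr = params.tau_decay, params.tau_rise
    return np.log(td / tr) * td * tr / (td - tr)


@dataclass
class SpikeTrain:
    """Event times (s) for one cell, nondecreasing, within the session duration."""

    times: np.ndarray
    duration: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) and (
            self.times.min() < 0 or self.times.max() >= self.duration
        ):
            raise ValueError("event times outside [0, duration)")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("event times must be nondecreasing")


def simulate_spikes(
    rate: np.ndarray,
    sample_rate: float,
    seed: int,
    burst_rate: float = 0.0,
    burst_duration: float = 0.3,
    burst_event_rate: float = 20.0,
    mode: str = "poisson",
    period: float = 1.0,
    period_pattern: Sequence[float] = (0.0, 0.04, 0.08),
) -> SpikeTrain:
    """Generate a spike train from a sample-gridded rate profile (Hz).

    ``mode="poisson"`` draws a doubly-stochastic train: Poisson events at the
    instantaneous rate plus Poisson-triggered bursts (triggers at
    ``burst_rate`` Hz; each elevates the rate by ``burst_event_rate`` Hz for
    ``burst_duration`` s).  ``mode="periodic"`` is deterministic: the offsets
    in ``period_pattern`` repeat with exact period ``period`` s.
    """
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rate profile must be nonnegative")
    duration = len(rate) / sample_rate
    if mode == "periodic":
        pattern = np.asarray(period_pattern, dtype=float)
        n_periods = int(np.floor(duration / period))
        times = (np.arange(n_periods)[:, None] * period + pattern[None, :]).ravel()
        return SpikeTrain(times=times[times < duration], duration=duration)
    if mode != "poisson":
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    dt = 1.0 / sample_rate
    lam = rate.copy()
    if burst_rate > 0:
        triggers = rng.poisson(burst_rate * dt, size=len(rate))
        box = np.ones(max(1, int(round(burst_duration * sample_rate))))
        lam = lam + np.convolve(triggers, box)[: len(rate)] * burst_event_rate
    counts = rng.poisson(lam * dt)
    idx = np.repeat(np.arange(len(rate)), counts)
    times = np.sort(idx * dt + rng.random(idx.size) * dt)
    return SpikeTrain(times=times, duration=duration)


def render_dff(
    spikes: SpikeTrain,
    kernel: KernelParams,
    sample_rate: float,
    noise_sigma: float = 0.0,
    seed: int = 0,
    magnitudes: Optional[np.ndarray] = None,
    circular: bool = False,
) -> np.ndarray:
    """Render a dF/F trace as a linear superposition of kernels plus Gaussian noise.

    Events are binned onto the sample grid; ``magnitudes`` (default all-1)
    scales each event's kernel.  With ``circular=True`` the convolution wraps,
    so an exactly P-periodic train yields an exactly P-periodic trace.
    """
    n = int(round(spikes.duration * sample_rate))
    amp = np.zeros(n)
    if len(spikes.times):
        idx = np.minimum((spikes.times * sample_rate).astype(int), n - 1)
        mags = np.ones(len(idx)) if magnitudes is None else np.asarray(magnitudes)
        np.add.at(amp, idx, mags)
    k = gcamp_kernel(kernel, sample_rate, duration=max(5 * kernel.tau_decay, 2.0))
    if circular:
        k_folded = np.zeros(n)
        for start in range(0, len(k), n):
            chunk = k[start : start + n]
            k_folded[: len(chunk)] += chunk
        trace = np.fft.irfft(np.fft.rfft(amp) * np.fft.rfft(k_folded), n=n)
    else:
        trace = np.convolve(amp, k)[:n]
    if noise_sigma > 0:
        trace = trace + np.random.default_rng(seed).normal(0, noise_sigma, n)
    return trace


@dataclass
class CohortSpec:
    """Generative parameters for a synthetic study cohort.

    Defaults mirror the target study design: 3 layers x 5 areas x 3 replicate
    sessions (45 sessions), 100-400 cells per session, and a category effect
    confined to L2/3 of AL and AM.
    """

    n_sessions_per_population: int = 3
    layers: Sequence[str] = LAYERS
    areas: Sequence[str] = AREAS
    n_cells_range: tuple[int, int] = (100, 400)
    baseline_rate: float = 0.5  # Hz, mean event rate per cell
    burst_rate: float = 0.08  # Hz, burst-trigger rate
    burst_duration: float = 0.3  # s
    burst_event_rate: float = 20.0  # Hz within a burst
    event_magnitude_mean: float = 1.0  # dF/F units per event
    effect_delta: float = EFFECT_DELTA_STAR
    rate_effect_delta: float = 0.0  # optional mean-rate gain on unscrambled trials
    responsive_populations: frozenset = frozenset({("L2/3", "AL"), ("L2/3", "AM")})
    modulator_base_var: float = 0.04
    noise_sigma: float = 0.05  # dF/F units
    # arousal model
    bout_rate: float = 1.0 / 60.0  # locomotion bout starts per second
    bout_mean_duration: float = 12.0  # s
    arousal_gain_coupling: float = 0.0  # rate gain per unit arousal (off by default)
    seed: int = 0

    # fixed study structure
    n_stimuli: int = 12
    n_blocks: int = 10
    trial_seconds: float = 30.0
    gap_seconds: float = 4.0
    sample_rate: float = 30.0

    def __post_init__(self):
        if self.effect_delta < 0:
            raise ValueError("effect_delta must be >= 0")
        pops = {(l, a) for l in self.layers for a in self.areas}
        if not set(self.responsive_populations) <= pops:
            raise ValueError("responsive_populations not a subset of generated populations")


#: A mean-one uniform gain on [1 - a, 1 + a] has variance a^2 / 3, so the
#: largest variance representable without negative gains is 1/3.
MAX_MODULATOR_VAR = 1.0 / 3.0


def _uniform_gain(var: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Mean-one uniform window gain with across-window variance exactly ``var``.

    A broad bounded distribution (rather than a skewed one) is used because
    the median-of-pairwise-distances measure responds to spread among typical
    window pairs, not to rare extreme windows.
    """
    if var > MAX_MODULATOR_VAR + 1e-12:
        raise ValueError(
            f"modulator variance {var} exceeds the representable maximum 1/3"
        )
    a = np.sqrt(3.0 * var)
    return rng.uniform(1.0 - a, 1.0 + a, size)


STIMULUS_IDS = tuple(
    [f"unscrambled-{i}" for i in (1, 2)]
    + [f"scrambled-{i}" for i in (1, 2, 3)]
    + [f"other-{i}" for i in range(1, 8)]
)


def _stimulus_category(stimulus_id: str) -> str:
    return stimulus_id.rsplit("-", 1)[0]


def _trial_table(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    fs = spec.sample_rate
    trial_len = int(round(spec.trial_seconds * fs))
    gap_len = int(round(spec.gap_seconds * fs))
    rows = []
    cursor = gap_len  # lead-in gray
    for block in range(spec.n_blocks):
        order = rng.permutation(spec.n_stimuli)
        for j in order:
            sid = STIMULUS_IDS[j]
            rows.append(
                {
                    "stimulus_id": sid,
                    "category": _stimulus_category(sid),
                    "block": block,
                    "start_sample": cursor,
                    "end_sample": cursor + trial_len,
                }
            )
            cursor += trial_len + gap_len
    return pd.DataFrame(rows)


def _arousal_traces(
    spec: CohortSpec, n_samples: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Locomotion velocity (cm/s), pupil diameter (a.u.), and a latent arousal state."""
    fs = spec.sample_rate
    dt = 1.0 / fs
    starts = rng.poisson(spec.bout_rate * dt, size=n_samples).astype(bool)
    running = np.zeros(n_samples)
    for s in np.flatnonzero(starts):
        length = int(rng.exponential(spec.bout_mean_duration) * fs)
        speed = rng.lognormal(mean=np.log(10.0), sigma=0.4)
        running[s : s + max(length, 1)] = speed
    velocity = gaussian_filter1d(running, sigma=0.5 * fs) + rng.normal(
        0, 0.3, n_samples
    )
    # slow traces smoothed on a 1-s grid, then linearly resampled to the clock
    coarse = (running > 0).astype(float)[: (n_samples // 30) * 30]
    coarse = coarse.reshape(-1, 30).mean(axis=1)
    t_coarse = np.arange(len(coarse)) * 30 + 15
    arousal = np.interp(
        np.arange(n_samples), t_coarse, gaussian_filter1d(coarse, sigma=2.0)
    )
    pupil_noise = np.interp(
        np.arange(n_samples),
        t_coarse,
        gaussian_filter1d(rng.normal(0, 2.0, len(coarse)), sigma=1.0),
    )
    pupil = 30.0 + 20.0 * arousal + pupil_noise
    return velocity, pupil, arousal


def generate_session(
    spec: CohortSpec, layer: str, area: str, seed: int, session_id: Optional[str] = None
) -> FluorescenceSession:
    """Generate one seeded session for a (layer, area) population.

    Deterministic given (spec, layer, area, seed).  The trial table realizes
    the 12 stimuli x 10 randomized blocks design; the category effect (window-
    gain variance increment ``effect_delta``, and optionally a mean-rate gain
    ``rate_effect_delta``) is applied on unscrambled trials only when
    (layer, area) is in ``responsive_populations``.
    """
    rng = np.random.default_rng(seed)
    fs = spec.sample_rate
    dt = 1.0 / fs
    trials = _trial_table(spec, rng)
    n_samples = int(trials["end_sample"].max() + spec.gap_seconds * fs)
    responsive = (layer, area) in set(spec.responsive_populations)
    win = int(round(fs))  # 1-s modulator windows

    # Shared slow modulator: per-trial, per-1-s-window multiplicative gain.
    gain = np.ones(n_samples)
    for row in trials.itertuples():
        boosted = responsive and row.category == "unscrambled"
        var = spec.modulator_base_var + (spec.effect_delta if boosted else 0.0)
        n_win = (row.end_sample - row.start_sample) // win
        g = _uniform_gain(var, n_win, rng)
        if boosted:
            g = g * (1.0 + spec.rate_effect_delta)
        gain[row.start_sample : row.start_sample + n_win * win] = np.repeat(g, win)

    velocity, pupil, arousal = _arousal_traces(spec, n_samples, rng)
    if spec.arousal_gain_coupling:
        gain = gain * (1.0 + spec.arousal_gain_coupling * arousal)

    n_cells = int(rng.integers(spec.n_cells_range[0], spec.n_cells_range[1] + 1))
    cell_rates = spec.baseline_rate * rng.lognormal(mean=-0.045, sigma=0.3, size=n_cells)
    kernel = gcamp_kernel(KernelParams(), fs, duration=3.0)
    box_len = max(1, int(round(spec.burst_duration * fs)))
    cum_gain = np.cumsum(gain) * dt  # integral of the gain, in gain-seconds
    total_gain_time = cum_gain[-1]

    dff = np.empty((n_cells, n_samples))
    chunk = 64  # bound peak memory for large populations
    for lo in range(0, n_cells, chunk):
        hi = min(lo + chunk, n_cells)
        amp = np.zeros((hi - lo, n_samples))
        for c in range(lo, hi):
            # burst triggers follow the modulated rate; each trigger elevates
            # the event rate by burst_event_rate for box_len samples
            n_trig = rng.poisson(spec.burst_rate * total_gain_time)
            trig_pos = np.searchsorted(cum_gain, rng.random(n_trig) * total_gain_time)
            edges = np.zeros(n_samples + box_len)
            np.add.at(edges, trig_pos, 1.0)
            np.add.at(edges, trig_pos + box_len, -1.0)
            in_burst = np.cumsum(edges[:n_samples])
            rate_c = cell_rates[c] * gain + in_burst * spec.burst_event_rate
            cum_c = np.cumsum(rate_c) * dt
            n_ev = rng.poisson(cum_c[-1])
            pos = np.searchsorted(cum_c, rng.random(n_ev) * cum_c[-1])
            # the modulator is a response gain: it scales event magnitudes as
            # well as rates, as arousal-like multiplicative gain does
            mags = rng.exponential(spec.event_magnitude_mean, n_ev) * gain[pos]
            np.add.at(amp[c - lo], pos, mags)
        traces = fftconvolve(amp, kernel[None, :], axes=1)[:, :n_samples]
        dff[lo:hi] = traces + rng.normal(0, spec.noise_sigma, traces.shape)

    if session_id is None:
        session_id = f"synthetic-{layer.replace('/', '')}-{area}-{seed}"
    cells = pd.DataFrame(
        {"cell_id": [f"{session_id}-c{i:04d}" for i in range(n_cells)], "valid": True}
    )
    session = FluorescenceSession(
        dff=dff,
        cells=cells,
        trials=trials,
        session_id=session_id,
        layer=layer,
        area=area,
        sample_rate=fs,
        behavior=BehaviorTraces(locomotion_velocity=velocity, pupil_diameter=pupil),
    )
    return session.validate()


def session_seed(spec_seed: int, index: int) -> int:
    """Deterministic per-session seed derived from the cohort seed."""
    return int(
        np.random.SeedSequence([spec_seed, index]).generate_state(1)[0] % (2**31)
    )


def generate_cohort(spec: CohortSpec):
    """Yield one seeded session per (layer, area, replicate), plus a manifest.

    Returns ``(sessions, manifest)`` where the manifest records session_id,
    layer, area, replicate, seed, and n_cells.
    """
    sessions = []
    records = []
    index = 0
    for layer in spec.layers:
        for area in spec.areas:
            for rep in range(spec.n_sessions_per_population):
                seed = session_seed(spec.seed, index)
                sid = f"synthetic-{layer.replace('/', '')}-{area}-r{rep}"
                s = generate_session(spec, layer, area, seed, session_id=sid)
                sessions.append(s)
                records.append(
                    {
                        "session_id": s.session_id,
                        "layer": layer,
                        "area": area,
                        "replicate": rep,
                        "seed": seed,
                        "n_cells": s.n_cells,
                    }
                )
                index += 1
    return sessions, pd.DataFrame(records)
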