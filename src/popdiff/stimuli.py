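"""Movie-stimulus operations: Fourier phase scrambling, blurring, and stimulus statistics.

Phase scrambling destroys high-level image structure while (up to uint8
quantization) preserving the power spectrum, yielding control stimuli whose
low-order statistics match the originals.  Two procedures are provided:

* temporal — each pixel's 30-sample intensity series within each contiguous
  1-s window gets a fresh conjugate-symmetric random phase (DC and Nyquist
  phases kept, the free phases drawn uniformly on [0, 2pi));
* spatial — each 1-s window's 3-D spectrum gets a single random 2-D phase
  field (itself the phase of a random real image, hence conjugate-symmetric)
  added to its spatial dimensions, broadcast across temporal frequencies.

Both leave every magnitude spectrum untouched before quantization; rounding
and clipping into [0, 255] then perturbs the spectra slightly, so quantized
outputs are closely matched but not spectrum-identical to their sources.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import MovieStimulus
from .differentiation import SpectralParams, spectral_differentiation


@dataclass
class ScrambleParams:
    mode: str = "temporal"  # "temporal" | "spatial"
    window_length: float = 1.0  # s
    seed: int = 0
    quantize: bool = True  # round + clip into [0, 255] -> uint8


@dataclass
class BlurParams:
    """Receptive-field-scale circular Gaussian blur.

    ``hwhm_degrees`` defaults to 8.92 (the median L2/3 V1 receptive-field
    radius in visual degrees).  ``degrees_per_pixel`` depends on screen
    geometry and must be set for real stimuli; the default of 0.625 deg/px
    corresponds to a 192-px-wide frame spanning roughly 120 degrees at a
    15-cm viewing distance.
    """

    hwhm_degrees: float = 8.92
    degrees_per_pixel: float = 0.625
    truncation_radius: float = 4.0  # in sigma multiples
    edge_mode: str = "reflect"  # "reflect" | "constant"

    def __post_init__(self):
        if self.hwhm_degrees <= 0 or self.degrees_per_pixel <= 0:
            raise ValueError("hwhm_degrees and degrees_per_pixel must be > 0")

    @property
    def sigma_pixels(self) -> float:
        return (self.hwhm_degrees / self.degrees_per_pixel) / np.sqrt(2 * np.log(2))


def _window_frames(movie: MovieStimulus, window_length: float) -> int:
    win = window_length * movie.frame_rate
    if abs(win - round(win)) > 1e-9:
        raise ValueError("window_length * frame_rate must be an integer")
    win = int(round(win))
    if movie.n_frames % win != 0:
        raise ValueError(
            f"{movie.n_frames} frames not divisible into {win}-frame windows"
        )
    return win


def _quantize(frames: np.ndarray) -> np.ndarray:
    # round half away from zero, then clip (negatives clip to 0 regardless)
    rounded = np.copysign(np.floor(np.abs(frames) + 0.5), frames)
    return np.clip(rounded, 0, 255).astype(np.uint8)


def _random_phase_vector(
    phase: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Conjugate-symmetric randomized phase along axis 0.

    For even N the N/2 - 1 free phases are drawn uniformly and mirrored with
    negation; the DC and Nyquist phases are kept from the input (for N = 30
    this is the 14-element construction).  For odd N there is no Nyquist term
    and (N - 1)/2 phases are free.
    """
    n = phase.shape[0]
    if n % 2 == 0:
        n_free = n // 2 - 1
        rand = rng.uniform(0, 2 * np.pi, size=(n_free,) + phase.shape[1:])
        return np.concatenate(
            [phase[:1], rand, phase[n // 2 : n // 2 + 1], -rand[::-1]], axis=0
        )
    n_free = (n - 1) // 2
    rand = rng.uniform(0, 2 * np.pi, size=(n_free,) + phase.shape[1:])
    return np.concatenate([phase[:1], rand, -rand[::-1]], axis=0)


def temporal_phase_scramble(movie: MovieStimulus, params: ScrambleParams):
    """Independently randomize each pixel's temporal phase within 1-s windows.

    Returns a :class:`MovieStimulus` when ``params.quantize`` is set, else the
    raw real-valued frame array (whose per-window per-pixel magnitude spectra
    equal the input's exactly, up to floating-point error).
    """
    win = _window_frames(movie, params.window_length)
    rng = np.random.default_rng(params.seed)
    frames = movie.frames.astype(float)
    out = np.empty_like(frames)
    for start in range(0, movie.n_frames, win):
        seg = frames[start : start + win]
        spectrum = np.fft.fft(seg, axis=0)
        new_phase = _random_phase_vector(np.angle(spectrum), rng)
        rebuilt = np.abs(spectrum) * np.exp(1j * new_phase)
        out[start : start + win] = np.fft.ifft(rebuilt, axis=0).real
    if params.quantize:
        return MovieStimulus(frames=_quantize(out), frame_rate=movie.frame_rate)
    return out


def spatial_phase_scramble(movie: MovieStimulus, params: ScrambleParams):
    """Randomize the spatial phase of each 1-s window's 3-D spectrum.

    One random 2-D phase field per window — the phase of the 2-D transform of
    a random real frame-shaped image, hence conjugate-symmetric — is added to
    the spatial dimensions of the 3-D phase, broadcast across temporal
    frequencies; magnitudes are kept.  The inverse transform is real up to
    numerical tolerance before rounding.
    """
    win = _window_frames(movie, params.window_length)
    rng = np.random.default_rng(params.seed)
    frames = movie.frames.astype(float)
    height, width = frames.shape[1:]
    out = np.empty_like(frames)
    for start in range(0, movie.n_frames, win):
        seg = frames[start : start + win]
        spectrum = np.fft.fftn(seg)
        random_frame = rng.random((height, width))
        phase_field = np.angle(np.fft.fft2(random_frame))
        rebuilt = np.abs(spectrum) * np.exp(
            1j * (np.angle(spectrum) + phase_field[None, :, :])
        )
        out[start : start + win] = np.fft.ifftn(rebuilt).real
    if params.quantize:
        return MovieStimulus(frames=_quantize(out), frame_rate=movie.frame_rate)
    return out


def scramble_movie(movie: MovieStimulus, params: ScrambleParams):
    """Dispatch on ``params.mode``."""
    if params.mode == "temporal":
        return temporal_phase_scramble(movie, params)
    if params.mode == "spatial":
        return spatial_phase_scramble(movie, params)
    raise ValueError(f"unknown scramble mode {params.mode!r}")


def window_magnitude_spectra(
    frames: np.ndarray, frame_rate: float, window_length: float = 1.0
) -> np.ndarray:
    """Per-window per-pixel temporal DFT magnitudes, stacked [windows, freq, H, W]."""
    frames = np.asarray(frames, dtype=float)
    win = int(round(window_length * frame_rate))
    n_win = frames.shape[0] // win
    mags = [
        np.abs(np.fft.fft(frames[i * win : (i + 1) * win], axis=0))
        for i in range(n_win)
    ]
    return np.stack(mags)


def quantization_spectrum_deviation(
    ideal_frames: np.ndarray,
    quantized: MovieStimulus,
    window_length: float = 1.0,
) -> float:
    """Max relative magnitude-spectrum deviation introduced by uint8 quantization.

    Compares the real-valued scramble output (``ideal_frames``, whose spectra
    match the source exactly) against its rounded-and-clipped uint8
    representation; the quantized spectra are closely matched but not equal.
    """
    m0 = window_magnitude_spectra(ideal_frames, quantized.frame_rate, window_length)
    m1 = window_magnitude_spectra(
        quantized.frames, quantized.frame_rate, window_length
    )
    scale = np.abs(m0).max()
    return float(np.abs(m1 - m0).max() / scale) if scale else 0.0


def blur_movie(movie: MovieStimulus, params: BlurParams) -> np.ndarray:
    """Per-frame circular Gaussian blur; returns real-valued frames.

    sigma_pixels = (hwhm / degrees_per_pixel) / sqrt(2 ln 2); the kernel is
    truncated at ``truncation_radius`` sigma.
    """
    frames = movie.frames.astype(float)
    return gaussian_filter(
        frames,
        sigma=(0.0, params.sigma_pixels, params.sigma_pixels),
        truncate=params.truncation_radius,
        mode=params.edge_mode,
    )


def stimulus_differentiation(
    movie: MovieStimulus,
    blur: BlurParams | None = None,
    spectral: SpectralParams | None = None,
    pre_blurred_frames: np.ndarray | None = None,
) -> float:
    """Spectral differentiation of a movie, treating each pixel as a "cell".

    Frames are blurred at receptive-field scale first (pass
    ``pre_blurred_frames`` to skip the internal blur), flattened to a
    [pixels x frames] matrix, and fed through the spectral differentiation
    measure including its sqrt(n_pixels) normalization.
    """
    if pre_blurred_frames is not None:
        frames = np.asarray(pre_blurred_frames, dtype=float)
    elif blur is not None:
        frames = blur_movie(movie, blur)
    else:
        frames = movie.frames.astype(float)
    traces = frames.reshape(frames.shape[0], -1).T  # pixels x frames
    return spectral_differentiation(
        traces, spectral or SpectralParams(), sample_rate=movie.frame_rate
    )


def stimulus_statistics(
    movie: MovieStimulus, blur: BlurParams | None = None
) -> dict[str, float]:
    """Low-level stimulus statistics.

    mean_luminance: average pixel intensity of the raw movie.
    contrast: SD of raw pixel intensities.
    spectral_energy: sum over pixels of the energy spectral density of each
    pixel's intensity timeseries with the DC component removed (computed on
    the blurred movie when ``blur`` is given); by Parseval this equals the
    energy of the mean-removed pixel traces.
    """
    raw = movie.frames.astype(float)
    frames = blur_movie(movie, blur) if blur is not None else raw
    traces = frames.reshape(frames.shape[0], -1)
    spectra = np.fft.fft(traces, axis=0)
    spectra[0] = 0.0  # remove DC
    energy = float((np.abs(spectra) ** 2).sum() / traces.shape[0])
    return {
        "mean_luminance": float(raw.mean()),
        "contrast": float(raw.std()),
        "spectral_energy": energy,
    }
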