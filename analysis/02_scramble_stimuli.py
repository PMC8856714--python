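"""Phase-scramble a synthetic movie and verify spectrum preservation.

Builds a 30-s, 120 x 192 greyscale movie with naturalistic-ish 1/f spatial
structure, applies the temporal and spatial phase scrambles, and reports the
magnitude-spectrum deviation before quantization (should be ~1e-15, i.e.
exact) and after rounding into uint8 (small but nonzero).  Movies go under
scratch/; the verification table under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from popdiff.core import MovieStimulus, write_movie
from popdiff.stimuli import (
    ScrambleParams,
    quantization_spectrum_deviation,
    scramble_movie,
    window_magnitude_spectra,
)

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "stimuli"
RESULTS = ROOT / "results"


def synthetic_movie(seed: int = 0, n_frames: int = 900, h: int = 120, w: int = 192):
    """Drifting 1/f-filtered noise, quantized to uint8."""
    rng = np.random.default_rng(seed)
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    amplitude = 1.0 / np.maximum(np.hypot(fy, fx), 1.0 / max(h, w))
    field = np.fft.ifft2(
        amplitude * np.exp(2j * np.pi * rng.random((h, w)))
    ).real
    field = (field - field.min()) / (field.max() - field.min())
    frames = np.empty((n_frames, h, w))
    for t in range(n_frames):
        frames[t] = np.roll(field, shift=(t // 3, t), axis=(0, 1))
    frames += rng.normal(0, 0.02, frames.shape)
    return MovieStimulus(np.clip(np.rint(255 * frames), 0, 255).astype(np.uint8))


def pre_quantization_deviation(movie, params):
    ideal = scramble_movie(
        movie, ScrambleParams(mode=params.mode, seed=params.seed, quantize=False)
    )
    if params.mode == "spatial":
        # the spatial scramble preserves each 1-s window's 3-D spectrum
        win = int(round(movie.frame_rate))
        m0 = np.stack(
            [
                np.abs(np.fft.fftn(movie.frames[i : i + win].astype(float)))
                for i in range(0, movie.n_frames, win)
            ]
        )
        m1 = np.stack(
            [np.abs(np.fft.fftn(ideal[i : i + win])) for i in range(0, movie.n_frames, win)]
        )
    else:
        m0 = window_magnitude_spectra(movie.frames, movie.frame_rate)
        m1 = window_magnitude_spectra(ideal, movie.frame_rate)
    return float(np.abs(m0 - m1).max() / np.abs(m0).max()), ideal


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    movie = synthetic_movie()
    write_movie(movie, SCRATCH / "movie_original.tif")
    rows = []
    for mode in ("temporal", "spatial"):
        params = ScrambleParams(mode=mode, seed=99)
        exact_dev, ideal = pre_quantization_deviation(movie, params)
        scrambled = scramble_movie(movie, params)
        write_movie(scrambled, SCRATCH / f"movie_{mode}_scramble.tif")
        quant_dev = quantization_spectrum_deviation(ideal, scrambled)
        rows.append(
            {
                "mode": mode,
                "pre_quantization_deviation": exact_dev,
                "quantization_deviation": quant_dev,
            }
        )
        print(
            f"{mode}: spectrum preserved to {exact_dev:.2e} before quantization; "
            f"uint8 rounding perturbs magnitudes by up to {quant_dev:.4f} (relative)"
        )
    pd.DataFrame(rows).to_csv(RESULTS / "scramble_verification.csv", index=False)


if __name__ == "__main__":
    main()
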