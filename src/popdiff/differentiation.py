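"""Neurophysiological differentiation (ND) measures.

Spectral differentiation: a trial's dF/F slice is cut into 1-s windows, the
one-sided spectrum of every cell in every window is estimated, and each
window's "population state" is the concatenation of the per-cell spectra.  ND
is the median of all pairwise distances between these states (Euclidean by
default), divided by sqrt(n_cells) so that duplicating a population leaves the
value unchanged.  A perfectly window-periodic population therefore has ND = 0,
while i.i.d. noise has strictly positive ND through finite-window estimation
error.

Multivariate differentiation: the selected trials' samples are concatenated to
an (samples x cells) matrix, embedded into a low-dimensional state space
(UMAP with n_components=8, n_neighbors=50, min_dist=0.5 by default; a seeded
linear projection and the identity are available for deterministic tests), and
each trial's ND is the mean Euclidean distance of its points to their
centroid.

Event-based variants: per-cell event magnitudes can be summed into 1-s bins
(all-zero bins dropped) for the multivariate measure, and the spectral measure
applies unchanged to event-magnitude timeseries sampled on the imaging clock.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import windows as _windows
from scipy.spatial.distance import cdist, pdist

from .core import ND_COLUMNS, FluorescenceSession, make_nd_table, params_digest

_METRIC_MAP = {
    "euclidean": "euclidean",
    "manhattan": "cityblock",
    "cosine": "cosine",
    "correlation": "correlation",
}


@dataclass
class SpectralParams:
    """Every knob of the spectral differentiation measure."""

    window_length: float = 1.0  # s
    spectrum_kind: str = "power"  # "power" (|X|^2) | "amplitude" (|X|)
    include_dc: bool = True
    freq_binning: str = "linear"  # "linear" | "logarithmic"
    n_log_bins: int = 5
    taper: str = "rectangular"  # "rectangular" | "tukey" | "kaiser"
    taper_shape: float = 0.25  # Tukey fraction; use 14 for Kaiser beta
    overlap_fraction: float = 0.0  # 0.125 with Tukey, 0.5 with Kaiser
    distance_metric: str = "euclidean"
    normalize_by_sqrt_n: bool = True

    def __post_init__(self):
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.distance_metric not in _METRIC_MAP:
            raise ValueError(f"unknown distance metric {self.distance_metric!r}")

    def window_samples(self, sample_rate: float) -> int:
        win = self.window_length * sample_rate
        if abs(win - round(win)) > 1e-9:
            raise ValueError("window_length * sample_rate must be an integer")
        return int(round(win))


@dataclass
class EmbeddingParams:
    """State-space embedding for the multivariate measure."""

    n_components: int = 8
    n_neighbors: int = 50
    min_dist: float = 0.5
    metric: str = "euclidean"
    method: str = "nonlinear-manifold"  # | "linear-projection" | "identity"
    seed: int = 0

    def __post_init__(self):
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


class EmbeddingError(RuntimeError):
    """The dimensionality-reduction step failed."""


def _taper(params: SpectralParams, win: int) -> np.ndarray:
    if params.taper == "rectangular":
        return np.ones(win)
    if params.taper == "tukey":
        return _windows.tukey(win, params.taper_shape)
    if params.taper == "kaiser":
        return _windows.kaiser(win, params.taper_shape)
    raise ValueError(f"unknown taper {params.taper!r}")


def _log_bin_matrix(freqs: np.ndarray, params: SpectralParams) -> np.ndarray:
    """Aggregation matrix summing one-sided spectra into geometric frequency bins.

    Bin edges run geometrically from the first nonzero frequency to Nyquist;
    when DC is included it is kept as its own bin.
    """
    has_dc = freqs[0] == 0.0
    pos = freqs[1:] if has_dc else freqs
    lo, hi = pos[0], pos[-1]
    edges = np.geomspace(lo, hi, params.n_log_bins + 1)
    edges[-1] = hi * (1 + 1e-12)
    idx = np.clip(np.searchsorted(edges, pos, side="right") - 1, 0, params.n_log_bins - 1)
    n_bins = params.n_log_bins + (1 if has_dc else 0)
    mat = np.zeros((len(freqs), n_bins))
    if has_dc:
        mat[0, 0] = 1.0
        for i, b in enumerate(idx):
            mat[i + 1, b + 1] = 1.0
    else:
        for i, b in enumerate(idx):
            mat[i, b] = 1.0
    return mat


def window_states(
    dff_slice: np.ndarray, params: SpectralParams, sample_rate: float
) -> np.ndarray:
    """Per-window population state vectors, stacked [n_windows x (cells * bins)].

    Windows tile the slice with hop = window * (1 - overlap); a trailing
    partial window is dropped.  Per cell and window the tapered one-sided
    spectrum is computed (squared magnitude or magnitude per
    ``spectrum_kind``), DC kept iff ``include_dc``, optionally summed into
    logarithmically spaced bins; the state is the concatenation across cells.
    """
    dff_slice = np.atleast_2d(np.asarray(dff_slice, dtype=float))
    n_cells, n_samples = dff_slice.shape
    win = params.window_samples(sample_rate)
    if n_samples < win:
        raise ValueError(f"slice of {n_samples} samples shorter than one {win}-sample window")
    hop = max(1, int(round(win * (1 - params.overlap_fraction))))
    starts = range(0, n_samples - win + 1, hop)
    taper = _taper(params, win)
    freqs = np.fft.rfftfreq(win, d=1.0 / sample_rate)
    keep = slice(None) if params.include_dc else slice(1, None)
    binmat = (
        _log_bin_matrix(freqs[keep], params)
        if params.freq_binning == "logarithmic"
        else None
    )
    if params.spectrum_kind not in ("power", "amplitude"):
        raise ValueError(f"unknown spectrum_kind {params.spectrum_kind!r}")
    # [cells, windows, win] view, tapered, transformed in one pass
    segs = np.lib.stride_tricks.sliding_window_view(dff_slice, win, axis=1)[:, ::hop]
    segs = segs[:, : len(starts)] * taper
    spec = np.abs(np.fft.rfft(segs, axis=2))
    if params.spectrum_kind == "power":
        spec = spec**2
    spec = spec[:, :, keep]
    if binmat is not None:
        spec = spec @ binmat
    # state = per-window concatenation across cells -> [windows, cells * bins]
    return np.ascontiguousarray(spec.transpose(1, 0, 2).reshape(spec.shape[1], -1))


def spectral_differentiation(
    dff_slice: np.ndarray, params: SpectralParams, sample_rate: float
) -> float:
    """Median pairwise distance between windowed spectral population states.

    Divided by sqrt(n_cells) when ``normalize_by_sqrt_n`` is set.  Requires at
    least two windows.  The median over an even number of pairwise distances
    is the mean of the two central values.
    """
    dff_slice = np.atleast_2d(np.asarray(dff_slice, dtype=float))
    states = window_states(dff_slice, params, sample_rate)
    if len(states) < 2:
        raise ValueError("need at least 2 windows to compute differentiation")
    distances = pdist(states, metric=_METRIC_MAP[params.distance_metric])
    nd = float(np.median(distances))
    if params.normalize_by_sqrt_n:
        nd /= np.sqrt(dff_slice.shape[0])
    return nd


def _select_trials(
    session: FluorescenceSession,
    categories: Optional[Sequence[str]],
    trial_mask: Optional[np.ndarray],
) -> pd.DataFrame:
    trials = session.trials
    if trial_mask is not None:
        return trials[np.asarray(trial_mask)]
    if categories is not None:
        return trials[trials["category"].isin(categories)]
    return trials


def nd_per_trial(
    session: FluorescenceSession,
    params: SpectralParams,
    categories: Optional[Sequence[str]] = None,
    trial_mask: Optional[np.ndarray] = None,
    dff: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """One spectral ND row per selected trial.

    ``dff`` substitutes an alternative matrix on the session clock (e.g.
    transient-removed traces or event-magnitude series) while keeping the
    session's trial structure.
    """
    data = session.dff if dff is None else dff
    digest = params_digest(params)
    rows = []
    for row in _select_trials(session, categories, trial_mask).itertuples():
        value = spectral_differentiation(
            data[:, row.start_sample : row.end_sample], params, session.sample_rate
        )
        rows.append(
            {
                "session_id": session.session_id,
                "layer": session.layer,
                "area": session.area,
                "stimulus_id": row.stimulus_id,
                "category": row.category,
                "block": row.block,
                "nd_value": value,
                "measure": "spectral",
                "params_digest": digest,
            }
        )
    return make_nd_table(rows)


def embed_states(matrix: np.ndarray, params: EmbeddingParams) -> np.ndarray:
    """Reduce an (samples x cells) matrix to (samples x n_components)."""
    matrix = np.asarray(matrix, dtype=float)
    try:
        if params.method == "identity":
            return matrix
        if params.method == "linear-projection":
            rng = np.random.default_rng(params.seed)
            proj = rng.standard_normal((matrix.shape[1], params.n_components))
            q, _ = np.linalg.qr(proj)
            return matrix @ q
        if params.method == "nonlinear-manifold":
            import umap  # heavy import; deferred

            reducer = umap.UMAP(
                n_components=params.n_components,
                n_neighbors=params.n_neighbors,
                min_dist=params.min_dist,
                metric=params.metric,
                random_state=params.seed,
            )
            return np.asarray(reducer.fit_transform(matrix))
    except Exception as exc:  # pragma: no cover - depends on embedding backend
        raise EmbeddingError(f"embedding failed ({params.method}): {exc}") from exc
    raise ValueError(f"unknown embedding method {params.method!r}")


def centroid_dispersion(points: np.ndarray) -> float:
    """Mean Euclidean distance of points to their centroid."""
    points = np.atleast_2d(points)
    centroid = points.mean(axis=0, keepdims=True)
    return float(cdist(points, centroid).mean())


def multivariate_differentiation(
    session: FluorescenceSession,
    embed: EmbeddingParams | None = None,
    categories: Sequence[str] = ("unscrambled", "scrambled"),
    trial_mask: Optional[np.ndarray] = None,
    dff: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Per-trial centroid dispersion of embedded population states.

    The selected trials' samples are concatenated (rows = imaging samples,
    columns = cells), embedded, regrouped by trial, and each trial's ND is the
    mean distance of its points to their centroid.
    """
    embed = embed or EmbeddingParams()
    data = session.dff if dff is None else dff
    selected = _select_trials(session, categories, trial_mask)
    blocks, owners = [], []
    for i, row in enumerate(selected.itertuples()):
        blocks.append(data[:, row.start_sample : row.end_sample].T)
        owners.append(np.full(row.end_sample - row.start_sample, i))
    matrix = np.vstack(blocks)
    owners = np.concatenate(owners)
    embedded = embed_states(matrix, embed)
    digest = params_digest(embed)
    rows = []
    for i, row in enumerate(selected.itertuples()):
        rows.append(
            {
                "session_id": session.session_id,
                "layer": session.layer,
                "area": session.area,
                "stimulus_id": row.stimulus_id,
                "category": row.category,
                "block": row.block,
                "nd_value": centroid_dispersion(embedded[owners == i]),
                "measure": "multivariate",
                "params_digest": digest,
            }
        )
    return make_nd_table(rows)


def event_binned_states(
    events: pd.DataFrame,
    n_cells: int,
    n_samples: int,
    sample_rate: float,
    bin_length: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sum event magnitudes into per-cell 1-s bins, dropping empty bins.

    ``events`` has columns (cell_index, sample_index, magnitude).  Returns the
    (kept_bins x n_cells) matrix and the original bin index of each kept row,
    mapping retained rows back to session time (and hence trials).
    """
    bin_samples = int(round(bin_length * sample_rate))
    n_bins = int(np.ceil(n_samples / bin_samples))
    matrix = np.zeros((n_bins, n_cells))
    if len(events):
        bins = (events["sample_index"].to_numpy() // bin_samples).astype(int)
        np.add.at(
            matrix,
            (bins, events["cell_index"].to_numpy().astype(int)),
            events["magnitude"].to_numpy(),
        )
    keep = np.flatnonzero(matrix.any(axis=1))
    return matrix[keep], keep


def remove_transients(
    dff: np.ndarray, event_samples: Sequence[int], span: int = 6
) -> np.ndarray:
    """Replace the ``span`` samples after each event with linear interpolation.

    Overlapping spans merge into one interpolated stretch; spans touching the
    trace ends are clamped to the nearest valid sample.  With no events the
    trace is returned unchanged (a copy).
    """
    dff = np.asarray(dff, dtype=float).copy()
    event_samples = np.asarray(list(event_samples), dtype=int)
    if event_samples.size == 0:
        return dff
    masked = np.zeros(len(dff), dtype=bool)
    for e in event_samples:
        masked[max(e, 0) : min(e + span, len(dff))] = True
    if masked.all():
        return dff
    idx = np.arange(len(dff))
    dff[masked] = np.interp(idx[masked], idx[~masked], dff[~masked])
    return dff


def sensitivity_grid(
    sessions: Iterable[FluorescenceSession],
    grid: dict[str, Sequence],
    stats_callback: Callable[[pd.DataFrame], dict],
    base_params: SpectralParams | None = None,
) -> pd.DataFrame:
    """Recompute ND and statistics over the Cartesian product of parameter values.

    ``grid`` maps :class:`SpectralParams` field names to candidate values;
    ``stats_callback`` maps a pooled ND table to a dict of scalars (e.g.
    p-values).  Returns one tidy row per parameter combination.
    """
    sessions = list(sessions)
    base_params = base_params or SpectralParams()
    names = list(grid)
    rows = []
    for combo in itertools.product(*(grid[n] for n in names)):
        params = replace(base_params, **dict(zip(names, combo)))
        table = pd.concat(
            [nd_per_trial(s, params) for s in sessions], ignore_index=True
        )
        rows.append({**dict(zip(names, combo)), **stats_callback(table)})
    return pd.DataFrame(rows)
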