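"""Domain containers and on-disk formats for calcium-imaging sessions and movie stimuli.

A session is a ``dff`` matrix (cells x samples, fractional fluorescence change
at 30 Hz) together with cell metadata, a trial table, and optional behavioral
traces (locomotion velocity in cm/s and pupil diameter).  Trial intervals are
half-open ``[start_sample, end_sample)`` with 0-based sample indices, so a 30-s
trial at 30 Hz spans exactly 900 samples and adjacent trials share no sample.

The canonical on-disk form is one directory per session: a ``.npy`` array for
the fluorescence matrix, UTF-8 CSV tables for cells/trials/behavior, and a JSON
metadata file.  Writes are deterministic (no timestamps), so fixtures diff
cleanly and repeated writes are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import tifffile

LAYERS = ("L2/3", "L4", "L5")
AREAS = ("V1", "LM", "AL", "PM", "AM")
CATEGORIES = ("unscrambled", "scrambled", "other")

TRIAL_COLUMNS = ("stimulus_id", "category", "block", "start_sample", "end_sample")
ND_COLUMNS = (
    "session_id",
    "layer",
    "area",
    "stimulus_id",
    "category",
    "block",
    "nd_value",
    "measure",
    "params_digest",
)


class SessionValidationError(ValueError):
    """A session violates one or more structural invariants."""

    def __init__(self, failures: list[str]):
        self.failures = list(failures)
        super().__init__("invalid session: " + "; ".join(self.failures))


class SessionLoadError(IOError):
    """A session directory is missing a required component."""


def params_digest(obj) -> str:
    """Short stable digest of a parameter object (dataclass or mapping)."""
    if hasattr(obj, "__dataclass_fields__"):
        items = {k: getattr(obj, k) for k in obj.__dataclass_fields__}
    else:
        items = dict(obj)
    payload = json.dumps({k: repr(v) for k, v in sorted(items.items())}, sort_keys=True)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class BehaviorTraces:
    """Behavioral covariates sampled on the session clock."""

    locomotion_velocity: Optional[np.ndarray] = None
    pupil_diameter: Optional[np.ndarray] = None

    def is_empty(self) -> bool:
        return self.locomotion_velocity is None and self.pupil_diameter is None


@dataclass
class FluorescenceSession:
    """One recording session: dF/F matrix plus metadata, trials, and behavior."""

    dff: np.ndarray
    cells: pd.DataFrame
    trials: pd.DataFrame
    session_id: str
    layer: str
    area: str
    sample_rate: float = 30.0
    behavior: Optional[BehaviorTraces] = None

    @property
    def n_cells(self) -> int:
        return self.dff.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dff.shape[1]

    def validate(self) -> "FluorescenceSession":
        failures = []
        if self.dff.ndim != 2:
            failures.append(f"dff must be 2-D, got {self.dff.ndim}-D")
        if self.sample_rate <= 0:
            failures.append(f"sample_rate must be > 0, got {self.sample_rate}")
        if len(self.cells) != self.n_cells:
            failures.append(
                f"cells table has {len(self.cells)} rows for {self.n_cells} traces"
            )
        if self.cells["cell_id"].duplicated().any():
            failures.append("cell_id values are not unique")
        if self.layer not in LAYERS:
            failures.append(f"unknown layer {self.layer!r}")
        if self.area not in AREAS:
            failures.append(f"unknown area {self.area!r}")
        t = self.trials
        missing = [c for c in TRIAL_COLUMNS if c not in t.columns]
        if missing:
            failures.append(f"trial table missing columns {missing}")
        else:
            if (t["start_sample"] >= t["end_sample"]).any():
                failures.append("trial with start_sample >= end_sample")
            if (t["start_sample"] < 0).any() or (t["end_sample"] > self.n_samples).any():
                failures.append("trial interval outside [0, n_samples)")
            if (t["block"] < 0).any():
                failures.append("negative block index")
            if not t["category"].isin(CATEGORIES).all():
                failures.append("unknown trial category")
            srt = t.sort_values("start_sample")
            if (srt["start_sample"].values[1:] < srt["end_sample"].values[:-1]).any():
                failures.append("overlapping trial intervals")
        if self.behavior is not None:
            for name in ("locomotion_velocity", "pupil_diameter"):
                v = getattr(self.behavior, name)
                if v is not None and len(v) != self.n_samples:
                    failures.append(f"{name} length {len(v)} != n_samples {self.n_samples}")
        if failures:
            raise SessionValidationError(failures)
        return self

    def trial_slice(self, trial_row) -> np.ndarray:
        """dF/F slice for one trial row; half-open interval, (end - start) samples."""
        return self.dff[:, int(trial_row["start_sample"]) : int(trial_row["end_sample"])]


def write_session(session: FluorescenceSession, path) -> None:
    """Write a session as a directory (npy matrix + CSV tables + JSON metadata)."""
    session.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "dff.npy", session.dff)
    session.cells.to_csv(path / "cells.csv", index=False)
    session.trials.loc[:, list(TRIAL_COLUMNS)].to_csv(path / "trials.csv", index=False)
    meta = {
        "session_id": session.session_id,
        "layer": session.layer,
        "area": session.area,
        "sample_rate": session.sample_rate,
        "behavior": session.behavior is not None and not session.behavior.is_empty(),
    }
    if meta["behavior"]:
        cols = {}
        if session.behavior.locomotion_velocity is not None:
            cols["locomotion_velocity"] = session.behavior.locomotion_velocity
        if session.behavior.pupil_diameter is not None:
            cols["pupil_diameter"] = session.behavior.pupil_diameter
        pd.DataFrame(cols).to_csv(path / "behavior.csv", index=False)
    with open(path / "session.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_session(path) -> FluorescenceSession:
    """Read a session directory written by :func:`write_session`; validates on load."""
    path = Path(path)
    for component in ("session.json", "dff.npy", "cells.csv", "trials.csv"):
        if not (path / component).exists():
            raise SessionLoadError(f"missing session component: {component}")
    with open(path / "session.json") as fh:
        meta = json.load(fh)
    dff = np.load(path / "dff.npy")
    cells = pd.read_csv(path / "cells.csv", dtype={"cell_id": str})
    trials = pd.read_csv(path / "trials.csv")
    behavior = None
    if meta.get("behavior"):
        if not (path / "behavior.csv").exists():
            raise SessionLoadError("missing session component: behavior.csv")
        bt = pd.read_csv(path / "behavior.csv")
        behavior = BehaviorTraces(
            locomotion_velocity=bt["locomotion_velocity"].to_numpy()
            if "locomotion_velocity" in bt
            else None,
            pupil_diameter=bt["pupil_diameter"].to_numpy()
            if "pupil_diameter" in bt
            else None,
        )
    session = FluorescenceSession(
        dff=dff,
        cells=cells,
        trials=trials,
        session_id=str(meta["session_id"]),
        layer=meta["layer"],
        area=meta["area"],
        sample_rate=float(meta["sample_rate"]),
        behavior=behavior,
    )
    return session.validate()


@dataclass
class MovieStimulus:
    """Greyscale movie as a uint8 stack [frames x height x width] at ``frame_rate`` fps."""

    frames: np.ndarray
    frame_rate: float = 30.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3-D, got shape {self.frames.shape}")
        if self.frames.dtype != np.uint8:
            raise ValueError(f"frames must be uint8, got {self.frames.dtype}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


class MovieConversionError(ValueError):
    """Input stack is not greyscale uint8 and conversion was not requested."""


def write_movie(movie: MovieStimulus, path) -> None:
    """Write a movie stack losslessly (.tif multi-page greyscale or .npy raw)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, movie.frames)
    elif path.suffix.lower() == ".npy":
        np.save(path, movie.frames)
    else:
        raise ValueError(f"unsupported movie container: {path.suffix!r}")


def read_movie(path, frame_rate: float = 30.0, convert: bool = False) -> MovieStimulus:
    """Read a greyscale uint8 movie stack.

    With ``convert=True``, RGB frames are collapsed to greyscale by channel
    averaging and non-uint8 data is clipped/rounded into [0, 255]; otherwise
    such input raises :class:`MovieConversionError`.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        frames = tifffile.imread(path)
    elif path.suffix.lower() == ".npy":
        frames = np.load(path)
    else:
        raise ValueError(f"unsupported movie container: {path.suffix!r}")
    frames = np.asarray(frames)
    if frames.ndim == 4:
        if not convert:
            raise MovieConversionError(
                "multi-channel stack; pass convert=True to collapse to greyscale"
            )
        frames = frames.mean(axis=-1)
    if frames.dtype != np.uint8:
        if not convert:
            raise MovieConversionError(
                f"dtype {frames.dtype} is not uint8; pass convert=True to quantize"
            )
        frames = np.clip(np.rint(frames), 0, 255).astype(np.uint8)
    return MovieStimulus(frames=frames, frame_rate=frame_rate)


def make_nd_table(rows: Iterable[dict]) -> pd.DataFrame:
    """Assemble a tidy per-trial differentiation table with the canonical columns."""
    table = pd.DataFrame(list(rows), columns=list(ND_COLUMNS))
    if len(table) and (table["nd_value"] < 0).any():
        raise ValueError("nd_value must be nonnegative")
    return table
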