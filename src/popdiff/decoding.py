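"""Stimulus decoding from single-trial population responses.

The contrast analysis to differentiation: a trial is represented as the
concatenation of every cell's dF/F slice (an s x (n * t) matrix over trials),
compressed with PCA retaining 99% of the variance, and classified with a
shrinkage-regularized linear discriminant (lsqr solver, automatic shrinkage)
under stratified fivefold cross-validation.  Performance is the mean balanced
accuracy over held-out folds (chance 0.5 for the two-way category target,
1/12 for the 12-way identity target); the five-continuous-stimuli target also
reports per-stimulus F1.  The PCA projection is fitted on each training fold
only, so no test information leaks into the compression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import balanced_accuracy_score, f1_score
from sklearn.model_selection import KFold, StratifiedKFold

from .core import FluorescenceSession


@dataclass
class DecodingParams:
    variance_retained: float = 0.99
    n_folds: int = 5
    stratified: bool = True
    seed: int = 0
    target: str = "category"  # "category" | "identity" | "continuous-five"

    def __post_init__(self):
        if not 0 < self.variance_retained <= 1:
            raise ValueError("variance_retained must be in (0, 1]")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class TrialFeatureMatrix:
    """Trials x flattened (cells * samples-per-trial) features, with labels."""

    X: np.ndarray
    labels: np.ndarray
    trial_index: np.ndarray


@dataclass
class DecodingResult:
    fold_scores: np.ndarray
    mean_score: float
    f1_per_class: Optional[pd.Series] = None


def build_trial_matrix(
    session: FluorescenceSession,
    target: str = "category",
    stimuli: Optional[Sequence[str]] = None,
) -> TrialFeatureMatrix:
    """Assemble the s x (n * t) matrix of concatenated per-cell trial slices.

    ``target="category"`` selects the unscrambled + scrambled trials with the
    category as the label; ``"identity"`` uses all trials with the stimulus id
    as the label; ``"continuous-five"`` uses the given ``stimuli`` (default:
    the first five stimulus ids of the "other" category) labeled by id.
    """
    trials = session.trials
    if target == "category":
        trials = trials[trials["category"].isin(["unscrambled", "scrambled"])]
        labels = trials["category"].to_numpy()
    elif target == "identity":
        labels = trials["stimulus_id"].to_numpy()
    elif target == "continuous-five":
        if stimuli is None:
            stimuli = sorted(
                trials.loc[trials["category"] == "other", "stimulus_id"].unique()
            )[:5]
        trials = trials[trials["stimulus_id"].isin(stimuli)]
        labels = trials["stimulus_id"].to_numpy()
    else:
        raise ValueError(f"unknown decoding target {target!r}")
    lengths = (trials["end_sample"] - trials["start_sample"]).unique()
    if len(lengths) != 1:
        raise ValueError(f"ragged trial lengths {sorted(lengths)}; need a fixed t")
    X = np.stack(
        [
            session.dff[:, row.start_sample : row.end_sample].ravel()
            for row in trials.itertuples()
        ]
    )
    return TrialFeatureMatrix(X=X, labels=labels, trial_index=trials.index.to_numpy())


def decode(matrix: TrialFeatureMatrix, params: DecodingParams | None = None) -> DecodingResult:
    """Cross-validated PCA + shrinkage-LDA decoding of the trial labels."""
    params = params or DecodingParams()
    X, y = matrix.X, matrix.labels
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < params.n_folds:
        raise ValueError(
            f"class with {counts.min()} trials cannot support {params.n_folds}-fold CV"
        )
    splitter = (
        StratifiedKFold(params.n_folds, shuffle=True, random_state=params.seed)
        if params.stratified
        else KFold(params.n_folds, shuffle=True, random_state=params.seed)
    )
    scores = []
    y_true_all, y_pred_all = [], []
    for train, test in splitter.split(X, y):
        pca = PCA(n_components=params.variance_retained, svd_solver="full")
        Z_train = pca.fit_transform(X[train])
        Z_test = pca.transform(X[test])
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        clf.fit(Z_train, y[train])
        pred = clf.predict(Z_test)
        scores.append(balanced_accuracy_score(y[test], pred))
        y_true_all.append(y[test])
        y_pred_all.append(pred)
    f1 = None
    if params.target == "continuous-five":
        y_true = np.concatenate(y_true_all)
        y_pred = np.concatenate(y_pred_all)
        f1 = pd.Series(
            f1_score(y_true, y_pred, labels=classes, average=None), index=classes
        )
    scores = np.asarray(scores)
    return DecodingResult(fold_scores=scores, mean_score=float(scores.mean()), f1_per_class=f1)


def decode_session(
    session: FluorescenceSession,
    params: DecodingParams | None = None,
    stimuli: Optional[Sequence[str]] = None,
) -> DecodingResult:
    """Convenience wrapper: build the trial matrix for ``params.target`` and decode."""
    params = params or DecodingParams()
    return decode(build_trial_matrix(session, params.target, stimuli), params)
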