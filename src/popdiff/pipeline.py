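"""End-to-end orchestration: simulate -> measure -> test -> model -> decode.

One declarative :class:`RunConfig` drives the whole analysis over a synthetic
cohort and writes tidy delimited tables plus a provenance record into a run
directory.  A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence``, so re-running an identical config reproduces
every numeric output byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import write_session
from .decoding import DecodingParams, decode_session
from .differentiation import (
    EmbeddingParams,
    SpectralParams,
    multivariate_differentiation,
    nd_per_trial,
)
from .stats import (
    PermutationParams,
    fit_category_interaction,
    permutation_test,
)
from .synth import CohortSpec, generate_cohort


@dataclass
class RunConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    spectral: SpectralParams = field(default_factory=SpectralParams)
    embedding: EmbeddingParams = field(default_factory=EmbeddingParams)
    permutation: PermutationParams = field(default_factory=PermutationParams)
    decoding: DecodingParams = field(default_factory=DecodingParams)
    out_dir: str = "popdiff-run"
    seed: int = 0
    run_multivariate: bool = True
    run_decoding: bool = True
    factors: Sequence[str] = ("layer", "area")
    write_sessions: bool = False


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _config_digest(config: RunConfig) -> str:
    payload = json.dumps(
        {k: repr(v) for k, v in sorted(asdict(config).items())}, sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    return [
        int(s) % (2**31)
        for s in np.random.SeedSequence(seed).generate_state(n)
    ]


def _write(table: pd.DataFrame, path: Path, digest: str) -> None:
    table = table.copy()
    table["config_digest"] = digest
    table.to_csv(path, index=False)


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = _config_digest(config)
    cohort_seed, perm_seed, embed_seed, decode_seed = _stage_seeds(config.seed)

    stage = "simulate"
    try:
        spec = replace(config.cohort, seed=cohort_seed)
        sessions, manifest = generate_cohort(spec)
        _write(manifest, out / "cohort_manifest.csv", digest)
        if config.write_sessions:
            for s in sessions:
                write_session(s, out / "sessions" / s.session_id)

        stage = "nd-spectral"
        nd_spectral = pd.concat(
            [nd_per_trial(s, config.spectral) for s in sessions], ignore_index=True
        )
        _write(nd_spectral, out / "nd_spectral.csv", digest)

        if config.run_multivariate:
            stage = "nd-multivariate"
            embed = replace(config.embedding, seed=embed_seed)
            nd_multi = pd.concat(
                [multivariate_differentiation(s, embed) for s in sessions],
                ignore_index=True,
            )
            _write(nd_multi, out / "nd_multivariate.csv", digest)

        stage = "permutation-tests"
        perm_rows = []
        for s in sessions:
            sub = nd_spectral[nd_spectral["session_id"] == s.session_id]
            res = permutation_test(
                sub["nd_value"].to_numpy(),
                sub["category"].to_numpy(),
                replace(config.permutation, seed=perm_seed),
            )
            perm_rows.append(
                {
                    "session_id": s.session_id,
                    "layer": s.layer,
                    "area": s.area,
                    "observed_diff": res.observed_diff,
                    "p": res.p,
                    "significant": res.p < 0.05,
                }
            )
        perm_table = pd.DataFrame(perm_rows)
        _write(perm_table, out / "permutation_tests.csv", digest)
        fractions = (
            perm_table.groupby(["layer", "area"])["significant"]
            .agg(["sum", "count"])
            .reset_index()
            .rename(columns={"sum": "n_significant", "count": "n_sessions"})
        )
        fractions["fraction_significant"] = (
            fractions["n_significant"] / fractions["n_sessions"]
        )
        _write(fractions, out / "significance_fractions.csv", digest)

        stage = "mixed-models"
        lrt_rows, contrast_tables = [], []
        for factor in config.factors:
            res = fit_category_interaction(nd_spectral, factor=factor)
            lrt_rows.append(
                {
                    "factor": factor,
                    "lrt_chi2": res.lrt_chi2,
                    "df": res.df,
                    "p": res.p,
                    "adjust_method": res.adjust_method,
                    "converged": res.converged,
                }
            )
            ct = res.contrasts.copy()
            ct.insert(0, "factor", factor)
            contrast_tables.append(ct)
        _write(pd.DataFrame(lrt_rows), out / "lme_tests.csv", digest)
        _write(pd.concat(contrast_tables, ignore_index=True), out / "lme_contrasts.csv", digest)

        if config.run_decoding:
            stage = "decoding"
            rows = []
            for s in sessions:
                res = decode_session(s, replace(config.decoding, seed=decode_seed))
                rows.append(
                    {
                        "session_id": s.session_id,
                        "layer": s.layer,
                        "area": s.area,
                        "target": config.decoding.target,
                        "balanced_accuracy": res.mean_score,
                    }
                )
            _write(pd.DataFrame(rows), out / "decoding.csv", digest)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    provenance = {
        "config_digest": digest,
        "seed": config.seed,
        "stage_seeds": {
            "cohort": cohort_seed,
            "permutation": perm_seed,
            "embedding": embed_seed,
            "decoding": decode_seed,
        },
        "version": __version__,
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
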