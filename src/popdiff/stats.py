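"""Statistical layer: permutation tests, effect sizes, and mixed-model contrasts.

Per-session inference is a one-sided trial-label permutation test: the
observed statistic is mean(unscrambled ND) - mean(scrambled ND), the null is
built by shuffling the labels (20,000 draws by default, or exhaustively on
small designs), and p is the fraction of null draws *strictly greater* than
the observed difference.

Cohort-level inference models log-transformed ND with linear mixed models
(maximum likelihood): stimulus category, a population factor (layer or area),
and their interaction as fixed effects with a random intercept per session.
Specificity is a likelihood-ratio test of the interaction (df = levels - 1),
followed by one-sided category contrasts within each level, adjusted for
multiplicity with a single-step max-Z adjustment computed from the contrast
correlation matrix (the same family as multcomp/emmeans adjustments).  Effect
sizes are Cohen's d with the pooled SD.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq
import statsmodels.formula.api as smf


@dataclass
class PermutationParams:
    n_permutations: int = 20000
    seed: int = 0
    exhaustive: bool = False
    add_one_smoothing: bool = False  # (1 + #greater) / (1 + n): guarantees p > 0


@dataclass
class PermutationResult:
    p: float
    observed_diff: float
    null: np.ndarray
    exhaustive: bool


def permutation_test(
    nd_values: np.ndarray,
    labels: Sequence[str],
    params: PermutationParams | None = None,
) -> PermutationResult:
    """One-sided trial-label permutation test (unscrambled > scrambled).

    With ``exhaustive`` set and a tractable number of label assignments the
    null is enumerated exactly; otherwise seeded Monte-Carlo shuffles are
    used.  p is the fraction of permuted differences strictly greater than the
    observed one (optionally add-one smoothed).
    """
    params = params or PermutationParams()
    values = np.asarray(nd_values, dtype=float)
    labels = np.asarray(labels)
    mask = (labels == "unscrambled") | (labels == "scrambled")
    values, labels = values[mask], labels[mask]
    is_u = labels == "unscrambled"
    n_u, n_s = int(is_u.sum()), int(len(values) - is_u.sum())
    if n_u == 0 or n_s == 0:
        raise ValueError("both unscrambled and scrambled labels must be present")
    n = len(values)
    observed = values[is_u].mean() - values[~is_u].mean()
    if params.exhaustive and comb(n, n_u) <= 1_000_000:
        null = np.array(
            [
                values[list(combo)].mean()
                - values[list(set(range(n)) - set(combo))].mean()
                for combo in itertools.combinations(range(n), n_u)
            ]
        )
    else:
        rng = np.random.default_rng(params.seed)
        order = np.argsort(rng.random((params.n_permutations, n)), axis=1)
        picked = order[:, :n_u]
        sums_u = values[picked].sum(axis=1)
        null = sums_u / n_u - (values.sum() - sums_u) / n_s
    greater = int((null > observed).sum())
    if params.add_one_smoothing:
        p = (1 + greater) / (1 + len(null))
    else:
        p = greater / len(null)
    return PermutationResult(
        p=float(p),
        observed_diff=float(observed),
        null=null,
        exhaustive=bool(params.exhaustive),
    )


def cohens_d(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Standardized mean difference with the pooled SD.

    pooled SD = sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2)) with sample
    variances (n-1 denominators).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0 or len(a) + len(b) <= 2:
        raise ValueError("need nonempty groups with n1 + n2 > 2")
    pooled_var = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
        len(a) + len(b) - 2
    )
    if pooled_var == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


# ---------------------------------------------------------------------------
# Mixed-model contrasts


@dataclass
class InteractionResult:
    factor: str
    lrt_chi2: float
    df: int
    p: float
    contrasts: pd.DataFrame  # level, estimate, se, z, p, p_adj, d, ci_lower
    adjust_method: str
    converged: bool


def _prepare_log_nd(table: pd.DataFrame) -> pd.DataFrame:
    df = table[table["category"].isin(["unscrambled", "scrambled"])].copy()
    if (df["nd_value"] <= 0).any():
        raise ValueError("log transform requires strictly positive nd values")
    df["log_nd"] = np.log(df["nd_value"])
    df["layer"] = df["layer"].astype(str)
    df["area"] = df["area"].astype(str)
    return df


def _fit_mixed(formula: str, data: pd.DataFrame):
    """ML fit of a random-intercept model.

    Several optimizers are run and the fit with the best finite log-likelihood
    is kept: single-optimizer fits occasionally stop at poor local optima (or
    report degenerate infinite likelihoods), which would corrupt the
    likelihood-ratio statistic between nested models.
    """
    best = None
    last_exc = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=data, groups=data["session_id"])
        for method in (None, "powell"):
            try:
                kwargs = {"method": method} if method else {}
                fit = model.fit(reml=False, maxiter=200, **kwargs)
            except Exception as exc:  # keep trying alternative optimizers
                last_exc = exc
                continue
            if np.isfinite(fit.llf) and (best is None or fit.llf > best.llf):
                best = fit
    if best is None:
        raise RuntimeError(f"mixed model did not converge for {formula!r}: {last_exc}")
    return best


def _max_z_quantile(corr: np.ndarray, level: float = 0.95, two_sided: bool = False) -> float:
    """Equicoordinate quantile of the max (|Z| or Z) of correlated standard normals."""
    mvn = sps.multivariate_normal(mean=np.zeros(len(corr)), cov=corr, allow_singular=True)

    def cdf(q):
        if two_sided:
            return mvn.cdf(np.full(len(corr), q), lower_limit=np.full(len(corr), -q))
        return mvn.cdf(np.full(len(corr), q))

    return brentq(lambda q: cdf(q) - level, 0.5, 8.0, xtol=1e-4)


def _single_step_p(z: np.ndarray, corr: np.ndarray, two_sided: bool = False) -> np.ndarray:
    """Single-step max-Z adjusted p-values from the contrast correlation matrix."""
    mvn = sps.multivariate_normal(mean=np.zeros(len(corr)), cov=corr, allow_singular=True)
    out = np.empty(len(z))
    for i, zi in enumerate(z):
        if two_sided:
            a = abs(zi)
            out[i] = 1 - mvn.cdf(np.full(len(z), a), lower_limit=np.full(len(z), -a))
        else:
            out[i] = 1 - mvn.cdf(np.full(len(z), zi))
    return np.clip(out, 0.0, 1.0)


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (len(p) - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def _contrast_stats(fit, contrast_rows: np.ndarray):
    """Estimates, SEs, z and the correlation matrix for a stack of fixed-effect contrasts."""
    fe_names = fit.model.exog_names
    params = fit.params[: len(fe_names)].to_numpy()
    cov = fit.cov_params().iloc[: len(fe_names), : len(fe_names)].to_numpy()
    est = contrast_rows @ params
    cmat = contrast_rows @ cov @ contrast_rows.T
    se = np.sqrt(np.diag(cmat))
    denom = np.outer(se, se)
    corr = np.where(denom > 0, cmat / np.where(denom == 0, 1, denom), np.eye(len(se)))
    np.fill_diagonal(corr, 1.0)
    return est, se, est / se, corr


def fit_category_interaction(
    table: pd.DataFrame,
    factor: str = "layer",
    covariates: Sequence[str] = (),
) -> InteractionResult:
    """Interaction LRT and per-level one-sided category contrasts on log ND.

    Full model: log ND ~ factor * category + covariates + (1 | session); the
    reduced model drops the interaction.  The LRT df equals (levels - 1).  Per
    level, the one-sided contrast tests unscrambled > scrambled; adjusted
    p-values and simultaneous one-sided lower confidence bounds [lower, inf)
    use the single-step max-Z method when the contrast covariance is
    available, otherwise Holm (flagged in ``adjust_method``).
    """
    if table["session_id"].nunique() < 2:
        raise ValueError("need at least 2 sessions for a mixed model")
    df = _prepare_log_nd(table)
    extra = "".join(f" + {c}" for c in covariates)
    cat = "C(category, Treatment('scrambled'))"
    full_formula = f"log_nd ~ C({factor}) * {cat}{extra}"
    red_formula = f"log_nd ~ C({factor}) + {cat}{extra}"
    full = _fit_mixed(full_formula, df)
    reduced = _fit_mixed(red_formula, df)
    chi2 = max(0.0, 2 * (full.llf - reduced.llf))
    levels = sorted(df[factor].unique())
    dof = len(levels) - 1
    p_lrt = float(sps.chi2.sf(chi2, dof))

    fe_names = full.model.exog_names
    cat_col = fe_names.index("C(category, Treatment('scrambled'))[T.unscrambled]")
    rows = []
    for level in levels:
        c = np.zeros(len(fe_names))
        c[cat_col] = 1.0
        inter = (
            f"C({factor})[T.{level}]:C(category, Treatment('scrambled'))[T.unscrambled]"
        )
        if inter in fe_names:
            c[fe_names.index(inter)] = 1.0
        rows.append(c)
    contrast_rows = np.asarray(rows)
    est, se, z, corr = _contrast_stats(full, contrast_rows)
    try:
        p_adj = _single_step_p(z, corr, two_sided=False)
        q = _max_z_quantile(corr, 0.95, two_sided=False)
        adjust_method = "single-step"
    except Exception:
        p_adj = _holm(sps.norm.sf(z))
        q = sps.norm.ppf(1 - 0.05 / len(z))
        adjust_method = "holm"
    d_values = []
    for level in levels:
        sub = df[df[factor] == level]
        d_values.append(
            cohens_d(
                sub.loc[sub["category"] == "unscrambled", "log_nd"],
                sub.loc[sub["category"] == "scrambled", "log_nd"],
            )
        )
    contrasts = pd.DataFrame(
        {
            "level": levels,
            "estimate": est,
            "se": se,
            "z": z,
            "p": sps.norm.sf(z),
            "p_adj": p_adj,
            "d": d_values,
            "ci_lower": est - q * se,
        }
    )
    return InteractionResult(
        factor=factor,
        lrt_chi2=float(chi2),
        df=dof,
        p=p_lrt,
        contrasts=contrasts,
        adjust_method=adjust_method,
        converged=bool(getattr(full, "converged", True))
        and bool(getattr(reduced, "converged", True)),
    )


@dataclass
class StimulusContrastResult:
    lrt_chi2: float
    df: int
    p: float
    pairs: pd.DataFrame  # a, b, estimate, se, z, p, p_adj, d, ci_lower, ci_upper
    adjust_method: str
    converged: bool


def stimulus_pairwise_contrasts(table: pd.DataFrame) -> StimulusContrastResult:
    """Stimulus fixed-effect LRT plus all pairwise two-sided contrasts on log ND.

    Model: log ND ~ stimulus + (1 | session) against an intercept-only reduced
    model; pairwise marginal-mean contrasts are adjusted family-wise with the
    single-step max-|Z| method (Tukey-style simultaneous inference).
    """
    df = table.copy()
    if (df["nd_value"] <= 0).any():
        raise ValueError("log transform requires strictly positive nd values")
    df["log_nd"] = np.log(df["nd_value"])
    stimuli = sorted(df["stimulus_id"].unique())
    if len(stimuli) < 2:
        raise ValueError("need at least 2 stimuli")
    full = _fit_mixed("log_nd ~ C(stimulus_id)", df)
    reduced = _fit_mixed("log_nd ~ 1", df)
    chi2 = max(0.0, 2 * (full.llf - reduced.llf))
    dof = len(stimuli) - 1
    fe_names = full.model.exog_names

    def mean_vec(stim):
        v = np.zeros(len(fe_names))
        v[fe_names.index("Intercept")] = 1.0
        name = f"C(stimulus_id)[T.{stim}]"
        if name in fe_names:
            v[fe_names.index(name)] = 1.0
        return v

    pairs = list(itertools.combinations(stimuli, 2))
    contrast_rows = np.asarray([mean_vec(a) - mean_vec(b) for a, b in pairs])
    est, se, z, corr = _contrast_stats(full, contrast_rows)
    try:
        p_adj = _single_step_p(z, corr, two_sided=True)
        q = _max_z_quantile(corr, 0.95, two_sided=True)
        adjust_method = "single-step"
    except Exception:
        p_adj = _holm(2 * sps.norm.sf(np.abs(z)))
        q = sps.norm.ppf(1 - 0.025 / len(z))
        adjust_method = "holm"
    d_values = [
        cohens_d(
            df.loc[df["stimulus_id"] == a, "log_nd"],
            df.loc[df["stimulus_id"] == b, "log_nd"],
        )
        for a, b in pairs
    ]
    out = pd.DataFrame(
        {
            "a": [a for a, _ in pairs],
            "b": [b for _, b in pairs],
            "estimate": est,
            "se": se,
            "z": z,
            "p": 2 * sps.norm.sf(np.abs(z)),
            "p_adj": p_adj,
            "d": d_values,
            "ci_lower": est - q * se,
            "ci_upper": est + q * se,
        }
    )
    return StimulusContrastResult(
        lrt_chi2=float(chi2),
        df=dof,
        p=float(sps.chi2.sf(chi2, dof)),
        pairs=out,
        adjust_method=adjust_method,
        converged=bool(getattr(full, "converged", True)),
    )


def effect_size_vs_arousal(
    effect_sizes: np.ndarray,
    running_fractions: Optional[np.ndarray] = None,
    pupil_means: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Pearson correlation of per-session effect sizes with arousal indices.

    One row per available covariate: r, the two-sided t statistic with n - 2
    degrees of freedom, its p-value, and the Fisher-z 95% CI.
    """
    d = np.asarray(effect_sizes, dtype=float)
    if len(d) < 3:
        raise ValueError("need at least 3 sessions")
    rows = []
    for name, x in (("running_fraction", running_fractions), ("pupil", pupil_means)):
        if x is None:
            continue
        x = np.asarray(x, dtype=float)
        r, p = sps.pearsonr(x, d)
        n = len(d)
        t = r * np.sqrt(n - 2) / np.sqrt(max(1 - r**2, 1e-300))
        zr = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
        half = sps.norm.ppf(0.975) / np.sqrt(n - 3) if n > 3 else np.inf
        rows.append(
            {
                "covariate": name,
                "r": float(r),
                "t": float(t),
                "df": n - 2,
                "p": float(p),
                "ci_lower": float(np.tanh(zr - half)),
                "ci_upper": float(np.tanh(zr + half)),
            }
        )
    return pd.DataFrame(rows)
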