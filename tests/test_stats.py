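import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popdiff.differentiation import SpectralParams, nd_per_trial
from popdiff.stats import (
    PermutationParams,
    cohens_d,
    effect_size_vs_arousal,
    fit_category_interaction,
    permutation_test,
    stimulus_pairwise_contrasts,
)
from popdiff.synth import EFFECT_DELTA_STAR, CohortSpec, generate_cohort


class TestPermutationTest:
    def test_exhaustive_toy_case(self):
        res = permutation_test(
            np.array([10.0, 9.0, 1.0, 2.0]),
            np.array(["unscrambled", "unscrambled", "scrambled", "scrambled"]),
            PermutationParams(exhaustive=True),
        )
        assert res.observed_diff == pytest.approx(8.0)
        assert len(res.null) == 6  # C(4, 2) label assignments
        assert res.p == 0.0

    def test_monte_carlo_agrees_with_exhaustive(self, rng):
        values = rng.normal(size=8)
        labels = np.array(["unscrambled"] * 3 + ["scrambled"] * 5)
        exact = permutation_test(values, labels, PermutationParams(exhaustive=True))
        mc = permutation_test(
            values, labels, PermutationParams(n_permutations=4000, seed=1)
        )
        se = np.sqrt(max(exact.p * (1 - exact.p), 1e-4) / 4000)
        assert abs(mc.p - exact.p) <= 3 * se + 1e-9

    def test_null_p_values_are_uniform(self, rng):
        from scipy.stats import kstest

        ps = []
        for _ in range(400):
            values = rng.normal(size=20)
            labels = np.array(["unscrambled"] * 8 + ["scrambled"] * 12)
            ps.append(
                permutation_test(
                    values, labels, PermutationParams(n_permutations=500, seed=int(rng.integers(2**31)))
                ).p
            )
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_add_one_smoothing_keeps_p_positive(self):
        res = permutation_test(
            np.array([10.0, 9.0, 1.0, 2.0]),
            np.array(["unscrambled", "unscrambled", "scrambled", "scrambled"]),
            PermutationParams(exhaustive=True, add_one_smoothing=True),
        )
        assert res.p == pytest.approx(1 / 7)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            permutation_test(
                np.ones(4), np.array(["unscrambled"] * 4), PermutationParams()
            )


class TestCohensD:
    def test_identical_groups_are_zero(self):
        assert cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_computed_example(self):
        assert cohens_d([1.0, 2.0, 3.0], [3.0, 4.0, 5.0]) == pytest.approx(-2.0)

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=10), rng.normal(1, 2, size=7)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    @given(
        st.floats(-100, 100),
        st.floats(0.01, 50),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_common_affine_transform(self, shift, scale, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=8), rng.normal(0.5, 1, size=9)
        d0 = cohens_d(a, b)
        d1 = cohens_d(scale * a + shift, scale * b + shift)
        assert d1 == pytest.approx(d0, rel=1e-9, abs=1e-9)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [1.0, 1.0])


def _synthetic_nd_table(rng, n_sessions=8, effect_by_layer=None, n_trials=12):
    """Log-normal ND draws with optional per-layer category effects."""
    effect_by_layer = effect_by_layer or {}
    rows = []
    layers = ["L2/3", "L4", "L5"]
    areas = ["V1", "LM", "AL", "PM", "AM"]
    for i in range(n_sessions):
        layer = layers[i % 3]
        area = areas[i % 5]
        intercept = rng.normal(0, 0.3)
        for cat in ("unscrambled", "scrambled"):
            boost = effect_by_layer.get(layer, 0.0) if cat == "unscrambled" else 0.0
            for t in range(n_trials):
                rows.append(
                    {
                        "session_id": f"s{i}",
                        "layer": layer,
                        "area": area,
                        "stimulus_id": f"{cat}-1",
                        "category": cat,
                        "block": t,
                        "nd_value": float(np.exp(intercept + boost + rng.normal(0, 0.4))),
                        "measure": "spectral",
                        "params_digest": "x",
                    }
                )
    return pd.DataFrame(rows)


class TestCategoryInteraction:
    def test_lrt_degrees_of_freedom(self, rng):
        table = _synthetic_nd_table(rng, n_sessions=15)
        assert fit_category_interaction(table, factor="layer").df == 2
        assert fit_category_interaction(table, factor="area").df == 4

    def test_planted_layer_effect_recovered_with_specificity(self, rng):
        table = _synthetic_nd_table(
            rng, n_sessions=15, effect_by_layer={"L2/3": 0.8}, n_trials=20
        )
        res = fit_category_interaction(table, factor="layer")
        assert res.p < 0.05
        contrasts = res.contrasts.set_index("level")
        assert contrasts.loc["L2/3", "p_adj"] < 0.05
        assert contrasts.loc["L4", "p_adj"] > 0.05
        assert contrasts.loc["L5", "p_adj"] > 0.05
        assert contrasts.loc["L2/3", "d"] > 0
        # one-sided lower confidence bound excludes zero for the true effect
        assert contrasts.loc["L2/3", "ci_lower"] > 0

    def test_contrast_direction_is_unscrambled_minus_scrambled(self, rng):
        table = _synthetic_nd_table(
            rng, n_sessions=9, effect_by_layer={"L2/3": 1.0, "L4": 1.0, "L5": 1.0}
        )
        res = fit_category_interaction(table, factor="layer")
        assert (res.contrasts["estimate"] > 0).all()

    def test_too_few_sessions_rejected(self, rng):
        table = _synthetic_nd_table(rng, n_sessions=1)
        with pytest.raises(ValueError):
            fit_category_interaction(table)


class TestStimulusContrasts:
    def test_pair_count_and_null_behavior(self, rng):
        rows = []
        for i in range(8):
            for stim in ("a", "b", "c", "d", "e"):
                for t in range(6):
                    rows.append(
                        {
                            "session_id": f"s{i}",
                            "stimulus_id": stim,
                            "nd_value": float(np.exp(rng.normal(0, 0.3))),
                        }
                    )
        table = pd.DataFrame(rows)
        res = stimulus_pairwise_contrasts(table)
        assert res.df == 4
        assert len(res.pairs) == 10  # C(5, 2)

    def test_planted_stimulus_tops_all_its_contrasts(self, rng):
        rows = []
        for i in range(8):
            for stim in ("a", "b", "c", "d", "e"):
                boost = 1.0 if stim == "c" else 0.0
                for t in range(8):
                    rows.append(
                        {
                            "session_id": f"s{i}",
                            "stimulus_id": stim,
                            "nd_value": float(np.exp(boost + rng.normal(0, 0.3))),
                        }
                    )
        res = stimulus_pairwise_contrasts(pd.DataFrame(rows))
        assert res.p < 0.05
        involving = res.pairs[(res.pairs["a"] == "c") | (res.pairs["b"] == "c")]
        signed = np.where(involving["a"] == "c", involving["estimate"], -involving["estimate"])
        assert (signed > 0).all()
        assert (involving["p_adj"] < 0.05).all()


class TestEffectSizeVsArousal:
    def test_perfect_linear_relation(self):
        d = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        out = effect_size_vs_arousal(d, running_fractions=2 * d + 1)
        assert out.iloc[0]["r"] == pytest.approx(1.0)

    def test_df_structure_with_six_sessions(self, rng):
        d = rng.normal(size=6)
        out = effect_size_vs_arousal(
            d, running_fractions=rng.random(6), pupil_means=rng.random(6)
        )
        assert (out["df"] == 4).all()
        assert set(out["covariate"]) == {"running_fraction", "pupil"}

    def test_independent_pairs_center_on_zero(self, rng):
        rs = []
        for _ in range(200):
            out = effect_size_vs_arousal(
                rng.normal(size=10), running_fractions=rng.random(10)
            )
            rs.append(out.iloc[0]["r"])
        assert abs(np.mean(rs)) < 3 / np.sqrt(9 * 200)


class TestEndToEndTypeI:
    def test_null_cohort_interaction_is_calibrated(self):
        """With no planted effect the interaction LRT rejects at ~nominal rate."""
        rejections = 0
        n = 15
        for seed in range(n):
            spec = CohortSpec(
                n_sessions_per_population=1,
                n_cells_range=(5, 5),
                effect_delta=0.0,
                seed=seed,
            )
            sessions, _ = generate_cohort(spec)
            table = pd.concat(
                [
                    nd_per_trial(
                        s, SpectralParams(), categories=["unscrambled", "scrambled"]
                    )
                    for s in sessions
                ],
                ignore_index=True,
            )
            res = fit_category_interaction(table, factor="layer")
            rejections += res.p < 0.05
        assert rejections <= 3  # binomial(15, 0.05) upper tail
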