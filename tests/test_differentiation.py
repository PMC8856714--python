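import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popdiff.differentiation import (
    EmbeddingParams,
    SpectralParams,
    centroid_dispersion,
    embed_states,
    event_binned_states,
    multivariate_differentiation,
    nd_per_trial,
    remove_transients,
    sensitivity_grid,
    spectral_differentiation,
    window_states,
)
from oracles import spectral_nd_bruteforce


class TestWindowStates:
    def test_thirty_second_slice_yields_thirty_states(self, rng):
        dff = rng.normal(size=(4, 900))
        assert window_states(dff, SpectralParams(), 30.0).shape[0] == 30

    def test_constant_trace_concentrates_in_dc(self):
        states = window_states(np.full((1, 60), 3.0), SpectralParams(), 30.0)
        assert states[0, 0] > 0
        np.testing.assert_allclose(states[:, 1:], 0.0, atol=1e-18)

    def test_pure_tone_power_obeys_parseval(self):
        t = np.arange(30)
        x = np.sin(2 * np.pi * 5 * t / 30)[None, :]
        states = window_states(x, SpectralParams(), 30.0)
        freqs = np.fft.rfftfreq(30, 1 / 30)
        tone_bin = np.argmin(np.abs(freqs - 5))
        others = np.delete(states[0], [tone_bin])
        np.testing.assert_allclose(others, 0.0, atol=1e-9)
        # Parseval with a one-sided squared-magnitude spectrum: the 5 Hz line
        # carries (N/2)^2 and its conjugate the same, so |X_5|^2 = 225
        assert states[0, tone_bin] == pytest.approx(225.0, rel=1e-9)

    def test_overlap_increases_window_count(self, rng):
        dff = rng.normal(size=(2, 300))
        base = window_states(dff, SpectralParams(), 30.0)
        lapped = window_states(
            dff, SpectralParams(taper="tukey", overlap_fraction=0.5), 30.0
        )
        assert lapped.shape[0] > base.shape[0]

    def test_log_binning_reduces_state_dimension(self, rng):
        dff = rng.normal(size=(3, 120))
        lin = window_states(dff, SpectralParams(), 30.0)
        log = window_states(
            dff, SpectralParams(freq_binning="logarithmic", n_log_bins=4), 30.0
        )
        assert log.shape[1] == 3 * 5  # 4 geometric bins + DC bin, per cell
        assert log.shape[1] < lin.shape[1]
        # binning only regroups power: totals match
        np.testing.assert_allclose(log.sum(axis=1), lin.sum(axis=1), rtol=1e-12)

    def test_short_slice_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            window_states(np.zeros((1, 10)), SpectralParams(), 30.0)


class TestSpectralDifferentiation:
    def test_matches_bruteforce_enumeration(self, rng):
        for n_cells, n_win in [(1, 2), (2, 3), (3, 5)]:
            dff = rng.normal(size=(n_cells, 30 * n_win))
            got = spectral_differentiation(dff, SpectralParams(), 30.0)
            expected = spectral_nd_bruteforce(dff, 30.0)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_duplicated_population_invariance(self, rng):
        dff = rng.normal(size=(3, 150))
        nd = spectral_differentiation(dff, SpectralParams(), 30.0)
        for k in (2, 4):
            dup = np.tile(dff, (k, 1))
            assert spectral_differentiation(dup, SpectralParams(), 30.0) == pytest.approx(nd, rel=1e-9)
            unnorm = SpectralParams(normalize_by_sqrt_n=False)
            assert spectral_differentiation(dup, unnorm, 30.0) == pytest.approx(
                np.sqrt(k) * spectral_differentiation(dff, unnorm, 30.0), rel=1e-9
            )

    @pytest.mark.parametrize(
        "kind, exponent", [("power", 2.0), ("amplitude", 1.0)]
    )
    def test_homogeneity_under_trace_scaling(self, rng, kind, exponent):
        dff = rng.normal(size=(2, 120))
        params = SpectralParams(spectrum_kind=kind)
        base = spectral_differentiation(dff, params, 30.0)
        scaled = spectral_differentiation(2.5 * dff, params, 30.0)
        assert scaled == pytest.approx(2.5**exponent * base, rel=1e-9)

    def test_invariant_under_per_window_phase_randomization(self, rng):
        """Randomizing each trace's phase within each window preserves the
        power spectrum and hence spectral differentiation."""
        dff = rng.normal(size=(2, 150))
        scrambled = dff.copy()
        for c in range(2):
            for w in range(5):
                seg = scrambled[c, w * 30 : (w + 1) * 30]
                spec = np.fft.fft(seg)
                r = rng.uniform(0, 2 * np.pi, 14)
                phase = np.concatenate(
                    [[np.angle(spec[0])], r, [np.angle(spec[15])], -r[::-1]]
                )
                scrambled[c, w * 30 : (w + 1) * 30] = np.fft.ifft(
                    np.abs(spec) * np.exp(1j * phase)
                ).real
        a = spectral_differentiation(dff, SpectralParams(), 30.0)
        b = spectral_differentiation(scrambled, SpectralParams(), 30.0)
        assert b == pytest.approx(a, abs=1e-9 * max(a, 1.0))

    def test_iid_noise_has_strictly_positive_nd(self, rng):
        dff = rng.normal(size=(3, 900))
        assert spectral_differentiation(dff, SpectralParams(), 30.0) > 0

    @pytest.mark.parametrize("metric", ["euclidean", "manhattan", "cosine", "correlation"])
    def test_alternative_metrics_are_nonnegative(self, rng, metric):
        dff = rng.normal(size=(2, 120))
        params = SpectralParams(distance_metric=metric)
        assert spectral_differentiation(dff, params, 30.0) >= 0

    def test_single_window_rejected(self):
        with pytest.raises(ValueError):
            spectral_differentiation(np.zeros((1, 30)), SpectralParams(), 30.0)


class TestNdPerTrial:
    def test_one_row_per_trial(self, small_session):
        table = nd_per_trial(small_session, SpectralParams())
        assert len(table) == 120
        assert (table["nd_value"] >= 0).all()
        assert set(table["measure"]) == {"spectral"}

    def test_values_are_local_to_trials(self, small_session):
        params = SpectralParams()
        table = nd_per_trial(small_session, params)
        shuffled = small_session.trials.sample(frac=1, random_state=0)
        session2 = type(small_session)(
            dff=small_session.dff,
            cells=small_session.cells,
            trials=shuffled.reset_index(drop=True),
            session_id=small_session.session_id,
            layer=small_session.layer,
            area=small_session.area,
            sample_rate=small_session.sample_rate,
        )
        table2 = nd_per_trial(session2, params)
        merged = table.merge(
            table2, on=["stimulus_id", "block"], suffixes=("_a", "_b")
        )
        np.testing.assert_allclose(merged["nd_value_a"], merged["nd_value_b"])

    def test_category_filter_selects_fifty_trials(self, small_session):
        table = nd_per_trial(
            small_session, SpectralParams(), categories=["unscrambled", "scrambled"]
        )
        assert len(table) == 50


class TestMultivariate:
    def test_degenerate_cloud_has_zero_dispersion(self):
        assert centroid_dispersion(np.ones((5, 3))) == 0.0

    def test_two_point_cloud_dispersion_is_half_distance(self):
        pts = np.array([[0.0, 0.0], [2.0, 0.0]])
        assert centroid_dispersion(pts) == pytest.approx(1.0)

    def test_identity_embedding_per_trial_values(self, small_session):
        table = multivariate_differentiation(
            small_session, EmbeddingParams(method="identity")
        )
        assert len(table) == 50
        assert (table["nd_value"] > 0).all()
        assert set(table["measure"]) == {"multivariate"}

    def test_identity_dispersion_invariant_under_rotation(self, rng):
        pts = rng.normal(size=(40, 5))
        q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        assert centroid_dispersion(pts @ q) == pytest.approx(
            centroid_dispersion(pts), rel=1e-12
        )

    def test_linear_projection_embeds_to_requested_dimension(self, rng):
        mat = rng.normal(size=(100, 20))
        emb = embed_states(mat, EmbeddingParams(method="linear-projection", n_components=8))
        assert emb.shape == (100, 8)

    def test_nonlinear_manifold_embeds_to_eight_dimensions(self, rng):
        # small instance through the real manifold embedding backend
        mat = rng.normal(size=(120, 6))
        emb = embed_states(
            mat,
            EmbeddingParams(method="nonlinear-manifold", n_neighbors=10, seed=0),
        )
        assert emb.shape == (120, 8)


class TestEventBinned:
    def test_no_events_yield_empty(self):
        matrix, kept = event_binned_states(pd.DataFrame(columns=["cell_index", "sample_index", "magnitude"]), 3, 300, 30.0)
        assert matrix.shape == (0, 3)
        assert len(kept) == 0

    def test_single_event_lands_in_its_bin(self):
        events = pd.DataFrame(
            {"cell_index": [1], "sample_index": [96], "magnitude": [2.5]}
        )
        matrix, kept = event_binned_states(events, 2, 300, 30.0)
        assert list(kept) == [3]  # t = 3.2 s
        assert matrix[0, 1] == 2.5

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_column_sums_conserve_total_magnitude(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 30)
        events = pd.DataFrame(
            {
                "cell_index": rng.integers(0, 4, n),
                "sample_index": rng.integers(0, 600, n),
                "magnitude": rng.exponential(1.0, n),
            }
        )
        matrix, _ = event_binned_states(events, 4, 600, 30.0)
        totals = events.groupby("cell_index")["magnitude"].sum()
        for c in range(4):
            assert matrix[:, c].sum() == pytest.approx(totals.get(c, 0.0))


class TestRemoveTransients:
    def test_no_events_is_identity(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_array_equal(remove_transients(x, []), x)

    def test_linear_ramp_is_reproduced_by_interpolation(self):
        ramp = np.linspace(0, 10, 60)
        np.testing.assert_allclose(remove_transients(ramp, [25]), ramp)

    def test_close_events_merge_into_one_span(self):
        x = np.zeros(40)
        x[10:22] = 5.0  # transient bump
        out = remove_transients(x, [10, 13], span=6)
        # events 3 apart merge into one 9-sample span, interpolated between
        # the flanking untouched samples x[9] and x[19]
        np.testing.assert_allclose(out[10:19], np.linspace(x[9], x[19], 11)[1:-1])

    def test_edge_spans_clamp_to_nearest_valid(self):
        x = np.arange(10.0)
        out = remove_transients(x, [7], span=6)
        np.testing.assert_allclose(out[7:], x[6])


class TestSensitivityGrid:
    def test_grid_cardinality_and_single_point(self, small_session):
        calls = []

        def callback(table):
            calls.append(len(table))
            return {"p": 0.5}

        grid = {"distance_metric": ["euclidean", "manhattan"], "window_length": [1.0, 2.0, 3.0]}
        out = sensitivity_grid([small_session], grid, callback)
        assert len(out) == 6
        assert set(out.columns) == {"distance_metric", "window_length", "p"}
        single = sensitivity_grid([small_session], {"window_length": [1.0]}, callback)
        assert len(single) == 1
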