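"""Population vectors, correlations, sparseness, tuning, PCA, sorting."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pirinv.core import ResponseTable, TrialTensor
from pirinv import population as pop
from pirinv.synth import concentration_series


def _tensor(rate, stimuli, frame_rate=15.0):
    return TrialTensor(data=rate, stimuli=stimuli, frame_rate=frame_rate)


class TestPopulationVectors:
    def test_constant_rate_in_window_gives_that_value(self):
        rate = np.zeros((3, 2, 4, 450))
        rate[..., 120:180] = 0.7
        table = pop.build_population_vectors(
            _tensor(rate, [("a", 1e-4), ("b", 1e-4)]))
        assert np.allclose(table.array(), 0.7)

    def test_window_mean_matches_frame_mean_oracle(self, rng):
        rate = rng.normal(size=(4, 2, 4, 450))
        table = pop.build_population_vectors(
            _tensor(rate, [("a", 1e-4), ("b", 1e-4)]))
        oracle = rate[..., 120:180].mean(axis=-1)
        assert np.allclose(table.array(), oracle)

    def test_zero_rate_cell_gives_zero_entries(self, rng):
        rate = rng.normal(size=(3, 1, 4, 450))
        rate[1] = 0.0
        table = pop.build_population_vectors(_tensor(rate, [("a", 1e-4)]))
        assert np.allclose(table.array()[1], 0.0)

    def test_missing_trials_rejected(self):
        rate = np.full((2, 1, 4, 450), np.nan)
        with pytest.raises(ValueError):
            pop.build_population_vectors(_tensor(rate, [("a", 1e-4)]))


class TestCorrelationMatrix:
    def test_duplicated_trial_correlates_at_one(self, rng):
        resp = rng.normal(size=(10, 1, 4))
        resp[:, 0, 1] = resp[:, 0, 0]
        table = ResponseTable.from_array(resp, [("a", 1e-4)])
        corr, _ = pop.correlation_matrix(table)
        assert corr[0, 1] == pytest.approx(1.0)

    def test_negated_vector_correlates_at_minus_one(self, rng):
        resp = rng.normal(size=(10, 1, 2))
        resp[:, 0, 1] = -resp[:, 0, 0]
        table = ResponseTable.from_array(resp, [("a", 1e-4)])
        corr, _ = pop.correlation_matrix(table)
        assert corr[0, 1] == pytest.approx(-1.0)

    def test_matches_pearson_formula(self):
        rng = np.random.default_rng(3)
        resp = rng.normal(size=(6, 1, 3))
        table = ResponseTable.from_array(resp, [("a", 1e-4)])
        corr, _ = pop.correlation_matrix(table)
        v = resp[:, 0, :]
        for i in range(3):
            for j in range(3):
                x, y = v[:, i] - v[:, i].mean(), v[:, j] - v[:, j].mean()
                expected = (x @ y) / np.sqrt((x @ x) * (y @ y))
                assert corr[i, j] == pytest.approx(expected)

    def test_zero_variance_vector_reported_missing(self, rng):
        resp = rng.normal(size=(5, 1, 3))
        resp[:, 0, 2] = 1.0                       # constant trial vector
        table = ResponseTable.from_array(resp, [("a", 1e-4)])
        corr, _ = pop.correlation_matrix(table)
        assert np.isnan(corr[0, 2]) and np.isnan(corr[2, 2])

    def test_affine_transform_of_trial_vectors_leaves_matrix(self, rng):
        resp = rng.normal(size=(8, 2, 3))
        table = ResponseTable.from_array(resp, [("a", 1e-4), ("b", 1e-4)])
        corr, _ = pop.correlation_matrix(table)
        scaled = ResponseTable.from_array(2.5 * resp + 1.0,
                                          [("a", 1e-4), ("b", 1e-4)])
        corr2, _ = pop.correlation_matrix(scaled)
        assert np.allclose(corr, corr2)


class TestCorrelationSummary:
    def test_identical_trials_give_unit_means_everywhere(self, rng):
        v = rng.normal(size=10)
        resp = np.tile(v[:, None, None], (1, 9, 4))
        table = ResponseTable.from_array(resp, concentration_series())
        corr, meta = pop.correlation_matrix(table)
        summary = pop.summarize_correlations(corr, meta)
        assert all(m == pytest.approx(1.0) for m in summary.values())

    def test_block_structured_correlations_recovered(self):
        # common signal per group + independent noise -> known block
        # correlation rho = var_common / (var_common + var_noise)
        rng = np.random.default_rng(8)
        n_cells, rho = 4000, 0.6
        stimuli = concentration_series()
        resp = np.empty((n_cells, 9, 4))
        common = {}
        for s, (o, d) in enumerate(stimuli):
            if o not in common:
                common[o] = rng.normal(size=n_cells)
            base = np.sqrt(rho) * common[o]
            for t in range(4):
                resp[:, s, t] = base + np.sqrt(1 - rho) * rng.normal(
                    size=n_cells)
        table = ResponseTable.from_array(resp, stimuli)
        corr, meta = pop.correlation_matrix(table)
        summary = pop.summarize_correlations(corr, meta)
        assert summary["intra_stimulus"] == pytest.approx(rho, abs=0.02)
        assert summary["inter_odorant"] == pytest.approx(0.0, abs=0.02)

    def test_single_odorant_has_no_inter_odorant_group(self, rng):
        resp = rng.normal(size=(6, 1, 4))
        table = ResponseTable.from_array(resp, [("a", 1e-4)])
        corr, meta = pop.correlation_matrix(table)
        assert "inter_odorant" not in pop.summarize_correlations(corr, meta)


class TestLifetimeSparseness:
    def test_uniform_profile_is_zero(self):
        assert pop.lifetime_sparseness(np.full(13, 2.5)) == pytest.approx(0.0)

    def test_one_hot_profile_is_one(self):
        r = np.zeros(13)
        r[4] = 3.0
        assert pop.lifetime_sparseness(r) == pytest.approx(1.0)

    def test_half_active_profile(self):
        assert pop.lifetime_sparseness([1, 1, 0, 0]) == pytest.approx(2 / 3)

    def test_all_zero_is_degenerate_zero(self):
        assert pop.lifetime_sparseness(np.zeros(5)) == 0.0

    def test_negative_responses_clipped(self):
        assert pop.lifetime_sparseness([1.0, -5.0, -2.0, 0.0]) == \
            pytest.approx(1.0)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_positive_scaling(self, scale):
        r = np.array([0.1, 0.9, 0.0, 0.4, 0.2])
        assert pop.lifetime_sparseness(scale * r) == \
            pytest.approx(pop.lifetime_sparseness(r))

    def test_per_cell_series_uses_odorant_trial_means(self, rng):
        resp = np.zeros((2, 9, 4))
        resp[0, 0:3, :] = 1.0                      # one odorant, all dils
        resp[1, :, :] = 1.0                        # everything
        table = ResponseTable.from_array(resp, concentration_series())
        sl = pop.sparseness_per_cell(table, dilution=1e-4)
        assert sl.loc[0] == pytest.approx(1.0)     # one odorant of three
        assert sl.loc[1] == pytest.approx(0.0)


class TestResponsiveFractions:
    def test_no_flags_zero_everything_flagged_hundred(self):
        flags = np.full((5, 2, 4), "none", dtype=object)
        out = pop.responsive_fractions(flags)
        assert (out["activated_pct"] == 0).all()
        flags[:] = "act"
        out = pop.responsive_fractions(flags)
        assert (out["activated_pct"] == 100.0).all()

    def test_two_of_four_trials_gives_fifty_percent(self):
        flags = np.full((1, 1, 4), "none", dtype=object)
        flags[0, 0, :2] = "act"
        out = pop.responsive_fractions(flags)
        assert out["activated_pct"][0] == pytest.approx(50.0)


class TestTuningFilter:
    def _setup(self, rng):
        resp = rng.random((3, 2, 4))
        flags = np.full((3, 2, 4), "none", dtype=object)
        flags[0, 0, :1] = "act"                    # 1 of 4: excluded
        flags[1, 0, :2] = "act"                    # 2 of 4: included
        flags[2, :, :] = "act"
        table = ResponseTable.from_array(resp, [("a", 1e-4), ("b", 1e-4)])
        return resp, flags, table

    def test_min_two_of_four_rule(self, rng):
        resp, flags, table = self._setup(rng)
        kept = pop.tuning_and_maps_filter(flags, table)
        assert 0 not in kept["cell_id"].tolist()
        assert 1 in kept["cell_id"].tolist()

    def test_preferred_is_argmax_of_kept_means(self, rng):
        resp, flags, table = self._setup(rng)
        resp[2, 1, :] = 5.0                        # odor b strongest
        table = ResponseTable.from_array(resp, [("a", 1e-4), ("b", 1e-4)])
        kept = pop.tuning_and_maps_filter(flags, table)
        pref = kept[(kept.cell_id == 2) & kept.preferred]
        assert pref["odorant"].tolist() == ["b"]


class TestPcaAndSorting:
    def test_one_dimensional_data_fully_explained_by_first_pc(self, rng):
        t = rng.normal(size=12)
        resp = np.outer(np.arange(1, 7), t).reshape(6, 3, 4)
        table = ResponseTable.from_array(resp, [("a", 1e-4), ("b", 1e-4),
                                                ("c", 1e-4)])
        _, var = pop.pca_project(table, n_components=3)
        assert var[0] == pytest.approx(1.0)

    def test_rotation_leaves_variance_spectrum(self, rng):
        resp = rng.normal(size=(6, 2, 4))
        table = ResponseTable.from_array(resp, [("a", 1e-4), ("b", 1e-4)])
        _, var = pop.pca_project(table, n_components=3)
        q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        mat, _ = table.matrix()
        rotated = ResponseTable.from_array(
            (q @ mat).reshape(6, 2, 4), [("a", 1e-4), ("b", 1e-4)])
        _, var2 = pop.pca_project(rotated, n_components=3)
        assert np.allclose(var, var2, atol=1e-10)

    def test_full_reconstruction_matches_input(self):
        rng = np.random.default_rng(2)
        mat = rng.normal(size=(10, 5))
        from sklearn.decomposition import PCA
        pca = PCA(n_components=5)
        coords = pca.fit_transform(mat)
        recon = pca.inverse_transform(coords)
        assert np.allclose(recon, mat, atol=1e-8)

    def test_fewer_trials_than_components_errors(self, rng):
        resp = rng.normal(size=(4, 1, 2))
        table = ResponseTable.from_array(resp, [("a", 1e-4)])
        with pytest.raises(ValueError):
            pop.pca_project(table, n_components=3)

    def test_identical_rows_sorted_adjacent(self, rng):
        m = rng.normal(size=(5, 8))
        m[3] = m[0]
        order = pop.hierarchical_sort(m).tolist()
        assert abs(order.index(0) - order.index(3)) == 1

    def test_two_blocks_stay_contiguous(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        rows = [a + 0.05 * rng.normal(size=8) for _ in range(4)] + \
               [b + 0.05 * rng.normal(size=8) for _ in range(4)]
        order = pop.hierarchical_sort(np.array(rows))
        groups = [int(i >= 4) for i in order]
        assert groups in ([0] * 4 + [1] * 4, [1] * 4 + [0] * 4)

    def test_single_item_identity_order(self, rng):
        assert pop.hierarchical_sort(rng.normal(size=(1, 5))).tolist() == [0]
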