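"""Per-cell three-test ANOVA and identity-shuffle bootstrap."""

import numpy as np
import pandas as pd
import pytest

from pirinv.core import ResponseTable
from pirinv import invariance as inv
from pirinv.synth import (SimConfig, concentration_series,
                          generate_response_dataset)


def _table_from(resp):
    return ResponseTable.from_array(
        resp.reshape(resp.shape[0], 9, resp.shape[-1]),
        concentration_series())


class TestAnovaCell:
    def test_matches_statsmodels_type_two(self, rng):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        resp = rng.normal(size=(4, 3, 3, 4)) + \
            rng.normal(size=(4, 3, 1, 1))
        mine = inv.anova_population(resp)
        for c in range(4):
            rows = [{"y": resp[c, o, k, t], "odor": o, "conc": k, "tri": t}
                    for o in range(3) for k in range(3) for t in range(4)]
            df = pd.DataFrame(rows)
            fit = ols("y ~ C(odor)*C(conc) + C(tri)", df).fit()
            tab = sm.stats.anova_lm(fit, typ=2)
            assert mine.loc[c, "p_identity"] == pytest.approx(
                tab.loc["C(odor)", "PR(>F)"])
            assert mine.loc[c, "p_concentration"] == pytest.approx(
                tab.loc["C(conc)", "PR(>F)"])
            assert mine.loc[c, "p_interaction"] == pytest.approx(
                tab.loc["C(odor):C(conc)", "PR(>F)"])
            assert mine.loc[c, "p_trial"] == pytest.approx(
                tab.loc["C(tri)", "PR(>F)"])

    def test_identity_only_cell_detected_at_high_effect(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(100):
            resp = 0.1 * rng.normal(size=(3, 3, 4))
            resp[0] += 1.0                         # effect/noise = 10
            r = inv.anova_cell(resp)
            hits += r.category == "concentration_invariant"
        assert hits >= 90

    def test_interaction_cell_flagged_mixed(self):
        rng = np.random.default_rng(2)
        resp = 0.1 * rng.normal(size=(3, 3, 4))
        resp[0, 2] += 1.5                          # one odor at one conc only
        r = inv.anova_cell(resp)
        assert r.p_interaction < 0.01
        assert r.category == "mixed_interaction"

    def test_zero_variance_cell_degenerate(self):
        r = inv.anova_cell(np.ones((3, 3, 4)))
        assert r.category == "degenerate"
        assert np.isnan(r.p_identity)

    def test_null_cells_rarely_invariant(self):
        rng = np.random.default_rng(3)
        out = inv.anova_population(rng.normal(size=(4000, 3, 3, 4)))
        rate = (out.category == "concentration_invariant").mean()
        assert rate <= 0.01


class TestClassifyPopulation:
    def test_all_null_site_invariant_rate_below_alpha(self, rng):
        table = _table_from(rng.normal(size=(2000, 3, 3, 4)))
        res = inv.classify_population(table)
        assert res["invariant_pct"] <= 1.5        # alpha=1% + sampling noise

    def test_identity_significant_set_monotone_in_alpha(self, rng):
        table = _table_from(rng.normal(size=(300, 3, 3, 4))
                            + 0.5 * rng.normal(size=(300, 3, 1, 1)))
        cells = inv.classify_population(table)["cells"]
        strict = set(cells.loc[cells.p_identity < 0.01, "cell_id"])
        loose = set(cells.loc[cells.p_identity < 0.05, "cell_id"])
        assert strict <= loose

    def test_successive_procedure_same_invariant_set(self, series_table):
        table, _ = series_table
        single = inv.classify_population(table, procedure="single")["cells"]
        succ = inv.classify_population(table, procedure="successive")["cells"]
        a = single.loc[single.category == "concentration_invariant",
                       "cell_id"]
        b = succ.loc[succ.category == "concentration_invariant", "cell_id"]
        assert set(a) == set(b)

    def test_planted_fraction_recovered(self, series_table):
        table, gt = series_table
        res = inv.classify_population(table)
        planted = 100 * (gt.category == "identity_only").mean()
        assert res["invariant_pct"] == pytest.approx(planted, abs=2.0)


class TestBootstrap:
    def test_block_shuffle_preserves_marginals(self, rng):
        # every odorant-concentration block keeps exactly the same values
        resp = rng.normal(size=(50, 3, 3, 4))
        table = _table_from(resp)
        responses = inv._responses_by_factor(table)
        flat = responses.reshape(50, 9, 4)
        shuffled = np.empty_like(flat)
        block_rng = np.random.default_rng(5)
        for s in range(9):
            shuffled[:, s, :] = flat[block_rng.permutation(50), s, :]
        for s in range(9):
            assert np.array_equal(np.sort(shuffled[:, s, :].ravel()),
                                  np.sort(flat[:, s, :].ravel()))
            # trials of a triplet stay together
            rows_orig = {tuple(r) for r in flat[:, s, :]}
            rows_shuf = {tuple(r) for r in shuffled[:, s, :]}
            assert rows_orig == rows_shuf

    def test_seeded_bit_identical(self, rng):
        table = _table_from(rng.normal(size=(80, 3, 3, 4)))
        b1 = inv.bootstrap_identity_shuffle(table, n_boot=100, seed=9)
        b2 = inv.bootstrap_identity_shuffle(table, n_boot=100, seed=9)
        assert np.array_equal(b1.null_fractions, b2.null_fractions)
        assert b1.p == b2.p

    def test_iid_table_consistent_with_null(self, rng):
        table = _table_from(rng.normal(size=(400, 3, 3, 4)))
        b = inv.bootstrap_identity_shuffle(table, n_boot=200, seed=3)
        lo, hi = np.percentile(b.null_fractions, [2.5, 97.5])
        assert lo - 1e-9 <= b.observed_fraction <= hi + 1e-9

    def test_planted_invariants_overrepresented(self, series_table):
        table, _ = series_table
        b = inv.bootstrap_identity_shuffle(table, n_boot=200, seed=7)
        assert b.p < 0.01
        assert b.observed_fraction > b.null_fractions.mean()

    def test_too_few_replicates_rejected(self, rng):
        table = _table_from(rng.normal(size=(20, 3, 3, 4)))
        with pytest.raises(ValueError):
            inv.bootstrap_identity_shuffle(table, n_boot=50, seed=0)


class TestPerSite:
    def test_identical_sites_and_seed_reproduce_flags(self, rng):
        tables = [_table_from(rng.normal(size=(100, 3, 3, 4)))]
        out1 = inv.per_site_significance(tables * 2, n_boot=100, seed=4)
        rerun = inv.per_site_significance(tables * 2, n_boot=100, seed=4)
        assert out1.equals(rerun)
        # a null site is flagged only rarely (99th-percentile criterion)
        assert out1["observed_pct"].max() < 5.0

    def test_strongly_invariant_site_flagged(self):
        rng = np.random.default_rng(6)
        resp = 0.1 * rng.normal(size=(200, 3, 3, 4))
        idx = rng.choice(200, 30, replace=False)
        for c in idx:                              # 15% strong invariants
            resp[c, rng.integers(3)] += 1.0
        out = inv.per_site_significance([_table_from(resp)], n_boot=200,
                                        seed=1)
        assert bool(out.loc[0, "significant"])


class TestSubsample:
    def test_full_subsample_degenerate_at_observed(self, series_table):
        table, _ = series_table
        full = inv.classify_population(table)["invariant_pct"]
        out = inv.subsample_comparison(table, n_target=table.n_cells,
                                       n_iter=20, seed=0)
        assert np.allclose(out, full)

    def test_subsample_mean_unbiased(self, series_table):
        table, _ = series_table
        full = inv.classify_population(table)["invariant_pct"]
        out = inv.subsample_comparison(table, n_target=100, n_iter=400,
                                       seed=1)
        se = out.std() / np.sqrt(len(out))
        assert abs(out.mean() - full) < max(2 * se, 0.5)

    def test_two_seeds_agree_within_error(self, series_table):
        table, _ = series_table
        a = inv.subsample_comparison(table, n_target=100, n_iter=300, seed=2)
        b = inv.subsample_comparison(table, n_target=100, n_iter=300, seed=3)
        se = np.sqrt(a.std() ** 2 / len(a) + b.std() ** 2 / len(b))
        assert abs(a.mean() - b.mean()) < 3 * se + 1e-9

    def test_oversized_target_rejected(self, series_table):
        table, _ = series_table
        with pytest.raises(ValueError):
            inv.subsample_comparison(table, n_target=table.n_cells + 1)
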