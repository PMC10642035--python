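"""Genome tiling, window tests, q-values, and overlap algebra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from oxbsdm.dmr import (
    WindowTable,
    call_dhmr,
    call_dmr,
    dhmr_from_levels,
    dmr_correlation,
    dmr_overlap,
    logistic_lrt,
    manual_q,
    tile_genome,
    window_levels,
)
from oxbsdm.io import SiteCalls, ValidationError


class TestTileGenome:
    def test_partial_final_tile(self):
        tiles = tile_genome({"chr1": 2500}, 1000)
        assert list(map(tuple, tiles[["start", "end"]].to_numpy())) == [(0, 1000), (1000, 2000), (2000, 2500)]

    def test_single_tile(self):
        assert len(tile_genome({"chr1": 1000}, 1000)) == 1

    def test_length_conserved(self):
        sizes = {"chr1": 12_345, "chr2": 999}
        tiles = tile_genome(sizes, 1000)
        assert (tiles["end"] - tiles["start"]).sum() == sum(sizes.values())


def _calls(rows, context="CG"):
    pos, cov, mod = zip(*rows)
    return SiteCalls.from_arrays(["chr1"] * len(pos), pos, ["+"] * len(pos), cov, mod, context)


class TestWindowLevels:
    def test_all_rule_drops_partially_covered_window(self):
        windows = tile_genome({"chr1": 2000}, 1000)
        calls = {
            "s1": _calls([(100, 10, 4), (1100, 10, 4)]),
            "s2": _calls([(100, 10, 4), (1100, 10, 4)]),
            "s3": _calls([(100, 10, 4)]),  # window 2 uncovered
            "s4": _calls([(100, 10, 4), (1100, 10, 4)]),
        }
        wt = window_levels(calls, windows, min_samples_rule="all")
        assert len(wt) == 1

    def test_at_least_two_rule_retains(self):
        windows = tile_genome({"chr1": 2000}, 1000)
        calls = {
            "s1": _calls([(1100, 10, 4)]),
            "s2": _calls([(1100, 10, 4)]),
            "s3": _calls([(100, 10, 4)]),
        }
        wt = window_levels(calls, windows, min_samples_rule="at_least_k", k=2)
        assert (wt.windows["start"] == 1000).any()

    def test_window_level_value(self):
        windows = tile_genome({"chr1": 1000}, 1000)
        wt = window_levels({"s1": _calls([(50, 10, 4)]), "s2": _calls([(50, 10, 4)])}, windows)
        assert wt.levels[0, 0] == pytest.approx(0.40)

    def test_context_mix_rejected(self):
        windows = tile_genome({"chr1": 1000}, 1000)
        with pytest.raises(ValidationError):
            window_levels({"a": _calls([(1, 5, 1)], "CG"), "b": _calls([(1, 5, 1)], "CH")}, windows)


class TestManualQ:
    def test_single_value(self):
        assert manual_q([0.5]) == pytest.approx([0.5])

    def test_hand_stepped_pair(self):
        np.testing.assert_allclose(manual_q([0.04, 0.01]), [0.04, 0.02])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            manual_q([0.5, 1.5])

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50))
    def test_equals_bh_adjustment(self, pvals):
        ours = manual_q(pvals)
        bh = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, bh, atol=1e-12)


def _window_table(mod, cov, samples=None):
    mod = np.asarray(mod)
    n_w = mod.shape[0]
    windows = tile_genome({"chr1": n_w * 1000}, 1000)
    samples = samples or tuple(f"s{i}" for i in range(mod.shape[1]))
    return WindowTable(windows=windows, samples=tuple(samples),
                       coverage=np.asarray(cov), modified=mod, width=1000)


GROUPS8 = {f"s{i}": ("A" if i < 4 else "B") for i in range(8)}


class TestCallDmr:
    def test_identical_counts_yield_no_records(self):
        cov = np.full((20, 8), 50)
        mod = np.full((20, 8), 25)
        wt = _window_table(mod, cov)
        assert len(call_dmr(wt, GROUPS8, ("A", "B"))) == 0

    def test_planted_window_recovered_and_small_diff_excluded(self, rng):
        n_w = 101
        cov = rng.poisson(50, (n_w, 8)) + 1
        p = np.full((n_w, 8), 0.5)
        p[0, :4] = 0.8  # 30 pp planted difference in window 0
        mod = rng.binomial(cov, p)
        wt = _window_table(mod, cov)
        res = call_dmr(wt, GROUPS8, ("A", "B"))
        assert 0 in set(res["start"] // 1000)
        # a window with tiny p but diff below 5 pp is filtered on effect size
        cov2 = np.full((2, 8), 100_000)
        mod2 = np.zeros((2, 8), int)
        mod2[0] = [50_000] * 4 + [45_100] * 4  # 4.9 pp apart, p ~ 0
        mod2[1] = 50_000
        res2 = call_dmr(_window_table(mod2, cov2), GROUPS8, ("A", "B"))
        assert len(res2) == 0

    def test_zero_coverage_group_window_skipped(self):
        cov = np.full((3, 8), 50)
        cov[1, :4] = 0
        mod = (cov * 0.5).astype(int)
        res = call_dmr(_window_table(mod, cov), GROUPS8, ("A", "B"))
        assert res.attrs["n_skipped_zero_coverage"] == 1

    def test_needs_two_replicates_per_group(self):
        cov = np.full((2, 3), 50)
        mod = np.full((2, 3), 10)
        wt = _window_table(mod, cov)
        with pytest.raises(ValidationError):
            call_dmr(wt, {"s0": "A", "s1": "A", "s2": "B"}, ("A", "B"))

    def test_lrt_matches_statsmodels_glm(self, rng):
        """Closed-form LRT equals an independent binomial-GLM deviance test."""
        import statsmodels.api as sm

        for _ in range(5):
            cov_a, cov_b = rng.poisson(40, 4) + 1, rng.poisson(40, 4) + 1
            mod_a = rng.binomial(cov_a, 0.6)
            mod_b = rng.binomial(cov_b, 0.4)
            ours = logistic_lrt([mod_a.sum()], [cov_a.sum()], [mod_b.sum()], [cov_b.sum()])[0]
            endog = np.column_stack([np.concatenate([mod_a, mod_b]),
                                     np.concatenate([cov_a - mod_a, cov_b - mod_b])])
            group = np.repeat([1.0, 0.0], 4)
            full = sm.GLM(endog, sm.add_constant(group), family=sm.families.Binomial()).fit()
            null = sm.GLM(endog, np.ones((8, 1)), family=sm.families.Binomial()).fit()
            from scipy import stats as sps
            theirs = sps.chi2.sf(2 * (full.llf - null.llf), 1)
            assert ours == pytest.approx(theirs, rel=1e-6, abs=1e-12)


class TestCallDhmr:
    def _tables(self, h_bs, h_ox):
        return _window_table((np.asarray(h_bs) * 100).astype(int), np.full(np.shape(h_bs), 100)), \
               _window_table((np.asarray(h_ox) * 100).astype(int), np.full(np.shape(h_ox), 100))

    def test_identical_groups_yield_no_records(self):
        bs = np.full((10, 8), 0.5)
        ox = np.full((10, 8), 0.3)
        res = call_dhmr(*self._tables(bs, ox), GROUPS8, ("A", "B"))
        assert len(res) == 0

    def test_large_diff_with_weak_evidence_excluded(self):
        # 6 pp group difference but replicate scatter makes p large
        ox = np.full((1, 8), 0.30)
        bs = ox + 0.30
        bs[0, :4] += np.array([0.18, -0.10, 0.10, 0.06])
        res = call_dhmr(*self._tables(bs, ox), GROUPS8, ("A", "B"))
        assert len(res) == 0

    def test_planted_difference_recovered(self, rng):
        n_w = 100
        ox = np.full((n_w, 8), 0.30)
        bs = ox + 0.15 + rng.normal(0, 0.02, (n_w, 8))
        bs[:5, :4] += 0.20  # planted in first five windows for group A
        res = call_dhmr(*self._tables(np.clip(bs, 0, 1), ox), GROUPS8, ("A", "B"))
        got = set(res["start"] // 1000)
        assert got.issuperset({0, 1, 2, 3, 4})

    def test_two_replicates_required(self):
        bs = np.full((3, 3), 0.5)
        ox = np.full((3, 3), 0.3)
        wt_bs, wt_ox = self._tables(bs, ox)
        groups = {"s0": "A", "s1": "A", "s2": "B"}
        with pytest.raises(ValidationError):
            call_dhmr(wt_bs, wt_ox, groups, ("A", "B"))

    def test_invariant_to_sample_and_window_order(self, rng):
        n_w = 30
        h = 0.2 + rng.normal(0, 0.05, (n_w, 8))
        windows = tile_genome({"chr1": n_w * 1000}, 1000)
        samples = tuple(f"s{i}" for i in range(8))
        base = dhmr_from_levels(windows, h, samples, GROUPS8, ("A", "B"))
        # permute samples within groups
        perm = [1, 3, 0, 2, 6, 4, 7, 5]
        swapped = dhmr_from_levels(windows, h[:, perm], tuple(f"s{i}" for i in perm),
                                   GROUPS8, ("A", "B"))
        pd.testing.assert_frame_equal(base, swapped)
        # permute window order
        worder = rng.permutation(n_w)
        shuffled = dhmr_from_levels(windows.iloc[worder].reset_index(drop=True), h[worder],
                                    samples, GROUPS8, ("A", "B"))
        a = base.sort_values("start").reset_index(drop=True)
        b = shuffled.sort_values("start").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestDmrOverlap:
    def _dmrs(self, starts, direction="hyper"):
        return pd.DataFrame({"chrom": "chr1", "start": starts,
                             "end": [s + 1000 for s in starts],
                             "direction": direction})

    def test_disjoint_sets(self):
        out = dmr_overlap(self._dmrs([0]), self._dmrs([1000]), self._dmrs([2000]))
        hyper = out["hyper"]
        assert all(len(k) == 1 for k in hyper)

    def test_identical_sets_all_triple(self):
        d = self._dmrs([0, 1000])
        out = dmr_overlap(d, d, d, names=("x", "y", "z"))
        assert out["hyper"] == {frozenset({"x", "y", "z"}): 2}

    def test_random_sets_match_brute_force(self, rng):
        universe = np.arange(0, 50_000, 1000)
        sets = [set(rng.choice(universe, size=15, replace=False)) for _ in range(3)]
        frames = [self._dmrs(sorted(s)) for s in sets]
        out = dmr_overlap(*frames)["hyper"]
        for w in set().union(*sets):
            member = frozenset(n for n, s in zip("abc", sets) if w in s)
            assert out[member] >= 1  # every window accounted for
        assert sum(out.values()) == len(set().union(*sets))

    def test_mismatched_grid_rejected(self):
        a = self._dmrs([0])
        b = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [500], "direction": ["hyper"]})
        with pytest.raises(ValidationError):
            dmr_overlap(a, b, self._dmrs([2000]))


def test_anticorrelated_planted_differences_detected(rng):
    """mC and hmC exchanging in the same windows shows as negative correlation."""
    starts = np.arange(0, 50_000, 1000)
    diff_m = rng.normal(0, 10, len(starts))
    base = dict(chrom="chr1", end=starts + 1000)
    dm = pd.DataFrame({**base, "start": starts, "diff_pp": diff_m, "direction": "hyper"})
    dh = pd.DataFrame({**base, "start": starts, "diff_pp": -diff_m + rng.normal(0, 2, len(starts)),
                       "direction": "hyper"})
    r, p, n = dmr_correlation(dm, dh)
    assert n == len(starts) and r < -0.9 and p < 1e-6
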