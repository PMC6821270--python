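"""t-statistic track, region segmentation, balanced permutations and gFWER."""

import numpy as np
import pandas as pd
import pytest

from methdiverge.differential import (
    CandidateRegion,
    DmrParams,
    GroupDesign,
    TStatTrack,
    assign_gfwer,
    balanced_permutations,
    compute_tstat,
    find_regions,
    null_regions,
)
from methdiverge.smoothing import SmoothedTrack, SmoothingParams


def _track(values, positions=None, chrom="chr1"):
    values = np.asarray(values, float)
    n_samples, n_sites = values.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    sites = pd.DataFrame({"chrom": chrom, "pos": positions})
    return SmoothedTrack(
        sites,
        values,
        np.zeros_like(values, dtype=bool),
        [f"s{i}" for i in range(n_samples)],
        ["A"] * (n_samples // 2) + ["B"] * (n_samples - n_samples // 2),
        SmoothingParams(),
    )


def _design(n1=2, n2=2):
    n = n1 + n2
    return GroupDesign.from_lists(
        [f"s{i}" for i in range(n)], [1] * n1 + [2] * n2, ["A"] * n1 + ["B"] * n2
    )


class TestComputeTstat:
    def test_identical_groups_zero_t(self, rng):
        v = rng.uniform(0.2, 0.8, size=(2, 30))
        track = _track(np.vstack([v, v]))  # group2 duplicates group1
        design = GroupDesign.from_lists(
            ["s0", "s1", "s2", "s3"], [1, 1, 2, 2], ["A", "A", "B", "B"]
        )
        out = compute_tstat(track, design, np.ones(30, bool))
        assert np.allclose(out.t[out.mask], 0.0)

    def test_constant_groups_floor_keeps_t_finite(self):
        vals = np.array([[0.2] * 20, [0.2] * 20, [0.7] * 20, [0.7] * 20])
        out = compute_tstat(_track(vals), _design(), np.ones(20, bool))
        assert np.isfinite(out.t[out.mask]).all()
        assert (out.sd[out.mask] > 0).all()

    def test_small_instance_matches_hand_computation(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 1, size=(4, 12))
        mask = np.ones(12, bool)
        mask[3] = False
        out = compute_tstat(_track(vals), _design(), mask, sd_smooth_window=5)

        # independent spreadsheet-style recomputation
        g1, g2 = vals[:2], vals[2:]
        md = g2.mean(0) - g1.mean(0)
        raw_sd = np.sqrt((g1.var(0, ddof=1) + g2.var(0, ddof=1)) / 2)
        floor = np.quantile(raw_sd[mask], 0.75)
        fl = np.maximum(raw_sd, floor)
        midx = np.flatnonzero(mask)
        sm_sd = np.empty(midx.size)
        for k in range(midx.size):
            lo, hi = max(0, k - 2), min(midx.size, k + 3)
            sm_sd[k] = fl[midx[lo:hi]].mean()
        t_expect = md[midx] / (sm_sd * np.sqrt(1 / 2 + 1 / 2))
        assert np.allclose(out.t[midx], t_expect, atol=1e-12)
        assert np.isnan(out.t[3])

    def test_single_sample_group_errors(self):
        track = _track(np.zeros((3, 5)))
        design = GroupDesign.from_lists(["s0", "s1", "s2"], [1, 2, 2], ["A", "B", "B"])
        with pytest.raises(ValueError, match="2 samples"):
            compute_tstat(track, design, np.ones(5, bool))


def _tstat_from_values(t, positions, mean_diff=None, mask=None, chrom="chr1"):
    t = np.asarray(t, float)
    n = t.size
    mask = np.ones(n, bool) if mask is None else mask
    md = np.sign(t) * 0.5 if mean_diff is None else np.asarray(mean_diff, float)
    sites = pd.DataFrame({"chrom": chrom, "pos": positions})
    return TStatTrack(np.zeros(n), md, md, np.ones(n), t, mask, sites)


class TestFindRegions:
    def test_no_site_passes(self):
        ts = _tstat_from_values([1, 2, -3], np.array([100, 200, 300]))
        assert find_regions(ts, DmrParams(cutoff=4.6)) == []

    def test_five_consecutive_sites(self):
        ts = _tstat_from_values([5.0] * 5, np.arange(1, 6) * 100, mean_diff=[0.2] * 5)
        regions = find_regions(ts, DmrParams(cutoff=4.6, max_gap=300))
        assert len(regions) == 1
        r = regions[0]
        assert (r.n_cpgs, r.area_stat, r.direction) == (5, 25.0, 1)
        assert (r.start, r.end) == (100, 500)
        assert r.mean_diff == pytest.approx(0.2)

    def test_gap_splits_region(self):
        pos = np.array([100, 200, 300, 5000, 5100, 5200])
        ts = _tstat_from_values([5.0] * 6, pos)
        regions = find_regions(ts, DmrParams(cutoff=4.6, max_gap=300))
        assert [(r.start, r.end) for r in regions] == [(100, 300), (5000, 5200)]

    def test_sign_flip_symmetry(self, rng):
        t = rng.normal(0, 4, 80)
        pos = np.arange(1, 81) * 50
        a = find_regions(_tstat_from_values(t, pos), DmrParams(cutoff=3, min_meandiff=0))
        b = find_regions(_tstat_from_values(-t, pos), DmrParams(cutoff=3, min_meandiff=0))
        assert [(r.start, r.end, r.n_cpgs) for r in a] == [(r.start, r.end, r.n_cpgs) for r in b]
        assert [r.direction for r in a] == [-r.direction for r in b]

    def test_matches_bruteforce_segmentation(self, rng):
        for _ in range(20):
            n = 60
            t = rng.normal(0, 3, n)
            mask = rng.random(n) > 0.2
            pos = np.sort(rng.choice(np.arange(1, 5000), n, replace=False))
            params = DmrParams(cutoff=2.5, max_gap=200, min_cpgs=2, min_meandiff=0.0)
            got = find_regions(_tstat_from_values(t, pos, mask=mask), params)

            # brute force over masked sites
            midx = [j for j in range(n) if mask[j]]
            runs, cur = [], []
            for j in midx:
                if abs(t[j]) < params.cutoff:
                    runs.append(cur)
                    cur = []
                    continue
                if cur and (
                    np.sign(t[j]) != np.sign(t[cur[-1]]) or pos[j] - pos[cur[-1]] > params.max_gap
                ):
                    runs.append(cur)
                    cur = []
                cur.append(j)
            runs.append(cur)
            expect = [
                (pos[r[0]], pos[r[-1]], len(r), sum(t[j] for j in r))
                for r in runs
                if len(r) >= params.min_cpgs
            ]
            assert [(r.start, r.end, r.n_cpgs, pytest.approx(r.area_stat)) for r in got] == [
                (a, b, c, pytest.approx(d)) for a, b, c, d in expect
            ]


class TestBalancedPermutations:
    def _design(self, na, nb):
        n = na + nb
        return GroupDesign.from_lists(
            [f"s{i}" for i in range(n)],
            [1] * (n // 2) + [2] * (n - n // 2),
            ["A"] * na + ["B"] * nb,
        )

    @pytest.mark.parametrize("na,nb,expected", [(2, 2, 2), (4, 4, 18), (6, 6, 200)])
    def test_counts_genotype_pure_observed(self, na, nb, expected):
        perms = balanced_permutations(self._design(na, nb))
        assert len(perms) == expected
        # brute-force check of balance on each returned assignment
        for p in perms:
            for g in ("A", "B"):
                in1 = sum(
                    1
                    for i in p.group_indices(1)
                    if p.genotypes[i] == g
                )
                assert in1 * 2 == sum(1 for x in p.genotypes if x == g)

    def test_balanced_observed_assignment_is_excluded(self):
        # observed groups already balanced: one of the C*C/2 assignments drops
        design = GroupDesign.from_lists(
            ["a1", "b1", "a2", "b2"], [1, 1, 2, 2], ["A", "B", "A", "B"]
        )
        perms = balanced_permutations(design)
        assert len(perms) == 1  # 2 balanced assignments minus the observed one
        assert all(set(p.group_indices(1)) != {0, 1} for p in perms)

    def test_odd_genotype_count_errors(self):
        design = GroupDesign.from_lists(
            ["s0", "s1", "s2", "s3"], [1, 1, 2, 2], ["A", "A", "A", "B"]
        )
        with pytest.raises(ValueError, match="even"):
            balanced_permutations(design)


class TestGfwer:
    def _region(self, n_cpgs, area):
        return CandidateRegion("chr1", 1, 100, n_cpgs, 0.2, area, int(np.sign(area)))

    def test_no_null_regions_gfwer_zero(self):
        obs = [self._region(5, 25.0)]
        out = assign_gfwer(obs, [[] for _ in range(18)])
        assert out[0].gfwer == 0.0

    def test_one_of_18_better(self):
        obs = [self._region(5, 25.0)]
        nulls = [[] for _ in range(17)] + [[self._region(6, 30.0)]]
        out = assign_gfwer(obs, nulls)
        assert out[0].gfwer == pytest.approx(1 / 18)

    def test_ties_count_against_observed(self):
        obs = [self._region(5, 25.0)]
        out = assign_gfwer(obs, [[self._region(5, -25.0)]])
        assert out[0].gfwer == 1.0

    def test_dominating_nulls_split(self):
        obs = [self._region(3, 10.0), self._region(8, 50.0)]
        nulls = [[self._region(5, 25.0)]] * 4
        out = assign_gfwer(obs, nulls)
        assert out[0].gfwer == 1.0 and out[1].gfwer == 0.0

    def test_dominance_monotonicity_random(self, rng):
        for _ in range(20):
            nulls = [
                [self._region(int(rng.integers(1, 20)), float(rng.normal(0, 30))) for _ in range(5)]
                for _ in range(10)
            ]
            a = self._region(6, 20.0)
            b = self._region(4, 15.0)  # dominated by a on both criteria
            out = assign_gfwer([a, b], nulls)
            assert out[0].gfwer <= out[1].gfwer

    def test_empty_permutation_list_errors(self):
        with pytest.raises(ValueError):
            assign_gfwer([self._region(3, 9.0)], [])


class TestNullRegions:
    def test_observed_design_reproduces_regions(self, rng):
        vals = rng.uniform(0, 1, size=(4, 40))
        vals[2:, 10:20] += 0.5
        vals = np.clip(vals, 0, 1)
        track = _track(vals)
        design = _design()
        mask = np.ones(40, bool)
        params = DmrParams(cutoff=2, max_gap=300, min_cpgs=2, min_meandiff=0.05)
        direct = find_regions(compute_tstat(track, design, mask), params)
        via_null = null_regions(track, design, mask, params)
        assert [(r.start, r.end) for r in direct] == [(r.start, r.end) for r in via_null]

    def test_empty_mask_no_regions(self, rng):
        track = _track(rng.uniform(0, 1, size=(4, 20)))
        assert null_regions(track, _design(), np.zeros(20, bool)) == []
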