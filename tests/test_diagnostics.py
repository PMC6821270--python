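"""Global/category methylation, wrong-reference bias simulation and the
unique-shared disparity."""

import numpy as np
import pandas as pd
import pytest

from methdiverge.cpg_catalog import COMMON_CG, OTHER_MUT, TG_CA
from methdiverge.diagnostics import (
    category_methylation,
    global_methylation,
    raw_region_diff,
    simulate_wrong_reference,
    unique_shared_disparity,
)
from methdiverge.differential import CandidateRegion, GroupDesign
from methdiverge.meth_io import MethMatrix, filter_variant_cpgs, restrict_to_shared


def _matrix(M, Cov, present=None, genotypes=("A", "A", "B", "B"), positions=None):
    M, Cov = np.asarray(M), np.asarray(Cov)
    n = M.shape[1]
    positions = np.arange(1, n + 1) * 10 if positions is None else positions
    sites = pd.DataFrame({"chrom": "chr1", "pos": positions})
    samples = [f"{g.lower()}{i}" for i, g in enumerate(genotypes)]
    return MethMatrix(
        sites, M, Cov, samples, list(genotypes), sorted(set(genotypes)),
        None if present is None else np.asarray(present),
    )


def _design(matrix):
    return GroupDesign.from_lists(
        matrix.samples, [1 if g == "A" else 2 for g in matrix.genotypes], matrix.genotypes
    )


class TestGlobalMethylation:
    def test_two_sites_half(self):
        mat = _matrix([[4, 0]], [[4, 3]], genotypes=("A",))
        assert global_methylation(mat)["a0"] == pytest.approx(0.5)

    def test_uncovered_sites_ignored(self):
        a = _matrix([[4, 0]], [[4, 3]], genotypes=("A",))
        b = _matrix([[4, 0, 0]], [[4, 3, 0]], genotypes=("A",))
        assert global_methylation(a)["a0"] == global_methylation(b)["a0"]

    def test_chrom_filter_and_missing(self):
        mat = _matrix([[2, 0]], [[2, 0]], genotypes=("A",))
        assert np.isnan(global_methylation(mat, chrom_filter=["chrX"])["a0"])

    def test_matches_bruteforce(self, rng):
        Cov = rng.integers(0, 5, (3, 40))
        M = rng.binomial(Cov, 0.4)
        mat = _matrix(M, Cov, genotypes=("A", "A", "A"))
        got = global_methylation(mat)
        for i, s in enumerate(mat.samples):
            vals = [M[i, j] / Cov[i, j] for j in range(40) if Cov[i, j] >= 1]
            assert got[s] == pytest.approx(np.mean(vals))


class TestCategoryMethylation:
    def test_all_common_equals_global(self, rng):
        Cov = rng.integers(1, 6, (2, 20))
        M = rng.binomial(Cov, 0.6)
        mat = _matrix(M, Cov, genotypes=("A", "B"))
        cls = pd.DataFrame({"chrom": "chr1", "pos": mat.sites["pos"], "category": COMMON_CG})
        out = category_methylation(mat, cls)
        assert np.allclose(out[COMMON_CG].to_numpy(), global_methylation(mat).to_numpy())

    def test_weighted_recomposition_of_global(self, rng):
        Cov = rng.integers(0, 6, (2, 30))
        M = rng.binomial(Cov, 0.5)
        mat = _matrix(M, Cov, genotypes=("A", "B"))
        cats = rng.choice([COMMON_CG, TG_CA, OTHER_MUT], 30)
        cls = pd.DataFrame({"chrom": "chr1", "pos": mat.sites["pos"], "category": cats})
        per_cat = category_methylation(mat, cls)
        glob = global_methylation(mat)
        for i, s in enumerate(mat.samples):
            total, acc = 0, 0.0
            for cat in per_cat.columns:
                n_cov = int(((Cov[i] >= 1) & (cats == cat)).sum())
                if n_cov and np.isfinite(per_cat.loc[s, cat]):
                    acc += per_cat.loc[s, cat] * n_cov
                    total += n_cov
            assert acc / total == pytest.approx(glob[s], abs=1e-12)


class TestWrongReference:
    def _setup(self):
        # sites: 0 shared, 1 ref(A)-unique TG_CA, 2 shared, 3 B-unique
        present = [[True, True, True, False], [True, False, True, True]]
        M = np.array([[5, 5, 5, 0], [5, 5, 5, 0], [4, 0, 4, 4], [4, 0, 4, 4]])
        Cov = np.array([[5, 5, 5, 0], [5, 5, 5, 0], [5, 0, 5, 5], [5, 0, 5, 5]])
        mat = _matrix(M, Cov, present=present)
        cls = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": mat.sites["pos"],
                "category": [COMMON_CG, TG_CA, COMMON_CG, COMMON_CG],
            }
        )
        return mat, cls

    def test_no_unique_sites_identity(self):
        mat = _matrix([[3, 2]], [[4, 4]], present=[[True, True]], genotypes=("A",))
        cls = pd.DataFrame(
            {"chrom": "chr1", "pos": mat.sites["pos"], "category": [COMMON_CG] * 2}
        )
        out = simulate_wrong_reference(mat, cls, "A")
        assert (out.M == mat.M).all() and (out.Cov == mat.Cov).all()

    def test_nonref_samples_get_zero_calls_at_ref_unique_tgca(self):
        mat, cls = self._setup()
        out = simulate_wrong_reference(mat, cls, "A")
        # B samples: fake coverage, 0 methylated at site 1; data gone at site 3
        assert (out.Cov[2:, 1] > 0).all() and (out.M[2:, 1] == 0).all()
        assert (out.Cov[2:, 3] == 0).all()
        # A samples untouched
        assert (out.M[:2] == mat.M[:2]).all()

    def test_global_methylation_depressed_and_analytic(self):
        # f of B's covered reference sites are ref-unique TG/CA at true
        # methylation m: wrong-ref global for B = m * (1 - f)
        rng = np.random.default_rng(3)
        n = 400
        n_unique = 100
        present = np.ones((2, n), bool)
        present[1, :n_unique] = False  # A-unique block
        Cov = np.full((4, n), 10)
        Cov[2:, :n_unique] = 0
        m_true = 0.8
        M = (Cov * m_true).astype(int)
        mat = _matrix(M, Cov, present=present)
        cats = np.where(np.arange(n) < n_unique, TG_CA, COMMON_CG)
        cls = pd.DataFrame({"chrom": "chr1", "pos": mat.sites["pos"], "category": cats})
        out = simulate_wrong_reference(mat, cls, "A")
        gm = global_methylation(out)
        f = n_unique / n
        assert gm["b2"] == pytest.approx(m_true * (1 - f), abs=1e-12)
        assert gm["b2"] < gm["a0"]

    def test_variation_filtering_restores_global(self):
        mat, cls = self._setup()
        wrong = simulate_wrong_reference(mat, cls, "A")
        ref_unique = mat.present[0] & ~mat.present[1]
        keys = [
            ("chr1", int(p)) for p, u in zip(mat.sites["pos"], ref_unique) if u
        ]
        filtered = filter_variant_cpgs(wrong, keys)
        correct = restrict_to_shared(mat)
        got = global_methylation(filtered)
        want = global_methylation(correct)
        assert np.allclose(got.to_numpy(), want.to_numpy(), atol=1e-12)


class TestRegionDiffs:
    def _region(self, start=1, end=1000):
        return CandidateRegion("chr1", start, end, 3, 0.2, 10.0, 1)

    def test_identical_counts_zero(self):
        mat = _matrix([[3, 2]] * 4, [[5, 5]] * 4, present=[[True] * 2, [True] * 2])
        assert raw_region_diff(mat, self._region(), "all", _design(mat)) == pytest.approx(0.0)

    def test_single_site_difference(self):
        M = [[9, 0], [9, 0], [4, 0], [4, 0]]
        Cov = [[10, 0], [10, 0], [10, 0], [10, 0]]
        mat = _matrix(M, Cov, present=[[True] * 2, [True] * 2])
        # group props 0.9 vs 0.4 -> diff (group2 - group1) = -0.5
        assert raw_region_diff(mat, self._region(), "all", _design(mat)) == pytest.approx(-0.5)

    def test_matches_bruteforce(self, rng):
        Cov = rng.integers(0, 8, (4, 20))
        M = rng.binomial(Cov, 0.5)
        mat = _matrix(M, Cov, present=[[True] * 20, [True] * 20])
        d = _design(mat)
        got = raw_region_diff(mat, self._region(), "all", d)
        diffs = []
        for j in range(20):
            c1, c2 = Cov[:2, j].sum(), Cov[2:, j].sum()
            if c1 > 0 and c2 > 0:
                diffs.append(M[2:, j].sum() / c2 - M[:2, j].sum() / c1)
        assert got == pytest.approx(np.mean(diffs))

    def test_no_eligible_site_missing(self):
        mat = _matrix([[1, 1]] * 4, [[2, 2]] * 4, present=[[True] * 2, [True] * 2])
        assert np.isnan(raw_region_diff(mat, self._region(2000, 3000), "all", _design(mat)))


class TestDisparity:
    def _matrix_with_unique(self):
        # sites: 0 shared, 1 shared, 2 A-unique, 3 B-unique
        present = [[True, True, True, False], [True, True, False, True]]
        M = np.array(
            [[5, 5, 5, 0], [5, 5, 5, 0], [6, 6, 0, 8], [6, 6, 0, 8]]
        )
        Cov = np.full((4, 4), 10)
        Cov[:2, 3] = 0
        Cov[2:, 2] = 0
        return _matrix(M, Cov, present=present)

    def test_constructed_arithmetic(self):
        mat = self._matrix_with_unique()
        d = _design(mat)
        r = CandidateRegion("chr1", 1, 100, 4, 0.1, 5.0, 1)
        # shared diff = 0.6 - 0.5 = 0.1; unique diff = B@B-unique (0.8)
        # - A@A-unique (0.5) = 0.3; disparity = 0.2
        assert unique_shared_disparity(mat, r, d) == pytest.approx(0.2)

    def test_equal_unique_and_shared_zero(self):
        mat = self._matrix_with_unique()
        mat.M[2:, 3] = 7  # B at B-unique 0.7
        mat.M[:2, 2] = 6  # A at A-unique 0.6
        # shared diff 0.1; unique diff 0.7-0.6 = 0.1
        r = CandidateRegion("chr1", 1, 100, 4, 0.1, 5.0, 1)
        assert unique_shared_disparity(mat, r, _design(mat)) == pytest.approx(0.0)

    def test_antisymmetric_under_group_swap(self):
        mat = self._matrix_with_unique()
        r = CandidateRegion("chr1", 1, 100, 4, 0.1, 5.0, 1)
        d = _design(mat)
        swapped = d.with_groups([3 - g for g in d.groups])
        assert unique_shared_disparity(mat, r, swapped) == pytest.approx(
            -unique_shared_disparity(mat, r, d)
        )

    def test_missing_subset_is_nan(self):
        mat = self._matrix_with_unique()
        r = CandidateRegion("chr1", 1, 15, 2, 0.1, 5.0, 1)  # shared sites only
        assert np.isnan(unique_shared_disparity(mat, r, _design(mat)))
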