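import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transgwas.io_formats import HaplotypePanel
from transgwas.popdiff import (
    HaplotypeFreqTable,
    compare_groups,
    enumerate_haplotypes,
    haplotype_entropy,
    regional_fst,
    rmi,
    snp_fst,
)
from transgwas.synthetic_data import PopulationModel, simulate_panel_pair


def _panel(matrix, positions=None, label="pop"):
    matrix = np.asarray(matrix, dtype=np.uint8)
    if positions is None:
        positions = np.arange(1, matrix.shape[1] + 1) * 10
    return HaplotypePanel(label, positions, [("A", "G")] * matrix.shape[1], matrix)


def _table(rows):
    return HaplotypeFreqTable(("1", 0, 100), ("a", "b"),
                              pd.DataFrame(rows, columns=["haplotype", "f_a", "f_b"]))


class TestSnpFst:
    def test_identical_frequencies_large_n_near_zero(self):
        assert snp_fst(0.5, 0.5, 10**9, 10**9) == pytest.approx(0.0, abs=1e-6)

    def test_extreme_divergence_formula_value(self):
        # (0.8)^2 / (0.1*0.1 + 0.9*0.9) = 0.64/0.82 at infinite sample size
        assert snp_fst(0.1, 0.9, 10**9, 10**9) == pytest.approx(0.64 / 0.82, abs=1e-6)

    def test_matches_brute_force_from_haplotype_counts(self):
        # oracle: Hudson's estimator written directly from allele counts
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_a, n_b = rng.integers(4, 60, 2)
            ca, cb = rng.integers(1, n_a), rng.integers(1, n_b)
            pa, pb = ca / n_a, cb / n_b
            num = (pa - pb) ** 2 - pa * (1 - pa) / (n_a - 1) - pb * (1 - pb) / (n_b - 1)
            den = pa * (1 - pb) + pb * (1 - pa)
            assert snp_fst(pa, pb, n_a, n_b) == pytest.approx(num / den, abs=1e-12)

    def test_weir_cockerham_close_to_hudson_at_equal_sizes(self):
        h = snp_fst(0.2, 0.6, 1000, 1000)
        wc = snp_fst(0.2, 0.6, 1000, 1000, estimator="weir-cockerham")
        assert wc == pytest.approx(h, abs=0.02)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            snp_fst(0.2, 0.4, 1, 10)


class TestRegionalFst:
    def test_identical_panels_near_zero(self):
        rng = np.random.default_rng(1)
        m = (rng.random((10_000, 20)) < 0.3).astype(np.uint8)
        p = _panel(m)
        val, n = regional_fst(p, p, index_pos=100, flank=200)
        assert n == 20
        assert abs(val) < 0.01

    def test_mean_of_two_hand_set_sites(self):
        a = _panel(np.array([[0, 0], [0, 1], [1, 1], [1, 0]] * 25), positions=[100, 200])
        b = _panel(np.array([[1, 0], [1, 1], [1, 0], [0, 0]] * 25), positions=[100, 200])
        fa, fb = a.frequencies(), b.frequencies()
        expect = np.mean([
            snp_fst(fa[i], fb[i], 100, 100) for i in range(2)
        ])
        val, n = regional_fst(a, b, index_pos=150, flank=50)
        assert n == 2 and val == pytest.approx(expect, abs=1e-12)

    def test_zero_flank_restricts_to_index_site(self):
        a = _panel(np.array([[0, 1], [1, 0]] * 10), positions=[100, 200])
        b = _panel(np.array([[0, 0], [1, 1]] * 10), positions=[100, 200])
        _, n = regional_fst(a, b, index_pos=100, flank=0)
        assert n == 1

    def test_no_shared_sites_warns_and_returns_nan(self):
        a = _panel(np.zeros((4, 1)), positions=[100])
        b = _panel(np.ones((4, 1)), positions=[999])
        with pytest.warns(UserWarning, match="no shared"):
            val, n = regional_fst(a, b, index_pos=100, flank=50)
        assert np.isnan(val) and n == 0


class TestEnumerateHaplotypes:
    def test_single_shared_haplotype(self):
        a = _panel(np.tile([0, 1, 0], (10, 1)))
        b = _panel(np.tile([0, 1, 0], (8, 1)))
        t = enumerate_haplotypes(a, b, (1, 100))
        assert len(t.rows) == 1
        assert t.rows.loc[0, "f_a"] == 1.0 and t.rows.loc[0, "f_b"] == 1.0

    def test_fully_private_haplotypes(self):
        a = _panel(np.zeros((10, 2)))
        b = _panel(np.ones((10, 2)))
        t = enumerate_haplotypes(a, b, (1, 100))
        f = t.rows[["f_a", "f_b"]].to_numpy()
        assert sorted(map(tuple, f)) == [(0.0, 1.0), (1.0, 0.0)]

    def test_rare_haplotype_excluded_by_threshold(self):
        a = np.zeros((1000, 2), dtype=np.uint8)
        a[:19] = [1, 1]  # 1.9% in A
        b = np.zeros((100, 2), dtype=np.uint8)
        b[:50] = [0, 1]
        t = enumerate_haplotypes(_panel(a), _panel(b), (1, 100), min_freq=0.02)
        assert "11" not in set(t.rows["haplotype"])

    def test_intersection_rule_drops_private_haplotypes(self):
        a = _panel(np.vstack([np.zeros((5, 1)), np.ones((5, 1))]))
        b = _panel(np.zeros((10, 1)))
        t_union = enumerate_haplotypes(a, b, (1, 100), rule="union")
        t_inter = enumerate_haplotypes(a, b, (1, 100), rule="intersection")
        assert len(t_union.rows) == 2 and len(t_inter.rows) == 1

    def test_disjoint_site_maps_rejected(self):
        a = _panel(np.zeros((4, 1)), positions=[100])
        b = _panel(np.zeros((4, 1)), positions=[500])
        with pytest.raises(ValueError, match="shared"):
            enumerate_haplotypes(a, b, (1, 200))


class TestRmi:
    def test_equal_frequencies_give_zero(self):
        for f in (0.01, 0.3, 1.0):
            assert rmi(f, f) == pytest.approx(0.0, abs=1e-12)

    def test_private_haplotype_gives_one(self):
        assert rmi(0.4, 0.0) == pytest.approx(1.0)
        assert rmi(0.0, 0.4) == pytest.approx(1.0)

    def test_worked_value(self):
        # F = (0.75, 0.25): 1 + (0.75 log2 0.75 + 0.25 log2 0.25)
        assert rmi(0.30, 0.10) == pytest.approx(0.18872, abs=1e-4)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            rmi(0.0, 0.0)

    @settings(deadline=None, max_examples=200)
    @given(f_a=st.floats(0, 1), f_b=st.floats(0, 1))
    def test_bounded_and_symmetric(self, f_a, f_b):
        if f_a + f_b == 0:
            return
        v = rmi(f_a, f_b)
        assert -1e-12 <= v <= 1 + 1e-12
        assert v == pytest.approx(rmi(f_b, f_a), abs=1e-12)


class TestHaplotypeEntropy:
    def test_identical_populations_zero(self):
        t = _table([("00", 0.5, 0.5), ("11", 0.5, 0.5)])
        assert haplotype_entropy(t) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_populations_one(self):
        t = _table([("00", 1.0, 0.0), ("11", 0.0, 1.0)])
        assert haplotype_entropy(t) == pytest.approx(1.0)

    def test_mixed_table_worked_value(self):
        t = _table([("00", 0.4, 0.4), ("01", 0.2, 0.0), ("10", 0.0, 0.2)])
        assert haplotype_entropy(t) == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            haplotype_entropy(_table([]))

    @settings(deadline=None, max_examples=200)
    @given(st.data())
    def test_bounded_scale_invariant_and_combine_equivalent(self, data):
        k = data.draw(st.integers(1, 6))
        fa = data.draw(st.lists(st.floats(0, 1), min_size=k, max_size=k))
        fb = data.draw(st.lists(st.floats(0, 1), min_size=k, max_size=k))
        rows = [(f"h{i}", a, b) for i, (a, b) in enumerate(zip(fa, fb))
                if a + b > 0]
        if not rows:
            return
        t = _table(rows)
        v = haplotype_entropy(t)
        assert -1e-12 <= v <= 1 + 1e-12
        assert haplotype_entropy(t, combine="sum") == pytest.approx(v, abs=1e-12)
        scaled = _table([(h, 3.7 * a, 3.7 * b) for h, a, b in rows])
        assert haplotype_entropy(scaled) == pytest.approx(v, abs=1e-9)

    def test_symmetric_under_population_exchange(self):
        t = _table([("00", 0.4, 0.1), ("01", 0.2, 0.6)])
        swapped = _table([("00", 0.1, 0.4), ("01", 0.6, 0.2)])
        assert haplotype_entropy(t) == pytest.approx(haplotype_entropy(swapped), abs=1e-12)


class TestMonotoneDifferentiation:
    def test_fst_and_entropy_increase_with_divergence(self):
        fst_means, ent_means = [], []
        for F in (0.01, 0.05, 0.15, 0.3):
            fst_vals, ent_vals = [], []
            for seed in range(10):
                rng = np.random.default_rng(seed)
                anc = rng.uniform(0.1, 0.9, 30)
                ma = PopulationModel("a", anc, F, n_haplotypes=400,
                                     n_founders=12, block_length=100_000)
                mb = PopulationModel("b", anc, F, n_haplotypes=400,
                                     n_founders=12, block_length=100_000)
                pa, pb = simulate_panel_pair(ma, mb, (1, 100_000), 30, seed,
                                             shared_founders=True)
                fst_vals.append(regional_fst(pa, pb, 50_000, flank=50_000)[0])
                tab = enumerate_haplotypes(pa, pb, (1, 100_000))
                ent_vals.append(haplotype_entropy(tab))
            fst_means.append(np.mean(fst_vals))
            ent_means.append(np.mean(ent_vals))
        assert all(np.diff(fst_means) > 0)
        assert all(np.diff(ent_means) >= 0)


class TestCompareGroups:
    def test_identical_groups_centre_p(self):
        t, p = compare_groups([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert t == pytest.approx(0.0) and p == pytest.approx(0.5)

    def test_separated_groups_significant(self):
        t, p = compare_groups([0.01, 0.02, 0.015], [0.05, 0.06, 0.055])
        assert p < 0.01

    def test_one_tail_symmetry_under_group_swap(self):
        a, b = [0.01, 0.03, 0.02], [0.05, 0.04, 0.06]
        _, p = compare_groups(a, b)
        _, p_swapped = compare_groups(b, a)
        assert p + p_swapped == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_zero_variance_warns(self):
        with pytest.warns(UserWarning, match="variance"):
            _, p = compare_groups([0.1, 0.1], [0.2, 0.2])
        assert p == 0.0

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([0.1], [0.2, 0.3])
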