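"""Two-locus statistics, windowing, bootstrap nulls, candidate calling."""

import numpy as np
import pandas as pd
import pytest

from hybarrier import scan
from hybarrier.scan import (
    PairCounts,
    bootstrap_aim_position_null,
    bootstrap_fraction_null,
    call_candidates,
    cutoff_grid,
    make_windows,
    pair_counts,
    pair_stat,
    pairwise_stats,
    window_pair_stats,
    all_window_pair_stats,
)

from conftest import matrix_from_array


class TestPairCounts:
    def test_four_distinct_haplotypes(self):
        m = matrix_from_array(np.array([[0, 0], [0, 1], [1, 0], [1, 1]]))
        c = pair_counts(m, 0, 1, min_n=1)
        assert (c.n00, c.n01, c.n10, c.n11) == (1, 1, 1, 1)

    def test_missing_at_either_locus_excluded(self):
        m = matrix_from_array(np.array([[0, 0], [0, -1], [1, 1]]))
        c = pair_counts(m, 0, 1, min_n=1)
        assert c.n_eff == 2

    def test_same_aim_twice_is_a_usage_error(self):
        m = matrix_from_array(np.zeros((3, 2), dtype=int))
        with pytest.raises(ValueError):
            pair_counts(m, 1, 1)

    def test_counts_match_per_individual_tally(self, rng):
        data = rng.integers(-1, 2, size=(40, 6))
        m = matrix_from_array(data)
        for i, j in [(0, 1), (2, 5), (3, 4)]:
            c = pair_counts(m, i, j, min_n=1)
            tally = {"00": 0, "01": 0, "10": 0, "11": 0}
            for row in data:
                if row[i] >= 0 and row[j] >= 0:
                    tally[f"{row[i]}{row[j]}"] += 1
            assert (c.n00, c.n01, c.n10, c.n11) == tuple(tally.values())


class TestPairStat:
    def test_full_symmetry_gives_zero(self):
        st = pair_stat(PairCounts(25, 25, 25, 25))
        assert st.x2 == pytest.approx(0.0)
        assert not st.ordering_ok

    def test_recombinant_deficit_arithmetic(self):
        # g = (0.30, 0.15, 0.30, 0.25): x2 = 0.15*0.30 - 0.30*0.25 = -0.030
        st = pair_stat(PairCounts(30, 15, 30, 25))
        assert st.x2 == pytest.approx(-0.030)

    def test_d_prime_normalization(self):
        # g = (0.4, 0.1, 0.1, 0.4): D = 0.15, Dmax = 0.25 -> D' = 0.6
        st = pair_stat(PairCounts(40, 10, 10, 40))
        assert st.d_prime == pytest.approx(0.6)

    def test_monomorphic_locus_unusable(self):
        st = pair_stat(PairCounts(50, 50, 0, 0))  # locus i fixed for ancestry 0
        assert not st.usable and np.isnan(st.x2)

    def test_chained_ordering_detected_with_direction(self):
        st = pair_stat(PairCounts(30, 2, 40, 28))
        assert st.ordering_ok and st.direction == "01"

    def test_relabel_01_10_leaves_x2_unchanged(self):
        a = pair_stat(PairCounts(30, 5, 40, 25))
        b = pair_stat(PairCounts(30, 40, 5, 25))
        assert a.x2 == pytest.approx(b.x2)

    def test_dprime_bounded_on_random_counts(self, rng):
        for _ in range(200):
            c = PairCounts(*rng.integers(0, 50, 4).tolist())
            st = pair_stat(c)
            if st.usable:
                assert abs(st.d_prime) <= 1.0 + 1e-12


class TestPairwiseStatsVectorization:
    def test_matches_scalar_pair_stat_everywhere(self, rng):
        data = rng.integers(-1, 2, size=(60, 15))
        m = matrix_from_array(data)
        pw = pairwise_stats(m, min_n=10)
        for i in range(15):
            for j in range(i + 1, 15):
                st = pair_stat(pair_counts(m, i, j, min_n=10))
                if st.usable:
                    assert pw.usable[i, j]
                    assert pw.x2[i, j] == pytest.approx(st.x2)
                    assert pw.d_prime[i, j] == pytest.approx(st.d_prime)
                else:
                    assert not pw.usable[i, j]

    def test_label_flip_leaves_x2_unchanged(self, rng):
        data = rng.integers(-1, 2, size=(50, 10))
        m = matrix_from_array(data)
        flipped = matrix_from_array(np.where(data >= 0, 1 - data, data))
        a, b = pairwise_stats(m, 10), pairwise_stats(flipped, 10)
        keep = a.usable & b.usable
        assert np.allclose(a.x2[keep], b.x2[keep])


class TestMakeWindows:
    def _sites(self, n, chrom="chr1"):
        return pd.DataFrame({"chrom": [chrom] * n, "pos": np.arange(n) * 1000})

    def test_47_aims_two_windows_7_dropped(self):
        ws = make_windows(self._sites(47), size=20)
        assert len(ws) == 2
        assert all(w.size == 20 for w in ws)

    def test_exactly_20_aims_single_window_span(self):
        ws = make_windows(self._sites(20), size=20)
        assert len(ws) == 1
        assert (ws[0].start, ws[0].end) == (0, 19_000 + 1)

    def test_windows_never_span_chromosomes(self):
        sites = pd.concat([self._sites(40, "chr1"), self._sites(40, "chr2")],
                          ignore_index=True)
        ws = make_windows(sites, size=20)
        assert len(ws) == 4
        assert [w.chrom for w in ws] == ["chr1", "chr1", "chr2", "chr2"]

    def test_sliding_windows_overlap_and_cover(self):
        ws = make_windows(self._sites(40), size=20, step=5)
        assert len(ws) == 5  # starts 0,5,10,15,20
        assert ws[0].aim_indices[5] == ws[1].aim_indices[0]


class TestWindowPairStats:
    def test_400_cross_comparisons_per_pair(self, rng):
        data = rng.integers(0, 2, size=(100, 40))
        m = matrix_from_array(data)
        ws = make_windows(m.sites, size=20)
        row = window_pair_stats(pairwise_stats(m, 1), ws[0], ws[1])
        assert row["n_comparisons"] == 400

    @staticmethod
    def _balanced_matrix(n_cols: int = 40):
        """Columns = parity codes: every pair of columns is exactly balanced
        over the 128 rows (each two-locus combination appears 32 times), so
        every pairwise x2 is exactly 0."""
        rows = np.arange(128)
        masks = np.arange(1, n_cols + 1)
        bits = ((rows[:, None] & masks[None, :]) != 0).astype(np.int8)
        # parity of the masked bits
        data = np.zeros((128, n_cols), dtype=np.int8)
        for j, mask in enumerate(masks):
            acc = np.zeros(128, dtype=np.int8)
            for b in range(8):
                if mask >> b & 1:
                    acc ^= (rows >> b & 1).astype(np.int8)
            data[:, j] = acc
        return data

    def test_no_signal_means_zero_fraction_and_candidates(self):
        m = matrix_from_array(self._balanced_matrix())
        ws = make_windows(m.sites, size=20)
        row = window_pair_stats(pairwise_stats(m, 1), ws[0], ws[1])
        assert row["frac_below"] == 0.0 and row["n_candidate_aims"] == 0

    def test_single_below_comparison_counts_two_aims(self):
        data = self._balanced_matrix()
        data[:, 20] = data[:, 0]  # perfect coupling only at pair (0, 20)
        m = matrix_from_array(data)
        pw = pairwise_stats(m, 1)
        ws = make_windows(m.sites, size=20)
        row = window_pair_stats(pw, ws[0], ws[1])
        assert row["frac_below"] == pytest.approx(1 / 400)
        assert row["n_candidate_aims"] == 2

    def test_symmetry_in_window_order(self, rng):
        data = rng.integers(-1, 2, size=(80, 40))
        m = matrix_from_array(data)
        pw = pairwise_stats(m)
        ws = make_windows(m.sites, size=20)
        a = window_pair_stats(pw, ws[0], ws[1])
        b = window_pair_stats(pw, ws[1], ws[0])
        assert a["mean_x2"] == pytest.approx(b["mean_x2"])
        assert a["frac_below"] == b["frac_below"]
        assert a["n_candidate_aims"] == b["n_candidate_aims"]

    def test_table_agrees_with_per_pair_calls(self, rng):
        data = rng.integers(-1, 2, size=(60, 60))
        m = matrix_from_array(data)
        pw = pairwise_stats(m)
        ws = make_windows(m.sites, size=20)
        table = all_window_pair_stats(pw, ws)
        for r in table.itertuples(index=False):
            single = window_pair_stats(pw, ws[r.window_i], ws[r.window_j])
            assert r.mean_x2 == pytest.approx(single["mean_x2"])
            assert r.n_candidate_aims == single["n_candidate_aims"]


class TestBootstrapNulls:
    def test_no_values_below_cutoff_gives_zero_percentile(self, rng):
        pool = rng.uniform(-0.004, 0.1, 5000)
        fracs, p99 = bootstrap_fraction_null(pool, reps=200, seed=1)
        assert (fracs == 0).all() and p99 == 0.0

    def test_fraction_null_matches_binomial_oracle(self, rng):
        pool = np.concatenate([np.full(1000, -0.01), np.full(9000, 0.01)])
        fracs, p99 = bootstrap_fraction_null(pool, n_draw=400, reps=1000, seed=2)
        assert np.mean(fracs) == pytest.approx(0.10, abs=3 * np.sqrt(0.09 / 400 / 1000) * 20)
        expected_p99 = 0.10 + 2.33 * np.sqrt(0.1 * 0.9 / 400)
        assert p99 == pytest.approx(expected_p99, abs=0.01)

    def test_fixed_seed_reproducible(self, rng):
        pool = rng.normal(0, 0.01, 2000)
        a = bootstrap_fraction_null(pool, reps=300, seed=9)
        b = bootstrap_fraction_null(pool, reps=300, seed=9)
        assert np.array_equal(a[0], b[0])

    def test_position_null_counts_match_brute_force(self, rng):
        data = rng.integers(0, 2, size=(80, 60))
        m = matrix_from_array(data)
        pw = pairwise_stats(m)
        counts, _ = bootstrap_aim_position_null(pw, reps=50, seed=5)
        # independent brute-force recomputation with the same draws
        rng2 = np.random.default_rng(5)
        for rix in range(50):
            pick = rng2.choice(60, size=40, replace=False)
            n = 0
            for a_ in pick[:20]:
                if any(
                    pw.usable[a_, b_] and pw.x2[a_, b_] < -0.005 for b_ in pick[20:]
                ):
                    n += 1
            for b_ in pick[20:]:
                if any(
                    pw.usable[a_, b_] and pw.x2[a_, b_] < -0.005 for a_ in pick[:20]
                ):
                    n += 1
            assert counts[rix] == n

    def test_too_few_aims_is_an_error(self, rng):
        m = matrix_from_array(rng.integers(0, 2, size=(30, 30)))
        with pytest.raises(ValueError, match="40"):
            bootstrap_aim_position_null(pairwise_stats(m), reps=10, seed=0)


class TestCallCandidates:
    @pytest.fixture
    def toy_scan(self, rng):
        data = rng.integers(0, 2, size=(100, 80))
        # plant coupling between window 0 and window 2 AIMs
        data[:, 40:60] = data[:, 0:20]
        m = matrix_from_array(data)
        pw = pairwise_stats(m)
        ws = make_windows(m.sites, size=20)
        return all_window_pair_stats(pw, ws), ws

    def test_nothing_passes_empty_call_set(self, toy_scan):
        stats, ws = toy_scan
        cs = call_candidates(stats, ws, frac_thresh=2.0, count_thresh=99, cutoff=-0.005)
        assert cs.n_pairs == 0 and cs.regions.is_empty()

    def test_planted_coupling_called_and_merged(self, toy_scan):
        stats, ws = toy_scan
        cs = call_candidates(stats, ws, frac_thresh=0.05, count_thresh=5, cutoff=-0.005)
        assert any(
            (r.window_i, r.window_j) == (0, 2) for r in cs.pairs.itertuples(index=False)
        )
        assert (cs.regions.df["score"] >= 1).all()

    def test_call_sets_nested_across_cutoff_grid(self, toy_scan):
        stats, ws = toy_scan
        sizes = [
            call_candidates(stats, ws, 0.01, 1, c).n_pairs for c in cutoff_grid()
        ]
        assert sizes == sorted(sizes)  # stricter (more negative) calls fewer

    def test_shared_window_counts_twice_in_region_degree(self):
        ws = make_windows(
            pd.DataFrame({"chrom": ["chr1"] * 60, "pos": np.arange(60) * 10}), size=20
        )
        stats = pd.DataFrame(
            {
                "window_i": [0, 0],
                "window_j": [1, 2],
                "n_comparisons": 400,
                "n_usable": 400,
                "mean_x2": [-0.1, -0.1],
                "mean_dprime": [0.5, 0.5],
                "frac_below": [0.9, 0.9],
                "n_candidate_aims": [40, 40],
                "interchromosomal": [False, False],
            }
        )
        cs = call_candidates(stats, ws, 0.5, 10, -0.005)
        # windows are disjoint -> three regions; window 0's region absorbed
        # two membership records (one per candidate pair)
        deg = dict(zip(cs.regions.df["start"], cs.regions.df["score"]))
        assert deg[ws[0].start] == 2


def test_cutoff_grid_matches_published_values():
    grid = cutoff_grid()
    assert len(grid) == 23
    assert grid[0] == pytest.approx(-0.0600)
    assert grid[-1] == pytest.approx(-0.0050)
    assert np.allclose(np.diff(grid), 0.0025)
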