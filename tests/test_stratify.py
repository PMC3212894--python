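from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from stratiforest import enforce_min_area, nonforest_mask, optimal_bin, volume_proxy
from stratiforest.stratify import StratumAssignment, build_strata, stratum_table


def brute_force_bin_sse(values, k):
    """Oracle: enumerate every contiguous partition of the sorted values."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)

    def sse(chunk):
        return float(np.sum((chunk - chunk.mean()) ** 2))

    if k == 1:
        return sse(v)
    best = np.inf
    for cuts in combinations(range(1, n), k - 1):
        edges = (0, *cuts, n)
        total = sum(sse(v[a:b]) for a, b in zip(edges, edges[1:]))
        best = min(best, total)
    return best


class TestVolumeProxy:
    def test_product(self):
        assert volume_proxy(np.array([40.0]), np.array([25.0]))[0] == 1000.0

    def test_absorbing_zero(self, rng):
        h = rng.uniform(5, 30, 10)
        assert (volume_proxy(np.zeros(10), h) == 0.0).all()

    def test_linear_in_height(self, rng):
        ba = rng.uniform(5, 80, 10)
        h = rng.uniform(5, 30, 10)
        np.testing.assert_allclose(volume_proxy(ba, 2 * h), 2 * volume_proxy(ba, h))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            volume_proxy(np.array([-1.0]), np.array([5.0]))


class TestOptimalBin:
    def test_worked_example(self):
        values = np.array([1, 2, 3, 10, 11, 20, 22], dtype=float)
        result = optimal_bin(values, 3)
        assert result.sse == pytest.approx(4.5, abs=1e-12)
        np.testing.assert_array_equal(result.assignment, [0, 0, 0, 1, 1, 2, 2])
        assert result.sse == pytest.approx(brute_force_bin_sse(values, 3), abs=1e-12)

    def test_all_equal_k1(self):
        result = optimal_bin(np.full(10, 7.0), 1)
        assert result.sse == 0.0

    def test_k_equals_n_singletons(self):
        values = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        result = optimal_bin(values, 5)
        assert result.sse == 0.0
        assert len(np.unique(result.assignment)) == 5

    def test_k_exceeds_distinct_values(self):
        with pytest.raises(ValueError, match="distinct"):
            optimal_bin(np.array([1.0, 1.0, 2.0]), 3)

    def test_matches_brute_force_random(self, rng):
        for _ in range(15):
            n = rng.integers(4, 13)
            k = int(rng.integers(1, min(4, n) + 1))
            values = np.round(rng.uniform(0, 50, n), 1)
            if len(np.unique(values)) < k:
                continue
            result = optimal_bin(values, k)
            assert result.sse == pytest.approx(brute_force_bin_sse(values, k), abs=1e-9)

    def test_beats_equal_width_and_equal_frequency(self, rng):
        values = np.sort(rng.lognormal(3, 0.8, 200))
        k = 6
        opt = optimal_bin(values, k).sse

        def partition_sse(assign):
            return sum(
                float(np.sum((values[assign == b] - values[assign == b].mean()) ** 2))
                for b in np.unique(assign)
            )

        width_edges = np.linspace(values.min(), values.max(), k + 1)[1:-1]
        eq_width = np.searchsorted(width_edges, values, side="left")
        eq_freq = np.minimum((np.arange(200) * k) // 200, k - 1)
        assert opt <= partition_sse(eq_width) + 1e-9
        assert opt <= partition_sse(eq_freq) + 1e-9

    def test_ties_with_duplicates(self):
        values = np.array([1.0, 1.0, 1.0, 5.0, 5.0, 9.0])
        result = optimal_bin(values, 3)
        assert result.sse == pytest.approx(0.0, abs=1e-12)


class TestNonforestMask:
    def make_cells(self, closure, height):
        return pd.DataFrame({"crown_closure_pct": [closure], "chm_mean": [height]})

    def test_bare_ground(self):
        assert nonforest_mask(self.make_cells(0.0, 0.0))[0]

    def test_forest(self):
        assert not nonforest_mask(self.make_cells(80.0, 30.0))[0]

    def test_threshold_equality_is_forest(self):
        # strict less-than rule: at the threshold the cell stays forest
        assert not nonforest_mask(self.make_cells(10.0, 2.0), 10.0, 2.0)[0]
        assert not nonforest_mask(self.make_cells(10.0, 0.0), 10.0, 2.0)[0]

    def test_tall_sparse_is_forest(self):
        assert not nonforest_mask(self.make_cells(5.0, 25.0))[0]


def toy_assignment(labels, proxy, cell_area_ha, attrs):
    labels = np.asarray(labels)
    proxy = np.asarray(proxy, dtype=float)
    return StratumAssignment(
        labels=labels,
        proxy=proxy,
        cell_area_ha=cell_area_ha,
        table=stratum_table(labels, proxy, attrs, cell_area_ha),
    )


class TestEnforceMinArea:
    def attrs(self, ba, h, tph, con):
        return pd.DataFrame({"ba": ba, "height": h, "tph": tph, "pct_conifer": con})

    def test_noop_when_all_large(self):
        labels = np.repeat([1, 2], 200)  # 200 cells x 0.04 ha = 8 ha each
        proxy = np.repeat([10.0, 50.0], 200) + np.tile(np.linspace(0, 1, 200), 2)
        attrs = self.attrs(proxy / 10, proxy / 50, proxy, proxy / 2)
        a = toy_assignment(labels, proxy, 0.04, attrs)
        merged = enforce_min_area(a, attrs, min_area_ha=4.05)
        np.testing.assert_array_equal(merged.labels, labels)

    def test_small_stratum_merges_to_nearer_neighbor(self):
        # stratum 2 has 2 cells whose attributes sit on top of stratum 1's
        labels = np.array([1] * 150 + [2] * 2 + [3] * 150)
        proxy = np.array([10.0] * 150 + [30.0] * 2 + [50.0] * 150)
        ba = np.array([10.0] * 150 + [10.5] * 2 + [60.0] * 150)
        attrs = self.attrs(ba, ba / 2, ba * 5, ba)
        a = toy_assignment(labels, proxy, 0.04, attrs)
        merged = enforce_min_area(a, attrs, min_area_ha=4.05)
        # brute-force standardized distance check: both cells nearer stratum 1
        assert merged.n_strata == 2
        # relabeled 1..2; the two moved cells carry proxy 30 into stratum 1
        moved = merged.labels[150:152]
        assert (moved == 1).all()

    def test_areas_respected_on_random_assignments(self, rng):
        for trial in range(50):
            n = 400
            labels = rng.integers(1, 7, n)
            proxy = rng.uniform(0, 100, n) + labels * 10
            attrs = self.attrs(
                rng.uniform(5, 80, n), rng.uniform(5, 35, n), rng.uniform(50, 600, n), rng.uniform(0, 100, n)
            )
            a = toy_assignment(labels, proxy, 0.04, attrs)
            merged = enforce_min_area(a, attrs, min_area_ha=4.05)
            table = merged.table
            forested = table[table["stratum"] > 0]
            assert (forested["area_ha"] >= 4.05 - 1e-9).all()
            assert merged.n_strata <= len(np.unique(labels))

    def test_labels_ordered_by_proxy_mean(self, rng):
        n = 500
        labels = rng.integers(1, 5, n)
        proxy = rng.uniform(0, 100, n)
        attrs = self.attrs(proxy, proxy / 3, proxy * 4, proxy / 2)
        a = toy_assignment(labels, proxy, 0.04, attrs)
        merged = enforce_min_area(a, attrs, min_area_ha=4.05)
        table = merged.table[merged.table["stratum"] > 0].sort_values("stratum")
        assert table["proxy_mean"].is_monotonic_increasing

    def test_total_forest_below_minimum_collapses(self):
        labels = np.array([1, 2, 0, 0])
        proxy = np.array([5.0, 50.0, 0.0, 0.0])
        attrs = self.attrs([5, 50, 0, 0], [5, 20, 0, 0], [100, 300, 0, 0], [50, 60, 0, 0])
        a = toy_assignment(labels, proxy, 0.04, attrs)
        with pytest.warns(UserWarning, match="single stratum"):
            merged = enforce_min_area(a, attrs, min_area_ha=4.05)
        assert set(np.unique(merged.labels)) == {0, 1}


class TestBuildStrata:
    def test_end_to_end_on_landscape(self, small_landscape):
        L = small_landscape
        proxy = volume_proxy(L.truth.ba.ravel(), L.truth.height.ravel())
        attrs = pd.DataFrame(
            {
                "ba": L.truth.ba.ravel(),
                "height": L.truth.height.ravel(),
                "tph": L.truth.tph.ravel(),
                "pct_conifer": L.truth.pct_conifer.ravel(),
            }
        )
        a = build_strata(proxy, 5, attrs, L.grid.cell_area_ha, min_area_ha=4.05)
        assert set(np.unique(a.labels)) <= set(range(6))
        forested = a.table[a.table["stratum"] > 0]
        assert (forested["area_ha"] >= 4.05 - 1e-9).all()
        # stratum means increase with the label
        assert forested.sort_values("stratum")["proxy_mean"].is_monotonic_increasing
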