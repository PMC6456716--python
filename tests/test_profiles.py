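import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from epiwalk.profiles import (
    MethylationProfile,
    RpkmTable,
    SiteRecord,
    filter_sites,
    m_value,
    merge_replicates,
    quantile_normalize,
)

rpkm = st.floats(min_value=0.0, max_value=1e4, allow_nan=False)


class TestMValue:
    def test_examples(self):
        assert m_value(1.9, 0.9) == pytest.approx(1.0)
        assert m_value(0.0, 0.9) == pytest.approx(np.log2(0.1 / 1.0))
        assert m_value(7.3, 7.3) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            m_value(-1.0, 2.0)
        with pytest.raises(ValueError):
            m_value(1.0, -0.1)

    @given(ip=rpkm, inp=rpkm, delta=st.floats(min_value=1e-3, max_value=100))
    @settings(max_examples=200, deadline=None)
    def test_monotone(self, ip, inp, delta):
        """Strictly increasing in IP, strictly decreasing in input."""
        assert m_value(ip + delta, inp) > m_value(ip, inp)
        assert m_value(ip, inp + delta) < m_value(ip, inp)

    @given(ip=rpkm, inp=rpkm)
    @settings(max_examples=100, deadline=None)
    def test_always_finite(self, ip, inp):
        assert np.isfinite(m_value(ip, inp))


class TestMergeReplicates:
    def make(self, cols, groups):
        return RpkmTable(pd.DataFrame(cols, index=["r1", "r2"]), groups)

    def test_mean_of_replicates(self):
        t = self.make(
            {"c1_a": [4.0, 0.0], "c1_b": [6.0, 0.0], "c2": [1.0, 3.0]},
            {"c1_a": "c1", "c1_b": "c1", "c2": "c2"},
        )
        merged = merge_replicates(t)
        assert list(merged.values.columns) == ["c1", "c2"]
        assert merged.values.loc["r1", "c1"] == pytest.approx(5.0)

    def test_single_replicate_identity(self):
        t = self.make({"c1": [2.0, 3.0]}, {"c1": "c1"})
        merged = merge_replicates(t)
        pd.testing.assert_frame_equal(merged.values, t.values)

    def test_three_replicates(self):
        t = self.make(
            {"x1": [0.0, 1.0], "x2": [0.0, 1.0], "x3": [3.0, 1.0]},
            {"x1": "x", "x2": "x", "x3": "x"},
        )
        assert merge_replicates(t).values.loc["r1", "x"] == pytest.approx(1.0)

    def test_merge_commutes_with_m_value(self):
        """M-value of merged RPKMs equals the pipeline's merged M-value."""
        ip = self.make({"x1": [4.0, 1.0], "x2": [6.0, 2.0]}, {"x1": "x", "x2": "x"})
        inp = self.make({"x1": [2.0, 5.0], "x2": [2.0, 7.0]}, {"x1": "x", "x2": "x"})
        got = m_value(
            merge_replicates(ip).values.to_numpy(),
            merge_replicates(inp).values.to_numpy(),
        )
        expected = m_value(np.array([[5.0], [1.5]]), np.array([[2.0], [6.0]]))
        np.testing.assert_allclose(got, expected)


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        mat = np.array([[3.0, 3.0], [1.0, 1.0], [2.0, 2.0]])
        np.testing.assert_allclose(quantile_normalize(mat), mat)

    def test_two_column_reference(self):
        mat = np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]])
        out = quantile_normalize(mat)
        np.testing.assert_allclose(out[:, 0], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out[:, 1], [2.5, 3.5, 4.5])

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(0)
        mat = rng.random((30, 5))
        out = quantile_normalize(mat)
        for j in range(5):
            assert (np.argsort(out[:, j]) == np.argsort(mat[:, j])).all()

    def test_column_multisets_identical(self):
        rng = np.random.default_rng(1)
        mat = rng.random((50, 4))
        out = quantile_normalize(mat)
        ref = np.sort(out[:, 0])
        for j in range(1, 4):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)
        assert np.ptp(out.mean(axis=0)) < 1e-12

    def test_tie_rule_mean_of_tied_reference(self):
        # column 0 has a 3-way tie occupying ranks 1-3
        mat = np.array([[1.0, 10.0], [1.0, 20.0], [1.0, 30.0], [5.0, 40.0]])
        out = quantile_normalize(mat)
        ref = np.sort(mat, axis=0).mean(axis=1)
        expected_tied = ref[:3].mean()
        np.testing.assert_allclose(out[:3, 0], expected_tied)
        np.testing.assert_allclose(out[3, 0], ref[3])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(np.empty((0, 2)))


def toy_profile():
    """10-site toy table with hand-checkable filter behaviour."""
    supports = [5, 10, 11, 12, 15, 20, 25, 30, 40, 50]
    m = np.array(
        [
            [0.0, 0.0, 0.0, 0.0],
            [5.0, 5.0, 5.0, 5.0],
            [0.1, 0.2, 0.3, 0.4],
            [2.0, 2.0, 2.1, 2.1],
            [9.0, 9.5, 9.0, 9.5],
            [-1.0, 1.0, -1.0, 1.0],
            [0.5, 0.5, 0.5, 0.5],
            [3.0, -3.0, 3.0, -3.0],
            [8.0, 8.0, 8.0, 8.0],
            [-0.5, -0.4, -0.3, -0.2],
        ]
    )
    sites = [
        SiteRecord(f"s{i}", "chr1", 100 * i, 100 * i + 101, "+", f"g{i}", supports[i])
        for i in range(10)
    ]
    return MethylationProfile(sites, ["c1", "c2", "c3", "c4"], m)


class TestFilterSites:
    def test_toy_survivors(self):
        """Frozen expectation from brute-force percentile arithmetic:
        support >10 drops s0, s1; the 70th-percentile mean cut (1.895)
        drops s3, s4, s8; the variance cut (>= 0.01) drops s6."""
        out = filter_sites(toy_profile())
        assert out.site_ids == ["s2", "s5", "s7", "s9"]

    def test_support_strictly_greater(self):
        out, diag = filter_sites(toy_profile(), return_diagnostics=True)
        assert diag.n_after_support == 8  # s0 (5) and s1 (exactly 10) removed

    def test_subset_of_input(self):
        prof = toy_profile()
        out = filter_sites(prof)
        assert set(out.site_ids) <= set(prof.site_ids)

    def test_identical_profiles_kept_by_variance_tie(self):
        """All-equal variances tie at the threshold and are all retained."""
        m = np.tile([0.0, 1.0, 2.0, 3.0], (5, 1))
        sites = [
            SiteRecord(f"s{i}", "chr1", 0, 101, "+", "g", 20) for i in range(5)
        ]
        prof = MethylationProfile(sites, ["a", "b", "c", "d"], m)
        out = filter_sites(prof, level_pct=100.0)
        assert len(out.sites) == 5

    def test_all_filtered_raises_with_counts(self):
        prof = toy_profile()
        with pytest.raises(ValueError, match="after support=0"):
            filter_sites(prof, min_support=100)

    def test_level_rule_flip(self):
        keep_low = filter_sites(toy_profile(), level_rule="le_pct", var_pct=100.0)
        keep_high = filter_sites(toy_profile(), level_rule="ge_pct", var_pct=100.0)
        assert max(s.site_id for s in keep_high.sites) in ("s8", "s4")
        assert set(keep_low.site_ids) != set(keep_high.site_ids)
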