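"""Slide feature equations checked against a naive loop-based reference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from her2mil.mil_features import (
    HISTOGRAM_EDGES,
    FeatureConfig,
    compute_features,
    features_table,
    frequency_Fh,
    indicator_G,
    positivity_P1,
    positivity_P2,
    positivity_P3,
)


# ---------------------------------------------------------------------------
# Independent reference: plain Python loops, no vectorization shared with
# the implementation.


def ref_G(p):
    return 1 if p >= 0.5 else 0


def ref_P1(p):
    star = sum(p) / len(p)
    return star, (1 if star >= 0.5 else 0)


def ref_P2(p):
    masked = sum(x * ref_G(x) for x in p) / len(p)
    return 1 if masked >= 0.66 else 0


def ref_P3(p):
    frac = sum(ref_G(x) for x in p) / len(p)
    return 1 if frac >= 0.35 else 0


def ref_Fh(p, h):
    if h == 0.9:
        count = sum(1 for x in p if 0.9 <= x <= 1.0)
    else:
        count = sum(1 for x in p if h <= x < h + 0.1)
    return count / len(p)


# ---------------------------------------------------------------------------


class TestIndicatorG:
    @pytest.mark.parametrize("p,expected", [(0.5, 1), (0.4999, 0), (1.0, 1), (0.0, 0)])
    def test_boundary_is_geq(self, p, expected):
        assert indicator_G(p) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            indicator_G(1.5)


class TestPositivityIndices:
    def test_P1_direct_arithmetic(self):
        assert positivity_P1([0.9, 0.7, 0.2]) == (pytest.approx(0.6), 1)

    def test_P1_single_tile_boundary(self):
        assert positivity_P1([0.5]) == (0.5, 1)

    def test_P1_all_zero(self):
        assert positivity_P1([0.0, 0.0, 0.0]) == (0.0, 0)

    def test_P2_masked_mean_over_all_tiles(self):
        # 2/3 ~ 0.667 clears 0.66; sub-threshold tiles stay in the denominator
        assert positivity_P2([1.0, 1.0, 0.0]) == 1
        assert positivity_P2([0.9, 0.9, 0.1, 0.1]) == 0

    def test_P2_mask_annihilates_below_half(self):
        assert positivity_P2([0.49, 0.3, 0.1]) == 0

    def test_P2_prose_variant_divides_by_positive_count(self):
        cfg = FeatureConfig(p2_over_positive_tiles=True)
        # conditional mean of {0.9, 0.9} = 0.9 >= 0.66, though masked mean is 0.45
        assert positivity_P2([0.9, 0.9, 0.1, 0.1], cfg) == 1
        assert positivity_P2([0.1, 0.2], cfg) == 0  # no super-threshold tiles

    def test_P3_counting(self):
        assert positivity_P3([0.6, 0.6, 0.4]) == 1
        assert positivity_P3([0.6, 0.1, 0.1, 0.1]) == 0

    def test_P3_boundary_exact_35_percent(self):
        p = [0.6] * 7 + [0.1] * 13  # 7/20 = 0.35 exactly
        assert positivity_P3(p) == 1

    def test_empty_vector_rejected(self):
        for fn in (positivity_P1, positivity_P2, positivity_P3):
            with pytest.raises(ValueError, match="empty"):
                fn([])


class TestFrequencyFh:
    def test_direct_counting(self):
        assert frequency_Fh([0.55, 0.95, 0.30], 0.5) == pytest.approx(1 / 3)

    def test_half_open_upper_edge(self):
        assert frequency_Fh([0.60], 0.5) == 0.0

    def test_top_bin_closed_at_one(self):
        assert frequency_Fh([1.0], 0.9) == 1.0

    def test_top_bin_half_open_variant(self):
        cfg = FeatureConfig(top_bin_closed=False)
        assert frequency_Fh([1.0], 0.9, cfg) == 0.0

    def test_invalid_h_rejected(self):
        with pytest.raises(ValueError):
            frequency_Fh([0.5], 0.55)


class TestComputeFeatures:
    def test_saturated_positive(self):
        f = compute_features("s", [1.0, 1.0, 1.0])
        assert (f.P1, f.P2, f.P3) == (1, 1, 1)
        assert f.F[0.9] == 1.0
        assert all(f.F[h] == 0.0 for h in HISTOGRAM_EDGES[:-1])

    def test_saturated_negative(self):
        f = compute_features("s", [0.0, 0.0, 0.0])
        assert (f.P1, f.P2, f.P3) == (0, 0, 0)
        assert all(v == 0.0 for v in f.F.values())

    def test_oracle_equivalence_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p = rng.uniform(0, 1, rng.integers(1, 51)).tolist()
            f = compute_features("s", p)
            star, p1 = ref_P1(p)
            assert f.P1_star == pytest.approx(star, abs=1e-12)
            assert f.P1 == p1
            assert f.P2 == ref_P2(p)
            assert f.P3 == ref_P3(p)
            for h in HISTOGRAM_EDGES:
                assert f.F[h] == ref_Fh(p, h)

    def test_table_has_one_row_per_slide(self):
        df = features_table([("a", [0.1, 0.9]), ("b", [0.7])])
        assert list(df["slide_id"]) == ["a", "b"]
        assert list(df["T"]) == [2, 1]


class TestProperties:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30),
        seed=st.integers(0, 10_000),
    )
    def test_permutation_invariance(self, p, seed):
        rng = np.random.default_rng(seed)
        q = list(rng.permutation(p))
        fa, fb = compute_features("s", p), compute_features("s", q)
        assert fa.P1_star == pytest.approx(fb.P1_star)
        assert (fa.P1, fa.P2, fa.P3) == (fb.P1, fb.P2, fb.P3)
        assert fa.F == fb.F

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_duplication_invariance(self, p):
        fa, fb = compute_features("s", p), compute_features("s", p + p)
        assert fa.P1_star == pytest.approx(fb.P1_star)
        assert (fa.P1, fa.P2, fa.P3) == (fb.P1, fb.P2, fb.P3)
        for h in HISTOGRAM_EDGES:
            assert fa.F[h] == pytest.approx(fb.F[h])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20),
        idx=st.integers(0, 1_000_000),
        bump=st.floats(0, 1, allow_nan=False),
    )
    def test_raising_one_probability_is_monotone(self, p, idx, bump):
        i = idx % len(p)
        q = list(p)
        q[i] = min(1.0, q[i] + bump)
        fa, fb = compute_features("s", p), compute_features("s", q)
        assert fb.P1_star >= fa.P1_star - 1e-12
        for a, b in ((fa.P1, fb.P1), (fa.P2, fb.P2), (fa.P3, fb.P3)):
            assert not (a == 1 and b == 0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_histogram_mass_equals_positive_fraction(self, p):
        f = compute_features("s", p)
        positive_fraction = sum(1 for x in p if x >= 0.5) / len(p)
        assert sum(f.F.values()) == pytest.approx(positive_fraction)
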