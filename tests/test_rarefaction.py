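import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from floraltse.rarefaction import (
    RarefactionCurve,
    RarefactionLibrary,
    assess_saturation,
    default_grid,
    expected_richness_analytic,
    merge_libraries,
    rarefaction_curve_analytic,
    rarefaction_curve_mc,
)


def enumerate_expected_richness(lib, n):
    """Exhaustive oracle: average distinct-gene count over all C(N, n)
    without-replacement subsamples of the read multiset."""
    reads = [g for g, k in lib.support.items() for _ in range(k)]
    subsets = list(itertools.combinations(range(len(reads)), n))
    total = sum(len({reads[i] for i in idx}) for idx in subsets)
    return total / len(subsets)


class TestAnalytic:
    def test_two_genes_two_reads_each(self):
        lib = RarefactionLibrary({"A": 2, "B": 2})
        # enumeration over the C(4,2)=6 subsamples gives 10/6 = 5/3
        assert expected_richness_analytic(lib, 2) == pytest.approx(5 / 3, abs=1e-12)

    def test_skewed_support(self):
        lib = RarefactionLibrary({"A": 3, "B": 1})
        assert expected_richness_analytic(lib, 2) == pytest.approx(1.5, abs=1e-12)

    def test_boundary_values(self):
        lib = RarefactionLibrary({"A": 5, "B": 2, "C": 1})
        assert expected_richness_analytic(lib, lib.N) == pytest.approx(lib.S)
        assert expected_richness_analytic(lib, 1) == pytest.approx(1.0)
        assert expected_richness_analytic(lib, 0) == 0.0

    def test_subsample_larger_than_library_is_error(self):
        with pytest.raises(ValueError):
            expected_richness_analytic(RarefactionLibrary({"A": 2}), 3)

    def test_matches_enumeration_on_small_libraries(self, rng):
        for _ in range(25):
            s = int(rng.integers(1, 5))
            support = {f"g{i}": int(rng.integers(1, 4)) for i in range(s)}
            lib = RarefactionLibrary(support)
            if lib.N > 10:
                continue
            for n in range(lib.N + 1):
                assert expected_richness_analytic(lib, n) == pytest.approx(
                    enumerate_expected_richness(lib, n), abs=1e-9
                )

    def test_numerically_stable_at_large_depth(self):
        # about a million reads with per-gene support up to 10^4; naive
        # binomial coefficients overflow here, the log-gamma path must not
        rng = np.random.default_rng(7)
        supports = rng.integers(1, 10**4, size=200)
        supports[0] = 10**4
        lib = RarefactionLibrary({f"g{i}": int(s) for i, s in enumerate(supports)})
        value = expected_richness_analytic(lib, lib.N // 2)
        assert math.isfinite(value) and 0 < value <= lib.S


class TestMonteCarlo:
    def test_full_depth_has_zero_sd(self):
        lib = RarefactionLibrary({"A": 3, "B": 2})
        curve = rarefaction_curve_mc(lib, [lib.N], reps=50, seed=1)
        assert curve.expected_richness[0] == pytest.approx(lib.S)
        assert curve.mc_sd[0] == 0.0

    def test_mean_tracks_analytic(self):
        rng = np.random.default_rng(11)
        support = {f"g{i}": int(k) for i, k in enumerate(rng.integers(1, 60, size=150))}
        lib = RarefactionLibrary(support)
        grid = default_grid(lib.N, 12)
        curve = rarefaction_curve_mc(lib, grid, reps=400, seed=5)
        for n, mean, sd in zip(curve.grid, curve.expected_richness, curve.mc_sd):
            exact = expected_richness_analytic(lib, int(n))
            tol = 3 * sd / math.sqrt(400) + 1e-9
            assert abs(mean - exact) <= tol

    def test_seeded_reproducibility(self):
        lib = RarefactionLibrary({f"g{i}": i + 1 for i in range(20)})
        a = rarefaction_curve_mc(lib, default_grid(lib.N, 8), reps=30, seed=42)
        b = rarefaction_curve_mc(lib, default_grid(lib.N, 8), reps=30, seed=42)
        np.testing.assert_array_equal(a.expected_richness, b.expected_richness)
        np.testing.assert_array_equal(a.mc_sd, b.mc_sd)

    def test_grid_point_beyond_library_is_error(self):
        lib = RarefactionLibrary({"A": 2})
        with pytest.raises(ValueError):
            rarefaction_curve_mc(lib, [3], reps=5, seed=0)


class TestMerge:
    def test_merge_with_singleton_identity_like(self):
        a = RarefactionLibrary({"x": 4, "y": 1})
        b = RarefactionLibrary({"z": 1})
        merged = merge_libraries(a, b)
        assert merged.support == {"x": 4, "y": 1, "z": 1}

    def test_disjoint_gene_sets_add_richness(self):
        a = RarefactionLibrary({"a1": 2, "a2": 3})
        b = RarefactionLibrary({"b1": 1, "b2": 1})
        merged = merge_libraries(a, b)
        assert merged.S == a.S + b.S and merged.N == a.N + b.N

    def test_merged_library_reaches_at_least_each_inputs_richness(self, rng):
        # pooling can only add genes: at full depth the merged curve ends at
        # or above either input's endpoint.  (At a fixed shared depth n the
        # merged expectation may legitimately dip below the richer input's —
        # mixing dilutes per-read discovery — so no pointwise dominance.)
        support_a = {f"g{i}": int(k) for i, k in enumerate(rng.integers(1, 9, size=30))}
        support_b = {f"g{i}": int(k) for i, k in enumerate(rng.integers(1, 9, size=45))}
        a, b = RarefactionLibrary(support_a), RarefactionLibrary(support_b)
        merged = merge_libraries(a, b)
        e_merged = expected_richness_analytic(merged, merged.N)
        assert e_merged >= expected_richness_analytic(a, a.N) - 1e-9
        assert e_merged >= expected_richness_analytic(b, b.N) - 1e-9
        assert merged.S >= max(a.S, b.S)


class TestSaturation:
    def test_all_singletons_never_saturated(self):
        lib = RarefactionLibrary({f"g{i}": 1 for i in range(200)})
        curve = rarefaction_curve_analytic(lib)
        call = assess_saturation(curve, theta=1e-3)
        assert call.tail_slope == pytest.approx(1.0)
        assert not call.is_saturated

    def test_deep_even_coverage_saturated(self):
        lib = RarefactionLibrary({f"g{i}": 1000 for i in range(10)})
        call = assess_saturation(rarefaction_curve_analytic(lib), theta=1e-3)
        assert call.is_saturated
        assert call.tail_slope == pytest.approx(0.0, abs=1e-6)

    def test_infinite_threshold_always_saturated(self):
        lib = RarefactionLibrary({f"g{i}": 1 for i in range(50)})
        call = assess_saturation(rarefaction_curve_analytic(lib), theta=math.inf)
        assert call.is_saturated

    def test_degenerate_grid_is_error(self):
        curve = RarefactionCurve(grid=np.array([5]), expected_richness=np.array([3.0]))
        with pytest.raises(ValueError):
            assess_saturation(curve)


@given(
    st.lists(st.integers(1, 12), min_size=1, max_size=12),
)
@settings(max_examples=60)
def test_curves_nondecreasing_and_concave(supports):
    lib = RarefactionLibrary({f"g{i}": s for i, s in enumerate(supports)})
    values = [expected_richness_analytic(lib, n) for n in range(lib.N + 1)]
    diffs = np.diff(values)
    assert np.all(diffs >= -1e-9)  # nondecreasing
    assert np.all(np.diff(diffs) <= 1e-9)  # concave
    assert values[-1] == pytest.approx(lib.S)
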