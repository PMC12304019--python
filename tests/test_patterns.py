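"""Pattern-encoding unit and property tests."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegentropy.patterns import (
    CapacityError,
    PatternConfig,
    UnsupportedConfigurationError,
    difference_code,
    encode,
    encode_difference_iterative,
    encode_difference_plain,
    encode_ordinal_overlap,
    encode_ordinal_plain,
    lehmer_code,
    right_inversion_counts,
    tuple_count,
    window_has_tie,
)

from conftest import brute_window_has_tie


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"m": 1},
            {"m": 3, "tau": 0},
            {"m": 3, "kind": "nope"},
            {"m": 3, "tie_policy": "nope"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PatternConfig(**kwargs)

    def test_capacity_caps(self):
        with pytest.raises(CapacityError):
            PatternConfig(m=21, kind="ordinal")
        with pytest.raises(CapacityError):
            PatternConfig(m=65, kind="difference")
        assert PatternConfig(m=20, kind="ordinal").alphabet_size == math.factorial(20)
        assert PatternConfig(m=64, kind="difference").alphabet_size == 2**63


class TestScalarCodecs:
    @pytest.mark.parametrize(
        "tup, expected",
        [
            ((1, 2, 3), (0, 0, 0)),
            ((3, 2, 1), (2, 1, 0)),
            ((2, 4, 1), (1, 1, 0)),
        ],
    )
    def test_right_inversion_counts(self, tup, expected):
        assert tuple(right_inversion_counts(tup)) == expected

    def test_short_tuple_rejected(self):
        with pytest.raises(ValueError):
            right_inversion_counts([1.0])
        with pytest.raises(ValueError):
            difference_code([1.0])

    @pytest.mark.parametrize(
        "tup, code", [((1, 2, 3), 0), ((3, 2, 1), 5), ((2, 4, 1), 3)]
    )
    def test_lehmer_examples(self, tup, code):
        assert lehmer_code(tup) == code

    @pytest.mark.parametrize(
        "tup, code", [((1, 2, 3, 4), 1), ((4, 3, 2, 1), 8), ((1, 2, 4, 1), 2)]
    )
    def test_difference_examples(self, tup, code):
        """Printed worked examples: [+,+,+] -> 1, [-,-,-] -> 8, and the
        tuple [1,2,4,1] with signs [+,+,-] -> 2."""
        assert difference_code(tup) == code

    @pytest.mark.parametrize("m", [2, 3, 4, 5, 6])
    def test_lehmer_bijective_over_permutations(self, m):
        codes = {lehmer_code(perm) for perm in itertools.permutations(range(m))}
        assert codes == set(range(math.factorial(m)))

    @pytest.mark.parametrize("m", [2, 3, 5, 8, 10])
    def test_difference_bijective_and_lexicographic(self, m):
        # realize each sign string by a walk: "-" steps down, "+" steps up
        codes = []
        for signs in itertools.product([False, True], repeat=m - 1):
            values = [0.0]
            for down in signs:
                values.append(values[-1] + (-1.0 if down else 1.0))
            codes.append(difference_code(values))
        # lexicographic order of sign strings ('-' = 1) is code order
        assert codes == list(range(1, 2 ** (m - 1) + 1))


class TestEncoders:
    def test_ordinal_plain_worked_example(self):
        ps = encode_ordinal_plain([1, 2, 4, 1], PatternConfig(3))
        assert ps.codes.tolist() == [0, 3]
        assert ps.k == 2
        assert ps.alphabet_size == 6

    def test_tuple_count(self):
        ps = encode_ordinal_plain(np.arange(10.0) ** 2 % 7, PatternConfig(3))
        assert ps.k == tuple_count(10, 3) == 8

    def test_increasing_signal_all_zero(self):
        for m in (2, 4, 6):
            ps = encode_ordinal_overlap(np.arange(50.0), PatternConfig(m))
            assert np.all(ps.codes == 0)

    def test_difference_plain_worked_example(self):
        ps = encode_difference_plain([1, 2, 4, 1], PatternConfig(4, kind="difference"))
        assert ps.external_codes.tolist() == [2]
        assert ps.codes.tolist() == [1]  # 0-based internally
        assert ps.k == 1

    def test_decreasing_signal_all_descending_code(self):
        ps = encode_difference_iterative(
            np.arange(20.0)[::-1], PatternConfig(4, kind="difference")
        )
        assert np.all(ps.external_codes == 8)

    def test_alternating_signal(self):
        ps = encode_difference_plain(
            [0, 1, 0, 1, 0], PatternConfig(3, kind="difference")
        )
        assert ps.external_codes.tolist() == [2, 3, 2]
        it = encode_difference_iterative(
            [0, 1, 0, 1, 0], PatternConfig(3, kind="difference")
        )
        assert np.array_equal(ps.codes, it.codes)

    def test_signal_too_short(self):
        with pytest.raises(ValueError):
            encode_ordinal_plain([1.0, 2.0], PatternConfig(4))
        with pytest.raises(ValueError):
            encode_difference_plain([1.0], PatternConfig(2, kind="difference"))

    def test_kind_mismatch_rejected(self):
        with pytest.raises(ValueError):
            encode_ordinal_plain([1, 2, 3], PatternConfig(2, kind="difference"))
        with pytest.raises(ValueError):
            encode_difference_plain([1, 2, 3], PatternConfig(2, kind="ordinal"))

    def test_incremental_requires_tau_1(self):
        cfg = PatternConfig(3, tau=2)
        with pytest.raises(UnsupportedConfigurationError):
            encode_ordinal_overlap(np.arange(10.0), cfg)
        with pytest.raises(UnsupportedConfigurationError):
            encode_difference_iterative(
                np.arange(10.0), PatternConfig(3, tau=2, kind="difference")
            )

    def test_auto_dispatch(self):
        x = np.random.default_rng(0).random(40)
        assert encode(x, PatternConfig(3)).algorithm == "overlap"
        assert encode(x, PatternConfig(3, kind="difference")).algorithm == "iterative"
        assert encode(x, PatternConfig(3, tau=2)).algorithm == "plain"
        with pytest.raises(ValueError):
            encode(x, PatternConfig(3), algorithm="lookup")

    def test_tau_2_plain_against_brute_force(self, rng):
        x = rng.random(30)
        cfg = PatternConfig(3, tau=2)
        ps = encode_ordinal_plain(x, cfg)
        assert ps.k == 30 - 2 * 2
        expected = [lehmer_code([x[t], x[t + 2], x[t + 4]]) for t in range(ps.k)]
        assert ps.codes.tolist() == expected

    @pytest.mark.parametrize("m", range(2, 10))
    def test_plain_overlap_equivalence(self, m, rng):
        for _ in range(20):
            x = rng.random(120)
            a = encode_ordinal_plain(x, PatternConfig(m))
            b = encode_ordinal_overlap(x, PatternConfig(m))
            assert np.array_equal(a.codes, b.codes)

    @pytest.mark.parametrize("m", range(2, 13))
    def test_plain_iterative_equivalence(self, m, rng):
        for _ in range(20):
            x = rng.random(120)
            a = encode_difference_plain(x, PatternConfig(m, kind="difference"))
            b = encode_difference_iterative(x, PatternConfig(m, kind="difference"))
            assert np.array_equal(a.codes, b.codes)


class TestComparisonCounts:
    """Exact operation counts mirror the O(N m^2) / O(N m) / O(N)
    complexity claims without wall-clock dependence."""

    @pytest.mark.parametrize("n, m", [(100, 5), (1000, 3), (53, 9)])
    def test_counts_match_formulas(self, n, m, rng):
        x = rng.random(n)
        k = tuple_count(n, m)
        pc_o = PatternConfig(m)
        pc_d = PatternConfig(m, kind="difference")
        assert encode_ordinal_plain(x, pc_o).comparison_count == k * m * (m - 1) // 2
        assert (
            encode_ordinal_overlap(x, pc_o).comparison_count
            == m * (m - 1) // 2 + (k - 1) * (m - 1)
        )
        assert encode_difference_plain(x, pc_d).comparison_count == k * (m - 1)
        assert encode_difference_iterative(x, pc_d).comparison_count == (m - 1) + (
            k - 1
        )

    def test_scaling_orders(self, rng):
        """Quadratic in m (ordinal plain), linear (overlap, difference
        plain), constant (difference iterative) at fixed k."""
        n = 600
        counts = {algo: [] for algo in ("op", "oo", "dp", "di")}
        for m in (4, 8):
            k = tuple_count(n, m)
            x = rng.random(n)
            counts["op"].append(
                encode_ordinal_plain(x, PatternConfig(m)).comparison_count / k
            )
            counts["oo"].append(
                encode_ordinal_overlap(x, PatternConfig(m)).comparison_count / k
            )
            counts["dp"].append(
                encode_difference_plain(
                    x, PatternConfig(m, kind="difference")
                ).comparison_count
                / k
            )            # iterative: absolute count fixed by n alone
            counts["di"].append(
                encode_difference_iterative(
                    x, PatternConfig(m, kind="difference")
                ).comparison_count
            )
        # per-tuple cost ratios when m doubles 4 -> 8
        assert counts["op"][1] / counts["op"][0] == pytest.approx(28 / 6)  # ~m^2
        assert counts["oo"][1] / counts["oo"][0] == pytest.approx(7 / 3, rel=0.02)
        assert counts["dp"][1] / counts["dp"][0] == pytest.approx(7 / 3)
        assert counts["di"][0] == counts["di"][1] == n - 1


class TestTies:
    @pytest.mark.parametrize(
        "window, m, expected",
        [
            ((1, 2, 3, 4), 3, False),
            ((1, 2, 2, 4), 3, True),
            ((1, 2, 3, 1), 3, False),
            ((1, 2, 3, 1), 4, True),
        ],
    )
    def test_window_has_tie_examples(self, window, m, expected):
        assert window_has_tie(window, PatternConfig(m)) is expected

    def test_tie_scope_is_per_tuple_with_stride(self):
        # duplicates at positions 0 and 2 share a tuple only at tau=2 m>=2,
        # or tau=1 m>=3
        window = [1.0, 5.0, 1.0, 7.0, 9.0]
        assert not window_has_tie(window, PatternConfig(2, tau=1))
        assert window_has_tie(window, PatternConfig(3, tau=1))
        assert window_has_tie(window, PatternConfig(2, tau=2))

    def test_against_brute_force(self, rng):
        for _ in range(200):
            window = rng.integers(0, 8, size=10).astype(float)
            for m, tau in ((2, 1), (3, 1), (4, 2), (2, 3)):
                assert window_has_tie(window, PatternConfig(m, tau=tau)) == \
                    brute_window_has_tie(window, m, tau)

    def test_tie_treated_as_ascending(self):
        # x_i = x_j behaves as x_i < x_j: (2, 2) is the ascending pattern
        assert lehmer_code([2.0, 2.0]) == 0
        assert difference_code([2.0, 2.0]) == 1


class TestAlgebraicProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=8, max_size=40, unique=True
        ),
        st.integers(2, 6),
    )
    def test_reversal_symmetry_difference(self, values, m):
        """Negating the signal complements every sign string:
        c -> 2^(m-1) + 1 - c in the 1-based convention."""
        x = np.asarray(values)
        cfg = PatternConfig(m, kind="difference")
        fwd = encode_difference_plain(x, cfg).external_codes
        neg = encode_difference_plain(-x, cfg).external_codes
        assert np.array_equal(neg, 2 ** (m - 1) + 1 - fwd)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=4, max_size=40, unique=True
        )
    )
    def test_m2_ordinal_difference_correspondence(self, values):
        """At m = 2 both alphabets are the binary up/down sequence."""
        x = np.asarray(values)
        ordinal = encode_ordinal_plain(x, PatternConfig(2)).codes
        diff = encode_difference_plain(x, PatternConfig(2, kind="difference")).codes
        assert np.array_equal(ordinal, diff)
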