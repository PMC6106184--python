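"""Patch extraction, the K statistic, and its randomization null."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reefpatch import (
    PresenceSequence,
    clean_sequence,
    exact_null,
    extract_patches,
    k_statistic,
    mean_patch_size,
    parse_sequence,
    randomized_null,
    summarize_tow,
)
from reefpatch.patchiness import tow_seed

M = None  # missing observation


def brute_force_null(binary):
    """Independent enumeration over raw permutations (not position subsets).

    Averages the mean patch size over the set of *distinct* arrangements of
    the multiset, obtained by deduplicating itertools.permutations. Slow but
    conceptually unrelated to the implementation under test.
    """
    arrangements = set(itertools.permutations(binary))
    means = []
    for arr in arrangements:
        sizes = [len(list(g)) for v, g in itertools.groupby(arr) if v == 1]
        means.append(sum(arr) / len(sizes))
    obs_sizes = [len(list(g)) for v, g in itertools.groupby(binary) if v == 1]
    p_o = sum(binary) / len(obs_sizes)
    p_value = sum(m > p_o for m in means) / len(means)
    return sum(means) / len(means), p_value


# ---------------------------------------------------------------------------
# Patch extraction


@pytest.mark.parametrize(
    "sequence,sizes",
    [
        ([1, 0, 0, 1, 1, 1, 0, 0, 1, 1, 0], (1, 3, 2)),  # published worked example
        ([0, 1, 1, 1, 0], (3,)),
        ([1, 1], (2,)),  # trailing run still counts as a patch
        ([0, 0, 0], ()),
        ([1], (1,)),
        ([1, 0, 1], (1, 1)),
    ],
)
def test_extract_patches(sequence, sizes):
    patches = extract_patches(sequence)
    assert patches.sizes == sizes
    assert patches.n_ones == sum(sequence)
    assert patches.n_zeros == len(sequence) - sum(sequence)


@pytest.mark.parametrize(
    "values,cleaned",
    [
        ([0, 1, M, 1, 1, 0], [0, 1, 1, 1, 0]),  # missing bridges the runs
        ([1, 0, 1], [1, 0, 1]),
        ([M, 1], [1]),
        ([1, M, M], [1]),
    ],
)
def test_clean_sequence_deletes_missing_and_concatenates(values, cleaned):
    assert clean_sequence(values).tolist() == cleaned


def test_missing_value_worked_example_single_patch_of_three():
    seq = parse_sequence("0 1 * 1 1 0")
    assert extract_patches(clean_sequence(seq)).sizes == (3,)


def test_all_missing_sequence_rejected():
    with pytest.raises(ValueError, match="no usable segments"):
        clean_sequence([M, M, M])


def test_parse_sequence_literals():
    assert parse_sequence("10.110").values == (1, 0, None, 1, 1, 0)
    assert parse_sequence("1 0 0 1 1 1 0 0 1 1 0").values == tuple(
        [1, 0, 0, 1, 1, 1, 0, 0, 1, 1, 0]
    )
    with pytest.raises(ValueError):
        parse_sequence("10x1")


@pytest.mark.parametrize(
    "patches,expected", [((1, 3, 2), 2.0), ((3,), 3.0), ((5, 5), 5.0)]
)
def test_mean_patch_size(patches, expected):
    assert mean_patch_size(extract_patches(_from_sizes(patches))) == expected


def _from_sizes(sizes):
    out = []
    for s in sizes:
        out.extend([1] * s)
        out.append(0)
    return out


def test_mean_patch_size_undefined_without_presence():
    with pytest.raises(ValueError, match="no presence"):
        mean_patch_size(extract_patches([0, 0]))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 1), min_size=1, max_size=50))
def test_patch_conservation_properties(binary):
    """Sizes sum to the 1-count; patch count equals the run-start count."""
    patches = extract_patches(binary)
    assert sum(patches.sizes) == sum(binary)
    starts = sum(
        1 for i, v in enumerate(binary) if v == 1 and (i == 0 or binary[i - 1] == 0)
    )
    assert len(patches.sizes) == starts


# ---------------------------------------------------------------------------
# Exact null (enumeration oracle)


@pytest.mark.parametrize(
    "binary,p_r,p_value",
    [
        ([1, 1, 0], 5 / 3, 0.0),  # arrangements 110->2, 101->1, 011->2
        ([1, 0, 1, 0], 1.5, 0.5),  # means (2,1,1,2,1,2); 3 of 6 exceed p_o=1
        ([1, 0], 1.0, 0.0),  # both arrangements: one patch of 1
    ],
)
def test_exact_null_frozen_values(binary, p_r, p_value):
    got_p_r, got_p = exact_null(binary)
    assert got_p_r == pytest.approx(p_r)
    assert got_p == pytest.approx(p_value)


@pytest.mark.parametrize(
    "binary",
    [
        [1, 1, 0], [1, 0, 1, 0], [1, 1, 1, 0, 0], [1, 0, 0, 1, 1, 1, 0],
        [0, 1, 1, 0, 1, 0, 1, 1],
    ],
)
def test_exact_null_matches_independent_brute_force(binary):
    p_r, p_value = exact_null(binary)
    ref_p_r, ref_p = brute_force_null(binary)
    assert p_r == pytest.approx(ref_p_r)
    assert p_value == pytest.approx(ref_p)


def test_exact_null_enumeration_cap():
    seq = [1] * 15 + [0] * 15
    with pytest.raises(ValueError, match="cap"):
        exact_null(seq, cap=1000)


@pytest.mark.parametrize("constant", [[1, 1, 1], [0, 0, 0]])
def test_degenerate_sequences_error(constant):
    with pytest.raises(ValueError, match="degenerate"):
        exact_null(constant)
    with pytest.raises(ValueError, match="degenerate"):
        randomized_null(constant, 10, seed=0)
    with pytest.raises(ValueError):
        k_statistic(constant, 10, seed=0)


# ---------------------------------------------------------------------------
# Randomized null and K


def test_randomized_null_reproducible_and_converges():
    binary = [1, 0, 0, 1, 1, 1, 0, 0, 1, 1, 0]
    p_r1, means1 = randomized_null(binary, 2000, seed=42)
    p_r2, means2 = randomized_null(binary, 2000, seed=42)
    assert p_r1 == p_r2
    assert np.array_equal(means1, means2)
    exact_p_r, _ = exact_null(binary)
    assert p_r1 == pytest.approx(exact_p_r, abs=0.05)


def test_k_statistic_on_published_sequence():
    seq = PresenceSequence(tuple([1, 0, 0, 1, 1, 1, 0, 0, 1, 1, 0]), tow_id="demo")
    result = k_statistic(seq, n_randomizations=10_000, seed=7)
    assert result.p_o == 2.0
    exact_p_r, exact_p = exact_null(clean_sequence(seq))
    assert result.p_r == pytest.approx(exact_p_r, abs=0.05)
    assert result.k == pytest.approx(2.0 / exact_p_r, abs=0.05)
    assert result.p_value == pytest.approx(exact_p, abs=0.05)
    assert result.tow_id == "demo"
    assert result.n_ones == 6 and result.n_zeros == 5


def test_k_statistic_regular_spacing_below_one():
    """Perfectly alternating presence is *less* patchy than random: K < 1."""
    result = k_statistic([1, 0, 1, 0], n_randomizations=5000, seed=3)
    assert result.p_o == 1.0
    assert result.k == pytest.approx((1.0 / 1.5), abs=0.05)
    assert result.p_value == pytest.approx(0.5, abs=0.05)


def test_k_near_one_for_iid_sequence(rng):
    binary = (rng.random(2000) < 0.3).astype(int)
    result = k_statistic(binary.tolist(), n_randomizations=500, seed=11)
    assert result.k == pytest.approx(1.0, abs=0.1)


def test_tie_corrected_p_value():
    # [1,0,1,0]: 3 of 6 arrangement means exceed p_o=1 and 3 equal it
    plain = k_statistic([1, 0, 1, 0], n_randomizations=6000, seed=5)
    corrected = k_statistic(
        [1, 0, 1, 0], n_randomizations=6000, seed=5, tie_corrected=True
    )
    n_greater = round(plain.p_value * 6000)
    assert corrected.p_value == pytest.approx((n_greater + plain.n_ties + 1) / 6001)
    assert corrected.p_value == pytest.approx(1.0, abs=0.05)


def test_missing_values_removed_before_randomization():
    """The null must act on the cleaned string: same result either way."""
    with_missing = k_statistic([0, 1, M, 1, 1, 0], n_randomizations=500, seed=9)
    cleaned = k_statistic([0, 1, 1, 1, 0], n_randomizations=500, seed=9)
    assert with_missing.p_o == cleaned.p_o == 3.0
    assert with_missing.p_r == cleaned.p_r
    assert with_missing.k == cleaned.k


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    st.lists(st.integers(0, 1), min_size=4, max_size=30).filter(
        lambda s: 0 < sum(s) < len(s)
    ),
    st.randoms(use_true_random=False),
)
def test_null_is_permutation_invariant(binary, pyrandom):
    """Any rearrangement of a sequence yields the identical null sample."""
    shuffled = list(binary)
    pyrandom.shuffle(shuffled)
    _, means_a = randomized_null(binary, 50, seed=21)
    _, means_b = randomized_null(shuffled, 50, seed=21)
    assert np.array_equal(np.sort(means_a), np.sort(means_b))


def test_keep_null_returns_all_randomized_means():
    result = k_statistic([1, 1, 0, 0, 1], n_randomizations=100, seed=2, keep_null=True)
    assert result.null_means is not None and len(result.null_means) == 100
    assert np.mean(result.null_means) == pytest.approx(result.p_r)


# ---------------------------------------------------------------------------
# Tow summaries


def test_summary_single_block_tow(block_series):
    summary = summarize_tow(block_series, n_randomizations=200, seed=1)
    assert summary.pct_no_reef == pytest.approx(60.0)
    assert summary.pct_low == pytest.approx(40.0)
    assert summary.n_patches == 1
    assert summary.mean_patch_len == summary.median_patch_len == 4.0
    assert summary.patch_size_min == summary.patch_size_max == 4
    assert summary.k is not None and summary.k > 1


def test_summary_percentages_sum_to_100(block_series):
    s = summarize_tow(block_series, n_randomizations=50, seed=1)
    total = s.pct_no_reef + s.pct_not_reef + s.pct_low + s.pct_medium + s.pct_high
    assert total == pytest.approx(100.0, abs=0.01)


def test_summary_degenerate_tow_returns_none_fields(caplog):
    from conftest import build_series

    series = build_series([20.0] * 5, [3.0] * 5)  # all presence: K undefined
    with caplog.at_level("WARNING"):
        summary = summarize_tow(series, n_randomizations=50, seed=1)
    assert summary.k is None and summary.p_value is None
    assert summary.n_patches == 1 and summary.mean_patch_len == 5.0
    assert "degenerate" in caplog.text


def test_tow_seed_deterministic_and_distinct():
    assert tow_seed(3, "A68") == tow_seed(3, "A68")
    assert tow_seed(3, "A68") != tow_seed(3, "A69")
    assert tow_seed(3, "A68") != tow_seed(4, "A68")
    assert 0 <= tow_seed(3, "A68") < 2**31
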