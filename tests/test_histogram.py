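import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from otsu2d import (
    FilterConfig,
    Strategy,
    add_salt_pepper,
    average_filter,
    build_histogram2d,
    coins_scene,
    histogram_compactness,
    histogram_from_pair,
    median_filter,
    pair_images,
    render,
)
from oracles import windowed_median

STRATEGIES = list(Strategy)


@pytest.mark.parametrize(
    "img,k,expected",
    [
        (np.full((4, 4), 7), 3, np.full((4, 4), 7)),  # mean of constants
        (np.array([[42]]), 3, np.array([[42]])),  # replicate padding on 1x1
    ],
)
def test_average_filter_identities(img, k, expected):
    np.testing.assert_array_equal(average_filter(img, k), expected)


def test_average_filter_center_spike():
    img = np.zeros((3, 3), dtype=int)
    img[1, 1] = 9
    assert average_filter(img, 3)[1, 1] == 1  # round(9/9)


def test_average_filter_rounds_half_up():
    # window sum 9 * 0 + ... mean 4.5 must go to 5, not banker's 4
    img = np.full((3, 3), 4)
    img[1, 1] = 8  # mean (8 + 8*4)/9 = 4.444 -> 4
    assert average_filter(img, 3)[1, 1] == 4
    img2 = np.array([[1, 2], [3, 12]])  # k=3 on 2x2 replicate: mean of corner
    out = average_filter(img2, 3)
    # bottom-right window (replicated): [1,2,2],[3,12,12],[3,12,12] -> 59/9 = 6.56 -> 7
    assert out[1, 1] == 7


def test_median_filter_removes_isolated_impulse():
    img = np.zeros((3, 3), dtype=int)
    img[1, 1] = 255
    np.testing.assert_array_equal(median_filter(img, 3), np.zeros((3, 3)))


def test_median_filter_matches_windowed_sort_oracle(rng):
    img = rng.integers(0, 256, size=(9, 7))
    np.testing.assert_array_equal(median_filter(img, 3), windowed_median(img, 3))
    np.testing.assert_array_equal(median_filter(img, 5), windowed_median(img, 5))


def test_median_filter_idempotent_on_smooth_images():
    const = np.full((5, 5), 9)
    np.testing.assert_array_equal(median_filter(const, 3), const)
    mono = np.tile(np.arange(8), (5, 1)).T  # monotone along rows
    once = median_filter(mono, 3)
    np.testing.assert_array_equal(median_filter(once, 3), once)


@pytest.mark.parametrize("k", [0, 2, 4])
def test_filters_reject_even_window(k):
    img = np.zeros((3, 3), dtype=int)
    with pytest.raises(ValueError):
        average_filter(img, k)
    with pytest.raises(ValueError):
        median_filter(img, k)


@pytest.mark.parametrize("strategy", STRATEGIES)
def test_constant_image_histogram(strategy):
    img = np.full((6, 6), 5)
    h = build_histogram2d(img, FilterConfig(strategy=strategy))
    assert h.p[5, 5] == 1.0
    assert h.mean_vector == (5.0, 5.0)


@settings(max_examples=25, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    strategy=st.sampled_from(STRATEGIES),
)
def test_histogram_normalization_and_mean_consistency(seed, strategy):
    """Probabilities sum to 1 and the mean vector matches the pair images."""
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 256, size=(12, 10))
    h = build_histogram2d(img, FilterConfig(strategy=strategy))
    assert abs(h.p.sum() - 1.0) <= 1e-12
    first, second = pair_images(img, FilterConfig(strategy=strategy))
    assert h.mean_vector[0] == pytest.approx(first.mean(), abs=1e-9)
    assert h.mean_vector[1] == pytest.approx(second.mean(), abs=1e-9)


def test_region_restricted_histogram_small_case():
    # two selected pixels carrying pairs (0,0) and (3,3) at L=4
    first = np.array([[0, 9], [9, 3]])
    second = np.array([[0, 9], [9, 3]])
    region = np.array([[1, 0], [0, 1]])
    h = histogram_from_pair(first, second, levels=4, region=region)
    assert h.p[0, 0] == 0.5 and h.p[3, 3] == 0.5
    assert h.mean_vector == (1.5, 1.5)


def test_region_filters_computed_on_whole_image():
    """Region restriction must not change the filtered values themselves."""
    rng = np.random.default_rng(3)
    img = rng.integers(0, 256, size=(10, 10))
    region = np.zeros((10, 10), dtype=np.uint8)
    region[:5] = 1
    h_whole = build_histogram2d(img)
    h_part1 = build_histogram2d(img, region=region)
    h_part2 = build_histogram2d(img, region=1 - region)
    np.testing.assert_array_equal(
        h_part1.counts + h_part2.counts, h_whole.counts
    )


def test_empty_region_rejected():
    img = np.zeros((4, 4), dtype=int)
    with pytest.raises(ValueError):
        build_histogram2d(img, region=np.zeros((4, 4)))


def test_compactness_examples():
    h = histogram_from_pair(np.full((2, 4), 2), np.full((2, 4), 2), levels=4)
    assert histogram_compactness(h) == 0.0
    h2 = histogram_from_pair(np.zeros((1, 1), int), np.full((1, 1), 3), levels=4)
    assert histogram_compactness(h2) == 9.0


def test_median_pairing_is_most_compact_under_impulse_noise(coins_pair):
    """The median/median-average histogram hugs the diagonal tightest."""
    img, _ = coins_pair
    noisy = add_salt_pepper(img, 0.1, 99)
    comp = {
        s: histogram_compactness(build_histogram2d(noisy, FilterConfig(strategy=s)))
        for s in STRATEGIES
    }
    assert comp[Strategy.MED_MEDAVG] <= comp[Strategy.ORIG_MEDAVG]
    assert comp[Strategy.MED_MEDAVG] <= comp[Strategy.AVG_ONLY]
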