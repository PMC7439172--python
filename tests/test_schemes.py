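import warnings

import numpy as np
import pytest
from sklearn.base import clone

from otsu2d import (
    Otsu2DSegmenter,
    PartitionedOtsu2DSegmenter,
    binarize,
    evaluate,
    find_threshold,
    histogram_from_pair,
    pair_images,
    run_pipeline,
    scheme1,
    scheme2,
)
from otsu2d.histogram import FilterConfig
from otsu2d.otsu import trace_criterion


def striped_image(m=12, n=12):
    """Every row identical: any split yields parts with the whole's histogram."""
    row = np.where(np.arange(n) % 4 < 2, 40, 210)
    return np.tile(row, (m, 1))


def test_uniform_illumination_parts_reuse_whole_image_threshold():
    img = striped_image()
    whole = Otsu2DSegmenter().fit(img).threshold_
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r1 = scheme1(img)
    for tp in r1.thresholds:
        assert (tp.s, tp.t) == (whole.s, whole.t)


def test_scheme2_identical_parts_equals_single_part_optimum():
    """Product of two equal criteria is maximised at the single-part argmax."""
    rng = np.random.default_rng(5)
    i_img = rng.integers(0, 8, size=(10, 10))
    h = histogram_from_pair(i_img, i_img, levels=8)
    single = find_threshold(h)
    joint = PartitionedOtsu2DSegmenter._joint_threshold([h, h])
    assert (joint.s, joint.t) == (single.s, single.t)
    assert joint.criterion == pytest.approx(single.criterion**2, rel=1e-9)


def test_scheme2_product_matches_exhaustive_search():
    # non-diagonal pairs: avoids structurally tied (s, t)/(t, s) optima
    rng = np.random.default_rng(11)
    a = rng.integers(0, 8, size=(9, 9))
    b = rng.integers(0, 8, size=(9, 9))
    h1 = histogram_from_pair(a, np.clip(a + rng.integers(-1, 2, a.shape), 0, 7), levels=8)
    h2 = histogram_from_pair(b, np.clip(b + rng.integers(-1, 2, b.shape), 0, 7), levels=8)
    best, arg = -1.0, None
    for s in range(7):
        for t in range(7):
            v = trace_criterion(h1, s, t) * trace_criterion(h2, s, t)
            if v > best:
                best, arg = v, (s, t)
    joint = PartitionedOtsu2DSegmenter._joint_threshold([h1, h2])
    assert (joint.s, joint.t) == arg
    assert joint.criterion == pytest.approx(best, rel=1e-9)


def test_scheme2_product_is_symmetric_in_the_parts():
    rng = np.random.default_rng(2)
    a = rng.integers(0, 8, size=(9, 9))
    b = rng.integers(0, 8, size=(9, 9))
    h1 = histogram_from_pair(a, a, levels=8)
    h2 = histogram_from_pair(b, b, levels=8)
    j12 = PartitionedOtsu2DSegmenter._joint_threshold([h1, h2])
    j21 = PartitionedOtsu2DSegmenter._joint_threshold([h2, h1])
    assert (j12.s, j12.t) == (j21.s, j21.t)


def test_scheme2_degenerate_part_falls_back_to_other():
    rng = np.random.default_rng(4)
    a = rng.integers(0, 8, size=(9, 9))
    h1 = histogram_from_pair(a, a, levels=8)
    const = np.full((9, 9), 3)
    h2 = histogram_from_pair(const, const, levels=8)
    single = find_threshold(h1)
    with pytest.warns(UserWarning, match="degenerate"):
        joint = PartitionedOtsu2DSegmenter._joint_threshold([h1, h2])
    assert (joint.s, joint.t) == (single.s, single.t)


def test_constant_image_yields_all_background():
    img = np.full((8, 8), 7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r1 = scheme1(img)
    assert r1.mask.sum() == 0


def test_scheme1_stitched_mask_matches_per_part_binarization(uneven_pair):
    img, _ = uneven_pair
    est = PartitionedOtsu2DSegmenter(scheme="s1")
    mask = est.fit_predict(img)
    first, second = pair_images(img, FilterConfig())
    for part, tp, h in zip(est.parts_, est.thresholds_, est.histograms_):
        alone = binarize(first, second, tp, ambiguous="smoothed", h=h)
        sel = part.astype(bool)
        np.testing.assert_array_equal(mask[sel], alone[sel])


def test_scheme1_recovers_dark_foreground_under_uneven_light(uneven_pair):
    """Partitioning beats whole-image thresholding under contrast inversion."""
    img, gt = uneven_pair
    me_global = evaluate(Otsu2DSegmenter().fit_predict(img), gt).me
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r1 = scheme1(img)
    assert evaluate(r1.mask, gt).me < me_global


def test_run_pipeline_selection_rules(uneven_pair):
    img, gt = uneven_pair
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r1, r2, sel = run_pipeline(img, gt=gt)
        assert sel == ("s1" if r1.report.me <= r2.report.me else "s2")
        assert r1.mask.shape == img.shape and r2.mask.shape == img.shape
        assert len(r1.thresholds) == 2 and len(r2.thresholds) == 1
        _, _, none_sel = run_pipeline(img)
    assert none_sel is None


def test_estimators_follow_sklearn_contract():
    est = PartitionedOtsu2DSegmenter(scheme="s2", k=5, w1=3.0)
    params = est.get_params()
    assert params["scheme"] == "s2" and params["k"] == 5 and params["w1"] == 3.0
    dup = clone(est)
    assert dup.get_params() == params
    est2 = Otsu2DSegmenter().set_params(strategy="avg_only")
    assert est2.strategy == "avg_only"
    with pytest.raises(ValueError):
        PartitionedOtsu2DSegmenter(scheme="bogus").fit(np.zeros((4, 4), int))
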