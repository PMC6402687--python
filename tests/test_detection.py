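import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from phasecell.detection import (DetectionConfig, GaussianPair, crop_regions,
                                 detect_cells, detection_metrics,
                                 fit_two_gaussians, mvr_metric, overlap_counts)
from phasecell.fixtures import make_frame


def test_fit_two_gaussians_constant_regions():
    frame = np.full((40, 40), 100.0)
    mask = np.zeros((40, 40), dtype=bool)
    mask[10:20, 10:20] = True
    frame[mask] = 200.0
    p = fit_two_gaussians(frame, mask)
    assert (p.mu_f, p.var_f, p.mu_b, p.var_b) == (200.0, 0.0, 100.0, 0.0)


def test_fit_two_gaussians_recovers_sampled_parameters(rng):
    mask = np.zeros((150, 150), dtype=bool)
    mask[:, :75] = True  # >= 10^4 px per side
    frame = np.where(mask, rng.normal(180, 15, mask.shape), rng.normal(90, 8, mask.shape))
    p = fit_two_gaussians(frame, mask)
    assert abs(p.mu_f - 180) <= 2 and abs(p.mu_b - 90) <= 2
    assert abs(p.var_f - 225) <= 0.2 * 225 and abs(p.var_b - 64) <= 0.2 * 64


def test_fit_two_gaussians_requires_both_regions():
    frame = np.zeros((5, 5))
    with pytest.raises(ValueError):
        fit_two_gaussians(frame, np.ones((5, 5), dtype=bool))


@pytest.mark.parametrize("pair,expected", [
    (GaussianPair(10, 2, 4, 2), 3.0),
    (GaussianPair(50, 10, 25, 5), 0.0),  # equal mean-to-variance ratios
])
def test_mvr_metric_examples(pair, expected):
    assert mvr_metric(pair) == pytest.approx(expected)


def test_mvr_metric_zero_variance_is_degenerate():
    with pytest.raises(ValueError):
        mvr_metric(GaussianPair(200, 0, 100, 5))


def test_mvr_metric_symmetric_under_label_swap(rng):
    for _ in range(20):
        mu1, mu2 = rng.uniform(0, 255, 2)
        v1, v2 = rng.uniform(1, 500, 2)
        a = mvr_metric(GaussianPair(mu1, v1, mu2, v2))
        b = mvr_metric(GaussianPair(mu2, v2, mu1, v1))
        assert a == pytest.approx(b)


def test_detect_cells_single_cell_jaccard(fixture_frame):
    frame, truth, params = make_frame(1, rng=7)
    res = detect_cells(frame)
    assert len(res.regions) == 1
    assert detection_metrics(res.mask, truth)["J"] >= 0.7


def test_detect_cells_counts_and_parameter_recovery(fixture_frame):
    frame, truth, gen_params = fixture_frame
    res = detect_cells(frame)
    assert len(res.regions) == 3
    assert detection_metrics(res.mask, truth)["J"] >= 0.7
    assert abs(res.params.mu_f - gen_params.mu_f) <= 5
    assert abs(res.params.mu_b - gen_params.mu_b) <= 5


def test_detect_cells_is_deterministic(fixture_frame):
    frame, _, _ = fixture_frame
    a = detect_cells(frame)
    b = detect_cells(frame)
    np.testing.assert_array_equal(a.mask, b.mask)
    assert [vars(r) for r in a.regions] == [vars(r) for r in b.regions]


def test_detect_cells_constant_frame_yields_no_regions():
    res = detect_cells(np.full((100, 120), 85.0))
    assert res.regions == [] and not res.mask.any()


def test_crop_regions_bounds():
    frame = np.arange(100.0 * 120).reshape(100, 120)
    from phasecell.detection import DetectionResult, Region

    res = DetectionResult(mask=np.zeros_like(frame, dtype=bool),
                          regions=[Region(10, 10, 20, 20, 100), Region(0, 0, 8, 8, 64)])
    crops = crop_regions(frame, res, pad=0)
    assert crops[0].shape == (10, 10)
    np.testing.assert_array_equal(crops[0], frame[10:20, 10:20])
    padded = crop_regions(frame, res, pad=5)
    assert padded[1].shape == (13, 13)  # clipped at the frame corner
    empty = DetectionResult(mask=np.zeros_like(frame, dtype=bool), regions=[])
    assert crop_regions(frame, empty, pad=3) == []


def test_detection_metrics_toy_counts():
    # 4x4 masks engineered to TP=2, FP=1, FN=1, TN=12
    pred = np.zeros((4, 4), dtype=bool)
    truth = np.zeros((4, 4), dtype=bool)
    pred[0, 0] = truth[0, 0] = True
    pred[0, 1] = truth[0, 1] = True
    pred[1, 0] = True   # FP
    truth[1, 1] = True  # FN
    assert overlap_counts(pred, truth) == (2, 1, 1, 12)
    m = detection_metrics(pred, truth)
    assert m["SEN"] == pytest.approx(2 / 3)
    assert m["SPC"] == pytest.approx(12 / 13)
    assert m["J"] == pytest.approx(1 / 2)
    assert m["DIC"] == pytest.approx(2 / 3)


def test_detection_metrics_edge_cases():
    truth = np.zeros((4, 4), dtype=bool)
    truth[1, 1] = True
    m = detection_metrics(np.zeros((4, 4), dtype=bool), truth)
    assert m["SEN"] == 0 and m["J"] == 0 and m["DIC"] == 0
    same = detection_metrics(truth, truth)
    assert all(same[k] == 1 for k in ("SEN", "SPC", "J", "DIC"))
    undef = detection_metrics(np.zeros((4, 4), dtype=bool), np.zeros((4, 4), dtype=bool))
    assert np.isnan(undef["SEN"]) and np.isnan(undef["J"])


@given(pred=arrays(bool, (6, 6)), truth=arrays(bool, (6, 6)))
def test_jaccard_never_exceeds_dice(pred, truth):
    m = detection_metrics(pred, truth)
    if not np.isnan(m["J"]):
        assert m["J"] <= m["DIC"] + 1e-12


def test_min_area_filter_drops_specks():
    frame = np.random.default_rng(3).normal(90, 8, (200, 200))
    frame[100:104, 100:104] += 120  # 16 px speck, below the 30 px default
    res = detect_cells(frame, DetectionConfig())
    assert all(r.area >= 30 for r in res.regions)
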