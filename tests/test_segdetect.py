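"""Segmentation network, HSV debris filter, detection post-processing,
morphometry and the morphology GBT."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk, ellipse as draw_ellipse
from skimage.measure import label as cc_label

from cytofna.segdetect import (HsvRange, SegNetConfig, SegTrainConfig,
                               SplitParams, TINY_SEG, build_seg_net,
                               deeplab_v1_reference_params,
                               default_hsv_ranges, detections_from_mask,
                               hsv_debris_filter, nuclear_morphometry,
                               segment_patch, train_seg_net,
                               train_morpho_gbt, classify_morpho,
                               MORPHO_FEATURE_NAMES, Detection)
from cytofna.segdetect.gbt import DataError
from cytofna.segdetect.net import ConfigurationError
from cytofna.synthcyto import SynthConfig, render_cell_crop, render_patch

SMALL = SegNetConfig(depth=2, base_width=4, pyramid_fusion=False,
                     input_size=64)


# ---------------------------------------------------------------------------
# network construction

def test_plain_encoder_decoder_shape_contract(rng):
    model = build_seg_net(SMALL, init_seed=0)
    x = rng.normal(size=(1, 3, 64, 64)).astype(np.float32)
    model.eval()
    assert model.forward(x).shape == (1, 1, 64, 64)


def test_same_config_and_seed_builds_identically(rng):
    a = build_seg_net(TINY_SEG, init_seed=3)
    b = build_seg_net(TINY_SEG, init_seed=3)
    assert a.n_params() == b.n_params()
    x = rng.normal(size=(1, 3, 128, 128)).astype(np.float32)
    a.eval(), b.eval()
    assert np.array_equal(a.forward(x), b.forward(x))


def test_input_size_must_match_pooling_factor():
    with pytest.raises(ConfigurationError):
        SegNetConfig(depth=3, base_width=8, input_size=100)


def test_tiny_net_is_below_a_fifth_of_the_reference_budget():
    model = build_seg_net(TINY_SEG)
    assert model.n_params() < 0.2 * deeplab_v1_reference_params(128)


# ---------------------------------------------------------------------------
# training

def _small_patches(n, seed, **kw):
    kw.setdefault("nuclei_per_patch", (4, 8))
    cfg = SynthConfig(patch_size=64, **kw)
    r = np.random.default_rng(seed)
    return [render_patch(cfg, int(s)) for s in r.integers(0, 2 ** 31, n)]


def test_training_on_background_predicts_background():
    patches = _small_patches(12, 0, nuclei_per_patch=(0, 0), debris_rate=0.0)
    model = build_seg_net(SMALL, init_seed=0)
    model, _ = train_seg_net(model, patches,
                             SegTrainConfig(lr=1e-2, epochs=15, seed=0))
    prob = model.predict_proba(patches[0].image)[0]
    assert (prob < 0.5).all()


def test_training_is_deterministic():
    patches = _small_patches(10, 1)
    runs = []
    for _ in range(2):
        model = build_seg_net(SMALL, init_seed=0)
        _, trace = train_seg_net(model, patches,
                                 SegTrainConfig(epochs=3, seed=4))
        runs.append(trace)
    assert runs[0] == runs[1]


def test_loss_trace_decreases_when_smoothed():
    """5-epoch moving average of the training loss is non-increasing (up to
    5% converged-plateau noise)."""
    patches = _small_patches(12, 2)
    model = build_seg_net(SMALL, init_seed=0)
    _, trace = train_seg_net(model, patches,
                             SegTrainConfig(epochs=15, seed=0))
    sm = np.convolve(trace, np.ones(5) / 5, mode="valid")
    assert all(sm[i + 1] <= sm[i] * 1.05 + 1e-4 for i in range(len(sm) - 1))
    assert sm[-1] < sm[0]


def test_empty_dataset_rejected():
    with pytest.raises(ValueError):
        train_seg_net(build_seg_net(SMALL), [])


# ---------------------------------------------------------------------------
# inference

def test_threshold_one_gives_empty_mask(fixture_models):
    p = render_patch(SynthConfig(patch_size=128), 9)
    mask, prob = segment_patch(p.image, fixture_models.seg, 1.0)
    assert not mask.any()
    assert (prob < 1.0).all()


def test_mask_equals_thresholded_probability(fixture_models):
    p = render_patch(SynthConfig(patch_size=128), 10)
    mask, prob = segment_patch(p.image, fixture_models.seg, 0.5)
    assert np.array_equal(mask, prob >= 0.5)


def test_object_recall_on_well_separated_nuclei(fixture_models):
    """>= 11 of 12 ground-truth nuclei overlap the predicted mask."""
    cfg = SynthConfig(patch_size=128, nuclei_per_patch=(12, 12),
                      cluster_rate=0.0, seed=1)
    p = render_patch(cfg, 1)
    mask, _ = segment_patch(p.image, fixture_models.seg, 0.5)
    hit = sum(1 for lab in np.unique(p.instance_mask) if lab and
              (mask & (p.instance_mask == lab)).sum()
              >= 0.5 * (p.instance_mask == lab).sum())
    assert hit >= 11


def test_undersized_image_rejected(fixture_models):
    with pytest.raises(ValueError):
        segment_patch(np.zeros((64, 64, 3), np.uint8), fixture_models.seg)


# ---------------------------------------------------------------------------
# HSV debris filter

def _rbc_and_nuclei_scene():
    img = np.full((96, 96, 3), 230, np.uint8)
    mask = np.zeros((96, 96), bool)
    rbc_centres = [(20, 20), (70, 30)]
    nuc_centres = [(30, 70), (70, 75)]
    for cy, cx in rbc_centres:
        rr, cc = draw_disk((cy, cx), 5)
        img[rr, cc] = (205, 40, 45)      # saturated red
        mask[rr, cc] = True
    for cy, cx in nuc_centres:
        rr, cc = draw_disk((cy, cx), 6)
        img[rr, cc] = (70, 60, 120)      # haematoxylin purple
        mask[rr, cc] = True
    return img, mask, rbc_centres, nuc_centres


def test_empty_ranges_is_identity():
    img, mask, *_ = _rbc_and_nuclei_scene()
    assert np.array_equal(hsv_debris_filter(img, mask, []), mask)


def test_red_debris_components_removed_nuclei_retained():
    img, mask, rbc, nuc = _rbc_and_nuclei_scene()
    out = hsv_debris_filter(img, mask, default_hsv_ranges())
    for cy, cx in rbc:
        assert not out[cy, cx]
    for cy, cx in nuc:
        assert out[cy, cx]


def test_filter_is_idempotent():
    img, mask, *_ = _rbc_and_nuclei_scene()
    once = hsv_debris_filter(img, mask, default_hsv_ranges())
    twice = hsv_debris_filter(img, once, default_hsv_ranges())
    assert np.array_equal(once, twice)


def test_high_bound_is_exclusive():
    """A component whose median hue sits exactly on the range's high bound
    is retained."""
    img = np.full((32, 32, 3), 255, np.uint8)
    mask = np.zeros((32, 32), bool)
    rr, cc = draw_disk((16, 16), 6)
    # hue exactly 1/3 (pure green), saturation 1
    img[rr, cc] = (0, 255, 0)
    mask[rr, cc] = True
    rng_ = [HsvRange(hue=(0.0, 1.0 / 3.0), saturation=(0.5, 1.0))]
    out = hsv_debris_filter(img, mask, rng_)
    assert np.array_equal(out, mask)


# ---------------------------------------------------------------------------
# detections

def test_empty_mask_gives_no_detections():
    assert detections_from_mask(np.zeros((32, 32), bool),
                                np.zeros((32, 32))) == []


def test_single_small_component_is_one_nucleus():
    mask = np.zeros((64, 64), bool)
    rr, cc = draw_disk((30, 28), 8)
    mask[rr, cc] = True
    prob = np.full((64, 64), 0.7)
    dets = detections_from_mask(mask, prob)
    assert len(dets) == 1
    d = dets[0]
    assert d.kind == "nucleus"
    ys, xs = np.nonzero(mask)
    assert d.bbox == (xs.min(), ys.min(), xs.max() + 1, ys.max() + 1)
    assert d.score == pytest.approx(0.7)


def test_two_overlapping_ellipses_become_one_cluster_by_default():
    mask = np.zeros((96, 96), bool)
    for cy, cx in ((45, 35), (50, 60)):
        rr, cc = draw_ellipse(cy, cx, 14, 16)
        mask[rr, cc] = True
    assert cc_label(mask).max() == 1  # genuinely one component
    dets = detections_from_mask(mask, np.full(mask.shape, 0.9))
    assert len(dets) == 1
    assert dets[0].kind == "cluster"
    assert dets[0].n_seeds >= 2


def test_oversized_component_is_watershed_split():
    mask = np.zeros((96, 96), bool)
    for cy, cx in ((45, 30), (50, 62)):
        rr, cc = draw_ellipse(cy, cx, 16, 18)
        mask[rr, cc] = True
    sp = SplitParams(max_single_area=800, min_peak_distance=7, min_area=30)
    dets = detections_from_mask(mask, np.full(mask.shape, 0.9), sp, 1e9)
    assert len(dets) == 2


def test_splitting_disabled_equals_connected_components(rng):
    """Oracle equivalence on 50 random blob masks."""
    from scipy.ndimage import gaussian_filter
    sp = SplitParams(max_single_area=np.inf, min_area=0)
    for _ in range(50):
        noise = gaussian_filter(rng.normal(size=(48, 48)), 3)
        mask = noise > np.quantile(noise, 0.8)
        dets = detections_from_mask(mask, np.full(mask.shape, 0.5), sp, 1e9)
        lab = cc_label(mask, connectivity=2)
        assert len(dets) == lab.max()
        covered = np.zeros_like(mask)
        for d in dets:
            x0, y0, x1, y1 = d.bbox
            covered[y0:y1, x0:x1] |= d.instance_mask
        assert np.array_equal(covered, mask)


def test_pixel_count_conservation(rng):
    """Assigned + discarded pixels account for the whole mask foreground."""
    from scipy.ndimage import gaussian_filter
    noise = gaussian_filter(rng.normal(size=(64, 64)), 2)
    mask = noise > np.quantile(noise, 0.85)
    sp = SplitParams(max_single_area=np.inf, min_area=40)
    dets = detections_from_mask(mask, np.full(mask.shape, 0.5), sp, 1e9)
    assigned = sum(d.area for d in dets)
    lab = cc_label(mask, connectivity=2)
    discarded = sum(int((lab == i).sum()) for i in range(1, lab.max() + 1)
                    if (lab == i).sum() < 40)
    assert assigned + discarded == int(mask.sum())


def test_scores_bounded_and_cluster_implies_seed_or_area(rng):
    p = render_patch(SynthConfig(patch_size=128, cluster_rate=0.5, seed=6), 6)
    prob = rng.uniform(size=p.instance_mask.shape)
    dets = detections_from_mask(p.instance_mask > 0, prob)
    for d in dets:
        assert 0.0 <= d.score <= 1.0
        if d.kind == "cluster":
            assert d.area > 1200 or d.n_seeds >= 2


# ---------------------------------------------------------------------------
# morphometry

def _det_from_mask(mask):
    ys, xs = np.nonzero(mask)
    bbox = (xs.min(), ys.min(), xs.max() + 1, ys.max() + 1)
    return Detection(bbox=bbox, instance_mask=mask[bbox[1]:bbox[3],
                                                   bbox[0]:bbox[2]],
                     kind="nucleus", score=1.0)


def test_disk_morphometry_matches_closed_form():
    mask = np.zeros((64, 64), bool)
    rr, cc = draw_disk((32, 32), 10)
    mask[rr, cc] = True
    img = np.full((64, 64, 3), 100, np.uint8)
    f = dict(zip(MORPHO_FEATURE_NAMES,
                 nuclear_morphometry(img, _det_from_mask(mask))))
    assert f["area"] == pytest.approx(100 * np.pi, rel=0.05)
    assert f["aspect_ratio"] == pytest.approx(1.0, rel=0.05)
    assert 0.8 < f["circularity"] <= 1.15


def test_ellipse_axes_and_eccentricity():
    mask = np.zeros((96, 96), bool)
    rr, cc = draw_ellipse(48, 48, 10, 20)   # semi-axes (20, 10), x-major
    mask[rr, cc] = True
    img = np.full((96, 96, 3), 100, np.uint8)
    f = dict(zip(MORPHO_FEATURE_NAMES,
                 nuclear_morphometry(img, _det_from_mask(mask))))
    assert f["aspect_ratio"] == pytest.approx(2.0, rel=0.05)
    assert f["eccentricity"] == pytest.approx(np.sqrt(3) / 2, rel=0.05)
    assert abs(f["orientation"]) < 0.1   # aligned with the x axis


def test_constant_intensity_nucleus():
    mask = np.zeros((32, 32), bool)
    rr, cc = draw_disk((16, 16), 6)
    mask[rr, cc] = True
    img = np.full((32, 32, 3), 77, np.uint8)
    f = dict(zip(MORPHO_FEATURE_NAMES,
                 nuclear_morphometry(img, _det_from_mask(mask))))
    assert f["gray_std"] == 0.0
    assert f["gray_min"] == f["gray_max"] == pytest.approx(f["gray_mean"])


def test_single_pixel_mask_is_defined():
    mask = np.zeros((8, 8), bool)
    mask[4, 4] = True
    img = np.full((8, 8, 3), 50, np.uint8)
    f = dict(zip(MORPHO_FEATURE_NAMES,
                 nuclear_morphometry(img, _det_from_mask(mask))))
    assert f["perimeter"] >= 1.0
    assert f["aspect_ratio"] == 1.0
    assert f["area"] == 1.0


def test_scale_property():
    """Doubling resolution: area x4, perimeter x2 (10% tol); shape ratios
    stable to 5%."""
    img1 = np.full((64, 64, 3), 90, np.uint8)
    img2 = np.full((128, 128, 3), 90, np.uint8)
    m1 = np.zeros((64, 64), bool)
    rr, cc = draw_ellipse(32, 32, 8, 14)
    m1[rr, cc] = True
    m2 = np.zeros((128, 128), bool)
    rr, cc = draw_ellipse(64, 64, 16, 28)
    m2[rr, cc] = True
    f1 = dict(zip(MORPHO_FEATURE_NAMES,
                  nuclear_morphometry(img1, _det_from_mask(m1))))
    f2 = dict(zip(MORPHO_FEATURE_NAMES,
                  nuclear_morphometry(img2, _det_from_mask(m2))))
    assert f2["area"] == pytest.approx(4 * f1["area"], rel=0.10)
    assert f2["perimeter"] == pytest.approx(2 * f1["perimeter"], rel=0.10)
    for k in ("aspect_ratio", "eccentricity", "solidity"):
        assert f2[k] == pytest.approx(f1[k], rel=0.05)


# ---------------------------------------------------------------------------
# morphology GBT

@pytest.fixture(scope="module")
def two_class_morpho():
    """400 nuclei: benign small round (C6) vs atypical large irregular (C1)."""
    feats, labels = [], []
    for ci, cls in enumerate(("C6", "C1")):
        for s in range(200):
            img, m = render_cell_crop(cls, 72, "pap", seed=ci * 50000 + s)
            feats.append(nuclear_morphometry(img, _det_from_mask(m)))
            labels.append(cls)
    feats = np.asarray(feats)
    labels = np.asarray(labels)
    r = np.random.default_rng(0)
    idx = r.permutation(len(feats))
    return feats[idx[:300]], labels[idx[:300]], feats[idx[300:]], labels[idx[300:]]


def test_two_class_benchmark_accuracy(two_class_morpho):
    xtr, ytr, xte, yte = two_class_morpho
    model, train_acc = train_morpho_gbt(xtr, ytr, seed=0)
    assert train_acc >= 0.95
    preds = [classify_morpho(x, model)[0] for x in xte]
    acc = np.mean([p == t for p, t in zip(preds, yte)])
    assert acc >= 0.95
    # macro F1
    from sklearn.metrics import f1_score
    assert f1_score(yte, preds, average="macro") >= 0.95


def test_duplicated_dataset_gives_identical_predictions(two_class_morpho):
    xtr, ytr, xte, _ = two_class_morpho
    m1, _ = train_morpho_gbt(xtr, ytr, seed=0)
    m2, _ = train_morpho_gbt(np.vstack([xtr, xtr]),
                             np.concatenate([ytr, ytr]), seed=0)
    p1 = m1.predict_proba(xte)
    p2 = m2.predict_proba(xte)
    assert np.allclose(p1, p2, atol=1e-5)


def test_single_class_is_a_data_error():
    x = np.zeros((10, 19))
    with pytest.raises(DataError):
        train_morpho_gbt(x, ["C6"] * 10)


def test_wrong_feature_length_is_a_contract_error(two_class_morpho):
    xtr, ytr, *_ = two_class_morpho
    model, _ = train_morpho_gbt(xtr, ytr, seed=0)
    with pytest.raises(ValueError):
        classify_morpho(np.zeros(18), model)


def test_training_set_vector_gets_its_class(two_class_morpho):
    xtr, ytr, *_ = two_class_morpho
    model, _ = train_morpho_gbt(xtr, ytr, seed=0)
    cls, p = classify_morpho(xtr[0], model)
    assert cls == ytr[0]
    assert p > 0.5
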