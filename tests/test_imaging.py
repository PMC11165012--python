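"""Imaging operators against constructed fixtures and generator ground truth."""

import itertools
import math

import numpy as np
import pytest

from neuroscreen import imaging
from neuroscreen.imaging import (
    NucleusRecord,
    Punctum,
    aggregate_well,
    call_synapses,
    coloc_fraction,
    compute_ratios,
    correct_illumination,
    detect_puncta,
    score_marker_positivity,
    segment_nuclei,
    skeletonize_neurites,
)
from neuroscreen.simulate import simulate_field

from conftest import make_image

PX = 0.65


# ------------------------------------------------------ illumination


def test_illumination_correction_identity_and_gradient_removal(rng):
    flat = make_image({"Hoechst": np.full((64, 64), 200.0)})
    out = correct_illumination(flat, sigma_px=16)
    np.testing.assert_allclose(out.pixels, flat.pixels, rtol=1e-6)

    base = np.full((128, 128), 200.0)
    gradient = np.linspace(0.7, 1.3, 128)[None, :]
    img = make_image({"Hoechst": base * gradient})
    out = correct_illumination(img, sigma_px=32)
    colmeans = out.pixels[0].mean(axis=0)
    assert colmeans[5:-5].max() / colmeans[5:-5].min() < 1.02

    zero = make_image({"Hoechst": np.zeros((32, 32))})
    np.testing.assert_array_equal(correct_illumination(zero).pixels, zero.pixels)


def test_illumination_correction_preserves_punctum_rank_order(rng):
    """A smooth gradient must not reorder punctum peak intensities."""
    h = w = 200
    img = np.full((h, w), 100.0)
    centers = [(30 + 40 * i, 30 + 40 * i) for i in range(4)]
    amps = [300.0, 260.0, 220.0, 180.0]
    for (r, c), a in zip(centers, amps):
        rr, cc = np.mgrid[r - 6:r + 7, c - 6:c + 7]
        img[r - 6:r + 7, c - 6:c + 7] += a * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / 8.0)
    gradient = 1.0 + 0.3 * np.linspace(-1, 1, w)[None, :]
    field = make_image({"Synapsin1": img * gradient})
    out = correct_illumination(field, sigma_px=50)
    peaks = [out.pixels[0][r, c] for r, c in centers]
    assert peaks == sorted(peaks, reverse=True)


# ------------------------------------------------------ segmentation


def _ellipse_field(centers, radius=8, amp=600.0, shape=(256, 256)):
    from skimage.draw import ellipse

    img = np.full(shape, 100.0)
    for r, c in centers:
        rr, cc = ellipse(r, c, radius, radius, shape=shape)
        img[rr, cc] += amp
    return img


def test_disjoint_ellipses_all_segmented_live(rng):
    centers = [(r, c) for r in (40, 100, 160, 220) for c in (40, 100, 160)][:10]
    img = make_image({"Hoechst": _ellipse_field(centers)})
    records, labels = segment_nuclei(img)
    assert len(records) == 10
    assert all(r.cls == "live" for r in records)
    found = {tuple(np.round(r.centroid).astype(int)) for r in records}
    for ctr in centers:
        assert any(abs(f[0] - ctr[0]) <= 2 and abs(f[1] - ctr[1]) <= 2 for f in found)


def test_small_bright_object_classified_dead():
    centers = [(40, 40), (40, 120), (120, 40), (120, 120), (200, 120)]
    img = _ellipse_field(centers, radius=9, amp=600.0)
    from skimage.draw import ellipse

    rr, cc = ellipse(200, 40, 5, 5, shape=img.shape)  # small and 2.5x brighter
    img[rr, cc] += 1500.0
    records, _ = segment_nuclei(make_image({"Hoechst": img}))
    by_pos = {tuple(np.round(r.centroid).astype(int)): r.cls for r in records}
    dead = [cls for pos, cls in by_pos.items() if abs(pos[0] - 200) < 4 and abs(pos[1] - 40) < 4]
    assert dead == ["dead"]
    assert sum(1 for c in by_pos.values() if c == "live") == 5


def test_touching_nuclei_split_by_watershed():
    img = _ellipse_field([(100, 100), (100, 117)], radius=9)
    records, _ = segment_nuclei(make_image({"Hoechst": img}))
    assert len(records) == 2


def test_empty_image_yields_empty_list():
    img = make_image({"Hoechst": np.zeros((64, 64))})
    records, labels = segment_nuclei(img)
    assert records == [] and labels.sum() == 0


def test_segmentation_recall_precision_on_simulated_fields(tiny_nuclei_config):
    """Detection recall and precision >= 0.95 against generator truth."""
    tp = fp = fn = 0
    for i in range(8):
        img, truth = simulate_field(tiny_nuclei_config, "test", 400 + i)
        img = correct_illumination(img)
        records, _ = segment_nuclei(img)
        pred = np.array([r.centroid for r in records]) if records else np.empty((0, 2))
        true = np.array([n["center"] for n in truth.nuclei])
        used = set()
        matched = 0
        for t in true:
            if len(pred) == 0:
                break
            d = np.sqrt(np.sum((pred - t) ** 2, axis=1))
            d[list(used)] = np.inf
            j = int(np.argmin(d))
            if d[j] < 6.0:
                used.add(j)
                matched += 1
        tp += matched
        fn += len(true) - matched
        fp += len(pred) - matched
    assert tp / (tp + fn) >= 0.95
    assert tp / (tp + fp) >= 0.95


# ------------------------------------------------------ marker positivity


def _one_nucleus_setup(marker_px, nucleus_area=100):
    """32x32 field: one 10x10 nucleus, marker covering marker_px of it."""
    labels = np.zeros((32, 32), dtype=np.int32)
    labels[10:20, 10:20] = 1
    marker = np.zeros((32, 32))
    flat = np.argwhere(labels == 1)
    for r, c in flat[:marker_px]:
        marker[r, c] = 1000.0
    img = make_image({"Ki67": marker, "HuCD": marker.copy()})
    rec = NucleusRecord(1, nucleus_area, (14.5, 14.5), 500.0, "live")
    return [rec], labels, img


THRESH = {"ki67_threshold": 500.0, "hucd_threshold": 500.0}


def test_sixty_percent_overlap_positive_for_both_rules():
    nuclei, labels, img = _one_nucleus_setup(60)
    (rec,) = score_marker_positivity(nuclei, labels, img, THRESH)
    assert rec.ki67_positive and rec.hucd_positive
    assert rec.hucd_overlap_frac == pytest.approx(0.60)


def test_exact_threshold_overlap_is_negative():
    """'over 50%' / 'over 5%' are strict: exactly 50 px (or 5 px) of 100 fails."""
    nuclei, labels, img = _one_nucleus_setup(50)
    (rec,) = score_marker_positivity(nuclei, labels, img, THRESH)
    assert not rec.hucd_positive and rec.ki67_positive
    nuclei, labels, img = _one_nucleus_setup(5)
    (rec,) = score_marker_positivity(nuclei, labels, img, THRESH)
    assert not rec.ki67_positive


@pytest.mark.parametrize("marker_px", [0, 3, 17, 51, 99])
def test_overlap_fraction_equals_pixel_count_oracle(marker_px):
    nuclei, labels, img = _one_nucleus_setup(marker_px)
    (rec,) = score_marker_positivity(nuclei, labels, img, THRESH)
    mask = img.channel("Ki67") > 500.0
    brute = sum(1 for r in range(32) for c in range(32) if labels[r, c] == 1 and mask[r, c])
    assert rec.ki67_overlap_frac == pytest.approx(brute / 100)


def test_positivity_monotone_under_growing_marker_mask():
    """Growing the marker mask never flips a positive nucleus negative."""
    prev_pos = False
    for marker_px in range(0, 101, 7):
        nuclei, labels, img = _one_nucleus_setup(marker_px)
        (rec,) = score_marker_positivity(nuclei, labels, img, THRESH)
        if prev_pos:
            assert rec.hucd_positive
        prev_pos = rec.hucd_positive


def test_missing_marker_channel_leaves_fields_unset():
    labels = np.zeros((16, 16), dtype=np.int32)
    labels[4:8, 4:8] = 1
    img = make_image({"Ki67": np.zeros((16, 16))})
    rec = NucleusRecord(1, 16, (5.5, 5.5), 500.0, "live")
    (out,) = score_marker_positivity([rec], labels, img)
    assert out.hucd_positive is None
    assert out.ki67_positive is not None


# ------------------------------------------------------ ratios


def test_ratios_over_live_nuclei_only():
    recs = [NucleusRecord(i, 100, (0, 0), 1.0, "live", ki67_positive=(i == 0),
                          hucd_positive=False) for i in range(4)]
    recs.append(NucleusRecord(9, 10, (0, 0), 9.0, "debris", ki67_positive=True,
                              hucd_positive=True))
    ki, hu, n_live, n_dead, n_debris = compute_ratios(recs)
    assert ki == pytest.approx(0.25) and hu == 0.0
    assert (n_live, n_dead, n_debris) == (4, 0, 1)


def test_all_debris_flags_undefined_not_zero():
    recs = [NucleusRecord(i, 5, (0, 0), 1.0, "debris") for i in range(3)]
    ki, hu, n_live, *_ = compute_ratios(recs)
    assert math.isnan(ki) and math.isnan(hu) and n_live == 0


# ------------------------------------------------------ skeleton


def test_skeleton_length_straight_and_diagonal_lines():
    img = np.zeros((64, 128))
    img[32, 10:111] = 1000.0  # 101 px horizontal
    skel = skeletonize_neurites(make_image({"MAP2": img}), threshold=500,
                                closing_px=0, spur_min_px=0)
    assert skel.total_length_um == pytest.approx(100 * PX)

    img = np.zeros((128, 128))
    for i in range(101):
        img[10 + i, 10 + i] = 1000.0
    skel = skeletonize_neurites(make_image({"MAP2": img}), threshold=500,
                                closing_px=0, spur_min_px=0)
    assert skel.total_length_um == pytest.approx(100 * math.sqrt(2) * PX)


def test_skeleton_length_rotation_tolerance():
    """A rotated copy of the same bar yields length within 15%."""
    from skimage.transform import rotate

    img = np.zeros((160, 160))
    img[78:83, 20:141] = 1000.0
    lengths = []
    for angle in (0, 30):
        rot = rotate(img, angle, preserve_range=True)
        skel = skeletonize_neurites(make_image({"MAP2": rot}), threshold=500, spur_min_px=4)
        lengths.append(skel.total_length_um)
    assert abs(lengths[1] - lengths[0]) / lengths[0] < 0.15


def test_empty_map2_gives_zero_length():
    skel = skeletonize_neurites(make_image({"MAP2": np.zeros((64, 64))}))
    assert skel.total_length_um == 0.0 and not skel.mask.any()


def test_simulated_tree_length_within_10_percent(tiny_synapse_config):
    rel_err = []
    for i in range(4):
        img, truth = simulate_field(tiny_synapse_config, "paired_only", 50 + i)
        skel = skeletonize_neurites(img)
        rel_err.append(abs(skel.total_length_um - truth.skeleton_length_um)
                       / truth.skeleton_length_um)
    assert np.mean(rel_err) < 0.10


# ------------------------------------------------------ puncta


def _spot_field(centers, amp=400.0, sigma=1.8, shape=(200, 200), noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    img = np.full(shape, 100.0)
    for r, c in centers:
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
        img += amp * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma**2))
    if noise:
        img += rng.normal(0, noise, shape)
    return img


def test_clean_gaussians_detected_at_known_centroids():
    centers = [(20 + 35 * i, 20 + 35 * j) for i in range(5) for j in range(5)]
    img = make_image({"Synapsin1": _spot_field(centers)})
    found = detect_puncta(img, "Synapsin1", {"intensity_min": 100})
    assert len(found) == 25
    for p in found:
        assert min((p.centroid[0] - r) ** 2 + (p.centroid[1] - c) ** 2
                   for r, c in centers) < 1.0


def test_dim_spot_excluded_by_intensity_threshold():
    img = make_image({"Synapsin1": _spot_field([(50, 50)], amp=30.0)})
    assert detect_puncta(img, "Synapsin1", {"intensity_min": 100, "snr_min": 0}) == []


def test_puncta_detection_f1_at_snr8(tiny_synapse_config):
    """F1 >= 0.9 against generator truth with spot amplitude 8x the noise SD."""
    import copy

    cfg = copy.deepcopy(tiny_synapse_config)
    cfg["image_sim"]["puncta"]["amplitude"] = 8 * cfg["image_sim"]["noise_sd"]
    cfg["image_sim"]["puncta"]["amplitude_sd"] = 0.0
    tp = fp = fn = 0
    for i in range(4):
        img, truth = simulate_field(cfg, "paired_only", 900 + i)
        found = detect_puncta(img, "Synapsin1",
                              {"snr_min": 4, "intensity_min": 20})
        pred = np.array([p.centroid for p in found]) if found else np.empty((0, 2))
        true = truth.puncta["Synapsin1"]
        used = set()
        matched = 0
        for t in true:
            if len(pred) == 0:
                break
            d = np.sqrt(np.sum((pred - t) ** 2, axis=1))
            d[list(used)] = np.inf
            j = int(np.argmin(d))
            if d[j] < 3.0:
                used.add(j)
                matched += 1
        tp += matched
        fn += len(true) - matched
        fp += len(pred) - matched
    f1 = 2 * tp / (2 * tp + fp + fn)
    assert f1 >= 0.9


# ------------------------------------------------------ synapses


def _punctum(r, c, channel="Synapsin1", integ=1000.0):
    return Punctum(channel, (float(r), float(c)), 9, 500.0, integ, 10.0)


def _full_skeleton(shape=(64, 64)):
    from neuroscreen.imaging import SkeletonGraph

    return SkeletonGraph(np.ones(shape, bool), 0.0, 0.65)


def _line_skeleton(shape=(64, 64), row=32):
    from neuroscreen.imaging import SkeletonGraph

    mask = np.zeros(shape, bool)
    mask[row, :] = True
    return SkeletonGraph(mask, 0.0, 0.65)


def test_coplaced_pairs_all_called():
    syn = [_punctum(32, 10 + 8 * i) for i in range(5)]
    sh = [_punctum(32, 10 + 8 * i, "SHANK3") for i in range(5)]
    out = call_synapses(syn, sh, _line_skeleton())
    assert len(out) == 5
    assert all(s.distance_px == 0 for s in out)


def test_pair_off_skeleton_not_called():
    syn = [_punctum(10, 20)]
    sh = [_punctum(10, 20, "SHANK3")]
    assert call_synapses(syn, sh, _line_skeleton(row=40)) == []


def _max_matching_bruteforce(syn, sh, radius):
    """Exhaustive maximum-cardinality matching over candidate pairs."""
    cand = [(i, j) for i in range(len(syn)) for j in range(len(sh))
            if math.dist(syn[i].centroid, sh[j].centroid) <= radius]
    best = 0
    for k in range(len(cand), 0, -1):
        for combo in itertools.combinations(cand, k):
            if len({i for i, _ in combo}) == k and len({j for _, j in combo}) == k:
                return k
    return best


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5])
def test_greedy_matching_equals_bruteforce_count(seed):
    rng = np.random.default_rng(seed)
    n_a, n_b = rng.integers(3, 9, 2)
    syn = [_punctum(*rng.uniform(5, 59, 2)) for _ in range(n_a)]
    sh = [_punctum(*rng.uniform(5, 59, 2), "SHANK3") for _ in range(n_b)]
    greedy = len(call_synapses(syn, sh, _full_skeleton(), pairing_radius_px=8.0))
    assert greedy == _max_matching_bruteforce(syn, sh, 8.0)


def test_synapse_carries_shank3_integrated_intensity():
    syn = [_punctum(32, 20)]
    sh = [_punctum(33, 21, "SHANK3", integ=777.0)]
    (s,) = call_synapses(syn, sh, _line_skeleton())
    assert s.shank3_integrated_intensity == 777.0


# ------------------------------------------------------ colocalization


def test_coloc_identical_disjoint_and_pixel_oracle():
    a = np.zeros((20, 20))
    a[2:8, 2:8] = 1000.0
    img = make_image({"A": a, "B": a.copy()})
    assert coloc_fraction(img, "A", "B", {"A": 500, "B": 500}) == 1.0

    b = np.zeros((20, 20))
    b[12:18, 12:18] = 1000.0
    img = make_image({"A": a, "B": b})
    assert coloc_fraction(img, "A", "B", {"A": 500, "B": 500}) == 0.0

    rng = np.random.default_rng(3)
    a = (rng.random((20, 20)) < 0.4) * 1000.0
    b = (rng.random((20, 20)) < 0.5) * 1000.0
    img = make_image({"A": a, "B": b})
    got = coloc_fraction(img, "A", "B", {"A": 500, "B": 500})
    inter = sum(1 for r in range(20) for c in range(20) if a[r, c] > 500 and b[r, c] > 500)
    denom = sum(1 for r in range(20) for c in range(20) if a[r, c] > 500)
    assert got == pytest.approx(inter / denom)

    img = make_image({"A": np.zeros((20, 20)), "B": b})
    assert math.isnan(coloc_fraction(img, "A", "B", {"A": 500, "B": 500}))


# ------------------------------------------------------ aggregation


def test_aggregate_well_means_and_undefined_handling():
    fields = [
        {"ki67_ratio": 0.2, "hucd_ratio": 0.3, "n_live": 100},
        {"ki67_ratio": 0.3, "hucd_ratio": float("nan"), "n_live": 120},
    ]
    wf = aggregate_well(fields)
    assert wf.ki67_ratio == pytest.approx(0.25)
    assert wf.hucd_ratio == pytest.approx(0.3)
    assert wf.n_fields_used["ki67_ratio"] == 2
    assert wf.n_fields_used["hucd_ratio"] == 1
    assert math.isnan(aggregate_well([{}]).ki67_ratio)


def test_nine_field_well_equals_hand_mean(rng):
    ratios = rng.uniform(0.1, 0.4, 9)
    wf = aggregate_well([{"ki67_ratio": r} for r in ratios])
    assert wf.ki67_ratio == pytest.approx(ratios.mean())
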