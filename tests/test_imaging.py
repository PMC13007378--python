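"""Segmentation, nucleus detection, Jaccard statistic and group comparison."""

import numpy as np
import pytest

from ttnvar.imaging import (JaccardRecord, SegmentationConfig, analyze_image,
                            compare_groups, detect_nuclei, jaccard, segment)
from ttnvar.synthetic import ImageConfig, gen_cell_images


def _disk_image(radius=12, shape=(96, 96), lo=5.0, hi=100.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    img = np.full(shape, lo)
    disk = (yy - shape[0] / 2) ** 2 + (xx - shape[1] / 2) ** 2 <= radius ** 2
    img[disk] = hi
    return img, disk


# ---------------------------------------------------------------------------
# jaccard
# ---------------------------------------------------------------------------

def test_jaccard_identity_disjoint_and_partial():
    a = np.zeros((10, 10), bool); a[:5] = True
    b = np.zeros((10, 10), bool); b[5:] = True
    assert jaccard(a, a) == 1.0
    assert jaccard(a, b) == 0.0
    # |a|=|b|=100 with overlap 50 -> 50/150
    a = np.zeros((20, 20), bool); a.flat[:100] = True
    b = np.zeros((20, 20), bool); b.flat[50:150] = True
    assert jaccard(a, b) == pytest.approx(50 / 150)


def test_jaccard_symmetry_and_empty_union():
    rng = np.random.default_rng(0)
    a = rng.random((30, 30)) > 0.5
    b = rng.random((30, 30)) > 0.5
    assert jaccard(a, b) == jaccard(b, a)
    z = np.zeros((30, 30), bool)
    assert jaccard(z, z) == 0.0


def test_jaccard_monotone_under_shared_pixels():
    a = np.zeros((10, 10), bool); a[2:6, 2:6] = True
    b = np.zeros((10, 10), bool); b[4:8, 4:8] = True
    j0 = jaccard(a, b)
    a2, b2 = a.copy(), b.copy()
    a2[0, 0] = b2[0, 0] = True   # add one shared pixel
    assert jaccard(a2, b2) > j0


def test_jaccard_shape_mismatch():
    with pytest.raises(ValueError):
        jaccard(np.zeros((4, 4), bool), np.zeros((5, 5), bool))


# ---------------------------------------------------------------------------
# segmentation and nucleus detection
# ---------------------------------------------------------------------------

def test_blank_image_raises_no_foreground():
    with pytest.raises(ValueError, match="no foreground"):
        segment(np.zeros((64, 64)))


def test_uniform_cell_masks():
    img, disk = _disk_image()
    res = segment(img, SegmentationConfig(sigma_cell=2, sigma_nuclear=1))
    # cell mask recovers the disk
    assert jaccard(res.cell_mask, disk) > 0.85
    # bright mask is roughly the top decile of in-cell pixels
    frac = res.bright_mask.sum() / res.cell_mask.sum()
    assert 0.03 < frac < 0.35


def test_single_disk_component_detected_as_nucleus():
    img, disk = _disk_image(radius=10)
    res = segment(img, SegmentationConfig(sigma_cell=2, sigma_nuclear=1))
    res.bright_mask = disk          # a clean disk: roundness ~ 1
    mask = detect_nuclei(res, area_range=(50, 5000), roundness_min=0.6)
    assert mask.sum() == disk.sum()
    assert len(res.nuclei) == 1 and res.nuclei[0]["roundness"] > 0.85


def test_small_puncta_rejected_by_area():
    img, _ = _disk_image()
    res = segment(img, SegmentationConfig(sigma_cell=2, sigma_nuclear=1))
    scatter = np.zeros_like(res.bright_mask)
    for y, x in [(10, 10), (20, 50), (70, 30)]:
        scatter[y:y + 2, x:x + 2] = True    # 4-px puncta, below area range
    res.bright_mask = scatter
    assert detect_nuclei(res, area_range=(80, 5000)).sum() == 0


def test_synthetic_nucleus_contained_in_bright_mask():
    scenes = gen_cell_images(ImageConfig(seed=9, n_images=5), "diffuse_nuclear")
    for img, truth in scenes:
        res = segment(img)
        overlap = (res.bright_mask & truth["nucleus_mask"]).sum()
        assert overlap / truth["nucleus_mask"].sum() >= 0.9


def test_detected_nucleus_matches_ground_truth():
    scenes = gen_cell_images(ImageConfig(seed=10, n_images=5), "diffuse_nuclear")
    for img, truth in scenes:
        res = segment(img)
        detect_nuclei(res)
        inter = (res.nuclear_mask & truth["nucleus_mask"]).sum()
        union = (res.nuclear_mask | truth["nucleus_mask"]).sum()
        assert inter / union >= 0.8


def test_pipeline_is_deterministic():
    img, _ = gen_cell_images(ImageConfig(seed=4, n_images=1), "punctate")[0]
    r1 = analyze_image(img)
    r2 = analyze_image(img)
    assert r1.jaccard == r2.jaccard


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def _records(values, group):
    return [JaccardRecord(str(i), v, group) for i, v in enumerate(values)]


def test_identical_groups_give_null_t():
    wt = _records([0.3, 0.4, 0.5], "WT")
    var = _records([0.3, 0.4, 0.5], "variant")
    res = compare_groups(wt, var)
    assert res["t"] == pytest.approx(0.0)
    assert res["p"] == pytest.approx(1.0)


def test_groups_of_one_are_rejected():
    with pytest.raises(ValueError):
        compare_groups(_records([0.5], "WT"), _records([0.1, 0.2], "variant"))


def test_diffuse_vs_punctate_separation():
    cfg = ImageConfig(seed=21, n_images=12)
    wt = [analyze_image(im, group="WT")
          for im, _ in gen_cell_images(cfg, "diffuse_nuclear")]
    var = [analyze_image(im, group="variant")
           for im, _ in gen_cell_images(cfg, "punctate")]
    res = compare_groups(wt, var)
    assert res["mean_wt"] > res["mean_variant"]
    assert res["p"] < 0.05 and res["t"] > 0
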