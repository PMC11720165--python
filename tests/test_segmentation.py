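"""Thresholding, nucleus/cell segmentation and border exclusion."""
import logging

import numpy as np
import pytest

import fociquant as fq
from fociquant.simulate import FieldConfig, generate_field, match_labels, _ellipse_mask


# ---------------------------------------------------------------- threshold
def _cross_entropy(values, t):
    """Li & Lee cross-entropy objective (up to the data-entropy constant)."""
    lo, hi = values[values <= t], values[values > t]
    if lo.size == 0 or hi.size == 0:
        return np.inf
    return -(lo.sum() * np.log(lo.mean()) + hi.sum() * np.log(hi.mean()))


def _exhaustive_li(values):
    cands = np.unique(values)[:-1]  # thresholds between consecutive values
    objs = [_cross_entropy(values, t) for t in cands]
    return cands[int(np.argmin(objs))]


def test_li_threshold_constant_image_raises():
    with pytest.raises(fq.DegenerateImageError):
        fq.li_threshold(np.full((10, 10), 42.0))


def test_li_threshold_two_valued_image_matches_exhaustive_search():
    img = np.concatenate([np.full(50, 10.0), np.full(50, 100.0)]).reshape(10, 10)
    t = fq.li_threshold(img)
    assert 10 < t < 100
    t_oracle = _exhaustive_li(img.ravel())
    # identical binarization as the exhaustive cross-entropy minimizer
    assert np.array_equal(img > t, img > t_oracle)


def test_li_threshold_separates_bimodal_gaussians():
    rng = np.random.default_rng(42)
    lo = rng.normal(20, 5, 5000)
    hi = rng.normal(200, 5, 5000)
    img = np.concatenate([lo, hi]).reshape(100, 100)
    t = fq.li_threshold(img)
    truth = np.concatenate([np.zeros(5000, bool), np.ones(5000, bool)])
    miscls = (truth != (img.ravel() > t)).mean()
    assert miscls < 0.01
    # and the threshold agrees with the exhaustive objective's binarization
    t_oracle = _exhaustive_li(img.ravel())
    assert (truth != (img.ravel() > t_oracle)).mean() < 0.01


# ------------------------------------------------------------------- nuclei
def test_blank_image_gives_empty_mask():
    labels = fq.segment_nuclei(np.zeros((64, 64)))
    assert labels.max() == 0


def test_two_disjoint_ellipses_recovered_with_areas():
    img = np.zeros((128, 128))
    m1 = _ellipse_mask((128, 128), 40, 40, 12, 10)
    m2 = _ellipse_mask((128, 128), 90, 90, 10, 13)
    img[m1] = 300.0
    img[m2] = 300.0
    labels = fq.segment_nuclei(img)
    found = np.unique(labels)[1:]
    assert len(found) == 2
    areas = sorted(int((labels == lab).sum()) for lab in found)
    expected = sorted([int(m1.sum()), int(m2.sum())])
    for got, exp in zip(areas, expected):
        assert got == pytest.approx(exp, rel=0.02)


def test_touching_nuclei_split_by_watershed():
    img = np.zeros((128, 128))
    img[_ellipse_mask((128, 128), 60, 50, 11, 11)] = 300.0
    img[_ellipse_mask((128, 128), 60, 70, 11, 11)] = 300.0  # thin shared neck
    labels = fq.segment_nuclei(img)
    assert len(np.unique(labels)) - 1 == 2


def test_nucleus_count_recovered_across_seeds():
    """Interior nucleus count matches ground truth in >= 95% of 20 seeds at
    low noise (<= 5% of the DAPI signal)."""
    hits = 0
    for seed in range(20):
        cfg = FieldConfig(width=256, height=256, n_cells=9, p_border=0.0,
                          noise_sd=7.0, seed=seed)
        stack, truth = generate_field(cfg)
        labels = fq.segment_nuclei(stack.channel("dna"))
        hits += (len(np.unique(labels)) - 1) == len(truth.cells)
    assert hits >= 19


# -------------------------------------------------------------------- cells
def test_single_cell_covers_rendered_ellipse():
    cfg = FieldConfig(width=160, height=160, n_cells=1, p_border=0.0,
                      p_transfected=0.0, noise_sd=5.0, seed=2)
    stack, truth = generate_field(cfg)
    nuclei = fq.segment_nuclei(stack.channel("dna"))
    cells = fq.segment_cells(stack.channel("f_actin"), nuclei)
    assert len(np.unique(cells)) - 1 == 1
    lab = np.unique(cells)[1]
    rendered = int((truth.cell_labels > 0).sum())
    assert int((cells == lab).sum()) == pytest.approx(rendered, rel=0.05)


def test_cells_partition_and_contain_their_nucleus(analyzed_field):
    _stack, _truth, bundle = analyzed_field
    cells = bundle["masks"]["cells"]
    nuclei = bundle["masks"]["nuclei"]
    nz = nuclei > 0
    # nucleus pixels carry the same label in the cell mask
    assert np.array_equal(cells[nz], nuclei[nz])
    # one nucleus per cell, same label set
    assert set(np.unique(cells)) == set(np.unique(nuclei))


def test_nucleus_in_dark_field_falls_back_to_nucleus(caplog):
    nuclei = np.zeros((64, 64), dtype=np.int32)
    nuclei[_ellipse_mask((64, 64), 32, 32, 10, 10)] = 1
    factin = np.zeros((64, 64))
    with caplog.at_level(logging.WARNING, logger="fociquant.segmentation"):
        cells = fq.segment_cells(factin, nuclei)
    assert np.array_equal(cells, nuclei)
    assert any("no surrounding" in rec.message for rec in caplog.records)


# ------------------------------------------------------------------- border
def test_interior_cell_retained_and_corner_cell_removed():
    cells = np.zeros((32, 32), dtype=np.int32)
    nuclei = np.zeros((32, 32), dtype=np.int32)
    cells[10:15, 10:15] = 1
    nuclei[11:14, 11:14] = 1
    cells[0:4, 0:4] = 2          # one corner pixel on row 0 / column 0
    nuclei[1:3, 1:3] = 2
    out_c, out_n = fq.exclude_border(cells, nuclei)
    assert set(np.unique(out_c)) == {0, 1}
    assert set(np.unique(out_n)) == {0, 1}
    assert np.array_equal(out_c == 1, cells == 1)  # labels preserved


def test_generator_border_cells_are_excluded(analyzed_field):
    _stack, truth, bundle = analyzed_field
    label_map = bundle["label_map"]
    retained_gt = {label_map.get(int(lab), 0)
                   for lab in np.unique(bundle["masks"]["cells"]) if lab > 0}
    border_gt = set(truth.cells.loc[truth.cells.border_touching, "cell_id"])
    interior_gt = set(truth.cells.loc[~truth.cells.border_touching, "cell_id"])
    assert retained_gt & border_gt == set()
    assert retained_gt == interior_gt
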