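"""The generator's ground truth must match its rendered pixels."""
import numpy as np
import pytest

import fociquant as fq
from fociquant.simulate import FieldConfig, generate_field


def test_empty_field_renders_background_only():
    stack, truth = generate_field(FieldConfig(n_cells=0, noise_sd=0.0, seed=3))
    assert stack.pixels.sum() == 0
    assert truth.cells.empty and truth.nodules.empty
    assert truth.cell_labels.max() == 0


def test_same_seed_is_bit_identical():
    cfg = dict(n_cells=20, include_polii=True, include_edu=True, seed=7)
    s1, t1 = generate_field(FieldConfig(**cfg))
    s2, t2 = generate_field(FieldConfig(**cfg))
    assert np.array_equal(s1.pixels, s2.pixels)
    assert t1.cells.equals(t2.cells)
    assert t1.nodules.equals(t2.nodules)


@pytest.mark.parametrize("bad", [
    dict(p_transfected=1.5), dict(ha_nuclear_fraction=-0.1),
    dict(n_cells=-1), dict(width=0), dict(noise_sd=-1),
    dict(nodule_rho=2.0), dict(phase_fractions=(0.5, 0.5, 0.5)),
])
def test_invalid_config_rejected(bad):
    with pytest.raises(fq.ConfigurationError):
        generate_field(FieldConfig(**bad))


def test_transfected_cells_have_brighter_ha_by_pixel_mean():
    """Brute-force per-mask pixel means: HA in transfected cells exceeds HA
    in untransfected cells, and the flags match the rendered contrast."""
    cfg = FieldConfig(n_cells=20, p_transfected=0.5, seed=1)
    stack, truth = generate_field(cfg)
    ha = stack.channel("ha")
    means = {}
    for _, row in truth.cells.iterrows():
        mask = truth.cell_labels == row.cell_id
        means[row.cell_id] = ha[mask].sum() / mask.sum()  # brute-force mean
    tf = truth.cells[truth.cells.transfected].cell_id
    utf = truth.cells[~truth.cells.transfected].cell_id
    assert len(tf) > 0 and len(utf) > 0
    assert min(means[c] for c in tf) > max(means[c] for c in utf)


def test_rendered_nuclear_fraction_matches_config():
    """Noise-free nuclear HA over whole-cell HA equals the configured
    fraction within +/-0.02 for every transfected cell."""
    for target in (0.2, 0.5, 0.8):
        cfg = FieldConfig(n_cells=30, p_transfected=0.5, p_nodule=0.5,
                          ha_nuclear_fraction=target,
                          ha_nuclear_fraction_sd=0.0, seed=21)
        _stack, truth = generate_field(cfg)
        clean_ha = truth.clean["ha"]
        tf = truth.cells[truth.cells.transfected]
        assert len(tf) >= 5
        for _, row in tf.iterrows():
            nuc = truth.nucleus_labels == row.cell_id
            cell = truth.cell_labels == row.cell_id
            frac = clean_ha[nuc].sum() / clean_ha[cell].sum()
            assert frac == pytest.approx(target, abs=0.02)


def test_nodule_correlation_endpoints():
    """rho=1 gives an affine relation (r == 1) on noise-free nodule pixels;
    rho=0 gives |r| < 0.2 on >= 100 pooled pixels."""
    cfg1 = FieldConfig(n_cells=30, p_transfected=0.6, p_nodule=1.0,
                       nodule_rho=1.0, noise_sd=0.0, seed=5)
    _s, truth = generate_field(cfg1)
    ha, fa = truth.clean["ha"], truth.clean["f_actin"]
    for nodule_id in truth.nodules.nodule_id:
        px = truth.nodule_pixels(nodule_id)
        r = np.corrcoef(ha[px], fa[px])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    cfg0 = FieldConfig(n_cells=30, p_transfected=0.6, p_nodule=1.0,
                       nodule_rho=0.0, noise_sd=0.0, seed=6)
    _s, truth0 = generate_field(cfg0)
    px = truth0.nodule_labels > 0
    assert px.sum() >= 100
    r = np.corrcoef(truth0.clean["ha"][px], truth0.clean["f_actin"][px])[0, 1]
    assert abs(r) < 0.2


def test_factin_scale_multiplies_nuclear_factin_exactly():
    base = dict(n_cells=20, p_transfected=0.4, seed=9, noise_sd=0.0)
    _s1, t1 = generate_field(FieldConfig(**base, factin_scale=1.0))
    _s2, t2 = generate_field(FieldConfig(**base, factin_scale=0.7))
    nuc = t1.nucleus_labels > 0
    i1 = t1.clean["f_actin"][nuc].sum()
    i2 = t2.clean["f_actin"][t2.nucleus_labels > 0].sum()
    assert i2 / i1 == pytest.approx(0.7, rel=1e-12)


def test_mask_containment_and_label_uniqueness(default_field):
    _cfg, _stack, truth = default_field
    assert not ((truth.nucleus_labels > 0) & (truth.cell_labels == 0)).any()
    assert not ((truth.nodule_labels > 0) & (truth.nucleus_labels == 0)).any()
    # nodule pixels lie inside their parent cell's nucleus
    for _, row in truth.nodules.iterrows():
        px = truth.nodule_labels == row.nodule_id
        assert (truth.nucleus_labels[px] == row.cell_id).all()
    ids = truth.cells.cell_id
    assert ids.is_unique and truth.nodules.nodule_id.is_unique


def test_border_cells_touch_the_border(default_field):
    _cfg, _stack, truth = default_field
    flagged = truth.cells[truth.cells.border_touching].cell_id
    assert len(flagged) > 0
    edge = np.zeros_like(truth.cell_labels, dtype=bool)
    edge[0] = edge[-1] = True
    edge[:, 0] = edge[:, -1] = True
    on_edge = set(np.unique(truth.cell_labels[edge])) - {0}
    assert set(flagged) == on_edge
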