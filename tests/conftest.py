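import numpy as np
import pandas as pd
import pytest

import fociquant as fq
from fociquant.simulate import match_labels


@pytest.fixture(scope="session")
def default_field():
    """One standard synthetic field with all optional channels."""
    cfg = fq.FieldConfig(n_cells=40, p_transfected=0.3, include_polii=True,
                         include_edu=True, seed=11)
    stack, truth = fq.generate_field(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def analyzed_field(default_field):
    """The standard field pushed through the single-field analysis, with the
    segmentation-to-truth label mapping attached."""
    _cfg, stack, truth = default_field
    run = fq.RunConfig(simulate={}, output_dir="unused")
    bundle = fq.analyze_field(stack, run, image_id="fixture")
    bundle["label_map"] = match_labels(bundle["masks"]["nuclei"],
                                       truth.nucleus_labels)
    return stack, truth, bundle


def truth_lookup(truth, label_map, cell_ids, column):
    """Ground-truth values for segmented cell ids via the overlap mapping."""
    gt = truth.cells.set_index("cell_id")[column]
    return pd.Series([gt.get(label_map.get(int(c), 0), np.nan)
                      for c in cell_ids], index=pd.RangeIndex(len(cell_ids)))
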