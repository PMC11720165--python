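"""Detect intranuclear nodules and compute nodule-restricted Pearson r.

Restricting the correlation to nodule pixels avoids inflation from jointly
dark nucleoplasm: with the generator set to rho=0.9 the per-cell r comes
back near 0.9, while rho=0.0 (emulating a non-colocalizing mutant) gives r
scattered around 0.
"""
import pandas as pd

import fociquant as fq

for rho in (0.9, 0.0):
    frames = []
    for i in range(2):
        cfg = fq.FieldConfig(n_cells=30, p_transfected=0.3, p_nodule=1.0,
                             nodules_per_cell=2, nodule_rho=rho, seed=5 + i)
        stack, truth = fq.generate_field(cfg)
        run = fq.RunConfig(simulate={}, output_dir="unused")
        frames.append(fq.analyze_field(stack, run)["nodule_coloc"])
    coloc = pd.concat(frames, ignore_index=True)
    print(f"generator rho={rho}: {len(coloc)} cells with nodules, "
          f"mean per-cell Pearson r = {coloc.pearson_r.mean():.3f} "
          f"(sd {coloc.pearson_r.std():.3f})")

# Each r pools all nodule pixels of one cell (one dot per cell); values are
# invariant to affine rescaling of either channel.
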