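"""Segment nuclei and cells, exclude border cells, and measure intensities.

Mirrors the measurement stage of a CellProfiler-style workflow: minimum
cross-entropy (Li) thresholding for nuclei and cell foreground, seeded
watershed propagation for cell bodies, then per-cell integrated/mean
intensities per compartment.
"""
import numpy as np

import fociquant as fq

stack, truth = fq.generate_field(fq.FieldConfig(n_cells=25, seed=7))

dna, factin, ha = (stack.channel(r) for r in ("dna", "f_actin", "ha"))
nuclei = fq.segment_nuclei(dna)
cells = fq.segment_cells(factin, nuclei)
cells, nuclei = fq.exclude_border(cells, nuclei)

df = fq.measure_field({"dna": dna, "f_actin": factin, "ha": ha}, cells, nuclei)
df["ha_nuclear_fraction"] = fq.nuclear_fraction(df, "ha")

print(f"nuclei found: {len(np.unique(nuclei)) - 1} "
      f"(ground truth interior: {int((~truth.cells.border_touching).sum())})")
print(df[["cell_id", "nucleus_area", "cell_area",
          "ha_cell_mean", "ha_nuclear_fraction"]].head())

# nucleus_area + cytoplasm_area == cell_area and integrated == mean * area
# hold exactly; the HA whole-cell mean cleanly separates the transfected
# population (hundreds of counts) from the untransfected baseline (~30).
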