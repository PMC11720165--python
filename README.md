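# fociquant

Quantitative confocal image analysis of intranuclear protein foci —
built for the kind of experiment where U2OS cells are transfected with an
HA-tagged actin nucleation-promoting factor (N-WASP and its mutants),
stained for DNA (DAPI), F-actin (phalloidin) and the tag, and the question
is how much of the protein sits in the nucleus, whether its intranuclear
nodules colocalize with nuclear F-actin, and how RNA Pol II clustering and
the cell cycle relate to it.

The package is a library first (import `fociquant`, see `examples/`), with
a thin `fociquant` CLI for end-to-end runs, and ships a synthetic-field
generator with full ground truth so every stage is validated without any
microscope data.

## What it computes

Given multi-channel fields (TIFF; z-stacks reduced to the plane of largest
nuclear area):

* **Segmentation** — nuclei from DAPI and cell bodies from phalloidin via
  minimum cross-entropy (Li) thresholding; touching nuclei split by
  distance-transform watershed; cell foreground partitioned among nucleus
  seeds by intensity-guided propagation; border-touching cells excluded.
* **Transfection classification** — a cell is transfected (TF) when its
  whole-cell mean HA exceeds median + k·MAD of the field (default k = 3);
  untransfected cells (UTF) provide the per-image background that is
  subtracted from TF compartment means, and the baseline for normalization.
* **Per-cell quantification** — integrated and mean intensity per channel
  and compartment; the **nuclear fraction**
  `NF = I_nuc(HA) / I_cell(HA)`; DAPI and phalloidin values of TF cells
  normalized to the UTF mean.
* **Nodule colocalization** — intranuclear HA nodules (intensity outliers
  over the nuclear background, median + 4·MAD, ≥15 px) and the Pearson
  correlation of HA vs a second channel **restricted to nodule pixels**,
  pooled per cell: `r = Σ(a−ā)(b−b̄) / √(Σ(a−ā)² Σ(b−b̄)²)`.
* **RNA Pol II clusters** — per-nucleus count, mean size, integrated and
  mean intensity of nuclear puncta, each divided by the UTF population
  mean.
* **Cell-cycle gating** — integrated DAPI (2N/4N modes, ±25% windows) ×
  mean EdU (median + 3·MAD cutoff; EdU⁺ ⇒ S) assigns G1/S/G2-M; plus the
  R² of nuclear fraction vs DNA content.
* **Statistics** — two-tailed Student t-test (2 groups), one-way ANOVA with
  Tukey HSD (≥3 groups), stars: ns p ≥ 0.05, \* <0.05, \*\* <0.01,
  \*\*\* <0.001, \*\*\*\* <0.0001.

## Worked example

```bash
python examples/03_nodule_colocalization.py
```

prints (exactly; the run is seeded):

```
generator rho=0.9: 14 cells with nodules, mean per-cell Pearson r = 0.901 (sd 0.023)
generator rho=0.0: 14 cells with nodules, mean per-cell Pearson r = 0.045 (sd 0.151)
```

Two synthetic conditions are generated, segmented and classified, nodules
are detected in the transfected nuclei, and the nodule-restricted Pearson
coefficient against F-actin is computed per cell. With the generator's
nodule correlation set to 0.9 (a colocalizing construct) the pipeline
recovers r ≈ 0.90; with 0.0 (a non-colocalizing mutant) it recovers r ≈ 0
— the qualitative contrast the analysis is designed to resolve. The other
examples cover simulation, measurement, gating, cluster metrics and group
statistics, one capability each.

End-to-end from a shell:

```bash
fociquant all --seed 1 --out run_out       # simulate + analyze + tables
fociquant analyze --config cfg.yaml field.tif --role dna=0 --role f_actin=1 --role ha=2
fociquant stats run_out/cells.csv --value ha_nuclear_fraction --group-by phase
```

Outputs are CSV tables (`cells.csv`, `nodules.csv`, `nodule_coloc.csv`,
`clusters.csv`, `phase_summary.csv`, `stats.csv`), 16-bit label-mask TIFFs
and a YAML manifest; identical config + seed reproduces identical CSVs.

## Layout

```
src/fociquant/      simulate, io, segmentation, classify, quantify,
                    nodules, clusters, cellcycle, stats, pipeline, cli
examples/           one narrative script per capability
tests/              unit + property tests and the acceptance suite
docs/methods.md     models, parameters, design choices, limitations
scripts/acceptance.py
```
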