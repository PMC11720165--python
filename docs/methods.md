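# Methods

## Scope and conventions

`fociquant` quantifies multi-channel fluorescence fields of sparse adherent
cells. Images are arrays indexed `[z, channel, y, x]`, 0-based, `(y, x)`
pixel order; label masks use 0 for background and keep their labels after
filtering so they remain join keys across all tables. All quantification
runs on a single z-plane: for stacks, the slice whose segmented nuclear
area is largest ("central plane of the nucleus"), ties broken toward the
lower index. Measuring on the central plane rather than a projection is an
interpretation choice; 3-D measurement is out of scope.

## Segmentation

* **Thresholding.** "Minimum cross-entropy" thresholding in the Li & Lee
  iterative formulation, via `skimage.filters.threshold_li`. A constant
  image raises a degenerate-input error; the returned threshold lies
  strictly between the image extrema. The unit tests check the result
  against an exhaustive search over the cross-entropy objective.
* **Nuclei.** Li threshold on the DNA channel → hole filling → distance
  transform → watershed from `peak_local_max` peaks (`min_distance` 10 px)
  to split touching nuclei → 8-connected labeling → area filter
  (defaults 200–20 000 px at the synthetic scale).
* **Cells.** Foreground = Li threshold of the phalloidin channel; each
  foreground pixel is assigned to the nucleus seed reached by
  intensity-guided watershed propagation (bright pixels claimed first, so
  boundaries fall along intensity minima between cells). Cells therefore
  partition the foreground and always contain their nucleus; a nucleus
  with no surrounding foreground keeps `cell = nucleus` with a logged
  warning.
* **Border exclusion.** Any cell with a pixel on the first/last row or
  column is removed together with its nucleus, without relabeling.

## Classification and background correction

Per-cell whole-cell mean HA is compared to `median + k·MAD` of the field
(raw MAD, no 1.4826 scaling; `k = 3`). The rule is scale-equivariant and
robust to the transfected tail, but it presumes a transfected *minority*:
when a field happens to contain ≥50% transfected cells the median migrates
into the transfected population and recall collapses (precision is
unaffected — the cutoff always clears the tight untransfected band). At
the default 30% transfection rate such fields are rare binomial outliers;
the classification guarantee is therefore stated over a 20-seed suite, not
per field. Fields with fewer than 3 cells are flagged all-untransfected
with a warning; a field with no untransfected cell raises an error because
it lacks a baseline.

Background correction subtracts, per compartment (nucleus, cytoplasm), the
untransfected-cell average of the compartment *mean* intensity, floors at
0, and recomputes integrated = corrected mean × area. Subtracting means
(not integrals) is an interpretation; both are exposed in the table.
UTF averaging is per image by default ("within the picture"), with an
optional grouping key for per-experiment pooling.

## Quantification

Integrated intensity is the exact sum over a pixel set; mean = sum/area;
`nucleus_area + cytoplasm_area = cell_area` holds exactly by construction
of the compartment masks. The nuclear fraction divides nuclear by
whole-cell integrated intensity of the same channel and is undefined
(missing, never 0) when the whole-cell signal is not positive; missing
values propagate as missing through group statistics. Normalization
divides by the untransfected mean, so untransfected cells have expected
normalized value 1. Both statistics are invariant to positive rescaling of
the channel.

## Nodules, clusters and restricted correlation

Nodules and clusters share one detector: pixels of the nuclear region
brighter than `median + k·MAD` of the in-region intensities, 8-connected,
minimum area applied. Defaults: nodules on the HA channel `k = 4`,
min 15 px; Pol II clusters `k = 3`, min 5 px. The criterion (an intensity
outlier over the nuclear background) is this package's own, since
fluorescence nodule detection has no canonical parameterization; all three
constants are configuration keys. Nodules are detected on the HA channel
only; the second channel is read through the correlation.

The colocalization statistic is Pearson's product-moment correlation over
exactly the nodule pixel set — mean-centering makes it independent of
signal level and background, and the restriction avoids inflation from
jointly dark nucleoplasm. Per cell, the pixels of all nodules are pooled
(one value per cell) rather than averaging per-nodule r. Undefined cases
(<3 pixels, constant channel) are missing values. Cluster metrics per
nucleus: count, mean component area ("size" read as mean area in px;
total area available by configuration), integrated intensity over the
cluster-pixel union, and mean = integrated/union area; size and mean
intensity are missing when the count is 0. Normalized variants divide by
the untransfected population mean per image.

## Cell-cycle gating

Per-cell integrated DAPI is histogrammed (128 bins, Gaussian-smoothed
σ = 2 bins, zero-padded so edge modes count); the highest peak is the 2N
mode and the peak nearest twice it is 4N (no such peak → gate-fitting
error). Windows are mode × [0.75, 1.25]. The EdU cutoff is
`median + 3·MAD` of the EdU means of the lower-DAPI half (the presumed
EdU-negative set). Assignment: EdU above cutoff → S (precedence, EdU being
the S marker); otherwise the DNA-content windows give G1/G2-M; cells
matching no gate are reported `unclassified`, never dropped. The procedure
replaces interactive scatter-plot gating with a deterministic,
scale-invariant rule; every constant is a parameter. R² is the squared
Pearson correlation of nuclear fraction vs integrated DAPI.

## Statistics

Two groups: classical two-tailed Student t-test with pooled variance
(Welch behind a flag). Three or more: one-way ANOVA, then Tukey HSD on the
pooled within-group mean square; unbalanced groups use the Tukey–Kramer
harmonic-mean correction (statsmodels' studentized-range implementation).
The monotonicity guarantee — adjusted p ≥ unadjusted p — is stated against
the pairwise t-test *from the same pooled-MSE model*; a two-group-only
t-test uses a different error term and can legitimately exceed the Tukey
p. Stars follow the ns/*/**/***/**** convention with half-open boundaries
(p = 0.05 is ns). Identical constant groups return the p = 1 convention.

## Synthetic fields

The generator renders what the analysis needs to be tested against, not
photorealism (no PSF, no chromatic aberration, no 3-D):

* **Geometry.** Axis-aligned elliptical cells (semi-axes 16–21 px) with a
  concentric elliptical nucleus (10–13 px), placed on a jittered grid
  whose pitch exceeds the cell diameter, so cells never overlap. A
  configurable fraction (`p_border`, default 0.1) is centered 8 px from an
  edge to exercise border exclusion. Default field 512×512 px, 30 cells.
* **DAPI.** Per-pixel level chosen so integrated nuclear DAPI is
  proportional to DNA content and independent of the drawn nucleus area:
  2N in G1, 4N in G2/M, uniform 1.1–1.9× in S. Phase weights default to
  (0.5, 0.3, 0.2).
* **Phalloidin.** Cytoplasm 150 counts/px; the entire nuclear pool
  (80 counts/px baseline plus nodule additions) is multiplied by
  `factin_scale`, so scaling it by s scales noise-free nuclear integrated
  F-actin by exactly s — the lever for two-arm inhibitor designs.
* **HA.** Untransfected cells carry a faint uniform 30 counts/px.
  Transfected cells (Bernoulli `p_transfected`, default 0.3) get an
  integrated budget (4×10⁵ × lognormal(0, 0.25) scatter) split between
  nucleus and cytoplasm to realize the per-cell target nuclear fraction
  (mean `ha_nuclear_fraction`, per-cell sd 0.05 as biological scatter, or
  a phase-dependent map). Nodule draws are charged against the nuclear
  budget (rescaled if they would exceed 80% of it), so the rendered
  fraction equals the target exactly before noise.
* **Nodules.** Disc-shaped (radius 2.5–3.6 px), disjoint with ≥1 px
  separation, inside the nucleus. Per-pixel HA and F-actin additions come
  from a bivariate Gaussian (means 1500/800, sd 200, clipped at 0) with
  the requested correlation `nodule_rho`; the realized sample correlation
  is recorded in the truth table. Very small nuclei can fit fewer than the
  requested `nodules_per_cell`; the truth table records what was placed.
* **Pol II / EdU.** Optional channels: Poisson-distributed puncta
  (radius 1.7–2.2 px, ~600 counts over a 50 count nucleoplasm), with a
  multiplier on the expectation in transfected cells; geometric packing
  caps the count at roughly 7 per nucleus, so doubling designs should use
  expectations ≲3. EdU nuclei render at 400 (S) vs 20 (non-S) counts/px.
* **Noise.** Additive Gaussian (`noise_sd`, default 10 counts ≈ 1–7% of
  the signals), clipped and rounded to uint16. Poisson noise, uneven
  illumination and bleed-through are not modeled — passing tests show the
  estimators are correct and well-calibrated on clean geometry, not that
  segmentation is robust to real-world artifacts.

One `numpy.random.default_rng(seed)` stream drives everything, so a
configuration is bit-reproducible.

## Validation design and problem sizes

The validation suite (tests/, reproduced by `scripts/acceptance.py`) runs
at desk scale: 20-field suites of 40–54 cells for classification, gating
and the null analyses; 4 fields × 50 cells per nuclear-fraction setting;
1000 simulations for test calibration; 40 seeds for the per-seed
phase-ANOVA null, where the binomial noise of a 5%-level test over a
20-seed suite would otherwise dominate the ≥90% non-significance summary.
The two-arm treatment recovery uses common random numbers — both arms share
their field seeds, so cell geometry cancels in the across-arm ratio and
only the treatment effect remains — and runs without nodules, since the
measured quantity (untransfected nuclear F-actin) involves none.

## Known limitations

* Thresholding assumes a roughly bimodal intensity structure; densely
  confluent fields or strong illumination gradients would need
  preprocessing the package does not provide.
* The transfection rule requires an untransfected majority and baseline in
  every image (see above).
* Gating needs a visible 4N mode; heavily G1-arrested populations raise a
  gate-fitting error rather than guessing.
* The nodule/cluster detector is intensity-only; it does not separate
  merged foci that touch, and objects below the minimum area are ignored
  by design.
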