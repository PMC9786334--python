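# Methods

## The measurement problem

Live/dead staining of adherent cells yields three registered fluorescence
channels: Hoechst 33342 marks every nucleus (the dye is membrane-permeable),
calcein marks the cytoplasm of viable cells (esterase conversion, retained
only by intact membranes), and propidium iodide marks nuclei of cells with
compromised membranes. Counting "nuclei behind the green mask" and "nuclei
behind the red mask" turns the image pair into two integers, N_viable and
N_dead, and viability is their ratio on a percent scale. The difficulty is
operational: nuclei touch, stains bleed, and manual thresholds are
observer-dependent. This package fixes every such choice to a deterministic,
logged rule.

## Imaging pipeline

**Binarization.** Otsu's global threshold (between-class variance
maximization) per channel; deterministic and parameter-free, with a manual
override per channel. Two guards make the automatic path safe: a
constant-intensity channel returns an all-background mask with a warning (no
threshold exists), and when the two Otsu classes differ by less than a
2-fold mean-intensity ratio the channel is treated as unstained background.
The second guard matters because Otsu always splits *something*: on a
noise-only channel (e.g. the red channel of a fully viable culture) it would
otherwise binarize the upper half of the background noise, which at 8-connectivity
percolates into large spurious components. The guard assumes stained
foreground is at least twice as bright as background, which holds by a wide
margin for the intended contrast regime; genuinely low-contrast data should
use the explicit override. Components smaller than `min_object_area`
(default 25% of the smallest expected nucleus area, i.e. ~79 px at a 10 px
expected radius) are removed as debris.

**Nucleus splitting.** Marker-controlled watershed on the negated Euclidean
distance transform (EDT) of the nuclei mask, 8-connected. Markers are local
maxima of the EDT, kept greedily from highest to lowest subject to a minimum
pairwise Euclidean separation `min_seed_distance` (default = the expected
nucleus radius, 10 px). The separation pruning doubles as plateau-noise
suppression: duplicate rasterization maxima inside one nucleus are always
within a radius of the true peak and are absorbed by the highest one. An
optional h-maxima prominence pre-filter (`h > 0`) is available for irregular
masks but is off by default — on disk-like nuclei it adds cost without
changing the result. Any connected component whose maxima are all pruned
receives a fallback marker at its EDT maximum, so the union of labels always
equals the mask foreground exactly and no nucleus can vanish. Nuclei touching
the image border are counted by default (`exclude_border` drops them).

Known failure mode: in dense multi-cell clusters the EDT develops "phantom"
maxima between cells (the union of several disks admits a large inscribed
circle centered between nuclei), which can absorb the per-nucleus peaks and
merge neighbors. At the field densities used for validation (50–300 cells
per 768×768 field with center separations ≥ 1.4 nucleus radii; up to 500
cells for viability scenes) the per-scene counting error stays within 2%,
but the method is not expected to hold that bound under substantially denser
packing.

**Classification.** For each labeled nucleus the overlap fractions
|nucleus ∩ green| / |nucleus| and |nucleus ∩ red| / |nucleus| are compared
against `overlap_threshold` (default 0.5). Dead (red) takes precedence on
double positives: a compromised membrane admits propidium iodide regardless
of residual calcein, so red is the stronger evidence. Nuclei under neither
mask are "unclassified"; they are excluded from the viability ratio (whose
denominator is N_viable + N_dead by definition) but always reported, so the
exclusion is visible. A centroid-in-mask mode is available as a cheaper
alternative. When no nucleus is classified the viability is reported as
missing — never 0 or 100.

**Replicate statistics.** A biological replicate contributes one viability
value, formed by pooling viable/dead counts over all of its frames (pooling
weights frames by cell count; per-frame averaging is available via
`pooling='frame'`). Condition-level values are summarized as mean ± sd,
screened with the Jarque–Bera test (JB = n/6·(S² + (K−3)²/4), p from χ²(2);
skipped when n < 3 or variance is zero, and flagged as asymptotic for
n < 30), and compared by one-way ANOVA (F = (SSB/(k−1))/(SSW/(N−k))) at
α = 0.05. Conditions with a single replicate are excluded from the ANOVA
with a warning. Degenerate data are handled explicitly: SSW = 0 with SSB > 0
gives F = ∞, p = 0 with a warning; SSW = SSB = 0 gives F = 0, p = 1. No
post-hoc test is run; only the omnibus ANOVA is part of the workflow.

## Assay calculators

**TNBS / degree of functionalization.** The glycine standard curve is an
ordinary least-squares line with a free intercept (the intercept absorbs the
reagent blank; a through-origin mode is selectable). Sample absorbances are
inverted through the curve to glycine-equivalent amine concentrations
(µg/mL) and normalized by protein concentration (mg/mL) to µg amine per mg
protein. Replicate dilutions (0.1, 0.3, 0.5, 0.8 mg/mL) are averaged within
a batch; the DoF is computed per batch and summarized as mean ± sd over
batches. Absorbances outside the calibration range (routine for high-DoF
samples, whose amine signal is tiny) are extrapolated with a warning;
back-calculated negative concentrations are flagged, never clipped. The DoF
standard deviation, when replicate sds are supplied, uses first-order
(delta-method) propagation.

**Swelling.** `m_swollen / m_dry`, elementwise over a sample table; dry mass
must be positive.

**Plateau modulus.** The storage modulus is reduced to one number by the
geometric mean over the frequency window (default 0.5–50 rad s⁻¹). The
geometric mean is used because moduli span decades across formulations and
the sweep is flat on a log scale; the arithmetic mean is available by flag.
For a power law G′ = a·ω^n sampled log-uniformly the geometric mean equals
a·(ω_lo·ω_hi)^(n/2), which the tests verify. The flatness diagnostic
(max/min of G′ in the window) warns above 1.5: such a sweep is not a plateau
and the single-number summary is suspect.

## Synthetic data: what it emulates and what it does not

Scenes are built from disk-shaped nuclei (radius uniform in 9–11 px by
default) with concentric cytoplasm disks (1.8× the nucleus radius) for
viable cells and PI-positive nuclei for dead cells. Placement is rejection
sampling with a minimum center separation (default 14 px, i.e. below two
nucleus diameters, so touching nuclei occur by design — that is the case the
watershed exists for); an unsatisfiable density raises an explicit error.
Intensities are flat per stain (foreground means 110/130/140 against a
background of 8) with Poisson shot noise on stained pixels and additive
Gaussian background noise (sd 3). Defaults keep the foreground/background
ratio far above the contrast guard so Otsu is well-posed. All geometry is in
pixels; no magnification or physical pixel size is modeled.

Viability assignment is exact by count (`round(n_cells · p)` viable cells)
so ground truth is exactly controllable; a Bernoulli per-cell mode provides
the replicate-to-replicate sampling variation of a real study and is what
the simulated multi-condition studies use. A configurable "leaky staining"
fraction makes viable cells double-positive to exercise the tie-break rule.

Deliberately not modeled: point-spread-function blur, z-structure,
photobleaching, uneven illumination, intensity gradients within cells,
non-circular or lobed nuclei, and real double-staining biology. Passing the
synthetic validation therefore demonstrates the correctness of the
algorithmic chain (thresholding, splitting, masking, arithmetic, statistics)
under controlled conditions — not robustness to every optical artifact of
real micrographs, where parameters (especially `min_seed_distance`,
`min_object_area`, and the overlap threshold) may need adjustment.

The TNBS generator places absorbances on a Beer–Lambert line (default slope
0.05 absorbance per µg/mL, intercept 0.02) at the standard glycine
concentrations (3, 5, 8, 10, 20 µg/mL) and sample dilutions, with Gaussian
noise; the gelatin reference defaults to 25 µg glycine-equivalent amine per
mg protein, a realistic free-amine content for type A gelatin, and the GelMA
amine fraction sets the true DoF. Negative generated absorbances are clipped
at zero and flagged.

## Validation conditions and problem sizes

The validation suite uses: 20 seeded fields of 50–300 cells (768² px,
separation ≥ 1.4 radii) for counting; six 500-cell fields at 50/90/95% true
viability for estimator recovery (error ≤ 2 percentage points); 100
touching-disk pairs (r = 10 px, center distance 12–18 px) for pair
splitting; 100 simulated two-condition studies (3 replicates × 500 cells
each, Bernoulli viability, 640² px) for each of the null (95% vs 95%) and
contrast (95% vs 70%) ANOVA checks; and 3-batch TNBS tables at zero and 2%
absorbance noise for DoF recovery. These sizes were chosen as realistic
study conditions that keep the full validation in the minutes range on a
single CPU. Note the ±0.05 noisy-DoF recovery is a statement about a 3-batch
mean whose own sd is ≈ 0.03: individual seeds can land outside it with small
probability, which is inherent to the assay's replicate structure rather
than an implementation artifact.

## Numerical and interface choices

- Coordinates are (row, col), 0-based, origin top-left, stated in every CSV
  header; CSVs carry a `schema_version` column.
- Connectivity is 8 (2D connectivity 2) throughout by default; it changes
  counts and is configurable in one place.
- Watershed ties at equidistant pixels follow the flooding order of the
  implementation; the partition line between equal touching disks lands
  within 2 px of their perpendicular bisector.
- Label maps are relabeled to contiguous 1..n on construction.
- Configuration precedence is flags > YAML file > defaults; unknown keys are
  errors. Every run writes a log with the effective parameters and the
  thresholds actually used.
- Determinism: all stochastic steps take explicit seeds (NumPy
  `default_rng`); an identical configuration reproduces CSV outputs byte for
  byte.
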