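# Methods

## The measurement problem

Epithelial junction proteins (EJPs) — desmoglein-1 (DSG1), claudin-1,
ZO-1 and E-cadherin — outline keratinocyte borders in the stratified
squamous epithelium of the ectocervix as thin, bright, net-like strands
in immunofluorescence images.  A continuous net is a physical barrier to
intercellular passage of microorganisms; breaks in the net open routes
toward the basal membrane.  `ejpnet` quantifies, per annotated region of
interest (ROI): protein expression (mean fluorescence intensity, MFI),
epithelial height, and the geometry of barrier integrity — how much of
the epithelium an external agent could reach (the *accessible region*)
and how much of the net-bearing layer is protected (*intact*) versus
opened (*fragmented*).  Per-ROI values are averaged per study
participant and correlated with plasma estradiol and progesterone by
Spearman's rank test.

## Pipeline

### 1. Curvilinear enhancement (`ridge`)

Strand brightness varies strongly between samples and staining batches,
so strands are detected with a contrast-independent ridge measure rather
than an intensity threshold.  For each analysis scale sigma, the image is
convolved with Gaussian-derivative kernels to obtain the Hessian; a
bright ridge has a strongly negative minimum eigenvalue lambda_min
across the strand, and the gamma-normalised ridge strength is
`sigma^2 * max(0, -lambda_min)`.  The response is the per-pixel maximum
over scales, divided by its maximum inside the ROI interior.  This makes
the response exactly invariant under multiplication of the image by any
positive constant, and maps it to [0, 1].

* **Scales** default to {1, 2} px.  Strand widths in this material are
  roughly 1–4 px (0.3–1.3 µm at 0.325 µm/px), which sigma of 1–2 px
  captures; adding sigma 3–4 px lets the scale maximum over-widen thin
  strands and smear the mask across neighbouring cells (mask Dice
  against ground truth drops from ~0.96 to ~0.78 on the synthetic
  fixtures).  The scale list is configurable.
* **Numerical detail**: truncated Gaussian-derivative kernels do not sum
  exactly to zero, so a flat region of intensity c leaks
  `c * sum(kernel)` (~7e-5 relative) into the second derivatives.  The
  implementation subtracts `sum(kernel) *` (the Gaussian-smoothed image),
  restoring a strictly zero response on locally constant patches.
* **Binarisation**: Otsu threshold computed from ROI-interior response
  values only (default), or a fixed threshold; 8-connected components
  smaller than `min_component_px` (default 20) are pruned as speckle.
  An all-zero response yields an empty mask with a warning, not an
  error, so a blank channel cannot abort a batch.
* Border handling is reflective everywhere, so image edges produce no
  spurious ridges.

### 2. Layer segmentation and geometry (`geometry`)

The epithelium is split into three strata by where the EJP is expressed:
superficial (apical, unstained), intermediate (strand-bearing), basal
(unstained).  The intermediate layer is the disc closing of the strand
mask — radius `closing_radius_px`, default 15 px, about half the ~30 px
cell diameter, so whole cells rather than just their borders join the
layer — hole-filled and clipped to the ROI interior.  Interior pixels
4-connected to the apical border without entering the intermediate band
form the superficial layer; every remaining interior pixel is basal.
The three masks partition the interior exactly, by construction.  Strands
touching a border leave that outer layer empty, which is flagged with a
warning rather than an error.

MFI is the arithmetic mean of **raw** intensities over a mask (the
enhanced response would distort the expression proxy); it is computed
for the whole compartment and for the intermediate layer.

Epithelial height uses a Euclidean distance transform seeded on the
basal border: each apical-border pixel reads its distance (µm) to the
nearest basal-border pixel, and the ROI height is the mean over
apical-border pixels.  The one-way apical-to-basal distance is reported
— the standard thickness estimator; `report_round_trip=True` doubles it
for the there-and-back encoding.  Height recovers known flat-band and
half-annulus thicknesses within 3%.

### 3. Barrier integrity (`integrity`)

The viral-passage rule: a break **greater than one pixel** (0.325 µm at
default resolution) is wide enough for passage; one-pixel breaks are
rasterisation noise and are sealed.

* **Sealing** is a morphological *bridge*: a background pixel is filled
  exactly when its 8-neighbour ring carries two or more mutually
  disconnected strand arcs (vectorised as a 256-entry lookup over the
  ring pattern).  This seals 1-px breaks and leaves 2-px breaks open at
  any strand thickness.  A plain 3x3 closing would not implement the
  rule: it also bridges 2-px breaks.
* **Connectivity duality** is load-bearing: strands are 8-connected,
  traversable background is 4-connected, so flow can never slip through
  the corner of a diagonal strand step (digital Jordan duality).
* **Accessible region**: 4-connected flood over `interior \ sealed`,
  seeded from free interior pixels adjacent to the apical border.  The
  flood is verified against an independent breadth-first search in the
  test suite and the acceptance script.
* **Intact/fragmented partition**: holes (4-connected components of
  `intermediate \ sealed`) seed a watershed whose elevation is the
  negated distance to the sealed net, so basin boundaries sit on strand
  ridgelines and each basin coincides with one morphological cell;
  strand pixels join the adjacent basin.  A basin is *fragmented* when
  its seed hole intersects the accessible region (the flood got into
  that cell) and *intact* otherwise — the partition interprets
  "fragmented" through the same viral-passage model that defines
  accessibility.  Holes smaller than `min_hole_px` (default 4 px) are
  slivers inside the strand lines left by rasterised breaks, not holes
  of the net; they do not seed basins and are absorbed into the
  surrounding cell.  Without this floor, sliver basins at extreme
  fragmentation can make intact coverage wiggle non-monotonically by a
  few tenths of a percent.
* **Reporting**: `pct_accessible` and `pct_intact` are percentages of
  the epithelial interior; `pct_fragmented_intermediate` is a percentage
  of the intermediate layer.  Both denominators are stored in the output
  so any ratio can be recomputed.

### 4. Cohort statistics (`stats`)

Hormone readings below the assay's lower limit of detection (LLD)
receive fixed phase-specific substitutes before statistics: follicular
(FOL) estradiol 22 pg/mL and progesterone 0.05 ng/mL; luteal (LUT)
estradiol 10 pg/mL (≈ half the 20 pg/mL limit) and progesterone
0.05 ng/mL.  Substitution is idempotent and detected values pass through
unchanged.  The two phases use different assays and substitution
principles, so phase-mixed comparisons should be avoided.

Per-ROI metrics are averaged per sample (unweighted mean, ROI count
recorded; a metric missing in some ROI is averaged over the others with
a warning).  Association uses Spearman's rho — the Pearson correlation
of mid-ranks, so mass ties from LLD substitution are handled by average
ranks.  The two-sided p-value is exhaustive over all n! permutations for
n ≤ 9 and the t approximation with n−2 degrees of freedom otherwise; at
n = 9 the two agree within 0.02.  No multiple-comparison correction is
applied by default, matching the targeted, pre-selected-parameter
design; pairs are dropped pairwise on missing values and the n per
correlation is reported.  A constant margin (e.g. all values censored at
the LLD) makes the correlation undefined; such pairs are skipped with a
warning.

## Synthetic data (`simulate`)

The generator emulates what the pipeline sees on real slides, with full
ground truth:

* A band-shaped epithelium between apical and basal borders (flat by
  default, per-column profiles supported), with the 0/1/2/3 label-mask
  annotation convention.
* A honeycomb net in the centred intermediate sub-band: jittered-grid
  seed points at the target cell diameter, Voronoi cell walls rasterised
  at the target strand width.  The band's top and bottom boundary rows
  are drawn as per-cell "lid" segments (split where the nearest seed
  changes), so marginal cells are closed like interior cells — and lids
  long enough to carry a break join the breakable edge list like any
  other wall.
* Fragmentation: each edge is broken with probability `gap_rate`; a
  break erases a slab of exactly `gap_width_px` pixels across the
  strand, centred at a uniformly chosen interior point of the edge — one
  break per selected edge, so break width is exactly controllable.
  Break indicators and centres are drawn for **all** edges before
  selection, so at fixed seed the broken-edge set is nested as
  `gap_rate` grows; nested sequences drive the monotonicity checks.
* Additive Gaussian noise clipped at zero.  Real staining noise is
  neither Gaussian nor additive (photon noise, autofluorescence,
  uneven illumination); the choice is a documented stand-in and the
  noise model is a parameter.
* Cohorts: log-normal hormone draws (progesterone correlated with
  estradiol on the log scale, r ≈ 0.45), censoring below the LLD stored
  exactly as an assay lab reports it (value at the limit plus a flag).
  Standardised log-estradiol drives per-sample image parameters through
  linear links: `gap_rate = base + effect_gap * z + scatter` and a
  log-linear link to strand intensity.  Defaults emulate a follicular
  visit: estradiol around 100 pg/mL with 22 pg/mL LLD, 2 ROIs per
  sample, a negative estradiol-to-fragmentation link (higher estradiol,
  fewer breaks) and independent biological scatter in the gap rate.

What passing tests on this generator do **not** show: robustness to
uneven illumination, autofluorescence, sectioning artefacts, out-of-band
EJP expression, or annotation error in real ROIs.  The generator's nets
are exactly rasterised Voronoi walls; real strands vary in width and
brightness along their length.

## Validation problem sizes

The cohort-level experiments run the full image pipeline end to end on
compact 96x128 images (18 px cells, 2 ROIs x 40 samples), which leaves
~30 cells per ROI so coverage percentages respond smoothly to the gap
rate.  Sign recovery uses 50 replicate cohorts; the type-I experiment
uses 200 null cohorts, enough that an observed rejection rate within
5% ± 3% is a reliable verdict on calibration (with 50 replicates the
binomial noise alone would leave that band ~37% of the time).

## Known limitations

* The enhancement declares a contract (contrast-independent curvilinear
  enhancement); equivalence with any particular published filter is not
  claimed.
* "Accessible" is a purely geometric construct — no diffusion, particle
  size or kinetics.
* The intact/fragmented labelling of watershed basins by accessibility
  is this package's interpretation; strand pixels are assigned to
  adjacent basins.
* Below-LLD mass substitution produces heavy rank ties; mid-ranks handle
  them, but a majority-censored margin carries little rank information
  and an all-censored margin is undefined and skipped.
* The one-pixel rule is resolution-bound: physical break width depends
  on `pixel_size_um`, and `break_seal_px` is intentionally fixed at 1
  (overriding it warns).
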