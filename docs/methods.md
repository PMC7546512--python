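# Methods

This package reimplements, as one tested pipeline, a specimen-level
integrative workflow for a Neotropical cryptine wasp: objective color
phenotyping from photographs, correlation of morphology and color with
altitude and latitude, species delimitation by implied-weights
parsimony on a printed 24-character matrix, and PCA of mixed
categorical + continuous data.  This note records the models, the
conventions that were genuinely open, and what the bundled synthetic
data can and cannot establish.

## Color phenotyping

Specimen images are compared on raw RGB values after being brought to a
common exposure.  Exposure is the normalized channel mean
`mean((R+G+B)/3)/255` over the specimen foreground, where the
foreground is the darkest 45% of pixels (specimens are photographed on
light backgrounds; the published protocol excludes the top 55%
brightest pixels).  "Brightest" for this ranking is the per-pixel
channel mean, the same quantity the exposure formula integrates — the
source protocol does not define it separately.

Exposure matching uses a single-parameter gamma curve with the exponent
solved by bisection, re-ranking the foreground after every adjustment.
The original operators matched exposures by hand with Bézier tone
curves; the contract here is the achieved exposure (relative deviation
≤ 0.05%, the figure the original procedure reports), not the curve
family.  On 8-bit output the deviation floor is one quantization step;
for degenerate images (e.g. uniform gray) the match is accepted when
the continuous tone curve meets the tolerance and the returned image is
its nearest 8-bit rendering.

Point sampling averages R, G, B over the Euclidean disc
`dx² + dy² ≤ r²`; at the protocol radius r = 2 an interior disc covers
exactly 13 pixels, the only disc convention with that property.
Landmarks come from TPS digitizing files, whose origin is bottom-left;
the reader flips the y axis to raster rows, and the synthetic-image
round-trip test covers the flip.

Perceived brightness is `sqrt(0.2989 R² + 0.5870 G² + 0.1140 B²)` on
[0, 1] channels.  The source that this luminance recipe cites includes
the square root; the radical-free weighted sum is exposed behind a flag
(`radical=False`) since both forms satisfy the printed 0-to-1 range
description.

Cross-camera calibration is the classic statistics-transfer method:
images are mapped to the decorrelated logarithmic lαβ space
(RGB → LMS → log → lαβ), source channels rescaled to the reference
mean and standard deviation per channel, and mapped back with
clipping.

## Cline statistics

Association of each variable with each environmental axis is computed
by type dispatch: categorical variable vs continuous altitude uses
point-biserial correlation for 2 observed states and full-ML polyserial
correlation for 3+; continuous (RGB) variables use Pearson against
altitude and polyserial against the 4-state ordinal latitude band;
categorical vs categorical uses Cramér's V.  All coefficients live in
|r| ≤ 1, so independently sorted absolute series are comparable and a
series is summarized by its mean absolute coefficient.  Missing cells
are deleted pairwise per variable (per-variable n varies in the real
material because of damaged parts); a variable with fewer than two
observed states yields an undefined (NaN) coefficient that is excluded
from the average.

The polyserial estimator maximizes the exact bivariate-normal
likelihood over ρ and the thresholds, with x standardized by its sample
mean and (n−1) standard deviation — the convention of the standard R
implementation the original analysis used — parametrized by atanh(ρ)
and log threshold spacings, initialized at the two-step estimate, and
optimized by Nelder–Mead to tight tolerances.  Two-step and full-ML
agree within 0.02 on clean simulated data, and the estimate recovers
generating ρ ∈ {0, 0.3, 0.6, 0.9} within three standard errors at
n = 2000 (tested).

Latitude needs care.  The collection sites cluster into four latitude
bands, so latitude is never used as a continuous correlate.  Two
categorical encodings are supported:

* **bands** (`bin_latitude`): the four ordered states [0] ≥ 0°,
  [1] (−10°, 0°), [2] [−15°, −10°], [3] < −15°.  The printed band
  limits leave (−5°, −10°) unassigned; the nearest-interval extension
  assigns it to band 1.  No studied specimen falls in the gap.  The
  bands are the ordinal variable for polyserial correlations with
  continuous color.
* **distinct sampled latitudes** (default for Cramér's V): each
  distinct latitude value is its own category.  On the published
  material only this encoding, combined with the Bergsma bias
  correction, reproduces the published latitude-series average
  (0.2438...); every 4-band variant (plain or corrected) lands far
  from it.  The original series was computed with a script derived
  from a library whose Cramér's V is bias-corrected, which is
  consistent with this reading.  The standalone `cramers_v` defaults
  to the plain variant; the series dispatch passes `corrected=True`.

Per-body-area darkening is tested by OLS of perceived brightness on
altitude with a two-sided t test on the slope; areas are reported from
most decreasing to most increasing.  The type-I error of this test is
~5% at α = 0.05 over 1000 null simulations (tested).  Where linearity
of a continuous relationship is doubtful, candidate curve families
(linear/quadratic/cubic/exponential) are ranked by Gaussian-likelihood
AIC `n ln(RSS/n) + 2k`; RSS is floored at numerical precision so exact
fits tie and the parameter count decides.

## Parsimony engine

Discrete characters are optimized by Fitch set intersection
(non-additive) or the Farris interval method (additive); continuous
characters use intervals on raw values (no rescaling — none is
specified for the original analysis; a TNT-compatibility rescaling
experiment can be done by transforming the input).  Missing entries
are "any state"; polymorphic entries are state sets satisfiable at no
cost at the leaf.  Per character, the minimum steps m are
(observed states − 1) (non-additive; with polymorphism, the minimal
hitting set of the leaf sets minus one) or the observed span
(additive), and the maximum g is the length on the star tree:
n_scored − largest satisfiable state count, or the median-center sum of
absolute deviations.  Homoplasy is h = s − m; implied weighting scores
a tree by the concave Σ h/(h+K) (minimized; the complementary Goloboff
form Σ K/(h+K) is also reported), CI = Σm/Σs and
RI = (Σg−Σs)/(Σg−Σm), reported ×100 and truncated to integers the way
TNT prints them.

For speed, all discrete characters are packed into one big integer per
taxon (11-bit fields) and scored by a single bit-parallel Fitch
downpass; additive characters enter this path by cumulative binary
recoding, which preserves lengths exactly.  The packed scorer is
validated three ways: against an independent interval/Fitch reference
path, against explicit minimization over all internal-node state
assignments on ≤6-taxon trees, and (during development) against an
independent Sankoff implementation with linear and unit cost matrices.

The search is a parsimony ratchet: random-addition Wagner starting
trees, first-improvement SPR hill climbing, and perturbation cycles
that upweight (×4–8), delete (weight 0), or boost (×5) a random ~15%
of characters, climb under the perturbed weights, then climb again
under the true weights, keeping improvements; all distinct tied-best
trees are retained up to `hold`.  On every random ≤7-taxon matrix
tried (hundreds, mixed additive/non-additive, 10% missing) a few
ratchet cycles reach the exhaustive-enumeration optimum (tested).  The
published analysis's sectorial-search tuning is not replicated; the
contract is the attained score, not the trajectory.

### Conventions behind the published tree statistics

The published delimitation run states a mixed additive set
(characters 0, 2, 3, 5, 6, 11–15, 17, 21–23 ordered).  Reimplementing
exactly that specification does **not** reproduce the published
numbers: the implied-weights optimum under the stated set is 8.40384
(several independent aggressive searches converge there, and the
engine matches exhaustive enumeration on small cases), the best-fit
trees have length ≈128, and the printed ensemble indices are
arithmetically inconsistent with the stated set's Σm = 44, Σg = 260.
The printed quantities are reproduced exactly by a different, entirely
coherent convention pair:

* searching with **all characters unordered** — the default state of
  the original software — yields an optimum of 8.313424, matching the
  published best score to all printed digits;
* scoring that same best tree with **all characters ordered** yields
  length 164, CI×100 = 26 and RI×100 = 57 (truncated), and the same
  Σm = 44 / Σg = 325 also reproduce the companion figure's
  length-275 / CI 16 / RI 17 report for the alternative color-based
  topology.

The delimitation driver and the acceptance script therefore follow the
publication-reproducing pair (search unordered, indices all-ordered)
and report the stated mixed set alongside; the engine itself takes the
additive set as an ordinary parameter, so any convention is one
argument away.  When several trees tie at the best implied-weights
score, the one shortest under the ordered scoring is reported.

Strict consensus keeps exactly the bipartitions present in every input
tree, built by nesting the shared splits.  Combined
categorical + color matrices drop the 9 color-coded categorical
characters and append three continuous additive columns per RGB sample
point (12 equivalent + 15 additional points → 24 − 9 + 81 = 96
columns).

## Mixed-data PCA and imputation

The mixed analysis is the PCAmix formulation: continuous columns
standardized with population (1/n) variance (a flag switches to
sample variance), categorical columns expanded to centered indicators
with column weight n/n_s, and a generalized SVD with row weights 1/n.
Pure limits are exact: all-continuous input reproduces
correlation-matrix PCA eigenvalues; all-categorical input reproduces
multiple correspondence analysis up to the known factor q (the number
of variables), which the oracle test pins down.  Total inertia is
p_cont + (total categories − number of categorical variables).  Axis
signs follow the largest-|loading| variable.  Missing continuous cells
are completed beforehand by iterative rank-k PCA (defaults
n_components = 2, tol = 1e-6, max_iter = 500; the source analysis
states only "iterative imputation"); observed cells are never altered,
and a rank-1 matrix with one missing cell is recovered to machine
precision (tested).  Categorical missing values are left to the caller
as an explicit extra level; the pipeline imputes the continuous block
first, then runs the mixed decomposition.

## Synthetic data: what it shows and what it does not

`gen_cline_matrix` draws the study conditions: ~50 specimens between
sea level and ~1150 m; latitudes clumped at +4°, −2°, −14.6° and
−20.2° (the four collection areas); ordinal characters generated by
thresholding a latent Gaussian correlated (ρ) with standardized
altitude at equally spaced normal quantiles — so the population
polyserial correlation equals ρ by construction — and RGB channels
linear in altitude (default ≈ −40 units per 1000 m, noise SD 8)
clipped to [0, 255].  Clipping biases recovery at extreme slopes;
the defaults keep values well inside the range.  The published color
table's shape (50 specimens × 78 variables, 174 missing cells, 3726
informative) is recreated by `inject_missing` with missing-at-random
cells.

These generators validate estimator calibration (parameter recovery,
type-I error, round-trip exactness) and pipeline plumbing.  They do
not emulate focus-stacked optics, specular highlights, correlated
missingness from damaged body parts, or phylogenetic correlation among
characters, so passing tests say nothing about those failure modes in
real material.  The published RGB-series averages and the 7-of-27
darkening body areas depend on the original supplementary spreadsheet
and deposited sequence accessions, which are not redistributed here;
the corresponding pipelines are exercised on synthetic tables of
identical shape and known truth instead, and accept real files with
the same layout.

## Numerical choices

* Polyserial: optimizer tolerances 1e-8/1e-10; ρ clipped inside
  (−1, 1) by the atanh parametrization; two-step start.
* Ratchet: perturbation fraction 0.15, styles cycling
  upweight/delete/boost; score ties at 1e-9; acceptance uses 300
  iterations and 6 random-addition starts (the published run used
  1000 iterations of its own ratchet; 300 reaches the same optimum
  from every seed tried here in a few minutes of CPU).
* Exposure matching: relative tolerance 5e-4 with 8-bit fallback as
  above; bisection bracket [1e-3, 1e3] on the exponent.
* Foreground mask ties at the 45% threshold: stable row-major scan
  order, keeping exactly ⌈0.45·N⌉ pixels.
* DMS latitude: seconds/minutes ≥ 60 carry over with a warning by
  default (the printed table contains one such value); strict mode
  rejects.  Ratio rounding: nearest 0.05, exact ties up.
* Imputation non-convergence returns the last iterate with a warning
  rather than failing, since downstream PCA is robust to near-converged
  completions.

## Known limitations

* The search is SPR-based with ratchet and random kicks; tree fusing,
  TBR and sectorial searches are not implemented.  On this 29-taxon
  matrix every seed tried reaches the published optimum, but much
  larger matrices would want the heavier machinery.
* Implied weighting uses a single K for all characters; extended
  (per-block) weighting schemes are out of scope.
* The mixed PCA reports eigenvalues, scores, loadings and squared
  loadings; confidence ellipses and plot cosmetics are left to the
  caller.
* `read_s1_table` expects the canonical pNN_R/G/B layout and accepts a
  column-mapping sidecar for files whose ordering is undocumented.
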