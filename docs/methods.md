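# Methods

## The assay and its endpoints

The package quantifies physiological colour change in crustacean
background-adaptation experiments. Each animal is observed on a white and
then a black substrate (a within-subject pair), across exposure times,
repeated trials and nominal drug doses (between-subject factors). Two
endpoints are produced per observation:

* the **chromatophore coefficient** — with $n_k$ cells graded at
  dispersion stage $k\in\{1..5\}$ and $T_c=\sum n_k$,
  $C=\sum_k (n_k/T_c)\cdot 20k = 20\cdot\overline{k}$, bounded in
  $[20, 100]$. The stage-weighted form is implied by the stated 20–100
  range and by the classical 20-cell scheme it standardises (20 cells
  scored 1–5 sum to 20–100); an unweighted sum of the proportions would be
  identically 20. Promotion of one cell by one stage moves $C$ by exactly
  $20/T_c$; the score is invariant to scaling all counts.
* **percent dark cover** — the fraction of the segment ROI classified as
  dark pigment after the image recipe below.

## Synthetic cohort generator

No public raw data exist for assays of this kind at the per-cell level, so
correctness is established on a generator with known ground truth.

**Stage counts.** Each observation has a latent dispersion level
$L = \mu_0 + \beta_{bg}\,[\text{black}] + \beta_{time} + \beta_{trial} +
\beta_{conc} + u_i + e_{obs}$, with specimen random effect
$u_i\sim N(0,\sigma_s^2)$ (persistent across that animal's repeated
measures) and observation noise $e_{obs}\sim N(0,\sigma_o^2)$. The segment
carries $N\sim\text{Poisson}(\lambda)$ chromatophores (truncated at
$N\ge 10$; $\lambda=40$ by default — per-segment counts vary between
animals, which is exactly why the coefficient is standardised by $T_c$).
Each cell adds $e_{cell}\sim N(0,\sigma_c^2)$ and is graded
$1+\#\{\tau_k < L+e_{cell}\}$ against fixed cutpoints
$\tau=(-1.5,-0.5,0.5,1.5)$ — an ordered-probit model whose analytic stage
probabilities ($p_k = \Phi((\tau_k-m)/\sigma)-\Phi((\tau_{k-1}-m)/\sigma)$
at marginal SD $\sigma=\sqrt{\sigma_s^2+\sigma_o^2+\sigma_c^2}$) serve as
the oracle for the sampled frequencies.

Default scales: $\sigma_s=0.3$, $\sigma_o=0.15$, $\sigma_c=0.6$. The
default $\mu_0$ and $\beta_{bg}$ are not free constants: they are solved
at model construction by root-finding on the analytic mean stage so that
the cohort mean coefficient is 45 on white and exactly 20% higher on black
($\mu_0\approx-0.756$, $\beta_{bg}\approx 0.455$) — the background effect
size this class of assay reproducibly shows. All dose effects default to
zero (null drug). Every random draw flows through one explicitly passed
`numpy.random.Generator`; identical seeds give bit-identical tables and
images.

**Images.** A bright elliptical ROI (intensity 230, Gaussian noise SD 5)
on a neutral canvas, 512x512 by default with ROI semi-axes (85, 140)
pixels chosen so that default cohorts land in the tens-of-percent cover
range. Each chromatophore is a dark disk of radius $2+1.5k$ px at stage
$k$ (intensity drop 180) with a linear 2-px rim centred on the nominal
radius, so any mid-range threshold recovers an area close to $\pi r^2$
and component area inverts cleanly to stage. Centres are placed by
rejection sampling, non-overlapping where the packing allows (dense
stage-5 segments may exceed the packing limit; overlaps are then accepted
and logged — they merge into one component, which the grader scores by
combined area). Coordinates are 0-based, row-major, origin top-left.

**What the generator does not emulate:** pigment colour classes
(black/red/yellow/white chromatosomes), irregular cell shapes, uneven
illumination, specular highlights, moulting or size covariates, and any
real pharmacodynamics of dose. Passing tests therefore demonstrate that
the measurement and inference chain is correct under the assay's
statistical structure — not that segmentation would survive arbitrary real
photographs.

## Image recipe

Greyscale uses ITU-R 601 weights (0.299, 0.587, 0.114), rounded half-up
and clipped to [0, 255]. The median filter uses a Euclidean-disk footprint
($dx^2+dy^2\le r^2$, default $r=2$) with reflected borders; ImageJ's rank
filters use a slightly different pixel-inclusion rule at some radii, so an
exact cross-check against ImageJ should fix the footprint first. The dark
threshold is Otsu's criterion computed over ROI pixels only — a
deterministic, blind surrogate for the original interactive adjustment —
recorded at the half-integer class boundary, with pixels strictly below it
marked dark; a fixed threshold can be supplied instead. Two guards matter:
a constant ROI is an error (degenerate histogram), and an ROI whose
intensity spread is below 50 grey levels is treated as pigment-free
(empty dark mask) because Otsu will otherwise bisect pure background
noise. Percent cover is computed strictly within the ROI; pixels outside
it can never influence the result.

## Statistics

Endpoints are natural-log transformed before modelling (offset 0 for the
coefficient, which is ≥ 20 by construction; offset 1 for percent cover,
which can be 0). The mixed ANOVA is the classical split-plot
decomposition:

* between-subject stratum — Type-III ANOVA (sum-to-zero coding, via OLS)
  of subject means across the two backgrounds, handling unbalanced cells;
* within-subject stratum — Type-III ANOVA of orthonormal contrast scores
  of the repeated measures; the within-factor main effect is the pooled
  intercept term, its interactions the corresponding between terms, each
  tested against the subject x background residual.

Greenhouse–Geisser epsilon is computed from the pooled covariance of the
contrast-score residuals, $\varepsilon = \mathrm{tr}(S)^2/((k-1)\,
\mathrm{tr}(S^2))$ on the doubly-centred covariance, clipped to
$[1/(k-1), 1]$; with the two-level background factor it is exactly 1 and
the adjusted p equals the raw p. Partial eta squared is
$SS_{effect}/(SS_{effect}+SS_{error})$ with the error taken from the
effect's own stratum. For a two-level within factor and no between
factors the background F is identically the squared paired-t statistic;
this identity, and exact agreement with an independent mixed-ANOVA
implementation on one-between designs, are enforced in the tests.

Exposure time is treated as a fixed between-subject factor, mirroring how
such assays report it. Because each specimen is nevertheless observed at
every time, the repeated-measures unit in `analyze_dataset` is the
specimen x time white/black pair; the specimen random effect cancels
inside each pair's difference, so the background test keeps its nominal
size (verified by simulation: type-I error within 3 binomial SEs of 0.05
over 200 null cohorts of 60 specimens).

Post hocs are pairwise comparisons of marginal means on the pooled
one-way error, Bonferroni-adjusted with the family equal to the number of
pairs ($m=k(k-1)/2$, adjusted $p=\min(1, mp)$); observations are first
aggregated to subject means within each level so repeated measures are
not treated as independent replicates. A "Tukey-style" reading of the
same comparisons is possible from the reported raw p-values. The Pearson
correlation between coefficient and percent cover is reported overall and
per trial with exact $r^2=r^2$ (no rounding shortcuts), and the ANOVAs
are re-fitted with each trial removed in turn (sequential removal), since
trial-to-trial heterogeneity is the assay's known weak point.

**Background-shift summaries.** Two estimators of the white-to-black
relative change are reported. The cohort-level
$100\,(\bar{B}-\bar{W})/\bar{W}$ estimates the calibrated population
quantity (delta-method SE, accounting for pairing); the per-specimen mean
of $100\,(B_i-W_i)/W_i$ is also given with a t-based CI, and sits
~1 point above the cohort value at the default noise scales because
$1/W$ is convex. The benchmark script reports the cohort-level estimator
on 450 specimens, which keeps its Monte-Carlo SE below 0.7 points.

## Numerical and design choices

* Otsu-in-ROI (not global) thresholding; automatic mode refuses
  low-contrast ROIs rather than fabricating a split.
* Grading bins are the midpoints between $\pi(2+1.5k)^2$ for consecutive
  stages; components below half the stage-1 area are discarded as
  speckle; components larger than any single cell are graded stage 5 by
  combined area and logged.
* Blinded labels are zero-padded integers 1..N from a seeded permutation;
  the key is a CSV written outside the blinded directory, and blinding
  always copies, never moves.
* All file formats are plain text or PNG; specimen tables validate counts
  (integer, nonnegative, $T_c=\sum n_k$) on both read and write.
* Problem sizes in the test-suite and benchmark script (120-specimen
  sweep, 450-specimen shift cohort, 200 null simulations of 60 specimens)
  were chosen so Monte-Carlo error is small relative to each check's
  tolerance while the whole suite runs in minutes on one CPU.

## Known limitations

* The automated stage grader assumes the renderer's radius-stage map; on
  real photographs cell areas would need recalibration, and touching
  cells are not split.
* Percent cover responds to the *area* of dispersed pigment and so is a
  nonlinear (roughly quadratic-in-radius) transform of stage; its
  white-to-black relative shift is therefore larger than the
  coefficient's under the same calibration.
* The mixed ANOVA supports one within-subject factor (the assay's
  white/black pair); multi-factor within designs are out of scope.
* Dose effects are additive on the latent scale; antagonistic or
  non-monotonic pharmacodynamics are not modelled.
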