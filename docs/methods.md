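# Methods

This note records the models, defaults, and numerical choices behind
`damfretkit`, and what the synthetic-data tests do and do not demonstrate.

## The measurement and its units

A DAmFRET experiment measures, per cell, an expression proxy (acceptor
fluorescence, procedure-defined units, p.d.u.) and AmFRET = FRET
intensity / acceptor intensity, a dimensionless assembly readout near 0 for
monomer and at some protein-specific plateau (typically 0.1–0.5) for
assemblies. AmFRET is computed on untransformed intensities; the logicle (or
asinh) transform is used only for gate geometry and display. All expression
axes in this package are log10 p.d.u.; the global histogram range defaults
to 10^0.5–10^4.5 p.d.u., wide enough to accommodate every data set, split
into 64 equal log-width bins (left-closed, top bin closed).

## Gating and QC

Gates are rectangles by default (polygons optional) on (FSC-A, SSC-A),
(FSC-H, FSC-W) and (donor, autofluorescence); gating writes flags and never
deletes rows, so QC and downstream statistics are always computed on the
flagged subset of an intact table. A well passes screen QC with at least
2500 expressing events and mean acceptor of at least 3.5 p.d.u.; both
boundaries are inclusive because the stated failing conditions are strict
("fewer than", "less than"). A DFD or seed whose surviving wells fall below
25% of its original instances is dropped entirely (boundary retained).

The logicle transform follows the standard biexponential definition
`B(y) = a e^{by} − c e^{−dy} − f` with parameters (T, W, M, A) and Newton
inversion from an interpolated start; an asinh fallback (cofactor 150) is
provided since no instrument-specific (T, W, M, A) values are prescribed.

## FRET-positive gate and fgate

The per-bin gate is the 99th percentile of AmFRET in each expression bin of
a monomer-only (mEos3 alone) control. Bins with fewer than 20 control cells
inherit the nearest populated bin's gate — a fallback that makes no
smoothness assumption. By construction the control's own fgate is ~0.01;
this is verified, not assumed. `fgate` is the gross above-gate fraction over
all in-range cells and equals the count-weighted mean of the per-bin
fractions.

## Continuity classification

1. **Binning.** Log-expression is binned by Scott's rule
   (width 3.49·sd·n^(−1/3), count = ceil(range/width)).
2. **Density cutoff.** A bin enters the spline when it has >= 20 cells,
   count/IQR(AmFRET) >= 500 (IQR 0 counts as infinite density), and at most
   25% of its cells beyond the Tukey fences (1.5·IQR past the quartiles) —
   "outlier" is otherwise unspecified, and Tukey fences are the standard
   parameter-free choice.
3. **Spline.** Per bootstrap replicate, cells are resampled with
   replacement — realised as multinomial bin counts with i.i.d. within-bin
   draws, which is distributionally identical and much faster — the
   per-eligible-bin medians are low-pass filtered with a zero-phase
   second-order-section Butterworth (order 2, normalized cutoff 0.2: mild
   smoothing that preserves step edges), and interpolated cubically onto a
   fixed 256-point grid. The reported spline is the mean of 100 replicates.
4. **Transition landmarks.** Per replicate, the transition point is the grid
   argmax of the first derivative (ties leftmost); the start is the argmax
   of the second derivative at or before it; the end is the argmin of the
   second derivative at or after it. Bootstrap medians are reported. A
   spline whose total rise is under 0.02 AmFRET units is degenerate (no
   transition): such wells are continuous by construction.
5. **Dip test.** AmFRET of cells inside the transition range is tested for
   unimodality. The dip statistic is the minimal sup-norm distance between
   the empirical CDF and any unimodal CDF, computed by the classical
   GCM/LCM modal-interval iteration; the implementation was validated
   exactly (to 1e-13) against a linear-programming projection onto unimodal
   CDFs on thousands of random samples, including tied data. P-values are
   Monte Carlo against uniform(0,1) nulls of the same n (n_null = 2000,
   seeded, memoised per sample size; add-one convention). Cells are
   subsampled to 2000 for the test so the null table is shared across wells;
   at that size the test's power on well-separated mixtures is effectively 1.
   p < 0.05 is discontinuous; p >= 0.05 (equality included) continuous.
6. **Subtype.** Continuous profiles are "low" (spline minimum and ending
   value below a reference AmFRET), "high" (both at/above), or "low_to_high"
   (minimum below, ending above). The reference corresponds to the
   transition-start AmFRET of a monomeric control and defaults to 0.1.
   Replicate labels are combined by majority; exact ties are "unresolved"
   and flagged for manual review.

## C50 (saturation concentration) fitting

The mean AmFRET curve uses bins holding at least 100 cells. The model is
`AmFRET(c) = Amp (1 − exp(−ln2 (c/C50)^a))`, whose value at c = C50 is
exactly Amp/2 for every steepness a. Initial values come from a
Gaussian-smoothed (sigma = 2 bins) curve: Amp0 = smoothed maximum, C50_0 =
first half-maximum crossing, a0 = 2; Amp and C50 are box-constrained to
within 2-fold of their guesses and a to [0.1, 10]; bounded trust-region
least squares with tolerances 1e-8. A solution on a box boundary reports
`converged=False`. The fit window — a deterministic surrogate for choosing
curve limits by eye — starts where the smoothed log-concentration slope
first exceeds 5% of its maximum for two consecutive bins and ends where it
falls back below; an explicit window always overrides. Parameter errors are
a residual-scale parametric bootstrap: 100 refits of the fitted curve plus
Gaussian noise at the residual SD. Supersaturability is
C50_stochastic / C50_seeded (>= 1 when seeding lowers the saturation
concentration), computed only within an experimental batch; both
orientations of the ratio are carried explicitly because either phrasing
appears in common usage.

## Seedability screen

log10 C50 and fgate are standardized to mean 0 / variance 1 (population SD)
within each experimental batch; degrees are invariant to that affine map, so
standardization matters only when batches are pooled. Per DFD, across all of
its seeds including the negative controls (which anchor the null), the
directional outlier degrees are max(0, (median − x)/IQR) for C50 and
max(0, (x − median)/IQR) for fgate; seedability is their mean; hits are
records at or above mean + 3 sample SD (ddof = 1, configurable) of all
defined seedability values. Replicate screens are compared by the
consistency rate with a Wald binomial CI — chosen because it reproduces the
printed intervals exactly; Wilson is available via
`statsmodels.proportion_confint` — and Pearson correlation of seedability
with and without double-negative pairs.

## Morphology

Brightest z-plane (ties to the lowest index), rolling-ball background
subtraction (radius 100 px by default; output clipped at 0), thresholding by
the ImageJ "Default" iterative intermeans on a 256-bin rescaled histogram.
The historical ImageJ trim of the first and last histogram bins is omitted:
after rolling-ball subtraction the background concentrates in the lowest
bin, which must stay in the intermeans balance. The Default iteration stops
one step before the pure isodata fixed point; tests allow that documented
offset. Objects are 8-connected components; AR is the major/minor axis
ratio of the ellipse with matching second central moments (1 for
single-pixel or degenerate components); CV = SD/mean × 100 over member
pixels. Classification applies the printed CV/AR rules verbatim; a (CV, AR)
pair matched by zero or more than one rule — the boundary slivers
(1.159–1.16, CV 17–18, CV exactly 55) and set1's uncovered low-CV/high-AR
quadrant — is "unclassified" rather than silently assigned, mirroring the
manual re-verification those edge cases received in practice. The
whole-image pipeline drops components under 5 px and declares "no objects"
when the threshold floods more than 30% of the image (the signature of a
background-only field).

## Network and statistics

Physical interaction edges with confidence >= 900 form a simple undirected
graph (duplicate edges keep the maximum score; self-loops dropped); a
multi-domain protein is discontinuous if any domain is. Degree and
betweenness centralities are emitted raw and normalized (networkx
conventions), betweenness validated against a brute-force BFS
path-counting oracle. Chi-square on 2×2 tables uses no Yates correction by
default, keeping V = sqrt(X²/n) self-consistent with the reported statistic
(the correction is available as an option). Mann-Whitney uses midranks and
the exact small-sample distribution where available; Spearman uses midranks
with the two-tailed analytic p. Power-law fits are OLS in log-log space with
a pointwise 95% band for the mean line. Seedability matrices are clustered
with Ward linkage on log10 values, zeros replaced by (smallest positive
value)/10.

## Synthetic data: what it emulates and what it does not

Per-cell log10 expression is Normal(2.5, 0.7) — about four usable decades
inside the global range. One-state wells have AmFRET ~ Normal(0, 0.05) (or
around the plateau); continuous wells follow the stretched-exponential mean
curve; discontinuous wells assemble each cell with a log-logistic
probability of concentration rising 5% -> 95% over 0.5 decades around C50 —
the minimal two-parameter model producing the required bimodal window.
Seeded wells have no barrier: every cell above C50/fold (default fold 4) is
assembled. Scatter/donor/autofluorescence channels place >= 90% of events
inside the default gates, with a 2% doublet population for the singlet gate
to remove. Screens add per-batch expression-axis shifts (SD 0.05 decades)
and independent per-well variability: realised C50 (SD 0.05 decades),
amplitude (5%), and induction level (SD 0.05 decades) — the last moves the
assembled fraction without moving the measured C50, as day-to-day induction
differences do. Rendered microscopy objects are low-contrast near-circular
ellipses (diffuse), compact high-contrast Gaussian spots (punctate), and
elongated ridges with axially fading intensity (fibrillar), placed on an
overlap-free grid with ground truth serialized beside every artifact.

The generator does not simulate FRET photophysics, photoconversion,
compensation, spectral spillover, or cell-cycle/size structure; AmFRET noise
is Gaussian and homoskedastic. Passing tests therefore demonstrate that the
statistical machinery recovers planted truth under the stated noise model,
not that instrument-specific artifacts are handled.

Problem sizes used by the test suite: single-well analyses use 1e5 cells
(matching the scale at which per-bin statistics stabilize); screens use
10 DFDs × 12 seeds (two negative-control seeds per DFD, 5% of seedable
pairs planted positive) at 1e4 cells per well, 100 screen seeds for the
averaged recovery figures; dip calibration uses n = 500 with 2000-sample
null tables.

### A known sensitivity of the 3-SD hit rule at small screen sizes

On 10×12 screens the measured planted-positive recovery averages ~0.83 at a
false-positive rate of ~2×10⁻⁴. This is a property of the rule at that
scale, not of the implementation: with ~5 positives among 120 records the
positives dominate the SD of seedability, so the mean + 3 SD threshold sits
at roughly 0.7× the mean positive score, and each DFD's median/IQR is
estimated from only 12 values (IQR CV ≈ 37%), spreading the positive scores
across the threshold. An idealized simulation of the bare rule — infinite
effect sizes, fully independent metrics — caps recovery at ~93% under these
conditions. At the scale of a real screen (>100 seeds per DFD, ~1.4% hit
rate) the same rule is comfortably sensitive.

## Determinism

Every stochastic step takes an explicit seed; dip null tables are memoised
by (n, n_null, seed); pipeline runs embed a config digest and produce
byte-identical summaries for identical configs.
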