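# Methods

This note records the models, the synthetic-data assumptions, the numerical
choices, and the design decisions taken where the problem was genuinely
open. Quantities quoted here are the package's configured parameters, not
empirical claims; every measured number lives in the tests and in
`scripts/acceptance.py` output.

## Circuit model

The clock is an imposed sinusoid Θ(t) = b + ½(A−b)(1+cos ωt); there is no
feedback from the circuit onto the clock. Promoters follow the two-input
AND-NOT Hill form f = V·a/((1+a)(1+c)) with a = (Θ/K_act)^h and
c = (S*/K_rep)^h; the regulatory inputs are non-dimensionalised by their
thresholds, so any rescaling of concentration units is absorbed into K.

SigC is modelled as two first-order interconverting forms: production enters
as inactive S, activation S → S* at k_act, deactivation S* → S at k_deact,
and both forms dilute at a single rate γ_S. Only S* regulates (represses the
targets and the sigC promoter itself); reported "SigC expression" is S + S*.
This is the minimal scheme in which a "deactivation rate" is a meaningful
tunable: the high-light variant multiplies k_deact by 100, which drains S*
(relieving repression of the targets, hence a near-single-peaked target
waveform) while the relieved autorepression raises total SigC. Whether the
two forms dilute at different rates is unknowable from the circuit's
behaviour alone; one γ_S is used for both.

Variants: `SIGC_KO` zeroes every S*-carrying regulatory term (S dynamics are
still integrated for reference); `NO_AUTOREG` zeroes only the sigC
self-repression; `KAIBC_KO` replaces Θ by its constant midpoint (A+b)/2 —
an exploratory clock-deletion stand-in, not part of the validated surface.
The rpoD6 promoter shares every parameter with psbAI except the
clock-activation threshold, which is **raised** (0.67 → 1.08 a.u.): a higher
threshold narrows the clock-activation window so the post-repression rebound
no longer clears a full second maximum, leaving a trailing shoulder. The
direction of the change was an open choice; raising is the one that produces
the shoulder phenotype.

### Default parameters

No published parameter table is available to this package, so the shipped
set (`src/circatree/data/default_model_params.json`) was selected by seeded
random search (`scripts/search_model_params.py`) under hard qualitative
constraints: wild-type double peak with the smaller peak trailing the main
one by ≈ 9 h; sigC knock-out single-peaked with larger amplitude; high light
suppressing the second peak while raising total SigC; autoregulation
dispensable for the doubling; rpoD6 shoulder-like. Among admissible sets the
one with trailing-gap closest to 9 h was frozen (achieved gap 9.2 h). The
defaults are a.u./h rates of order 1 against a clock of amplitude A = 2.

### Numerics

`scipy.integrate.solve_ivp` with LSODA (stiff-capable), rtol 1e-6,
atol 1e-9. All species start at 0; a 240-h (ten-cycle) burn-in is discarded,
after which the trajectory is periodic at the clock period to integrator
tolerance (asserted by the periodicity test), making initial conditions
immaterial. Waveform classification calls a secondary local maximum a peak
only if its topographic prominence reaches 1% of the primary's — below that,
numerical ripple is indistinguishable from structure — and otherwise looks
for an inflexion pair on the trailing flank (a strict local maximum of the
derivative that stays below zero: the descent slows, then resumes) to call
a shoulder.

## Synthetic lineage movies

The generator emulates segmented-and-tracked microscopy of rod-shaped cells
in a growing micro-colony, sampled every 0.75 h (45 min) for 120 h by
default. What it reproduces, and the configured values:

* **Division**: timer-based; each cell draws its cycle time at birth from a
  normal truncated at > 2 h. Preset means/sds are the measured growth
  statistics at each light level: (19.5, 4.6) h at low light, (9.3, 2.7) h
  at high light, (25.2, 5.8) h at very low light. Because completed cycles
  observed in an exponentially growing tree over-represent fast-cycling
  lineages, the timer mean is shifted up by the first-order bias term
  ln2·σ²/μ (≈ 0.75 h at low light) so the *measured* completed-cycle mean
  matches the configured value — the generator's contract is about realised
  statistics. No size control ("sizer") is modelled, as only timer
  statistics are available. Division is not gated by clock phase.
* **Partition**: daughters receive Beta-distributed fractions around 0.5
  (sd 0.02), giving the slight asymmetry real segmentations show and
  preventing artificial symmetry in de-duplication tests.
* **Elongation**: per-cell base rate ~ Normal(mean, sd) with preset values
  (0.031, 0.004) h⁻¹ at low light, (0.07, 0.01) at high, (0.025, 0.004) at
  very low. Lengths are noise-free (segmentation noise is not emulated).
* **Fluorescence**: a clock-period-periodic waveform per cell — a primary
  Gaussian bump of unit height and 6-h FWHM at the cell's circadian phase,
  plus, for double-peak presets, a secondary bump of relative height 0.6
  placed 9 h later; knock-out presets drop the secondary bump and scale the
  amplitude (psbAI-reporter KO ×1.4; sigC-reporter KO ×3.5, single-peaked in
  both reporter presets). A Gaussian-bump waveform rather than the ODE
  output is the default because downstream recovery tests need direct,
  independent control of separation and relative amplitude; the circuit
  model remains available to drive fluorescence for qualitative studies.
  yfp = 0.2 (baseline) + waveform × (1 + ε) with multiplicative frame noise
  ε ~ N(0, 0.05).
* **Desynchronisation**: the founder's phase is uniform over the cycle and
  each daughter inherits its mother's phase plus N(0, 1 h) per cycle. One
  hour per cycle keeps single lineages clearly rhythmic while colonies
  visibly dephase over five days; the population-averaging loss of the
  second peak is demonstrated in tests at 3 h/cycle.
* **Growth modulation**: the instantaneous elongation rate is
  base·(1 + 0.3·ŵ(t − 1 h)), where ŵ is the zero-mean, unit-max-abs
  normalised *derivative* of the expression waveform — growth follows the
  expression **rate**, delayed by 1 h, reproducing the observed lead of
  expression rate over elongation rate. Lengths are re-integrated in closed
  form (the modulation integrates to the waveform itself), and division
  lengths propagate down the tree with the stored partition fractions.

What the generator does **not** emulate: imaging, segmentation/tracking
errors, photobleaching, reporter maturation, length-measurement noise,
clock-gated division, or mother-daughter growth correlations beyond phase
inheritance. Passing recovery tests therefore demonstrates correctness of
the estimators under the stated statistical structure, not robustness to
segmentation artefacts.

## Trace preparation

Smoothing is a centered 5-point (3-h) moving average applied **per cell**,
with windows that straddle a cell's first/last two frames completed from the
mother's trailing frames (left) and the two daughters' element-wise average
(right) when those cells were captured; otherwise the window shrinks
symmetrically, which keeps the filter centered and exact for linear trends.
Smoothing per cell makes shared ancestral segments identical across
lineages — de-duplication and the tree correction rely on this. Detrending
subtracts the least-squares quadratic. The cosinor fit minimises squared
error in closed form (cos/sin regression) at each period on a 0.01-h grid
over [21, 27] h; the boundary is attainable and boundary hits are visible as
τ = 21 or 27 exactly. β ≥ 0 is enforced by folding the sign into the
acrophase, giving a unique representation.

Smoothing precedes detrending and fitting because it is part of trace
quantification (applied to everything), whereas detrending/fitting belong to
rhythm analysis.

## Peak analysis

Windows are trough-to-trough intervals of the fitted sinusoid (troughs where
the cosine term is −1, spaced exactly τ); partial windows at movie edges are
dropped. Candidate peaks are strict local maxima (plateau runs yield their
centre sample). The 3-h separation rule keeps the highest peak first and
discards the lower of any closer pair. FWHM is measured at half height above
the **window minimum**, with interpolated crossings; walking outward from a
peak, entering terrain taller than the peak itself truncates the width at
the intervening valley — without this, a secondary peak overlapping its
larger neighbour inherits a half-level below the saddle and its width
swallows both peaks, which would misfire the width-difference rule on
exactly the double peaks the pipeline exists to measure.

The 25%-height / 10%-prominence rule is applied as OR (discard when either
criterion fails relative to the major peak) — the stricter reading of an
ambiguous conjunction, consistent with the rule's purpose of removing
spurious fluctuations; AND is available (`combine="and"`). The 5-h
width-difference rule compares each retained peak with the major peak and
discards the non-major offender. Pair identity for de-duplication is
(first time, second time, first cell, second cell) with times rounded to the
sampling grid, since shared-segment copies differ only by float noise. A
lone peak is paired with the first peak of the *immediately next* window
(none if that window is empty); distances above 36 h are dropped.

## Growth rates

Lineage log-lengths are stitched before smoothing: at each division the jump
between the mother's last and daughter's first log-length is removed after
accounting for one sampling interval of growth extrapolated from the
mother's local slope (the daughter's side for a one-frame mother). This
undoes an f/(1−f) split exactly and yields an exactly linear profile for
noiseless exponential growth. The mother/daughter *padding* used for
fluorescence is deliberately not applied to raw lengths — averaging across a
division would mix pre- and post-division length scales; smoothing (the same
5-point filter) is applied to the stitched log-length instead, where it is
harmless (linear-exact). The window width is one-third of the colony's mean
completed cycle time (censored cells excluded), the slope is ordinary least
squares on log-length (identical optimum to a nonlinear exponential fit
under multiplicative noise, and deterministic), and windows shrink at
lineage ends (minimum 3 points) rather than extrapolate. Expression rate is
the centered finite difference of the smoothed reporter signal, one-sided at
the ends.

Per-cell rate tables take each cell's frames from the first depth-first
lineage containing it, so colony means count each cell once.

## Tree-corrected correlation

Lags are integer multiples of the frame interval. The estimator sums lagged
products over depth-first lineages and subtracts products lying entirely
within the shared prefix of each consecutive lineage pair; the telescoping
leaves each distinct (n, n+τ) pair exactly once (kept with its last
containing lineage). Three open choices were resolved as follows:

* **Denominator**: the corrected sum is divided by the distinct-pair count
  D(τ) = N_c(N_t−τ) − Σ max(d_i−τ, 0), not by the duplicate-inclusive
  N_c(N_t−τ). With the raw count, the duplication fraction — large at small
  lags in a single-founder colony, vanishing at large lags — becomes a
  lag-dependent gain on R and can move global maxima to the lag window with
  the least shared ancestry. Per-pair weighting removes that artefact and
  makes duplication invariance exact (`normalisation="counts"` restores the
  raw-count form).
* **Centring**: per-lineage temporal mean by default. This is the choice
  under which the estimator reduces *exactly* to the standard single-series
  estimator for one lineage, for literally duplicated lineages, and under
  adding an identical sibling — the properties the oracle tests assert.
  Frame-wise per-movie centring (`centring="movie"`), which isolates
  fluctuations around the colony average, is available.
* **Divergence indices** d_i are the longest common *data* prefix of
  consecutive lineages. For measured data this equals the division frame
  (shared segments are literal copies); for degenerate identical siblings it
  extends through the whole trace, which is what "discard all repeated data
  points" requires.

Negative lags follow S_xy(−τ) = S_yx(τ): when y is a delayed copy of x
(y lags x by d), R peaks at lag −d. With x = expression rate and
y = elongation rate, the growth delay therefore appears at negative lag;
reported headline values use |lag|. Movie averaging is unweighted, with the
across-movie standard error attached.

## Problem sizes

The validation and reproduction runs use 6-10 colonies per condition at
120 h (60 h at high light), i.e. roughly 50-130 cells and 50-70 lineages per
colony — enough for standard errors comfortably inside the stated
tolerances (e.g. ~500 completed cycles give a 0.2-h standard error on the
mean cycle time) while the whole suite runs in well under a minute.

## Known limitations

* The ODE parameterisation is a qualitative-phenotype reconstruction, not a
  fit to data; absolute concentrations and rates are arbitrary units.
* The elongation estimator's boxcar window attenuates rate oscillations by
  3(sin u − u·cos u)/u³ (u = ω·half-width); tests account for this
  analytically, but users comparing modulation depths should too.
* Cosinor windows assume one dominant period in [21, 27] h; strongly
  arrhythmic or < 36-h traces are rejected rather than fitted.
* The correlation estimator assumes all lineages share the movie's full
  frame grid (movies grown from a single founder); colonies seeded
  mid-movie would need masked variants.
* Reading a movie CSV reconstructs birth/division times only to within one
  sampling interval; generator-side truth is exact, so cycle-time statistics
  from re-read files carry that quantisation.
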