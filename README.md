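# circatree

Circadian **frequency doubling** in cyanobacterial gene expression: a model
of the clock-driven incoherent feedforward loop, a synthetic lineage-movie
generator, and the single-cell rhythm-analysis pipeline that quantifies two
expression peaks per 24-h cycle in growing micro-colonies.

## The problem

In *Synechococcus elongatus*, single-cell reporters of the photosystem gene
*psbAI* show **two** expression peaks per circadian cycle — a main dusk-timed
peak and a smaller peak roughly 9 h later — even though the KaiABC clock
itself completes only one cycle per day. Cell-to-cell desynchronisation hides
the second peak in population averages, so the phenomenon is only accessible
through time-lapse microscopy of growing micro-colonies, where each cell's
fluorescence and length are tracked through divisions. The doubling is
generated by an incoherent feedforward loop: the clock activates *psbAI*
directly while also activating the sigma factor SigC, whose active form
represses *psbAI* (and its own promoter). The delayed repressive pulse carves
a trough into the clock-driven production plateau. Growth inherits the
rhythm: the single-cell elongation rate peaks twice per day, lagging the
expression rate by about one hour.

`circatree` is for quantitative/systems biologists who want to (i) simulate
this circuit and its perturbations, (ii) generate realistic synthetic lineage
movies with known ground truth, and (iii) run the exact single-cell analysis
chain — smoothing, cosinor windowing, peak filtering, elongation-rate
estimation and tree-corrected correlation — on movie tables, synthetic or
segmented from real data.

## The model and statistics

**Clock signal.** Θ(t) = b + ½(A − b)(1 + cos ωt), with basal level b,
maximum A and angular frequency ω (period 2π/ω = 24 h).

**Gene kinetics.** Each species obeys dx/dt = f_x − γx with the two-input
AND-NOT Hill production

f_x = V·u₁^h¹ / (1 + u₁^h¹ + u₂^h² + u₁^h¹·u₂^h²),  uᵢ = (regulator)/Kᵢ,

activated by the clock (u₁) and repressed by active SigC (u₂). SigC is
tracked in inactive/active forms S ⇌ S* (rates k_act, k_deact); a "high
light" variant multiplies k_deact by 100, and the sigC knock-out severs every
S*-carrying term.

**Cosinor windowing.** Each root-to-leaf lineage trace is smoothed (5-point,
3-h moving average with mother/daughter padding), detrended by a quadratic,
and fitted with the best single-period sinusoid
F(t) = α + β·cos(2π(t + φ)/τ) with τ constrained to [21, 27] h (closed-form
regression on a 0.01-h period grid). Troughs of F delimit the circadian
windows in which peaks are counted.

**Peak rules.** Candidate peaks must be ≥ 3 h apart with FWHM ≥ 2 h; given
the major peak, others are discarded below 25% of its height or 10% of its
prominence, or when widths differ by more than 5 h. Unique consecutive-peak
distances (≤ 36 h, de-duplicated across lineages sharing ancestry) give the
peak-to-peak distributions.

**Elongation rate.** Log cell length is stitched across divisions into a
continuous profile and the instantaneous rate is the least-squares slope over
a moving window of one-third of the colony's mean cycle time — exact for
noiseless exponential growth.

**Tree-corrected correlation.** For lineage matrices x_i, y_i the estimator
averages lagged products while subtracting those repeated in the shared
prefixes of consecutive depth-first lineages (divergence indices d_i), so
each distinct data pair is weighed once; R(τ) = S_xy(τ)/√(S_xx(0)·S_yy(0)).

## Worked example

```python
from circatree import (GeneratorConfig, generate_movie, analyze_movie_peaks,
                       simulate, classify_waveform)
from circatree.pipeline import pair_distances

# circuit simulation: wild type doubles the clock frequency
traj = simulate(variant="WT")
cls = classify_waveform(traj, "P")
print(f"wild-type PsbAI waveform: {cls.kind}, peak separation "
      f"{cls.separation_h:.1f} h, secondary/primary prominence "
      f"{cls.prominence_ratio:.2f}")

# synthetic movie -> full single-cell peak pipeline
cfg = GeneratorConfig.from_preset("WT_LOW", seed=1)
movie = generate_movie(cfg)
analysis = analyze_movie_peaks(movie)
within = pair_distances([analysis], same_window=True)
print(f"{len(analysis.traces)} lineages, {len(within)} unique "
      f"within-cycle peak pairs")
print(f"mean within-cycle peak-to-peak distance: {within.mean():.2f} h")
```

prints

```
wild-type PsbAI waveform: double, peak separation 9.2 h, secondary/primary prominence 0.08
49 lineages, 39 unique within-cycle peak pairs
mean within-cycle peak-to-peak distance: 8.85 h
```

The simulated circuit places the smaller secondary peak 9.2 h behind the
main one, and the full pipeline recovers a ~9-h within-cycle peak distance
from a movie whose generator placed the second fluorescence bump 9 h after
the first — the frequency-doubling signature.

The same stages are scriptable from the shell:

```bash
circatree generate --preset WT_LOW --duration 120 --colonies 10 --seed 1 --out movies/
circatree analyze peaks --movie movies/ --out peaks/
circatree correlate --movies movies/ --x expr_rate --y elong_rate --out corr/
circatree run --preset WT_LOW --seed 1 --colonies 2 --out run/
```

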