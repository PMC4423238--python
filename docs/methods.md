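# Methods

This note documents the models, parameter choices and numerical decisions
behind `sersband`, and what the synthetic experiments do and do not show.

## Data model

A spectrum is a vector of intensities (arbitrary units) on a strictly
increasing wavenumber grid in cm⁻¹; the default grid is 1270 evenly spaced
points on 400–1800 cm⁻¹ (~1.1 cm⁻¹ spacing), but nothing downstream assumes
even spacing — quadrature and band lookups always use the stored values.
Class labels are the literal strings `normal` and `cancer`; `cancer` is the
positive class in every metric. Spectra circulate as wide CSV
(`sample_id,label,<wavenumber...>`), written with `%.17g` and parsed with
round-trip float precision so read(write(x)) is bit-identical. Derived
results are JSON with a `schema_version` field.

## Synthetic generator

Each spectrum is

```
y(ν) = B(ν) + Σ_p A_p · L(ν; c_p, w_p) + ε(ν)
A_p  = a_p · s · (1 + e_p·[label = cancer]) · (1 + j_p)
```

* `L` is a unit-height Lorentzian with half-width-at-half-maximum `w_p`
  (default 9 cm⁻¹, i.e. 18 cm⁻¹ FWHM — typical for serum SERS bands).
* `B` is a per-spectrum random positive fifth-order polynomial (Chebyshev
  coefficients: constant ~ U(5, 10) a.u., higher orders ~ U(−1.5, 1.5),
  shifted so min B ≥ 0.5). It is deliberately the *same family* the
  preprocessing removes, so baseline-removal error is a measurable quantity
  rather than an assumption.
* `s` is a per-spectrum lognormal global scale (σ = 0.2) multiplying the
  Raman signal — the SERS enhancement variability that area normalization
  must cancel.
* `j_p ~ N(0, 0.05)` is per-peak amplitude jitter (within-class chemical
  variability), `ε ~ N(0, 0.12)` i.i.d. additive noise.
* The 15 peaks sit at the canonical serum SERS positions (481, 650, 683,
  725, 830, 859, 915, 1025, 1135, 1219, 1314, 1346, 1445, 1585,
  1640 cm⁻¹), amplitudes 0.45–1.0 with the strongest bands at 481, 1135,
  1219, 1445 and 1585. Eight peaks carry a signed relative class effect of
  magnitude 0.15: negative in cancer at 481, 1219, 1445, 1585; positive at
  683, 1025, 1314, 1640. `six_band_config()` keeps effects only at the six
  diagnostic bands (481, 683, 1025, 1314, 1445, 1585) used in the
  recovery experiments.

The noise level was calibrated once so that the six-band LOOCV-LDA operating
point lands in the realistic 90–95 % accuracy range for this assay (neither
saturated nor at chance): a sweep over σ ∈ {0.08, 0.1, 0.12, 0.15} put
σ = 0.12 at ~91–94.5 % and it was frozen there. Default cohort: 55 cancer
+ 36 normal spectra.

Determinism: spectrum *i* of class *c* draws from
`default_rng([seed, class_code, i])`, so enlarging one class never perturbs
previously generated spectra. Draw order within a spectrum is fixed
(baseline coefficients, scale, per-peak jitter, noise vector).

What the generator does **not** emulate: structured (high-rank, spectrally
correlated) within-class variability of real serum — person-to-person
composition differences, nanoparticle aggregation state, cosmic rays,
wavenumber miscalibration. All of its class signal and within-class
structure therefore live in a few dozen smooth directions, which has one
important consequence discussed under "Limitations".

## Preprocessing

Stage order (fixed default, switchable): baseline removal → Savitzky–Golay
smoothing → area normalization.

* **Baseline**: iterative peak clipping. Fit an order-5 polynomial
  (Chebyshev basis for conditioning) by least squares, replace every point
  of the working signal above the fit by the fitted value, refit; stop when
  `max|Δ| / max|working|` < 1e-6 or after 100 iterations (the last iterate
  is then returned with a `converged=False` flag — on noisy spectra the
  clipping tail converges slowly and the capped iterate is the intended
  output, not an error). The working signal is pointwise non-increasing
  across iterations by construction. This is the plain member of the
  modified multi-polynomial family; the noise-dependent dead-band
  refinement is intentionally not implemented. Known artifact: the clip
  ratchet undershoots slightly at the grid edges, proportionally to total
  peak mass; at realistic peak-to-background ratios the error stays below
  5 % of the background's dynamic range away from peaks, and planted peaks
  keep ≥ 98 % of their height.
* **Smoothing**: Savitzky–Golay, window 5, local order 3 — mild at
  ~1 cm⁻¹ resolution; exactly reproduces global polynomials up to cubic.
* **Normalization**: trapezoidal area over the stored grid set to 1
  (idempotent, scale-invariant, exact to 1e-10); a non-positive area raises
  an error naming the sample.

## Fisher LDA and LOOCV

Two-class Fisher discriminant with pooled within-class scatter:
`w ∝ (S_w + λI)⁻¹(μ_cancer − μ_normal)`, threshold at the midpoint of the
projected class means (equal priors, chosen because sensitivity and
specificity are reported symmetrically), oriented so cancer scores higher.
An exact tie at the threshold is called `normal` — conservative for a
screening positive. Default ridge λ = 1e-8·trace(S_w)/p stabilizes
collinear variables; λ = 0 recovers the exact Fisher solution and is used
in the oracle tests (direction within 1° of a brute-force criterion grid
search; LOOCV predictions identical to a naive fold-by-fold refit).

LOOCV refits the model for every held-out spectrum. Implementation: class
means and scatters are downdated per fold
(`S_c → S_c − n_c/(n_c−1)·dd'`) and all fold systems are solved in one
batched call; reported scores are centred on each fold's threshold so that
score > 0 ⇔ cancer across folds. Each class needs ≥ 3 members so every
training fold keeps ≥ 2.

PCA-LDA comparator: column-centred PCA (no variance scaling), 20 components
by default, fitted once on the full matrix — the common chemometric
shortcut, optimistically biased because held-out spectra shape the
components; `refit_per_fold=True` removes the bias. Similarly, GA band
selection uses the full dataset before the final LOOCV — the replicated
workflow's optimism, documented rather than hidden; a nested design is
possible by driving the GA per fold but is not the default.

## Genetic algorithm

Chromosome: 6 unique segment ids (integer encoding) out of 254 contiguous
5-variable segments, kept in ascending order. Fitness: LOOCV-LDA overall
accuracy on the expanded 30 variables (overall rather than class-balanced
accuracy; balanced can be obtained by weighting the confusion counts).
Fitness values are memoized per dataset keyed by the segment set — a pure
function of the data — and the cache is shared across repeated runs.

Per generation: evaluate → copy the top ⌈25 %⌉ over the bottom ⌈25 %⌉
(only when strictly fitter, so an all-tied population passes through
unchanged; ranking ties break by canonical chromosome order) → random
disjoint pairing, each pair crossed with probability 0.7 at a uniform cut
in {1..5}, duplicate genes repaired by uniform redraw from unused segments
→ per-individual mutation with probability 0.05 (one uniformly chosen gene
replaced by an unused id) → elitism: if the all-time best chromosome is
absent from the offspring and no offspring matches its fitness, it
replaces the worst. Best-fitness history is therefore non-decreasing;
mutation is per-individual (not per-gene), a deliberate reading of an
ambiguous convention.

Consensus: run *r* uses `default_rng([seed, r])`; each run's best
chromosome increments its 6 segments, so counts sum to `n_runs × 6`.
`top_bands` ranks segments by count (ties toward lower ids), takes them
greedily, merges adjacent selections into contiguous bands, and stops at
exactly *k* bands; fewer nonzero-count segments than needed is an error.

## Evaluation

ROC is computed from the pooled held-out LOOCV scores over all distinct
thresholds; AUC by trapezoid rule, which equals the tie-half-credited
pair-counting probability (property-tested). Band t-tests use the
classical pooled-variance two-sided Student test on per-spectrum band
means (mean over member variables — chosen over the band maximum for noise
robustness).

## Problem sizes in tests and the acceptance script

Oracle checks use 100 random small instances. Recovery experiments use the
study-sized cohort (n = 91) with 25 GA runs per master seed over 5 master
seeds; the method comparison uses 10 cohorts with 5-run consensus per
cohort; the headline pipeline uses 25-run consensus. These sizes give
stable medians and counts while keeping a full run of the suite and the
acceptance script at a few minutes each on one CPU; the GA defaults
(population 20, 100 generations, 100 runs) remain the package defaults.

## Limitations

* **PCA-LDA is near-perfect on this generator.** Because the synthetic
  within-class variability is low-rank and smooth and the residual noise is
  i.i.d., the first 20 principal components capture essentially all
  discriminative structure *and* denoise it; PCA-LDA therefore attains
  ~99–100 % LOOCV accuracy, above the 6-band GA-LDA model (~92–96 %),
  inverting the ordering seen on real serum spectra, where structured
  high-rank variability contaminates full-spectrum components. Passing
  recovery tests here show the GA finds the planted chemistry; they do not
  show feature selection beats feature extraction on real data.
* The selection-then-LOOCV workflow (and full-data PCA) is optimistically
  biased; the reported accuracies are workflow-faithful, not unbiased
  generalization estimates.
* The baseline iterate undershoots at grid edges for very peak-heavy
  spectra; the dead-band refinement that would mitigate it is out of scope.
* Only two-class problems, one spectra format (wide CSV), and no handling
  of mismatched grids.
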