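# sersband

Genetic-algorithm Raman band selection and linear-discriminant diagnostics
for serum surface-enhanced Raman spectroscopy (SERS), with a synthetic
two-class spectrum generator so the whole pipeline is testable without any
patient data.

## The problem

Label-free serum SERS is a candidate tool for non-invasive cancer screening:
a drop of serum mixed with silver nanoparticles yields a vibrational
fingerprint of circulating proteins, nucleic acids and lipids. Disease
shifts the *relative* intensities of a handful of Raman bands by a few
percent, buried under a strong autofluorescence background, per-sample
intensity variability and noise. Whole-spectrum classifiers (PCA-LDA, SVM)
can separate the classes but leave the clinician with no idea *which*
chemistry drives the call. This package implements the interpretable
alternative: a genetic algorithm (GA) that searches for a small set of
spectral bands whose leave-one-out cross-validated (LOOCV) LDA accuracy is
maximal, so the final diagnostic model is a six-band linear discriminant
whose inputs are nameable vibrational bands.

## The method

* **Preprocessing** — iterative fifth-order polynomial peak-clipping fit of
  the fluorescence background (fit, clip the signal to the fit, refit until
  stable), Savitzky–Golay smoothing, and normalization to unit area under
  the curve.
* **Segment encoding** — the 1270-variable, 400–1800 cm⁻¹ spectrum is tiled
  into 254 contiguous 5-variable segments; a *chromosome* is 6 unique
  segment ids (30 variables).
* **Fitness** — LOOCV accuracy of a two-class Fisher discriminant
  `w ∝ (S_w + λI)⁻¹(μ_cancer − μ_normal)` restricted to the chromosome's
  variables, with the threshold at the midpoint of the projected class
  means (cancer scores higher).
* **GA loop** — population 20, 100 generations, single-point crossover
  (p = 0.7) with duplicate repair, per-individual mutation (p = 0.05),
  copy of the best 25 % over the worst 25 %, and elitism (the all-time
  best individual is reinserted whenever it would otherwise be lost, so
  the best fitness never decreases).
* **Consensus** — the GA is rerun independently (100 runs by default) and
  each run's best segments are cumulatively counted; the top-count
  segments, merged when adjacent, are the diagnostic bands.
* **Evaluation** — confusion metrics (cancer = positive class), ROC/AUC
  from the pooled held-out discriminant scores (trapezoid rule, equal to
  tie-corrected pair counting), per-band pooled-variance t-tests, and a
  PCA-LDA comparator (LOOCV-LDA on the first 20 principal-component
  scores).

The synthetic generator emulates the target data: Lorentzian peaks at 15
canonical serum SERS positions on a random positive fifth-order
background, with signed relative class effects (negative in cancer at 481,
1219, 1445, 1585 cm⁻¹; positive at 683, 1025, 1314, 1640 cm⁻¹), lognormal
global scale, per-peak amplitude jitter and additive noise; the default
cohort is 55 "cancer" + 36 "normal" spectra.

## Worked example

```python
import numpy as np
import sersband as sb

# simulate the study-sized cohort and preprocess it
cfg = sb.SyntheticConfig(seed=0)
clean, _ = sb.preprocess_set(sb.simulate_dataset(cfg))

# repeated GA band selection with consensus counting
idx = sb.build_segment_index(clean.grid.n_points, 5)
counts, runs = sb.consensus_counts(
    clean, sb.GAConfig(n_runs=10, seed=0), idx,
    evaluator=sb.FitnessEvaluator(clean, idx))
bands = sb.top_bands(counts, idx, clean.grid, k=6)
for b in bands:
    print(f"band {b.lo:7.1f}-{b.hi:7.1f} cm^-1  segments {b.segments}  count {b.total_count}")

# LOOCV-LDA on the selected variables, and the PCA-LDA comparator
variables = np.sort(np.concatenate(
    [sb.expand_chromosome(b.segments, idx) for b in bands]))
cv = sb.loocv(clean.matrix, clean.labels, variables=variables, ids=clean.ids)
m = sb.compute_metrics(cv)
print(f"GA-LDA: sensitivity {100*m.sensitivity:.1f}%  specificity {100*m.specificity:.1f}%  "
      f"accuracy {100*m.accuracy:.1f}%  AUC {sb.roc_from_cv(cv).auc:.3f}")
```

prints (about a minute on one CPU):

```
band   477.2-  487.2 cm^-1  segments (14, 15)  count 4
band   681.3-  685.7 cm^-1  segments (51,)  count 2
band  1221.9- 1226.3 cm^-1  segments (149,)  count 3
band  1304.6- 1309.1 cm^-1  segments (164,)  count 4
band  1586.0- 1590.4 cm^-1  segments (215,)  count 3
band  1646.7- 1651.1 cm^-1  segments (226,)  count 3
GA-LDA: sensitivity 92.7%  specificity 91.7%  accuracy 92.3%  AUC 0.970
```

The six consensus bands sit at (or immediately beside) six of the eight
peaks the generator perturbs — 481, 683, 1219, 1314, 1585 and 1640 cm⁻¹ —
and the six-band discriminant separates the held-out spectra with ~92 %
accuracy: the tally tells you *where* the diagnostic chemistry is, the
metrics tell you how well those bands alone classify.

The same pipeline is scriptable from the shell:

```sh
sersband simulate   --seed 0 --out raw.csv
sersband preprocess --in raw.csv --out clean.csv
sersband select     --in clean.csv --runs 10 --seed 0 --out counts.json
sersband classify   --in clean.csv --bands counts.json --out cv.json
sersband evaluate   --cv cv.json --out roc.json
sersband run        --seed 0 --out-dir results/   # all five stages + manifest
```

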