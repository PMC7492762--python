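# flimlca

Latent-class survival analysis of FRET-FLIM molecular imaging cohorts.

Randomized oncology trials often hide subgroups: a small fraction of
patients with a distinct prognosis and a distinct treatment response that
average-effect analyses cannot see.  `flimlca` implements, on fully
synthetic data with known ground truth, the statistical chain used to find
such subgroups from HER2-HER3 dimerization imaging in advanced colorectal
cancer:

1. **FRET-FLIM quantification** — matched donor (D) and donor-with-acceptor
   (DA) fluorescence-lifetime images give a per-region FRET efficiency
   `E = 1 − τ_DA / τ_D`, a concentration-independent measure of receptor
   dimerization, after an autofluorescence lifetime filter.
2. **Latent-class survival model** — a K-component mixture of
   proportional-hazards models.  Patient `i` in class `k` has hazard
   `h_k(t | x) = h0_k(t) · exp(β_k·x)` with class-specific piecewise-constant
   baseline hazards `h0_k` and class-specific coefficients `β_k`; classes are
   latent with mixing weights `π_k`.  The model is fitted by EM, `K` and the
   baseline complexity are chosen by BIC, and patients are assigned by
   maximum a posteriori (MAP) membership.
3. **Covariate reduction** — backwards elimination under repeated
   cross-validated held-out partial log-likelihood, with ridge
   (Gaussian-prior MAP) inner fits.
4. **Class-prediction signature** — a zero-mean linear score
   `s = w·x̃ + c` on standardized covariates, thresholded at the Youden
   point (`J = sensitivity + specificity − 1`) of its ROC curve, applicable
   blind to a validation cohort.
5. **Survival statistics and a permutation overlap test** — Kaplan-Meier
   curves, log-rank tests, univariable hazard ratios, and a fixed-marginal
   permutation test of agreement between two class assignments
   (alignment-maximized so a 2-class and a 3-class structure can be
   compared).

The synthetic-data module is a first-class component: its `coin-os` preset
generates 398-patient cohorts with a 15.6% good-prognosis class (treatment
hazard ratio 0.43 inside that class, FRET hazard ratio 0.64 per SD in the
majority class) and a cohort FRET-efficiency distribution calibrated to
mean 1.6% with quartiles 0.18% / 2.7%, plus matched synthetic D/DA lifetime
image pairs with planted efficiencies and autofluorescence contamination.

## Worked example

```python
import numpy as np
from flimlca import (coin_os_spec, simulate_cohort, fit_latent_class_model,
                     class_proportion, hazard_ratios)

cohort = simulate_cohort(coin_os_spec(n_patients=2000, separation=2.0, seed=7))
model, assignment = fit_latent_class_model(
    cohort, ["trt", "ras_mut", "fret", "fret_x_her3"],
    k=2, n_bins=4, n_restarts=6, seed=1)

print(f"mixing weights: {np.round(model.mixing_weights, 3)}")
print(class_proportion(assignment)[["class", "count", "percent"]])
print(f"MAP accuracy: {(assignment.map_label == cohort.true_class).mean():.3f}")
hr = hazard_ratios(model)
print(hr[(hr["class"] == 1) & (hr.covariate == "trt")]
      [["hr", "ci_low", "ci_high"]].round(2))
```

prints

```
mixing weights: [0.14 0.86]
   class  count  percent
0      1    164      8.2
1      2   1836     91.8
MAP accuracy: 0.910
     hr  ci_low  ci_high
0  0.13    0.05     0.35
```

The fitted mixing weight recovers the planted 15.6% class-1 share (0.14 at
this seed), 91% of patients are assigned to their true class, and the
class-1 treatment hazard ratio CI covers the planted value (0.43² ≈ 0.18 at
this doubled-separation setting).  Note the MAP-assigned share (8.2%) sits
below the mixing weight: borderline patients default to the majority class,
a generic feature of MAP assignment under a skewed prior.

A full pipeline (simulation → imaging → latent classes → reduction →
signature → permutation test) runs from a YAML config:

```bash
flimlca run --config config.yaml --seed 1 --outdir out/
```

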