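# svispec

Screen-illumination video colorimetry for powder authentication.

A smartphone held over a pressed powder pellet displays a colour gradient
sweeping from purple to red on its screen while the front camera records a
short video of the illuminated sample surface. Because each surface
reflects each illumination colour differently, the per-frame colour
response is sample-specific: splitting the video into F frames, cropping a
fixed region of interest (ROI), and averaging each RGB channel over the
ROI yields a length-3F feature vector (R block | G block | B block; 531
variables at the canonical F = 177) that behaves like a spectrum. Standard
chemometrics then links these "spectra" to sample labels.

`svispec` implements that pipeline end to end for whey protein concentrate
(WPC) authentication — brand identification over 15 brands, fat and energy
quantification, adulterant-type detection (maltodextrin, wheat flour, milk
powder) and adulteration-level quantification — for food-quality
researchers who want a desk-reproducible version of the method. Since
recorded videos are bulky and instrument-specific, the package ships a
seeded forward simulator that renders complete synthetic studies
(screen gradient × class reflectance curves × sensor noise), so every
stage is testable from scratch.

## Models

All three predictive models are implemented from first principles:

- **PLSR** — partial least squares regression via NIPALS (PLS1 per
  response column): latent variables t = Xw maximising cov(t, y), with the
  component count A ∈ {1..10} as hyperparameter.
- **PLS-DA** — PLSR on a one-hot class indicator matrix with an argmax
  decision rule.
- **K-ELM** — kernel extreme learning machine, a kernel ridge-style
  learner: output weights solve (I/C + K)α = T with the RBF kernel
  K(u, v) = exp(−‖u−v‖²/σ); C and σ are searched on the log grid 2¹..2¹⁰.

The evaluation protocol is a stratified 2:1 train/test split, 10-fold
cross-validated hyperparameter selection on the training set (pooled
out-of-fold RMSE or accuracy), refit, and held-out prediction, reporting
RMSE/MAE/R² (subscripts CV and P for cross-validation and prediction) or
accuracy with a confusion matrix. Min-max normalization to [0, 1] is
fitted on training rows only and refitted inside each CV fold; a
`--paper-compat` flag reproduces the common (mildly leaky) normalize-first
order instead.

## Worked example

Simulate the milk-powder adulteration series (task 5: 10 levels × 5
replicates plus 5 unadulterated samples, 55 in total), then quantify the
adulteration level with K-ELM:

```
$ svispec simulate --task 5 --seed 1 --out runs/t5 --spectra-only
INFO simulated task 5: 55 samples -> runs/t5

$ svispec train --task 5 --model kelm --seed 1 --data runs/t5/spectra.csv --out runs/t5/report.json
task 5 | kelm | selected {'C': 1024.0, 'sigma': 1024.0} | RMSE_CV=0.01034 R2_CV=0.9958 | RMSE_P=0.01119 MAE_P=0.009147 R2_P=0.9942 | n_train=37 n_test=18
```

Reading the output: 10-fold cross-validation on the 37 training samples
selected regularisation C = 1024 and kernel width σ = 1024; on the 18
held-out samples the predicted adulteration fraction deviates from truth
by 0.011 RMS (RMSE_P), 0.009 on average (MAE_P), explaining 99.4% of the
level variance (R²_P). `train` without `--data` simulates the task's
default synthetic dataset itself; `svispec convert` turns directories of
recorded frames into the same spectra CSV, and `svispec evaluate` applies
a saved model bundle (`--model-out`) to new spectra.

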