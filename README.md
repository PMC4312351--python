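# scglasso

Structure-adaptive graphical lasso for MEG envelope connectomics:
sparse precision-matrix estimation for region-level amplitude-envelope
time series in which anatomically weaker connections receive stronger
penalties, with BIC model selection under temporal autocorrelation and
a nested cross-validated classification pipeline for patient-group
discrimination.

## The problem

Resting-state functional connectivity between cortical regions is often
summarized by the precision matrix Θ = Σ⁻¹ of the region-level envelope
signals: under a Gaussian model, Θᵢⱼ = 0 means regions *i* and *j* are
conditionally independent given all others, so the nonzero pattern of Θ
is the functional network. With finite noisy data the naive inverse of
the sample covariance *S* is dense and unstable, so Θ is estimated by
maximising the ℓ1-penalized log-likelihood

```
log det Θ − tr(S Θ) − λ Σ_{i≠j} W_ij |Θ_ij|
```

over positive-definite Θ. Three penalty variants are implemented:

| mode | weights | meaning |
|------|---------|---------|
| `GL`  | W ≡ 1            | plain graphical lasso |
| `GLa` | W_ij = 1/\|S_ij\| | functionally adaptive: weakly covarying pairs penalized more |
| `GLd` | W_ij = 1/FD_ij   | structurally adaptive: pairs without anatomical support penalized more |

`FD` is the tractography fiber density, FDᵢⱼ = (nᵢⱼ/N) · 2/(Vᵢ+Vⱼ)
(streamline share normalized by mean region volume). Absent tracts get
a large *finite* weight, so anatomy guides — but never forbids — a
functional connection. The diagonal is unpenalized and weight matrices
are rescaled to unit mean so λ is comparable across modes.

λ is chosen by minimising BIC over a log-spaced grid that is sharpened
up to three times around the running minimiser, subject to a 20 %
network-density cap (the density of the group-average structural
network). Because envelope series are strongly autocorrelated, BIC uses
the effective sample size n_eff = n / (1 + 2 Σₖ ρ̂ₖ) instead of the raw
point count. Variants are compared by 10-fold cross-validated Gaussian
log-likelihood over contiguous time blocks, and the resulting networks
feed a two-group classification pipeline: Mann-Whitney feature
screening of the vectorized precision entries, then regularized LDA,
kNN, or polynomial/RBF SVM with feature count and hyperparameters
chosen by nested 10-fold cross-validation (screening and fitting never
see held-out subjects).

A built-in cohort simulator generates coupled structural/functional
networks, AR(1) Gaussian envelope series with stationary covariance
exactly Θ⁻¹, and a planted between-group difference on structurally
supported edges, so the whole pipeline is testable without any data
download.

## Worked example

```python
import scglasso as sg

cohort = sg.make_cohort(sg.CohortSpec(n_per_group=2, seed=11))
rec = cohort[0]

S = sg.sample_covariance(rec.envelopes, rec.fd.labels)
n_eff = sg.multichannel_ess(rec.envelopes)
W = sg.structural_weights(rec.fd)

sel = sg.select_lambda(S, W, n_eff, weight_mode="GLd")
print(f"effective sample size : {n_eff:.1f} (of T = {rec.envelopes.shape[0]})")
print(f"selected lambda       : {sel.lam_min:.4f}")
print(f"network density       : {sel.final.density:.3f}")

rep = sg.crossval_compare(rec.envelopes, "GLd", rec.fd, labels=rec.fd.labels)
print(f"mean CV log-likelihood: {rep.fold_logliks.mean():.1f}")
print(f"mean fold lambda      : {rep.mean_lam:.4f}")
```

prints

```
effective sample size : 389.0 (of T = 1200)
selected lambda       : 0.4539
network density       : 0.200
mean CV log-likelihood: -1372.0
mean fold lambda      : 0.7040
```

The effective sample size is roughly T(1−φ)/(1+φ) = 400 for the
generator's AR(1) coefficient φ = 0.5; the selected network sits at the
20 % density cap, as resting-state envelope covariances typically do;
and the mean fold λ is what the final, classification-ready network
would be refit with.

A command-line interface mirrors the library
(`scglasso simulate | fit | select | crossval | classify | stability`);
run `scglasso --help` for the options.

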