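# attachkin

Quantitative analysis of heterogeneous bacterial surface attachment, for
microbiologists and biophysicists studying the initial stage of biofilm
formation in *Pseudomonas aeruginosa* (or any organism whose planktonic
population mixes attachment phenotypes).

## The model

In a no-growth attachment assay the total cell number
N = N_b(t) + N_s(t) (bulk + surface) is conserved, and the kinetics follow

    dN_b/dt = -dN_s/dt = - Σᵢ αᵢ N_bⁱ(t) + Σᵢ βᵢ N_sⁱ(t)

for i coexisting phenotypes with attachment rates αᵢ and detachment rates
βᵢ. When detach events are rare (the package audits this with an event-ratio
check), the detaching term drops and the bulk fraction decays as an
exponential mixture:

    N_b(t)/N = Σᵢ fᵢ exp(-αᵢ t),   Σᵢ fᵢ = 1,

with fᵢ = N_bⁱ(0)/N the number fraction of phenotype i. For
later-exponential-phase *P. aeruginosa* the published fit is two components:
f_fast ≈ 0.8 at α_fast = 5.45×10⁻³ s⁻¹ and f_slow ≈ 0.2 at
α_slow = 2.52×10⁻⁴ s⁻¹ (~20-fold apart), predicting >80% of cells attached
within 15 min.

Around this core the package provides:

* **`attachkin.simulate`** — seeded generators for every input: per-cell
  attachment tracks (event-driven exponential waiting times), bivariate
  inverted-reporter/lectin fluorescence (Gaussian copula calibrated to a
  target Pearson correlation), genealogical trees with drawn postdivision
  fates, and biofilm thickness grids calibrated to a target roughness.
* **`attachkin.tracks`** — displacement-window attached/mobile
  classification, N_b/N_s count series, attach/detach flux audit,
  division-event extraction from parent-linked tracks.
* **`attachkin.kinetics`** — mixture evaluation, multi-start least-squares
  fitting with a simplex/log parameterisation, corrected-information-criterion
  component selection with identifiability guards, derived quantities.
* **`attachkin.hetero`** — background subtraction, CV, threshold
  proportions, channel Pearson correlation, Gaussian-kernel density at 100
  points, CV trajectories, Student's t plumbing.
* **`attachkin.lineage`** — both-stay / one-stays / both-leave fate
  classification and probability estimates with 1/N_div and binomial-SE
  uncertainty conventions.
* **`attachkin.biofilm`** — average thickness and roughness coefficient
  Ra* = mean(|L − L̄|)/L̄ on thickness grids.

## Worked example

`examples/attachment_kinetics.py` simulates 10,000 cells at the published
mixture, classifies and counts the tracks, and fits the model:

```
fast fraction : 0.796   (generating value 0.800)
alpha_fast    : 5.527e-03 1/s (generating value 5.450e-03)
alpha_slow    : 2.506e-04 1/s (generating value 2.520e-04)
rate ratio    : 22.1    (published: ~20-fold)
attached @15min: 83.2%  (published: ~80% within 15 min)
```

The recovered fractions and rates match the generating mixture to a few
percent from raw per-frame positions alone — the whole chain
(simulate → classify → count → fit) is exercised, not just the fitter. The
other scripts in `examples/` cover model selection, fluorescence
heterogeneity, lineage fates, biofilm metrics and the detachment audit,
each printing the numbers it computes and what they mean.

A thin CLI mirrors the pipeline for shell use:

```sh
attachkin simulate attach --config cfg.yaml --seed 1 --out tracks.csv
attachkin count --tracks tracks.csv --out series.csv
attachkin fit --series series.csv --kmax 3 --seed 1 --out fit.json
```

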