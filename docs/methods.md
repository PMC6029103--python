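# Methods

This note documents the models, the synthetic-data generators, the
numerical choices and the limitations of `attachkin`. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Attachment kinetics model

The package models surface attachment of a conserved population
(N = N_b + N_s) as a mixture of first-order processes: phenotype i attaches
at rate αᵢ (s⁻¹) and, optionally, detaches at rate βᵢ. With all βᵢ = 0 the
bulk fraction is the exponential mixture
N_b(t)/N = Σᵢ fᵢ exp(−αᵢ t). The analytic curve is verified in the tests
against brute-force numerical integration of the per-phenotype rate
equations (agreement ≤ 10⁻⁸ over an hour-long grid).

Detachment is never *fitted*. Instead `tracks.flux_check` counts attach and
detach transitions and warns when their ratio drops below 10:1 — the
regime in which dropping the detaching term is no longer defensible. This
keeps the model honest on datasets the simplification does not fit.

### Fitting

`kinetics.fit_mixture` minimises squared residuals on the untransformed
N_b/N scale. Late-time bulk counts are small; a log-scale objective would
overweight the slow tail, and nothing in the data model justifies that
weighting. Constraints are handled by parameterisation rather than by a
constrained optimiser: fractions through a softmax (simplex) map with the
last logit pinned to zero, rates through logarithms. The optimiser
(Levenberg–Marquardt) therefore runs unconstrained. Log-rate values are
clipped to ±50 so wild multi-start excursions stay finite.

Multi-start defaults: 20 starts, rates drawn log-uniformly from
[10⁻⁵, 10⁻¹] s⁻¹ (generously bracketing bacterial attachment timescales),
fractions from a flat Dirichlet, all from one seeded generator. Components
are reported fastest-first. Approximate standard errors come from the
Gauss–Newton covariance in the free parameterisation, propagated to the
natural scale by the chain rule.

### Component-count selection

`kinetics.select_k` scores k = 1…k_max by a small-sample corrected AIC
(p = 2k − 1 mixture parameters + 1 noise variance) and additionally rejects
any k whose fit is unidentifiable: two rates within a factor of 3, or a
component fraction below 2%. Such a fit can always be mimicked by k − 1
components, so the guard collapses it. The guard thresholds are
deliberately coarse — they encode "a phenotype must be kinetically
distinguishable and non-negligible", not a statistical test.

On a noiseless single-exponential curve a two-component fit attains a
slightly smaller RSS with a redundant component; only the guard, not the
criterion, reliably rejects it. Both mechanisms are therefore kept.

## Synthetic generators: what they emulate, and what not

All generators draw every random quantity from a single
`numpy.random.Generator` seeded per call, so outputs are bit-reproducible.

### Attachment tracks (`simulate.simulate_attachment`)

Event-driven: each cell draws its phenotype from the number fractions and
an exponential attachment waiting time at that phenotype's rate, which is
then discretised to the frame grid (3-s frames over a 165 × 139 µm field by
default, matching a typical single-field assay). Drawing waiting times
avoids the per-frame Bernoulli bias a time-stepped scheme would incur at
coarse frame intervals. With βᵢ > 0 a per-cell alternating
exponential-clock walk generates attach/detach cycles.

Positions: mobile cells perform a reflected Gaussian random walk with
per-axis step SD √(2·D·Δt) (default D = 0.5 µm²/s); attached cells hold
their landing position plus Gaussian jitter (default 0.05 µm). The step
into the frame in which a cell first counts as attached is *not*
suppressed: the cell walked before landing, so its landing position
differs from the previous frame. This detail is what lets the displacement
classifier detect the attachment at the correct frame.

Not emulated: cell shape and pole positions, drift, crowding, hydrodynamic
interactions, pixel-level imaging noise. Passing tests show the counting
and fitting machinery recovers generative truth from idealised tracks; they
cannot certify the displacement classifier against real microscopy
artefacts.

### Two-channel fluorescence (`simulate.simulate_fluorescence`)

Latent single-cell expression is log-normal — measured intensity
histograms are unimodal and right-skewed, and no distribution family is
established for this reporter, so log-normal is a documented stand-in, not
a biological claim. Each channel applies a monotone log-linear transfer to
its own standard-normal copula coordinate (direction +1 for the lectin
stain, −1 for the inverted reporter, whose EGFP output falls as *psl*
expression rises) plus multiplicative log-normal noise.

The two copula coordinates are jointly Gaussian with correlation ρ.
Calibration happens in two stages. The Pearson correlation of a bivariate
log-normal has a closed form, and inverting it for the requested target
(−0.45 by default) gives the population-level ρ — and an attainability
check, since log-normal marginals bound how negative a Pearson correlation
can be; unattainable targets raise a parameter error. But with heavy-tailed
marginals the *sample* Pearson of a 2000-cell draw scatters by ±0.05 or
more around the population value, so the generator then refines ρ by a
one-dimensional root search until the realised sample correlation of the
actual draw (fixed normal deviates and noise, only the mixing coefficient
varying) hits the target to solver precision. The generator's contract is
thus on the sample it returns, not on an asymptotic property; samples below
10 cells skip the refinement and are flagged, and the returned metadata
records both the refined and the population ρ. Default channel maps put
the inverted-reporter marginal at mean ≈ 312 a.u. with CV ≈ 0.99, the
scale of published background-subtracted single-cell measurements.

### Lineage forests (`simulate.simulate_lineage`)

Founders and every "stay" daughter divide after exponential waiting times
(only the mean interval is constrained by the data being emulated; the
exponential family is a configurable modelling choice). Each division
draws an independent fate from (p_both_stay, p_one_stays, p_both_leave);
"leave" daughters terminate with a recorded detach, "stay" daughters keep
dividing until the observation ends. Daughters observed for less than
`censor_window` (default 9 s = 3 frames at 3-s intervals) are censored and
their division excluded from N_div — the movie-edge rule that prevents
fate misclassification at the end of an acquisition.

`presets.lineage_config` sizes the forest from the fate triple's branching
factor m = 2·p_both_stay + p_one_stays: a Markov branching process with
division rate 1/interval accumulates (e^{(m−1)T/interval} − 1)/(m−1)
divisions per founder by time T, and founders are scaled so the expected
total is ~600 — comfortably inside the N_div > 200 regime published fate
probabilities rest on, for sub- and supercritical regimes alike.

The three strain presets complete partially-published fate triples:
only the headline category is pinned by the published bar chart
(both-leave = 60% for the Psl-null strain, both-stay ≈ 80% for the uniform
RBS-replacement strain, one-stays > 40% for the wild type); the remaining
entries — (0.30, 0.45, 0.25), (0.80, 0.15, 0.05), (0.10, 0.30, 0.60) — are
chosen once to match the qualitative description of each strain and are
not revisited.

### Thickness grids (`simulate.simulate_heightmap`)

The exponential of a smoothed Gaussian field (correlation length 4 px by
default) — positive by construction and right-skewed like real
local-thickness maps. The exponent scale is calibrated by a Brent root
search so the realised roughness coefficient hits the target to solver
precision, and the grid is renormalised so the mean is exact. Roughness
targets beyond the construction's reachable value (~1.9) raise a parameter
error. No spatial statistics beyond the two summary metrics are emulated.

## Track classification

A frame is attached when it lies inside *some* window of 5 consecutive
frames (15 s) whose maximum pairwise displacement is below 1 µm. Marking
the whole certifying window ("backdating") puts the detected attach time at
the first stationary frame; the pure trailing-window variant
(`backdate=False`) is retained and lags by window − 1 frames, which
systematically inflates fitted fast amplitudes. The real operational
definition of "surface-attached" in tracking pipelines is tied to
pole-resolved imaging that is out of scope here; this rule is the simplest
auditable surrogate, and the round-trip test pins exactly when it
reproduces generator truth (zero attached jitter, mobile steps well above
threshold, away from the final window − 1 frames of the movie, where no
complete stationary window can exist).

## Fate probabilities

Estimates are category counts over N_div (per-division, matching the
three-way partition). Two uncertainty conventions are always reported: the
literal 1/N_div convention used alongside published fate bar charts —
preserved for comparability, though it is likely a shorthand for the
√N_div-type scaling — and the per-category binomial SE √(p(1−p)/N_div),
which is the one to use for inference.

## Heterogeneity statistics

CV uses the n−1 sample SD (the convention is not fixed by any published
definition; the scale-invariance property tested is unaffected). Threshold
proportions use strict inequality, matching "greater than X a.u."
phrasing. KDE uses a Gaussian kernel with Silverman bandwidth on a
100-point grid spanning the sample range. Background subtraction clips at
zero and reports the clip count rather than hiding it, since whether
published CVs were computed before or after clipping is unknowable.

## Problem sizes and determinism

Default verification sizes — 10⁴ cells for Monte-Carlo/pipeline checks,
2000 cells for correlation recovery, ~600 divisions for fate recovery,
10⁶-count noiseless curves for exact-recovery tests — were chosen so every
stochastic assertion sits at 3 standard errors with comfortable margin
while the whole suite runs in well under a minute per module. All
stochastic tests and the acceptance script are seeded; the acceptance
script derives independent sub-seeds (< 2³¹) from its single `--seed`
argument via `numpy.random.SeedSequence`.

## Known limitations

* The displacement classifier is a surrogate, not a reimplementation of
  pole-resolved two-point tracking; its parameters (5 frames / 1 µm) are
  defaults to be tuned per dataset.
* Whether published mixture fractions are fitted amplitudes or event-count
  fractions is ambiguous; this package reports fitted amplitudes.
* Biofilm metrics operate on thickness grids only; z-stack segmentation,
  biovolume, substratum coverage and the rest of the COMSTAT feature set
  are out of scope.
* Gene-regulatory dynamics (RsmY/RsmZ/RsmA) are represented only through
  their measured statistical signatures, never mechanistically.
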