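"""Fit the two-phenotype attachment mixture to a simulated one-hour movie.

Simulates 10,000 planktonic cells at the published later-exponential-phase
parameters (80% fast-attaching at 5.45e-3 1/s, 20% slow at 2.52e-4 1/s),
classifies each frame of each track as attached or mobile from the
displacement criterion, counts the bulk/surface series, and fits the
exponential mixture N_b(t)/N = sum_i f_i exp(-alpha_i t).
"""

from attachkin import (
    count_series,
    derived_quantities,
    fit_mixture,
    presets,
    simulate_attachment,
)
from attachkin.tracks import classify_tracks

cfg = presets.attachment_config(n_cells=10_000, seed=1)
tracks = simulate_attachment(presets.LATE_EXPONENTIAL_MIX, cfg)
attached = classify_tracks(tracks)          # displacement-window classifier
series = count_series(tracks, attached)     # N_b(t), N_s(t), N
fit = fit_mixture(series, k=2, n_starts=20, seed=1)
dq = derived_quantities(fit)

print(f"fast fraction : {dq.fraction_fast:.3f}   (generating value 0.800)")
print(f"alpha_fast    : {fit.rates[0]:.3e} 1/s (generating value 5.450e-03)")
print(f"alpha_slow    : {fit.rates[1]:.3e} 1/s (generating value 2.520e-04)")
print(f"rate ratio    : {dq.rate_ratio:.1f}    (published: ~20-fold)")
print(f"attached @15min: {dq.percent_attached_at(900.0):.1f}%  (published: ~80% within 15 min)")
# The fast fraction and rates recover the generating mixture from raw
# per-cell tracks; the 15-min attachment percentage is the model's headline
# prediction for a later-exponential-phase culture.
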