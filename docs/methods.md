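# Methods

## Growth laws

The package models post-weaning live weight `W(t)` (kg, `t` in days since
weaning) with two nested laws.

**Gompertz.** `dW/dt = μW`, `dμ/dt = −Dμ`, closed form
`W(t) = W₀ exp[(μ₀/D)(1 − e^(−Dt))]`, asymptote `W₀ e^(μ₀/D)`.  The
implementation uses `expm1`, so the `D → 0` limit degrades gracefully to
exponential growth at rate `μ₀`.

**Perturbed (Gompertz–Makeham).** The growth rate is reduced by an
age-independent term `C` during a perturbation window `[0, t_s]` and the
deduction is switched off afterwards.  The trajectory integrates piecewise
to closed form; continuity at `t_s` is exact by construction and verified
to 1e−9 relative in the property tests.  The boundary point `t = t_s` is
assigned to the perturbation window (a measure-zero choice that does not
affect the trajectory).  With `C = 0` the perturbed law equals the Gompertz
law pointwise.

The closed forms are the production code path.  A numerical integrator
(`integrate_ode_oracle`, RK45 at rtol 1e−10 with the switch as a hard
integration breakpoint) is retained purely as an independent cross-check;
the suite verifies agreement to ≤1e−6 relative over 100 random parameter
draws on [0, 75] d.

## Calibration

Per animal, `W₀` is fixed at the observed weighing at `t = 0` (it is a
measurement, not a free parameter), and weighings after the 75-day horizon
are ignored.  `(μ₀, D)` and `(μ₀, D, C, t_s)` are estimated by Nelder–Mead
on the weighted objective `J = SSE/n_t` (kg²).  Positivity of `μ₀, D, C` is
enforced by optimising logarithms; `t_s` is mapped into (0, horizon) by a
logistic transform, so the search is unconstrained.  Because the objective
is only piecewise-smooth in `t_s`, the perturbed fit multi-starts from
`t_s ∈ {5, 10, 15, 20}` d plus one near-zero-`C` start (which guarantees
the nested Gompertz solution is always reachable, so
`J_perturbed ≤ J_gompertz` holds by construction up to solver tolerance).
Each start gets a coarse simplex run; the winner (ties broken toward
smaller `t_s`) receives one seeded jittered restart and a tight polish
(`xatol` 1e−8 in transformed space, `fatol` 1e−14 kg²).  On noiseless data
this recovers generating parameters to ~1e−8 relative; tighter tolerances
only lengthen noisy fits without changing any reported digit.  Starts
inherited from the animal's own Gompertz fit are clamped to
μ₀ ∈ [1e−3, 0.3], D ∈ [0.005, 0.1] d⁻¹, because on strongly perturbed data
the Gompertz fit legitimately collapses toward its exponential limit
(D → 0) and would otherwise strand the simplex.

Animals with fewer than 4 (Gompertz) or 6 (perturbed) in-horizon weighings
are flagged and skipped, never silently dropped; the pipeline manifest
counts them.

**Identifiability.** The fit is practically identifiable whenever at least
one weighing falls strictly inside the perturbation window.  If the fitted
window closes before the first post-weaning weighing (day 3 on the default
schedule), only the product `C·t_s` enters the likelihood — the objective
has an exactly flat ridge in `(C, t_s)` — and the reported coordinates on
that ridge are a tie-break choice, not estimates.  `FitResult` flags this
(`n_obs_in_window` / `window_identifiable`); the pipeline masks flagged
`C` and `t_s` from population summaries and correlation screens while
keeping the (valid) fitted curve, `J`, AIC and ABC.  Under the default
generator (`t_s ~ N(9, 3)` truncated to (2, 30) d) about 1.3% of animals
draw `t_s < 3` d and hit this boundary.

**Goodness of fit.** `r² = 1 − SSE/SStot` and Lin's concordance
coefficient with population (1/n) moments,
`CCC = 2s_xy / (s_x² + s_y² + (x̄ − ȳ)²)`, which penalises location as
well as dispersion disagreement, so `CCC ≤ |r|`.  Zero-variance observed
series yield flagged NaNs.

**Model selection.** Least-squares AIC `n_t ln J + 2(n_p + 1)` with
`n_p = 2` vs 4 (the +1 counts the residual variance); smaller wins; a
perfect fit returns a −∞ sentinel.  An optional second-order small-sample
correction (`compute_aic(..., small_sample=True)`) adds
`2k(k+1)/(n_t−k−1)`, `k = n_p+1` — relevant because `n_t ≈ 14` per animal
is small relative to 5 effective parameters.  Simulation at the default
study conditions (1.5% CV noise, 14-point schedule) shows the plain AIC
prefers the perturbed model for essentially all animals generated with
`C = 0.08` d⁻¹, but also for ~34% of animals generated with `C = 0`: the
extra `(C, t_s)` pair can mimic a slowly varying trend in log-weight
(`t_s` drifting to the horizon) and its typical noise-chasing gain exceeds
the penalty at this `n_t`.  The small-sample correction reduces the null
false-selection rate to ~12% but does not eliminate it.  Users doing formal
null-hypothesis screening at these sample sizes should prefer the
corrected criterion or a likelihood-ratio test; the plain form is kept as
the default selection rule for comparability.

## Resilience indices

Ranking animals by the weighted Gompertz `J` orders them by degree of
growth perturbation (dense ranks, deterministic tie-break by animal id).

The **unperturbed reference** is a Gompertz fit to exactly 5 points: the
weaning weighing plus the last four records within the horizon.  Because
that subset also contains the weaning weight of a perturbed animal, the
reference absorbs a small structural residual (<2% on the late points);
this is inherent to the construction, not a solver artefact.

The **ABC index** integrates the signed difference (reference − perturbed)
from weaning to the first crossing after `t_s`, found by sign-change
bracketing on a 0.1-day grid refined by Brent root-finding (1e−8 d), with
adaptive quadrature carrying `t_s` as an interior breakpoint.  Design
choices where the procedure was open: if the curves never cross within the
horizon the integral runs to the horizon and the record is flagged
*censored*; a crossing before `t_s` (reference below the perturbed curve
during the window) is anomalous and flagged rather than used; coincident
curves (C = 0, matched parameters) give ABC = 0 exactly; negative ABC is
left signed and surfaced as an anomaly flag.  The integrand is the signed
difference, not an absolute value, matching the geometric reading of the
index.

Population summaries report mean, SD (n−1), min, quartiles and max per
parameter; values are sorted before accumulation so the summaries are
bitwise permutation-invariant.

## Phenotype statistics

Faecal scores (0 normal / 1 soft / 2 evident diarrhoea) are aggregated per
animal as `FS_sum` (diarrhoea records over observations), `FS_gr`
(0 / 1 / ≥2 records → levels 0/1/2) and `FS_p_a` (any record).  A
"diarrhoea record" is score 2 only — the scale explicitly calls score 1
"without diarrhoea" — but the threshold is configurable
(`diarrhoea_scores=(1, 2)`).

`N/Lym` is the neutrophil over lymphocyte percentage ratio (NaN-flagged
when Lym = 0).  Trait normalisation is off by default with per-trait
log₂/log₁₀ overrides; correlations are Pearson and Spearman (mid-rank
ties) with two-sided t-approximation p-values and pairwise deletion,
delegated to scipy.stats and verified in the tests against hand-derived
textbook formulas to 1e−10.  The screen flags pairs at raw p < α
(default 0.05) without multiplicity correction; a Benjamini–Hochberg
`q_bh` column is emitted alongside as a clearly-labelled extension and
plays no role in the flag.

## Synthetic cohorts

The generator emulates the targeted field conditions: weaning at 28 d of
age; weighings at `t = 0`, then alternating 3/4-day gaps until 50 d of age
and weekly until 100 d (13 post-weaning points within the 75-day horizon);
`W₀ ~ N(8.91, 0.49²)` kg (the ±0.49 treated as a population SD);
`μ₀` and `D` lognormal with medians 0.05 and 0.02 d⁻¹ and log-SD 0.1 —
chosen to give a plausible mature weight `W₀e^(μ₀/D) ≈ 110` kg —
`C ~ U(0, 0.12)` d⁻¹ with an optional point mass at 0, and
`t_s ~ N(9, 3)` d truncated to (2, 30), centred on the ~9-day average
recovery.  Measurement noise is multiplicative lognormal (default CV
1.5%, a realistic livestock-scale precision): it preserves positivity and
scales with weight, and it applies to the weaning weighing too, so the
fixed `W₀` carries measurement error like any other record.

Diarrhoea risk on the 9 panel days (0–34 post-weaning) follows
`P(score 2) = logistic(−2.2 + 25·C − 0.3·max(0, d − t_s))` — risk rising
with perturbation depth and decaying after recovery — with soft faeces at
a fixed conditional probability 0.2.  Haemogram traits are
`mean + sd·(r·z + √(1−r²)·ε)` around field-plausible baselines, where `z`
is the standardised driver parameter and `r` the target correlation; the
default loadings reproduce the signs and approximate magnitudes of the
strongest associations reported for weaned piglets (Hct, Hgb, MCV, Ery
negative and MCHC positive with perturbation depth at 28 d of age; Hgb,
MCH negative and Plt positive with `D`, and Mon negative / Eos positive
with the perturbation at 34 d).  Where a reported association involves the
ABC index, the generator uses `C` as the latent driver, since ABC is
monotone in `C` at fixed other parameters.  Percent-valued traits are
truncated at zero.

Each animal draws from its own `SeedSequence` substream, so cohorts are
reproducible animal-by-animal and all emitted CSVs are byte-identical for
a fixed seed (floats are written in shortest-round-trip form and parsed
with the round-trip parser).

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: litter, batch, sex and genetic structure;
correlated `(μ₀, D)` draws (field estimates correlate strongly);
within-animal serial correlation of weighing errors; missing weighings and
scale changeovers; diarrhoea contagion between pen mates.  Parameter
recovery results are therefore a statement about the estimator under the
stated noise model, not about biological validity.

## Problem sizes and numerics

The test suite exercises cohorts of 6–50 animals, 100-replicate noise and
screening studies at n = 300, and 100-draw oracle sweeps; the acceptance
script runs the full pipeline on one 325-animal cohort.  A perturbed fit
takes ~0.2 s, a full per-animal pipeline pass ~0.4 s.  Degenerate inputs
are handled explicitly: flat trajectories (fitted μ₀ → 0, flagged NaN r²),
perfect fits (J = 0 → −∞ AIC sentinel), zero-variance vectors in
correlations (flagged undefined), animals lacking a weaning record or
enough points (skipped with logged reasons, counted in the manifest).

## Known limitations

* `C` and `t_s` are unidentifiable when recovery precedes the first
  post-weaning weighing (flagged, see Calibration); denser early weighing
  is the only remedy.
* The unperturbed reference is biased low for animals still perturbed in
  their last four in-horizon weighings (very late `t_s`); their ABC is
  then an underestimate.
* No uncertainty quantification on per-animal parameters (a bootstrap
  would be straightforward but is out of scope).
* The AIC null-selection behaviour at `n_t ≈ 14` (see Model selection)
  means "perturbed preferred" should not be read as a per-animal
  significance statement.
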