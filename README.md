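# weanling

Quantifying piglet resilience to weaning from body-weight trajectories.

Weaning is the most disruptive event in a piglet's life: an abrupt switch
from milk to solid feed, separation from the sow and a new social
environment, typically around 28 days of age.  Most piglets transiently
lose weight (100–250 g on the first day is common), some develop diarrhoea,
and individuals differ markedly in how deep the growth dip is and how fast
they recover.  `weanling` turns routinely collected post-weaning weighings
into per-animal resilience parameters, for quantitative geneticists,
precision-livestock researchers and modellers who want robustness
phenotypes without additional instrumentation.

## The model

Unperturbed growth follows a Gompertz law with exponentially decaying
specific growth rate,

```
μ(t) = μ₀ e^(−D t),        W(t) = W₀ exp[(μ₀/D)(1 − e^(−D t))],
```

with `t` days since weaning, `W₀` the weaning weight (kg), `μ₀` (d⁻¹) the
specific growth rate at weaning and `D` (d⁻¹) its decay coefficient.
Weaning is modelled as a Gompertz–Makeham perturbation: an additive,
age-independent deduction `C` (d⁻¹) acts on the growth rate during a
perturbation window and is switched off at a per-animal recovery time
`t_s` (days):

```
dW/dt = (μ(t) − C(t)) W,    C(t) = C for t ≤ t_s,   C(t) = 0 for t > t_s.
```

With `C = 0` the model reduces exactly to the Gompertz law; with
`C > μ(t)` the animal loses weight, which reproduces the early post-weaning
dip.  Both models are calibrated per animal by Nelder–Mead least squares on
the weighings of the first 75 days after weaning (`W₀` fixed at the
observed weaning weight; objective `J = Σ(W_d − W)²/n_t`), and compared by
the least-squares AIC `n_t ln J + 2(n_p + 1)`.

Resilience is summarised three ways:

* `C` — depth of the perturbation; `t_s` — recovery onset;
* the animal's Gompertz lack-of-fit `J`, which ranks the cohort by degree
  of growth perturbation;
* the **ABC index** (area between curves): the area between an
  *unperturbed reference* curve (Gompertz refitted to the weaning weight
  plus the last four in-horizon weighings, approximating growth had the
  perturbation not happened) and the perturbed fit, integrated from
  weaning to the first intersection of the two curves — an
  amplitude × duration summary of the perturbation, in kg·days.

Fitted parameters are screened against diarrhoea scores (FS_sum, FS_gr,
FS_p_a aggregates of a 0/1/2 faecal scale) and 13 haematological traits
plus the neutrophil/lymphocyte stress ratio, with Pearson and Spearman
correlations at a raw p < 0.05 threshold.

Because real cohort data of this kind are not publicly deposited, the
package ships a first-class synthetic-cohort generator
(`weanling.simulate`) that emulates the field conditions — weaning at
28 d of age at 8.91 ± 0.49 kg, twice-weekly then weekly weighings,
recovery at ~9 days on average, perturbation-linked diarrhoea risk and
haemogram loadings — so the whole pipeline is testable end-to-end against
known ground truth.

## Worked example

`examples/02_fit_single_animal.py` simulates one perturbed piglet
(μ₀ = 0.05, D = 0.02, C = 0.08, t_s = 9) on the standard weighing schedule
with 1.5% measurement noise and calibrates both models:

```
animal pig-42: 14 weighings, weaning weight 8.95 kg

Gompertz:   mu0=0.0166/d  D=0.0000/d  J=4.0977 kg^2  r2=0.925  AIC=25.7
perturbed:  mu0=0.0496/d  D=0.0193/d  C=0.0802/d  ts=9.11 d
            J=0.0196 kg^2  r2=1.000  CCC=1.000  AIC=-45.1

truth:      mu0=0.0500/d  D=0.0200/d  C=0.0800/d  ts=9.00 d
AIC selects the perturbed model (difference 70.8).
```

The Gompertz model cannot represent the dip-and-recover shape (its J is
200× larger) while the perturbed model recovers all four generating
parameters to within a few percent.  The other examples show the growth
laws themselves (`01`), a 25-animal cohort run with the ABC index and
population summary (`03`), and the phenotype correlation screen (`04`).
The same stages are available from the shell:

```
weanling simulate --n-animals 50 --seed 1 --out cohort/
weanling run --synthetic 50 --seed 1 --out run/
weanling plot cohort/weights.csv --out fit.png
```

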