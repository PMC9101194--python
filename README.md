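# pffuzzy

Fuzzy evaluation of individual physical-fitness indices from small
repeated-measurement samples.

## The problem

Individual fitness testing — a 1600 m run/walk time, sit-ups per minute,
standing long jump, seated forward flexion — produces only a handful of
measurements per item (ten is typical), yet the practical question is
binary: does each item meet a required level of healthy fitness?
Classical point estimation on n = 10 is noisy, and a classical
confidence-limit test is so forgiving at that sample size that a clearly
sub-par item can still "pass". `pffuzzy` implements a fuzzy evaluation
procedure designed for exactly this small-sample regime, for coaches,
clinicians and quantitatively minded individuals tracking a battery of
one-sided fitness indicators.

## The model

Measurements of each item h are assumed i.i.d. normal, X_h ~ N(μ_h, σ_h²).
Each item has a one-sided specification limit — an upper limit U for
smaller-the-better items (run time), a lower limit L for
larger-the-better items — and a capability-style index

    PF = (U − μ)/σ   or   PF = (μ − L)/σ,

the distance from the mean to the limit in standard-deviation units; the
population proportion of attempts meeting the limit is Φ(PF). From a
sample of size n with mean x̄ and standard deviation s (denominator
n − 1), the point estimate is PF\* = (U − x̄)/s (resp. (x̄ − L)/s), and a
conservative one-sided 100(1 − α)% upper confidence limit is

    U_PF = PF\* · sqrt(χ²_{1−α/2; n−1} / n) + z_{1−α/2} / √n,

combining a chi-square bound on σ and a normal bound on μ via Boole's
inequality. The nested family of such limits defines a half-triangular
fuzzy number with apex PF_M = PF\* · sqrt(χ²_{0.5; n−1}/n) (membership 1)
and right endpoint PF_R = U_PF (membership 0). The requirement PF ≥ k is
then judged by the fraction of the fuzzy number's base right of k,

    d_R / d_T = (PF_R − k) / (PF_R − PF_M),

against thresholds 0 < φ₁ < φ₂ < 1: at most φ₁ → **improve** (requirement
clearly missed), at least φ₂ → **maintain** (clearly met), in between →
**re-evaluate**. Defaults are α = 0.05, φ₁ = 0.4, φ₂ = 0.8.

## Worked example

The package ships a four-item fixture (an 18-year-old male student,
ten tests per item, k = 6, α = 0.05):

```sh
pffuzzy fixture exdir
pffuzzy evaluate exdir/example_measurements.csv exdir/example_spec.yaml
```

prints

```
## Testing statistics and index estimates

| item_id | name | limit | mean | sd | pf_star |
| --- | --- | --- | --- | --- | --- |
| cardio | Cardiorespiratory endurance (1600 m run/walk, s) | 598.0 | 590.6 | 1.838 | 4.03 |
| situps | Muscular endurance (sit-ups per minute) | 33.0 | 37.8 | 0.789 | 6.09 |
| jump | Muscular power (standing long jump, cm) | 185.0 | 190.3 | 1.16 | 4.57 |
| flex | Flexibility (seated forward flexion, cm) | 18.0 | 18.61 | 0.137 | 4.45 |

## Fuzzy evaluation table

| item_id | pf_m | pf_r | d_r | d_t | ratio | outcome |
| --- | --- | --- | --- | --- | --- | --- |
| cardio | 3.678 | 6.173 | 0.173 | 2.495 | 0.069 | improve |
| situps | 5.558 | 9.013 | 3.013 | 3.454 | 0.872 | maintain |
| jump | 4.175 | 6.924 | 0.924 | 2.749 | 0.336 | improve |
| flex | 4.066 | 6.759 | 0.759 | 2.693 | 0.282 | improve |
```

Reading the cardio row: the run-time estimate PF\* = 4.03 is well below
the requirement k = 6, and although the 95% upper confidence limit 6.173
exceeds 6 (so a classical test would not reject), only 6.9% of the fuzzy
number's base lies right of 6 — far below φ₁ = 0.4 — so cardiorespiratory
endurance is flagged **improve**. The sit-ups ratio 0.872 ≥ φ₂ = 0.8 says
that requirement is clearly met (**maintain**).

Note that the fixture's raw jump and flexion samples disagree with the
summary statistics published alongside them (raw jump mean 190.3 vs a
published 192); `pffuzzy.datasets` ships both, and feeding the published
estimates instead (`PhysicalFitnessModel.from_estimates`) reproduces the
published fuzzy table (ratios 0.071, 0.874, 0.859, 0.827 and maintain for
items 2–4). See `docs/methods.md`.

The same pipeline is available as a library:

```python
from pffuzzy import PhysicalFitnessModel, datasets

model = PhysicalFitnessModel(datasets.example_measurements(),
                             datasets.example_specs())
results = model.fit()
print(results.outcomes)   # {'cardio': 'improve', 'situps': 'maintain', ...}
print(results.summary())
```

Monte-Carlo operating characteristics (UCL coverage, outcome rates as
the true index moves around k) are in `pffuzzy.simulation` and the
`pffuzzy simulate` verb.

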