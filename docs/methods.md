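# Methods

## Model and assumptions

Each fitness item h is a one-sided quality characteristic measured by
i.i.d. normal repeats X_h ~ N(μ_h, σ_h²). The index

PF_h = (U_h − μ_h)/σ_h (smaller-the-better) or (μ_h − L_h)/σ_h
(larger-the-better)

is dimensionless and invariant under common affine changes of the
measurement scale and limit; the compliance ratio Φ(PF_h) is the
population fraction of attempts meeting the limit. The procedure tests
H0: PF_h ≥ k per item. Normality is assumed, not tested; heavy-tailed or
skewed measurement processes (fatigue drift across test days, learning
effects, rounded recording) are outside the model.

## Estimation and the upper confidence limit

From n repeats, x̄ and s (denominator n − 1) give the plug-in estimate
PF\*. Using the exact sampling facts √n(x̄ − μ)/σ ~ N(0,1) and
(n−1)s²/σ² ~ χ²_{n−1}, a one-sided bound for each nuisance parameter at
level 1 − α/2 is combined via Boole's inequality into

U_PF = PF\* · sqrt(χ²_{1−α/2; n−1}/n) + z_{1−α/2}/√n,

with guaranteed coverage P(PF ≤ U_PF) ≥ 1 − α. The bound is
conservative: the Monte-Carlo module measures empirical coverage ≈ 0.99
at nominal 0.95 for n = 10. Note the chi-square factor uses /n, not
/(n−1) — it is part of the index construction, not a variance estimate.

The sample-sd denominator is switchable (`sd_denominator: n | n_minus_1`,
default `n_minus_1`). The default is the one that makes the shipped
worked example internally consistent: its published s-values (1.838,
0.789) arise only with n − 1, even though a 1/n formula is sometimes
quoted for this estimator.

## The half-triangular fuzzy number

Viewing the level as free, the map a ↦ U_PF(a) is strictly decreasing
(for PF\* ≥ 0), giving nested intervals [PF_M, U_PF(a)] with apex
PF_M = PF\* · sqrt(χ²_{0.5; n−1}/n) at a = 1 (the chi-square median
quantile, so PF_M < PF\*). The fuzzy number is the half-triangle with
apex PF_M (membership 1) and right endpoint PF_R = U_PF(α) (membership
0). The membership of x ∈ (PF_M, PF_R) is the level a solving
x = U_PF(a), obtained by Brent root-finding on the bracket [α, 1]
(tolerance 1e−9 in a; the bracket is guaranteed because U_PF(α) = PF_R
and U_PF(1) = PF_M). Two deliberate quirks:

* η drops from ≈ α to exactly 0 at x = PF_R — α-cuts below the working
  level reuse that level's interval, so memberships below α never occur;
  the membership function is implemented literally with this
  discontinuity.
* For strongly negative PF\* the decreasing chi-square term can overcome
  the increasing normal term, the base PF_R − PF_M collapses, and the
  procedure raises a degenerate-fuzzy-number error rather than reporting
  an undefined ratio. Mildly negative PF\* (subject worse than the limit
  on average) flows through all formulas unchanged, with no clipping.

## Decision rule

d_R = PF_R − k, d_T = PF_R − PF_M, and the statistic is the base
fraction d_R/d_T — a pragmatic simplification of the area-ratio variant
of fuzzy testing (the areas are never integrated; a numeric-integration
ordering cross-check lives in the test suite only). The ratio is left
unclamped: values < 0 (even the UCL misses k) or > 1 (k left of the
apex) are reported as computed. Outcomes:

* ratio ≤ φ₁ → improve (reject H0),
* φ₁ < ratio < φ₂ → re-evaluate,
* ratio ≥ φ₂ → maintain (do not reject).

φ₁ = 0.4 and φ₂ = 0.8 are the defaults; φ₂ has no canonical published
value, so 0.8 is this package's symmetric-by-construction choice, and
both are per-item configurable. Since maintain requires d_R > 0, i.e.
PF_R > k, a maintain verdict always agrees with the classical UCL test;
the converse fails by design — that asymmetry (classical pass, fuzzy
improve) is the procedure's entire point at small n, as the worked
example's cardio item shows (UCL 6.178 > 6 but ratio 0.071).

A level inconsistency exists in some published statements of d_R/d_T
(quantiles at 0.995/0.005 alongside endpoints at 0.975/0.025).
Everything here is parameterised by one working α (quantiles 1 − α/2 and
α/2); α = 0.05 reproduces every published worked-example number, and the
0.995/0.005 variant is simply α = 0.01.

## Worked-example fixture and its inconsistencies

The packaged fixture carries both the raw 10-value samples and the
published summary statistics, because they disagree: the jump sample's
mean is 190.3 against a published 192 (whose index 6.04 is consistent
only with 192), and the flexion sample has mean 18.61 / sd 0.137 against
published 18.59 / 0.099. Neither file is corrected toward the other;
analyses choose a starting point explicitly. Reproducing the published
fuzzy table also requires feeding the 2-dp rounded estimates (4.03,
6.09, 6.04, 5.93) via `PhysicalFitnessModel.from_estimates` — full
precision from raw data gives, e.g., an apex of 3.678 rather than the
published 3.681. The library always computes full precision; rounding
(2 dp for PF\*, 3 dp for fuzzy quantities) happens only at rendering.

## Synthetic data and what the simulations show

The generator draws i.i.d. normal samples per item — exactly the model's
assumption, so simulations validate internal correctness (coverage,
determinism, operating characteristics), not robustness to real-data
features such as day-to-day dependence, practice effects, measurement
rounding or non-normality. Seeding uses seed-sequence spawning with one
child stream per replicate, so results are independent of execution
order; the contract is same seed → bit-identical results. Degenerate
replicates (zero sample sd, probability zero under the continuous model)
are counted and excluded with a warning.

Default study sizes: the operating-characteristics grid puts the true
index at k + {−2, −1, −0.5, 0, 0.5, 1, 2} with n ∈ {10, 30} and 10,000
replicates per cell (a cell runs in about two seconds on one CPU); the
package's own coverage validation uses 10,000 replicates per (μ, σ)
setting, and auxiliary checks use 400–2,000. The simulation report
includes the classical UCL test's rejection rate next to the fuzzy
outcome rates, leaving the comparison of the two procedures to the
reader.

## Known limitations

* Normal i.i.d. measurements only; no robust or non-parametric variant.
* The coverage guarantee is one-sided and conservative; the procedure
  says nothing about lower confidence limits.
* φ₂ and the handling of out-of-[0,1] ratios are package conventions,
  configurable but not canonical.
* Body-mass index is not modelled: it barely moves over a short testing
  window, so a short-horizon index of this form is uninformative for it.
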