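# Methods

## Model

One row of evidence is the mean treatment difference `y` (active arm minus
control) on one instrument, with its standard error and the trial's pooled
SD on that instrument.  Writing `i` for trial, `a` for active arm, and `k`
for instrument (reference instrument `k = 1`):

* **Random effects.**  δ_{ia} ~ N(μ, σ²), independently for every active
  arm, including the M − 1 arms of a multi-arm trial.  All active
  treatments are treated as exchangeable; treatment differences are
  absorbed into σ.
* **Mappings.**  E[y_{iak}] = β_{1→k} δ_{ia} with β_{1→1} ≡ 1
  (fixed-ratio variant), or β_{i,1→k} δ_{ia} with trial-specific ratios
  β_{i,1→k} ~ N(β_{1→k}, (φ |β_{1→k}|)²) shared across the arms of a trial
  (random-ratio variant).  φ is the between-trials coefficient of
  variation of the ratios.  The `ratios_one` variant clamps every ratio to
  1 and is the model-form equivalent of assuming all (standardised)
  instruments equally responsive.  Only the M − 1 basic ratios are
  parameters; every other pairwise ratio is the quotient of two basic ones
  (transitivity), so mappings are identifiable exactly within a connected
  component of the instrument co-reporting graph, and the reference must
  sit in that component.  Trials reporting a single instrument inform
  (μ, σ) but not the mappings.
* **Likelihood.**  Per trial, the observation vector (arms × instruments)
  is multivariate normal around the expected effects with covariance:
  diagonal se²; same arm, instruments h ≠ k: ρ·se_h·se_k; different arms,
  same instrument: sd²/n_control; different arms, different instruments:
  ρ·sd_h·sd_k/n_control.  ρ is a single between-instrument score
  correlation applied to all pairs (default 0.65, from external
  psychometric literature; 0.55/0.75 as sensitivity values).  The
  shared-control terms use the trial's pooled SD and control-arm size; if a
  multi-arm trial lacks a pooled SD the build fails loudly rather than
  approximating.  Every matrix must pass a Cholesky positive-definiteness
  gate.  The construction is verified against brute-force simulation of
  arm-level sample means (Monte-Carlo oracle, within 3 MC standard
  errors).

Standardised analyses divide each observation's `y` and `se` by its own
pooled SD and run the identical machinery; the pooled estimate is then the
effect on the standardised *reference* scale specifically.

## Priors

μ ~ N(0, 100²); basic ratios β_{1→k} ~ N(0, 100²); σ ~ U(0, 50) on raw
scales and U(0, 5) on standardised ones (both far above any plausible
heterogeneity for the packaged data, where |μ| ≈ 12 raw / 0.45
standardised); φ ~ U(0, 2).  All are configurable through `PriorSpec` and
surfaced in tests as live knobs.  The trial-ratio hierarchy uses |β| in its
SD so the density stays proper if a mean ratio crosses zero during
sampling; an alternative lognormal hierarchy with matching CV
(`ratio_hierarchy="log"`) is available for ratios constrained to one sign.
φ is floored at machine level (1e−12) when evaluating the hierarchical
density so the φ → 0 point-mass limit degrades gracefully; φ may also be
clamped exactly (`phi_fixed=0`), in which case the random-ratio model
reduces — bit-for-bit in the sampler — to the fixed-ratio model.

## Computation

A bespoke adaptive random-walk Metropolis-within-Gibbs sampler updates
scalar blocks in a fixed order: μ, log σ, each β_{1→k}, log φ, each
δ_{ia}, each β_{i,1→k}.  Per-trial likelihood contributions are cached
(precomputed V⁻¹ and log-determinants), so a block update touches only the
trials it enters.  Proposal steps adapt every 50 iterations during burn-in
toward 0.44 acceptance and are frozen afterwards, preserving detailed
balance for the kept draws.  Chains start from overdispersed positions in
a data-informed box (crude effect/ratio estimates jittered by factors up
to ~e).  All randomness flows from one integer seed (per-chain
`SeedSequence` spawns); runs are bit-reproducible, and posteriors are
invariant to input row order because trials and within-arm observations
are canonically ordered before compilation.

Defaults follow the reference analysis (4 chains, 30 000 burn-in, 20 000
kept per chain), but this problem (≈ 80 parameters, 88 observations) mixes
well long before that: the packaged analyses use 4 × (5000 + 5000), for
which split-R̂ < 1.02 on every parameter, and the test suite uses shorter
runs still.  Convergence is gated at max split-R̂ < 1.05 (configurable);
the split-R̂ implementation is cross-checked against ArviZ.

Model fit is the posterior mean residual deviance
Σ_i (y_i − θ_i)ᵀ V_i⁻¹ (y_i − θ_i), about one per observation for a
well-fitting model (88 here).  Mapped summaries transform each draw
(effect β·μ, heterogeneity |β|·σ) before summarising; μ is conventionally
reported as mean (SD), spread parameters as median (2.5%, 97.5%).

## Synthetic data

`simulate_dataset` draws trial networks from the same hierarchy the
sampler fits: per-arm effects from N(μ, σ²), fixed or CV-varying ratios,
and observations drawn with exactly the analytic within-trial covariance.
Simulated SEs are derived from the simulated SDs and arm sizes
(se² = sd²(1/n_c + 1/n_a)), making the Monte-Carlo covariance check exact
rather than approximate.  Defaults mirror the packaged evidence base: 22
trials with a 15/6/1 mix of 2/3/4-arm designs, nine instruments with the
reference reported by ~80% of trials and acting as the network hub
(connectivity is repaired by adding the reference to a component that
lacks it), arm sizes 30–200, per-instrument typical SDs near the observed
pooled SDs, and generating parameters at the magnitudes estimated from
that dataset (μ = −11.7, σ = 3.2, φ = 0.18, ρ = 0.65).

What the generator does **not** emulate: non-normal score distributions,
skewed or truncated scales, follow-up versus change-from-baseline
differences, selective outcome reporting, and SD heterogeneity beyond a
lognormal jitter (20% CV) — so recovery tests demonstrate correctness of
the estimator under its own assumptions, not robustness to violations of
them.

## Design choices and numerical notes

* Effects are stored exactly as printed in the source table (negative =
  improvement); no re-signing.  Follow-up versus change-score basis is
  carried as metadata only — raw-scale mapping models apply to both
  without further assumptions — and is `unknown` in the packaged fixture,
  which does not attribute the basis per trial.
* Arms combining drug with a non-drug co-therapy are ordinary active arms;
  any systematic difference is absorbed by σ.
* Multi-arm random effects are drawn independently from N(μ, σ²);
  between-arm dependence enters only through the likelihood covariance.
* Trial-specific ratios exist only for instruments a trial actually
  reports.
* The random-ratio model is not exactly invariant to the choice of
  reference; the fixed-ratio likelihood is, and that invariance is tested
  exactly.  The reference defaults to the most frequently reported
  instrument (LSAS).
* Degenerate inputs fail loudly with the offending trial named:
  non-positive SE/SD, duplicate (trial, arm, instrument) rows, missing
  pooled SD in a multi-arm trial, non-positive-definite covariance,
  reference outside the main network component, re-standardising an
  already standardised dataset.
* Bartlett's test and the pooled within-study SD use df = total randomised
  n minus the number of arms, matching a pooled across-arm SD; the
  statistic is computed from summary (sd, df) pairs and cross-checked
  against a raw-data implementation.

## Known limitations

* ρ is a single scalar for all instrument pairs and is not estimated from
  data; per-pair correlation matrices are out of scope.
* No treatment-level network meta-analysis: all active arms are
  exchangeable draws from one effect distribution.
* Missing SDs are not imputed; inputs must arrive complete.
* Model comparison is by mean residual deviance only (no DIC/pD).
* The scalar-block sampler is adequate at this problem size but would mix
  slowly on much larger networks; blocked or gradient-based updates would
  be the next step.
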