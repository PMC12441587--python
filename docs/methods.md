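# Methods

## Health-state taxonomy and strata

A respondent-wave is classified from two self-reported quantities: an
arthritis flag (`ar`, doctor-diagnosed rheumatoid arthritis,
osteoarthritis or other rheumatism) and a count of other surveyed chronic
conditions (`n_other`). The mapping is total and partitions the lattice:
(0,0)→H, (1,0)→A, (0,1)→O, (1,k≥1)→AC, (0,k≥2)→OC. The package takes
`n_other` as given rather than re-deriving it from named diagnoses: the
states, not the individual diseases, drive the stratification, and survey
condition lists vary by release.

Complete-case filtering precedes everything: a respondent must have
answered both the mental- and physical-health battery in both waves. The
attrition percentage is reported to one decimal, with a
nearest-integer headline figure.

The 25 ordered state pairs across waves are the analysis strata,
optionally crossed with sex. Small or empty strata are legitimate (several
reference cells hold under 100 respondents) and produce empty networks,
never errors.

## Association estimation

Pairwise association between binary symptoms is the sample odds ratio of
the 2×2 co-occurrence table, with the Woolf standard error of ln OR —
the square root of the sum of reciprocal cell counts — and the log-normal
interval exp(ln OR ± z_{α/2}σ). Design choices:

* **Zero cells**: Haldane–Anscombe by default (+0.5 to all four cells when
  any is zero, flagged `corrected`); a `strict` policy raises instead. The
  cross-product ratio is undefined at zero and the correction is the
  field-standard remedy.
* **z quantile**: computed as `scipy.stats.norm.ppf(1 − α/2)` (1.959964…
  at α = 0.05) rather than the rounded 1.96, for cross-platform
  reproducibility; the difference is below reporting precision.
* **Missingness**: pairwise-complete within a wave. The complete-case
  filter removes whole-wave missingness; item-level gaps simply drop the
  affected rows from that pair's table.
* **Multiple testing**: none by default — each of the 66 pairs per stratum
  and wave is tested marginally at α = 0.05, matching how such symptom
  networks are usually reported. Benjamini–Hochberg across all estimated
  edges is available behind `adjust="bh"` for users who want FDR control.
* These are marginal odds ratios, not conditional (Ising/partial
  correlation) edges; a dense, transitivity-inflated network is the
  expected signature of the method, not a bug.

## Networks, weights, strength

An edge between two symptoms requires **more than 20** respondents in the
stratum reporting the pair together — strictly greater, so 21 is the
minimum admissible co-occurrence. For `or_ratio` weights the threshold
must clear in both waves, since the ratio needs both ORs to exist.

The `significant_or` weight gates on the **lower CI bound exceeding 1**
(one-sided "significantly above unity"). A two-sided gate (`gate="diff"`,
CI excluding 1, so significantly protective pairs also keep their OR) is
available; the two conventions genuinely diverge for OR < 1 edges, and the
package follows the one-sided rule because node strength is defined as a
sum of ORs *significantly higher than 1*. Node strength is the weighted
degree under `significant_or`; the handshake identity (Σ strengths = 2 Σ
weights) holds exactly and is asserted in tests. Strength change is
strength(wave 8) − strength(wave 6), reported ordered by |Δ|.

## Synthetic cohort generator

The generator emulates the study conditions a two-wave SHARE panel
presents to this pipeline:

* **Sex**: Bernoulli(0.58) female, matching the source panel's 42/58
  split.
* **States**: wave-6 state from an initial distribution defaulting to the
  reference table's row margins; wave-8 state from the respondent's row of
  a transition matrix defaulting to the row-normalized reference counts.
  AC/OC respondents receive extra Poisson(0.8) comorbidity counts so the
  classifier sees the full (ar, n_other) lattice.
* **Attrition**: one dropout event per respondent with probability
  0.0623 (= 1998/32082, the source panel's realized attrition); a dropout
  misses both waves' batteries and its symptoms are recorded missing. The
  realized complete-case fraction therefore matches the configured rate.
* **Symptoms**: a latent 12-variate Gaussian per respondent-wave,
  thresholded at per-item quantiles. The latent correlation for each pair
  is calibrated by Brent root-finding on the bivariate-normal orthant
  probability so the implied 2×2 cell-probability table hits the target
  log OR to 10⁻⁴. Pairwise solutions are assembled into a correlation
  matrix; if jointly infeasible it is projected to the nearest
  positive-definite matrix (eigenvalue clipping + renormalization), making
  the joint calibration approximate when targets conflict. Three-way and
  higher structure is whatever the Gaussian copula implies — it is not
  controlled.
* **Defaults**: per-item prevalences use a plausible EURO-D profile for
  Europeans aged 50+ (fatigue 0.33, sleep 0.29, depressed mood 0.28, …,
  suicidality 0.07 in the non-AR profile), scaled ×1.47 in AR states
  (A, AC), with a uniform target pairwise OR of 2.5. These values were
  fixed once, by simulation, to reproduce the study's reported symptom
  burden contrast: ≈26% of non-AR respondents with zero symptoms and
  ≈12.5% with more than four, versus ≈14% and ≈25% in AR strata.
* **Sex and symptoms**: independent given the state by default (sex is a
  stratifier, not a generative factor). An optional female prevalence
  offset shifts thresholds only, reusing the base correlation matrix — an
  approximation adequate for small offsets.
* **Reproducibility**: one root seed feeds named substreams
  (sex/states, symptoms, dropout) via `numpy.random.SeedSequence.spawn`,
  so identical configurations give byte-identical cohorts.

### What the generator does and does not emulate

It reproduces the margins and pairwise association structure the estimator
consumes; it does **not** model item-level response processes, country
effects, age structure, informative (health-dependent) dropout, or
within-person symptom persistence across waves (wave-6 and wave-8 symptom
draws are independent given the states). Passing tests therefore
demonstrate estimator and pipeline correctness under a faithful
*pairwise* data-generating process, not robustness to longitudinal
dependence or informative missingness in real survey data.

A statistical subtlety the test suite respects: when symptom prevalence
differs by health state, pooling strata induces a positive marginal
association between symptoms even if they are independent within every
state (confounding by state). Independence-limit and parameter-recovery
checks therefore hold prevalence uniform across states, the setting in
which pooled estimates are unconfounded; the state-dependent defaults are
kept for everything else.

## Numerical choices and degenerate inputs

* Calibration root-finding searches ρ ∈ (−0.999, 0.999) with tight
  Brent tolerance; an unattainable prevalence/OR combination raises a
  calibration error naming the offending pair.
* Orthant probabilities are clipped away from 0 and min(p_i, p_j) by
  10⁻¹² before forming the log OR, avoiding spurious infinities near
  |ρ| → 1.
* Empty transition cells display a missing female percentage, not 0%.
* An all-zero 2×2 table raises an empty-stratum error; `estimate_all`
  skips such pairs rather than failing the run.
* Figures carry CSV sidecars with the exact plotted numbers; correctness
  is defined on sidecars, never pixels. Node layout is a fixed circle,
  alphabetical by item code, for cross-panel comparability.

## Problem sizes

Distributional tests use 20,000–50,000 simulated respondents (margins,
prevalence and OR recovery stabilize well within ±10% bands there) and
10,000 replicate tables for CI calibration; hand-built fixtures of 4–6
records pin down the arithmetic. The acceptance script uses the same
sizes.

## Known limitations

* Joint feasibility of arbitrary target-OR matrices is not guaranteed;
  the PD projection silently trades exactness for validity (the
  recovery tests quantify the effect under the shipped defaults).
* The Woolf interval is asymptotic; for the sparse cells common in small
  transition groups its coverage is approximate even with the
  continuity correction (the calibration test pins behaviour at n = 500,
  p = 0.3).
* Strength comparisons across strata inherit the marginal-OR caveat:
  denser strata mechanically support larger strengths.
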