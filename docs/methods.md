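# Methods

## The drift test

Two closed lines bred in parallel accumulate random divergence in every
heritable trait. For a neutral additive trait on a unit phenotypic scale,
classical drift theory puts the variance among replicate lines at 2·F·σ²_A
(σ²_A = h² in SD units), where F is the mean pedigree inbreeding
coefficient relative to the founder population. The test statistic is the
standardized line divergence

    D_y = (mean_selected − mean_control) / s_pooled,

and the null band used here is

    CI = z_{1−α/2} · sqrt( 2 · (2·F·h² + 2/n) ),

read as: per line, a drift variance 2·F·h² plus a family-sampling variance
2/n (n = families represented in the measured cohorts), doubled for the
difference of two independent lines, with a normal quantile (1.96 at
α = 0.05).

**Provenance.** The published analyses this package targets print per-trait
(h², F, n, CI) values but not the closed form. The formula above was
reconstructed from those printed values; it reproduces every printed
interval to ±0.01 after rounding to 2 decimals, and no variant tried
(control-SD-only pooling, unweighted pooling, t-quantiles, undoubled
sampling term) does. It is therefore documented as a reverse-engineered
reconstruction of the Henderson-style drift criterion, not a derived
result. The interpretation of the 2/n term cannot be pinned down from the
published material; the calibration experiment below measures what the band
actually delivers.

Decisions fixed in code:

* Pooling is df-weighted (Cohen's-d style); SEM→SD conversion uses the
  printed group size, never the family count.
* The exceed flag compares |D_y| with the band at full precision; rounding
  to 2 decimals is display-only.
* α defaults to 0.05 and is exposed; no multiple-testing correction is
  applied (matching the published usage).
* Traits lacking h² or a family count are reported as not testable rather
  than dropped.

## Statistical calibration of the band

Because the band is a reconstruction, the package measures its operating
characteristics rather than assuming them. `run_calibration` simulates the
full study design — two lines, 10 families per line, 16 generations of
within-family selection on one trait, a focal second trait with genetic
correlation r_g to it — and, per replicate, measures the focal trait on
**one individual per family per line** in the final generation (mirroring
cohorts drawn from distinct families, which is how the target experiment
sampled; its group sizes track the family counts), forms group summaries,
computes D_y, and compares against the band built from the focal trait's
true h², the replicate's realized pedigree F and the family count.

Measured at the suite's fixed seed: null (r_g = 0) exceedance
0.034 ± 0.004 over 2,000 replicates — the band is close to, and slightly
more conservative than, its nominal 5% — and power 0.21 / 0.72 / 0.98 at
r_g = 0.3 / 0.6 / 0.9 (300 replicates each), monotone in r_g. The
conservatism is expected: the 2/n-per-line sampling term in the variance
model is larger than the sampling variance of a one-per-family cohort mean,
so real error rates sit a little below α. Users measuring many individuals
per family should expect stronger conservatism.

## Breeding simulator

Infinitesimal model, no explicit loci (the target population is a
genetically heterogeneous 8-strain cross; polygenic trait architecture is
the operative assumption):

* Founders: n_families × offspring_per_family unrelated, non-inbred
  individuals per line; breeding values multivariate normal with additive
  covariance Σ_A = G ∘ (σ_A σ_Aᵀ) from per-trait h², phenotypic variances
  (default 1) and a genetic correlation matrix G (default identity);
  environmental deviations with Σ_E analogous (default diagonal —
  environmental correlations exposed but zero by default).
* Offspring: midparent breeding value + Mendelian sampling deviation with
  covariance ½·Σ_A·(1 − (F_sire + F_dam)/2), so within-family variance
  shrinks as inbreeding accumulates.
* Selection: `within_family` takes the best male and best female per family
  by the selected trait's phenotype (ties broken by seeded jitter);
  `random` takes a random male and female per family (equal family
  contributions — the control line always breeds this way); `mass` takes
  the top n males and females overall. Mating is a seeded derangement of
  selected females against males avoiding full-sib pairs; an arrangement-
  free pedigree raises a breeding-failure error.
* Sexes alternate within litters so every family has eligible parents;
  litter-size variation is not modelled.
* Kinship is tracked exactly generation-to-generation (offspring kinship =
  mean of parental kinships), so realized per-generation F is identical to
  Meuwissen–Luo F computed from the recorded pedigree — the suite asserts
  exact agreement — without rebuilding a pedigree object per replicate.

Defaults (10 families/line, 8 offspring/family, 16 generations, h² = 0.33)
are the scale of the target colony. Expected diagnostics hold in the suite:
zero response at h² = 0, one-generation response = h²·S (breeder's
equation) under mass selection, ΔF ≈ 1/(8n) per generation under random
within-family breeding, and slower inbreeding under within-family than mass
selection at the same census size.

What the generator does **not** emulate: founder haplotype structure of the
8-way cross, dominance/epistasis, maternal effects, litter-size variation,
sex-specific trait expression, or pharmacological response traits. Passing
calibration therefore shows the band's behaviour under the idealised
additive model, not under every feature of real colony data.

## Behavioral scoring

Go/No-go sessions are scored from time-stamped event logs. Definitions:
hit / false alarm = first cue-recess poke inside a go / no-go cue window;
latency = poke time − cue onset, averaged over responded trials only
(unanswered trials are excluded, not imputed at the window length, because
published mean latencies behave response-conditionally); precue responses =
cue-recess pokes in the final 3 s of a precue period; cue-side pokes =
cue-recess pokes outside any cue window and outside that precue tail;
reinforcers = hits + correct rejections; efficiency = 100 × reinforcers /
total pokes, uncapped (correct rejections dispense rewards without
requiring a poke, so >100% is legitimate) and null — not zero — for a
pokeless session. Each poke counts in exactly one category, resolved by
cue-window-first priority; center-recess pokes count only in the efficiency
denominator. Response windows follow the protocol's cue durations (5 s
testing, 10 s/30 s in training phases); precue durations are drawn from
{3, 4.5, 6} s and precue pokes do not reset the precue clock.

Training passes on the first day whose predecessor and self both reach 30
hits in under 40 minutes. Animals with any session earning reinforcers but
collecting none are excluded.

Y-maze: an alternation is a 3-entry window covering all three arms;
percent alternation = 100 × alternations / (entries − 2) — the standard
sliding-window denominator. Rotarod: per-day mean and max over 4 trials,
with trials under a slip threshold (default 5 s; the protocol prints none)
replaced in order by supplied extra trials.

The Go/No-go scorer and the alternation counter are verified field-by-field
against independent brute-force rescorers on 1,000 random synthetic
sessions/sequences.

## Numerical and interface choices

* Pedigree F uses Meuwissen–Luo (linear in ancestors); the quadratic
  tabular relationship matrix is kept as the in-package cross-check, and a
  third, memoised recursive-kinship oracle lives in the test suite. Unknown
  parents are unrelated non-inbred founders. Pedigrees are validated
  (duplicate ids, dangling parents, cycles) and topologically ordered on
  load; topological order is not unique, so file round-trips are compared
  by content.
* All file formats are plain CSV/TSV; writers emit `%.17g` floats and
  readers parse with exact rounding so write→read is lossless.
* Every stochastic routine is driven by a single integer seed through
  numpy `SeedSequence` spawning; identical configs give identical outputs.
* Problem sizes in the suite (2,000 calibration replicates; 300 per power
  point; 500 breeder's-equation replicates; 1,000 scorer-equivalence
  sessions; 100 random pedigrees ≤ 200 individuals) were chosen to keep
  Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* The variance model behind the CI is a reconstruction; its second term
  lacks a published derivation, and the band is mildly conservative under
  the simulated design.
* Heritabilities are always user-supplied literature values; the package
  neither estimates h² nor fits animal models.
* Several published D_y values (drug-effect rows and two hit/latency rows)
  are not recomputable from printed group summaries under any pooling
  variant tried — they likely used family means — and are reported by the
  model at face value from the printed summaries without claiming
  agreement.
* The drift band assumes two independent replicate lines from a common
  non-inbred base; it does not cover multi-line designs or shared founder
  bottlenecks.
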