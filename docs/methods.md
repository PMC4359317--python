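# Methods

`mirpath` asks a simple systems-level question of paired miRNA/mRNA tumour
data: are there pathways whose gene membership is targeted, as a whole, by a
single miRNA — and does that regulatory link show up clinically? The
pipeline has five statistical stages; this note records the model behind
each one, the defaults and why, and the places where the design was
genuinely open.

## 1. Evidence set: multi-tool target predictions

Input is a table of (miRNA, gene, tool) predictions in the style of
multi-algorithm aggregators that pool eight prediction programs. Individual
tools are noisy, so a pair only counts as evidence when at least `k`
distinct tools agree (default `k = 2`, the standard consensus rule;
`--min-tools` to change). Pairs are then restricted to the pathway gene
universe: the universe size `M` is the number of distinct genes across all
pathways in the analysis, *including* pathway genes that nobody predicts as
a target — `M` describes the sampling frame of the enrichment test, not the
evidence. `M` is deliberately not conditioned on the expression platform.

## 2. Best-miRNA hypergeometric enrichment

For each pathway `i` (size `N_i`) and each miRNA `j` (with `K_j` supported
targets in the universe), let `x` be the number of the miRNA's targets
inside the pathway. The pathway is affiliated with the single miRNA
maximising `x`, and the association is scored with the hypergeometric tail

    p_j = 1 − Σ_{i=0..x} C(K,i) C(M−K, N−i) / C(M,N)  =  P(X > x),

evaluated via `scipy.stats.hypergeom.sf` (log-gamma based, stable for large
`M`). Note the *strict* inequality: `p` is the probability of hitting more
than the observed count. That is the package's default because it is the
convention the pipeline's reference counts were scored under (e.g. a miRNA
with `K = 124` hitting 6 of a 13-gene pathway at `M = 1460` gives
`p = 3.0e-5`; the conventional `P(X ≥ x)` tail gives `3.5e-4`). Users who
want the conventional enrichment tail can pass `tail="geq"` / `--tail-geq`.
Ties on `x` are broken by smaller `p`, then lexicographic miRNA id, so the
affiliation is deterministic and order-independent.

Two caveats are inherent to this procedure and are *not* corrected by the
package, matching the procedure it reimplements:

* **Post-selection inflation.** Choosing the max-`x` miRNA among hundreds
  and then testing that same overlap makes the p-values optimistically
  biased. Even with purely random predictions, best-of-300 selection
  produces per-pathway p-values around 1e-4. The p-values should be read
  as ranking scores; the randomized-pathway null (stage 3) is the honest
  calibration instrument.
* **FDR over selected records only.** q-values are computed across the one
  record per pathway, not across all miRNA × pathway pairs.

### Storey q-values

False-discovery control uses Storey's q-value: `q_i = π̂₀ · min_{p_(j) ≥
p_(i)} m p_(j)/j`, with the null proportion estimated from the p-value
distribution: `π̂₀(λ) = #{p > λ}/(m(1−λ))` on the grid λ = 0.05, 0.10, …,
0.95, smoothed by a cubic polynomial fit and evaluated at λ = 0.95, clipped
to (0, 1]. With `π₀` pinned at 1 this reduces exactly to
Benjamini–Hochberg, which is the oracle used in the tests. When essentially
every p-value is tiny (the usual regime after best-miRNA selection), `π̂₀`
collapses toward 0 and q-values become much smaller than their p-values;
the q *ranking* is unaffected, but absolute q magnitudes in this regime
should not be over-interpreted. Pathways in which no miRNA hits any gene
are reported but excluded from the q-value computation.

## 3. Randomized-pathway null

To show that enrichment is a property of curated pathways rather than of
any gene set, the analysis is re-run on random "pathways": gene sets drawn
uniformly without replacement from the pool of pathway-member genes, with
sizes uniform on [4, 50] (matching the curated collection), the same number
of sets as observed, and the same evidence set, `K` and `M`. Default 1000
iterations (50 in the scaled-down test configurations); per-iteration seeds
are spawned from one master seed, so results are reproducible and
independent of execution order. Observed and pooled random q-values are
compared with a Welch two-sample t-test, the generic two-group comparison
used throughout the pipeline.

**Known limitation.** This pooled t-test is a separation *report*, not a
calibrated hypothesis test. q-values within one run are coupled by the
step-up transform and by the shared `π̂₀`, and after best-miRNA selection
they span tens of orders of magnitude; a t-test comparing one observed run
against pooled null runs then rejects a true null far more often than its
nominal level (roughly 20% at the 5% level in the package's own no-signal
simulations, on raw or log scale alike). With planted structure the
separation is enormous (t ≈ −50), so the report is useful; small p-values
near the threshold should not be taken at face value.

## 4. Pathway activity from expression

The clinical stages need a per-sample, per-pathway activity score. The
score follows the semantics of interaction-likelihood pathway tools (gene
up/down states → interaction likelihood → pathway summary) but is a
transparent surrogate specified entirely by this package, not a bit-level
clone of any published implementation:

* **Gene states.** Each gene's expression across samples is modelled as a
  two-component Gaussian mixture fitted by EM, vectorised across genes.
  Initialisation is deterministic (component means at the 25th/75th
  percentiles, both variances at the gene variance, weights 0.5); variances
  are floored at 1e-4 of the gene variance; convergence tolerance 1e-8 on
  mean log-likelihood, at most 500 iterations. `p_up(g, s)` is the
  posterior of the higher-mean component. Constant genes get `p_up = 0.5`
  and a degenerate flag. Below 8 samples a mixture is not identifiable in
  practice, so the fit falls back to a rank score `(rank + 0.5)/S`,
  flagged as such.
* **Interactions.** A signed interaction (promoters, inhibitors) occurs
  with likelihood `Π_promoters p_up · Π_inhibitors (1 − p_up)`.
* **Pathway score.** Mean over the pathway's interactions; pathways
  without interaction structure use the mean `p_up` over their genes.
  Interactions referencing unmeasured genes are skipped (pathways with
  more than half skipped are flagged low-coverage); pathways with no
  measurable genes give NaN rows and are excluded downstream.

All scores are in [0, 1], and adding an inhibitor can never increase an
interaction's likelihood. Only activity levels are used downstream; no
"consistency"-style metric is computed.

## 5. Clinical linkage

* **Group stratification:** Welch's unequal-variance t-test of a pathway's
  activity between two named phenotype groups (Welch rather than pooled
  Student: more robust, asymptotically equivalent). Scanning all pathways
  attaches Storey q-values.
* **Survival:** samples split at the *median* activity (the split rule is a
  package choice), Kaplan–Meier halves compared by log-rank test
  (lifelines). Requires ≥10 samples with follow-up and ≥1 event.
* **Differential correlation ("broken control"):** Pearson correlation
  (Spearman optional) between miRNA expression and pathway activity (or a
  target gene's expression), per clinical group, contrasted with Fisher's
  z: `z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3))`, two-sided normal
  p. The per-group correlations alone cannot support "present in one
  group, absent in the other"; the contrast makes that claim testable.
  Pearson is the default because the sought pattern is a linear repression
  trend. Groups need ≥4 samples; zero-variance vectors are flagged rather
  than scored.

Multi-level phenotypes (stage, morphology) are not dichotomised
automatically: the configuration must name the two groups.

## Synthetic data generator

All tests run on seeded synthetic bundles with known ground truth; no
downloads. The generator emulates the *statistical* structure of a
multi-cohort tumour study at a scaled-down size chosen to keep the full
test suite fast: 100 pathways (sizes uniform 4–50) over a 1500-gene
universe, 300 miRNAs, 8 tools, 100 samples per clinical group.

* **Predictions.** Background (miRNA, gene) pairs appear independently
  with probability 0.01; their extra-tool support is Binomial(7, θ) with
  θ = 1 − 0.5^(1/7), so about half of background pairs survive the ≥2-tool
  filter. Every pathway gets one planted miRNA targeting 50% of its genes
  with ≥2-tool support — the "curated pathways are coherent" property the
  null model is meant to detect.
* **Focal pathway.** One pathway additionally carries the clinical signal
  and is the ground-truth answer for end-to-end recovery: its planted
  miRNA targets *all* of its genes (making its enrichment tail exactly 0,
  hence unambiguously rank-1), its genes are shifted up by Δ = 2 noise-SD
  in group A, and within group A the miRNA and its target genes are drawn
  with a Gaussian copula-style joint correlation ρ = −0.6 (a configurable
  subset of targets can get +|ρ| to mimic sign-mixed regulation); in group
  B they are independent.
* **Expression.** Non-focal genes follow a two-state Gaussian generative
  model (random up/down state per sample, separation 3 SD) matching the
  fitted mixture family; miRNA expression is Gaussian around per-miRNA
  baselines. No count noise, batch effects, platform effects or real
  pathway topology are simulated — passing tests demonstrate correctness
  of the statistical machinery under the assumed model, not robustness to
  real-data artefacts.
* **Survival.** Exponential times with hazard ratio 3 for group A,
  censored at 3000 days.
* **Interactions.** Each synthetic pathway gets ⌈N/3⌉ interactions of 1–3
  promoters, 0–1 inhibitors and one output gene.

Same seed ⇒ byte-identical bundle. A `null_scenario` preset removes every
planted signal (no planted pairs, Δ = 0, ρ = 0, hazard ratio 1) for
calibration experiments.

## Numerical and reproducibility choices

* All randomness flows from one master seed through `numpy` SeedSequence
  spawning; null-model iterations are independently seeded and
  order-independent.
* The pipeline is a pure function of (inputs, config, seed): artefact
  files contain no timestamps or timings (those go to the logging stream),
  so a rerun is byte-identical.
* Expression TSVs are written with shortest-exact float representation and
  read with round-trip float parsing, so file round-trips are lossless.
* Degenerate cases are explicit: zero-variance groups in a t-test return
  (0, 1) when means agree and (±inf, 0) with a warning otherwise; constant
  genes and empty median-split halves raise or flag rather than silently
  producing numbers.
* Scaled-down problem sizes used by the test suite (e.g. 50 null
  iterations, 20–100 pathways) are the package's own test configurations;
  the method defaults (1000 iterations, full bundle sizes) are what `run`
  uses.

## Known limitations

* Best-miRNA p-values are post-selection biased (see above); the package
  reproduces the procedure rather than correcting it, and the randomized
  null is the intended calibration.
* The observed-vs-null pooled t-test is anticonservative as a hypothesis
  test (see stage 3); treat it as an effect-size report.
* The activity model is a surrogate: users needing exact parity with a
  specific pathway-activity tool (different mixture family, different
  interaction aggregation) should not expect numerical agreement.
* Gene identifiers are opaque case-sensitive strings; no alias mapping is
  attempted.
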