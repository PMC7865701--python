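# Methods

## Gene disruption model

A gene is *disrupted* in a sample iff at least one of:

* a missense variant with SIFT strictly below `sift_threshold`
  (default 0.05; missense calls with a missing SIFT score are **not**
  disruptive — the rule requires an observed intolerant score);
* a loss-of-function consequence. The default set is
  `{stop_gained, frameshift_variant, start_lost, splice_acceptor_variant,
  splice_donor_variant, splice_region_variant}`. Whether "splice-site
  region" includes the milder `splice_region_variant` is a judgment call;
  we include it by default and expose the set as a parameter so the
  narrower reading is one argument away;
* a homozygous deletion, defined as total copy number exactly 0. No
  segment-level or partial-gene logic; heterozygous loss (CN 1) and
  amplification are never disruptive.

Disruption is a per-(sample, gene) OR over events: a single qualifying event
suffices (no biallelic requirement). Absence of evidence is absence of
disruption — samples without records get all-zero rows.

Population-frequency filtering removes variants whose ESP frequency is
≥ 2.5×10⁻⁴ or whose 1000 Genomes frequency is ≥ 1.4×10⁻³; variants with
missing frequencies are retained. Rationale: the filter exists to remove
germline variants and sequencing artifacts, and it is the *common*
population variants that are germline. Missing values are never coerced
to 0.

MAF ingestion maps `Variant_Classification` terms to Sequence Ontology
consequences through a versioned table (`MAF_CONSEQUENCE_MAP`); unknown
terms become `"other"` with a warning and never abort a run. SIFT
annotations are accepted as plain numbers or VEP-style
`deleterious(0.01)` strings.

## The SC screen

For a gene pair (A, B), samples holding a response are partitioned by
(status_A, status_B) into both / A-only / B-only / neither. Three
comparisons of ln IC50 — both vs each other group — use the Wilcoxon
rank-sum (Mann–Whitney) test. Choices:

* **Direction.** One-sided ("both" stochastically smaller) by default: the
  SC definition is inherently directional. A `two_sided` mode combined with
  the median-direction requirement is available as the alternative reading.
* **Exactness.** The exact null permutation distribution is used when
  `max(n_x, n_y) ≤ exact_cutoff` (default 25) and the pooled data are
  tie-free; otherwise a tie-corrected normal approximation with continuity
  correction. The exact branch is verified in the tests against brute-force
  enumeration of all C(n_x+n_y, n_x) rank assignments.
* **Entry filters.** Genes must be disrupted in strictly more than
  `min_gene_freq` (5%) of response-bearing samples. A pair is *tested* only
  if each of the four groups holds at least ⌈`min_group_frac` · n⌉ samples
  (2.5%; ceiling, applied to all four groups — the plain reading of "each
  group"); otherwise it is reported untested with sizes and medians but no
  p-values.
* **Verdict.** `is_sc = 1` iff all three p-values < α (0.05) *and* the
  both-group median is strictly the minimum of the four. No
  multiple-testing correction by default, matching the published raw-p
  procedure; a Benjamini–Hochberg switch (`bh_correct`) exists as a
  documented deviation, applied to each tested pair's worst p-value.

Scan output is ordered lexicographically and invariant to input row/column
order.

A property worth knowing: when several true SC pairs coexist, a pair whose
two genes belong to two *different* true pairs inherits part of their
response shift (its both-disrupted samples are enriched for satisfying the
true pairs), and the marginal raw-p screen will declare many such pairs.
This is a property of the published procedure itself, not of this
implementation; it is why the recovered interaction networks are dense and
why precision against planted truth is modest in simulations with many
planted pairs.

## Burden and cross-drug analysis

Burden(s) = number of SC pairs with both genes disrupted in sample s.
Default group breakpoints (0, 2, 9) give G1 = 0, G2 = 1–2, G3 = 3–9,
G4 ≥ 10; breakpoints are parameters, with no quantile auto-binning. Group
responses are compared with the tie-corrected Kruskal–Wallis H (chi-square
reference, k−1 df). Cross-drug robustness compares *consecutive* populated
burden groups (G1 vs G2, G2 vs G3, G3 vs G4) with one-sided rank-sum tests
(higher burden expected lower ln IC50); which group pairs the original
boxplot annotations compared is not recoverable, and consecutive groups
match the boxplot style. Empty groups are skipped with a note. The SC pair
set is treated as fixed before cross-drug comparisons.

## Network

Genes are nodes, declared SC pairs edges (undirected, deduplicated,
self-pairs rejected). Louvain community detection runs through networkx
with a required seed; the node sweep is order-dependent, so we guarantee
seeded reproducibility rather than bit-compatibility with any particular
GUI tool, and assert that modularity is non-decreasing across the
algorithm's levels. Resolution defaults to 1.0. Community labels are
renumbered by each community's smallest member, making labels themselves
deterministic. Export: GraphML with degree and community node attributes
(lossless round-trip) or a two-column edge TSV.

## Firth-penalized Cox regression

Implemented in-package (no installed dependency provides it): Breslow ties,
penalized partial log-likelihood ℓ*(β) = ℓ(β) + ½ log det I(β).
Newton-type iterations use the modified score
U*(β) = U(β) + ½ tr(I⁻¹ ∂I/∂β_r), with analytic third derivatives of the
Breslow likelihood, step-halving on ℓ*, a per-iteration step cap (max-norm
5), and convergence at max|U*| < 10⁻⁶ (cap 100 iterations;
non-convergence is flagged, never silent). Numerical safeguards: the linear
predictor is max-shifted before exponentiation; a non-positive-definite
information matrix aborts the step.

Inference is by penalized likelihood-ratio tests — each covariate profiled
at the hypothesised value with the remaining coefficients re-maximised —
rather than Wald, the established recommendation for Firth-type fits under
sparse events (Wald intervals misbehave exactly where the penalty
matters). `firth_lrt(design, covariates, covariate, value)` exposes the
profile test at arbitrary values, which is also how interval coverage is
checked (truth inside the 95% profile CI iff the statistic ≤ χ²₁,₀.₉₅).

Design-matrix contracts: at least one event; constant columns are rejected
naming the covariate; rank deficiency is rejected as collinearity. Stage
enters multivariate fits as a single ordinal code (I=1 … IV=4) by default —
per-stage dummies are unstable at realistic subgroup sizes — with a
`dummy_stage` flag for indicator coding. In the four-group pair
stratification, `both_mut` is the reference level, so reported hazard
ratios > 1 mean worse survival than the double-disrupted group.

Kaplan–Meier estimation delegates to lifelines (product-limit, censored
subjects at t remain at risk at t); with no censoring the curve equals the
empirical survival function, which the tests assert exactly.

## Synthetic cohorts

*Cell lines.* Disruption is independent Bernoulli(f_g) per sample and gene;
by default f_g ~ U(0.1, 0.3), the range of frequently altered genes that
clear the screen's 5% entry filter. Each disruption is realised as a
disruptive variant row (intolerant missense with SIFT ~ U(0, 0.0499), or a
loss-of-function consequence) or a homozygous-deletion row, chosen with
equal probability; non-disruptive heterozygous losses (CN 1) are sprinkled
at rate 0.05 for realism. Response: ln IC50 = μ + Σ_p δ_p·1[both genes of
pair p disrupted] + ε, ε ~ N(0, σ²), with μ = −2.0 (inside the published
paclitaxel ln IC50 range; the printed summary statistic for that
distribution is internally inconsistent and not reproduced) and σ = 1.0.
The screened drug always carries the planted deltas; drugs listed in
`shared_effect_drugs` reuse them; all others are noise-only.

*Patients.* Anchor and partner mutations are independent Bernoulli
(defaults: anchor 0.5 — roughly the TP53-mutant fraction of urothelial
cohorts — partners 0.3 and 0.15). Survival is exponential with hazard
h = h₀ · HR^(burden · anchor), h₀ = 10⁻³/day, independent exponential
censoring at 8×10⁻⁴/day (≈ 50–60% events), stage multinomial
(0.05, 0.30, 0.35, 0.30). The closed-form hazard structure makes
parameter-recovery targets exact in expectation.

What the generators do **not** emulate: mutational signatures, hypermutator
samples, co-mutation correlation (a pairwise knob exists for stress tests
but defaults to independence), tumor purity/subclonality, tissue effects,
and non-proportional hazards. Passing tests therefore demonstrate
correctness of the procedures under the stated sampling models, not
performance on real cohorts — in particular, real mutation data are
overdispersed and correlated in ways that change both the screen's false
discovery behaviour and the burden distribution.

## Problem sizes used in checks

The calibration and recovery suites run at n = 400 samples with 50 genes
(20 null seeds; 10 recovery seeds with ten planted pairs at δ = −2.5,
f = 0.15), Firth recovery at n = 400 with 200 replicates, the patient
contrast at n = 800 with 50 replicates, and cross-drug robustness at
n = 400 with 20 genes over 30 replicates — sizes at which the Monte-Carlo
targets (coverage, rejection rates) have binomial standard errors of a few
percent. Under these conditions the screen's planted-pair recall is
intrinsically capped: at f = 0.15 a planted pair's both-disrupted group is
Binomial(400, 0.0225) and reaches the ⌈2.5%·n⌉ = 10-sample testability
floor with probability ≈ 0.41, so roughly half the planted pairs are
reported untested rather than detected; and precision is deflated by the
induced cross-pair effects described above. Both are consequences of the
screening rules and the sampling model, measured and reported as-is by
`scripts/acceptance.py`.

## Known limitations

* The screen tests marginal pair effects; it cannot distinguish a true SC
  interaction from the induced signal of overlapping true pairs, and with
  raw p < 0.05 and ~10³–10⁵ candidate pairs a non-trivial false-discovery
  load is expected by design.
* Breslow tie handling only; heavy ties in event times would favour Efron.
* The ordinal stage code assumes a log-linear stage effect.
* Exact rank-sum enumeration refuses tied data (falls back to the
  tie-corrected approximation) — exact conditional-on-ties enumeration is
  not implemented.
* GraphML edge-list export cannot carry isolated nodes; SC networks built
  from pairs never contain any.
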