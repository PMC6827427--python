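# Methods

`cnvcerna` identifies competing-endogenous-RNA (ceRNA) interactions whose
strength changes with DNA copy-number state, from discrete gene-level
copy-number calls and mRNA / lncRNA / miRNA expression matrices. This note
documents the statistical model, the defaults and why they were chosen, what
the synthetic-cohort generator does and does not emulate, and the numerical
and design decisions a maintainer should know about.

## The model

Two RNAs that share miRNA binding sites compete for the shared miRNA pool and
are therefore positively co-expressed, while each is negatively correlated
with the miRNA. A copy-number event that perturbs this balance in the carrier
samples changes the pair correlation there. The pipeline formalises this in
four stages.

**1. CNV-driven genes.** Discrete GISTIC-style calls in {−2, −1, 0, 1, 2} are
reduced to high-level events: ±1 is recoded to 0, genes with a non-zero call
in fewer than `min_cnv_fraction` (default 0.10) of samples are dropped, and a
gene carrying both +2 and −2 is resolved by an exact binomial test of the
minority count against Binomial(n_amp + n_del, ½), two-sided by doubling the
smaller tail and capping at 1: if p < 0.05 the minority state is treated as
call noise and zeroed, otherwise the gene is ambiguous and removed. Expression
is prefiltered by detection (non-missing, non-zero in ≥ 30% of samples;
missing in ≤ 10%). A gene is *CNV-driven* for a direction when the two-sided
Wilcoxon rank-sum test between its aberrant and copy-neutral samples gives
p < 0.05 **and** the median shift is concordant (amplified above neutral,
deleted below). The rank-sum p is exact (full enumeration, via
`scipy.stats.mannwhitneyu(method="exact")`) for tie-free groups of ≤ 10, and
the tie-corrected normal approximation otherwise. Driver p-values are not
multiplicity-corrected; the raw-α rule is deliberate and the calibration
analysis (below) quantifies its type-I behaviour.

**2. Candidate triplets.** For one driver and one copy-number status
(amplification, deletion or normal), all expressed RNA pairs sharing ≥ 1
miRNA in the interaction table are screened over that status's samples
(minimum `min_samples_per_status` = 5): Pearson r with the two-sided p from
the t distribution on n − 2 df, computed on pairwise-complete observations. A
triplet (ceRNA1, ceRNA2, miRNA) is a candidate when r(pair) > 0 and both
r(miRNA, ceRNA) < 0, each at BH-adjusted q < 0.05. The Benjamini–Hochberg
family is per (driver, status) screen, with the pair tests and the
miRNA–target tests adjusted as two separate families, mirroring the two-gate
structure of the screen. Pairs are canonically ordered, so the output is
invariant to ceRNA labelling.

**3. Dysregulation.** For every pair that is a candidate in the driver's
aberrant status and/or its neutral status,

    ΔR = | cor_v − cor_n |

where cor_v is the pair's Pearson correlation over the aberrant samples and
cor_n over the neutral samples. A pair seen in only one status still gets its
other-status correlation computed from that status's samples. Direction is
*enhanced* when cor_v > cor_n and *weakened* otherwise (ties, which have
measure zero for continuous data, count as weakened and are logged).
Significance comes from shuffling the aberrant/neutral labels uniformly at
random with group sizes preserved, `n_perm` = 1000 times, with the add-one
Monte-Carlo estimate

    p = (1 + #{ΔR_perm ≥ ΔR_obs}) / (n_perm + 1),

so p ∈ [1/(n_perm+1), 1] and −log p stays finite. Pairs with p < 0.05 are
reported once each, with all supporting miRNAs accumulated as annotation.
Permutations that produce a constant subgroup are redrawn (up to 50 rounds)
and counted in the log. Ties between a permuted and the observed ΔR are
counted with an absolute tolerance of 1e−9 because a permutation that
reproduces the observed labelling recomputes the same correlation through a
different floating-point summation order. An analytic Fisher-z differential
correlation test is provided as a cross-check utility only; the pipeline's
call is always the permutation test.

**4. Network, communities, enrichment, clinic.** Significant pairs form an
undirected graph (no self-loops; a pair reported for two drivers collapses to
one edge carrying both records). Community structure is multilevel (Louvain)
modularity optimisation on the unweighted graph — edge weights are
deliberately not used; ΔR is kept as an attribute — with 10 seeded restarts,
reporting the partition with the highest Newman modularity
Q = Σ_c (e_cc − a_c²), and falling back to the single-community partition
(Q = 0 exactly) if no restart beats it. Gene-set enrichment is the exact
inclusive hypergeometric upper tail P(X ≥ m) over a universe defined as all
mRNA/lncRNA features surviving the expression prefilter (miRNAs excluded:
ceRNA networks contain only mRNA and lncRNA nodes), BH-adjusted across the
supplied collection. Clinical association per driver: Kaplan–Meier curves and
the two-group log-rank test for carriers of the aberrant state versus
copy-neutral samples (±1 samples excluded, consistent with the high-level-only
analysis), Cox proportional-hazards fits (Efron tie handling, Wald CIs) on
carrier status and on expression, and an exact r×c Fisher test of
copy-number status against histological subtype.

## The exact r×c Fisher test

No installed Python library provides the exact test beyond 2×2, so it is
implemented directly: with margins fixed, every table is enumerated
recursively; table probabilities are multivariate hypergeometric, computed in
log space via `gammaln`; and p is the total probability of tables no more
probable than the observed one, with a relative tolerance of 1e−7 on the
comparison (the convention of the standard R implementation). An enumeration
bound derived from the margins guards against infeasible tables (~10⁷
budget); larger tables raise with a suggestion to use a Monte-Carlo fallback
rather than silently approximating. On the six published 2×3
status-by-subtype tables the test reproduces the published p-values to three
significant figures (e.g. 5.61E−05 for the MTAP table), and it matches
`scipy.stats.fisher_exact` on an exhaustive 2×2 sweep and a brute-force
enumeration oracle on 2×3 sweeps.

One printed formula in the source literature sums the hypergeometric mass to
m, implying the exclusive tail P(X > m); the standard inclusive tail
P(X ≥ m) is implemented, treating the printed bound as a typesetting
artifact.

## The synthetic cohort generator

Real inputs of this kind (tumor-cohort CNV calls plus RNA-seq) cannot ship
with the package, so `cnvcerna.simulate` generates cohorts with exactly the
structure the method assumes, plus ground truth:

* each of `n_driver_genes` driver genes carries a high-level event (+2 or −2,
  alternating) in `cnv_carrier_fraction` (0.15) of samples; driver expression
  is baseline + `cnv_expression_effect`·(state/2) + noise, i.e. a 1.5
  log2-unit dose shift at default;
* each miRNA has a latent N(0,1) activity per sample; miRNA expression is
  baseline + activity + noise, and each target receives
  −`mirna_coupling`·activity (0.8), giving miRNA–target correlations near
  −0.9 and shared-target pair correlations near c²/(c²+σ²) ≈ 0.88 at the
  default noise σ = 0.3;
* planted weakened pairs have their coupling multiplied by
  `dysregulation_attenuation` (0.2) in their driver's carrier samples only
  (enhanced pairs by `enhancement_factor`); background miRNAs and their
  targets have status-independent coupling and constitute the declared null
  pairs;
* survival is exponential (median ≈ 800 days, uniform censoring giving ≈ 30%
  censored) with log-hazard `survival_log_hr` (0.7) for carriers of one
  designated driver, and subtype frequencies over three histology labels
  depend on the same carrier status, so the clinical stages have signal;
* a fraction of non-driver genes receives low-level (±1) calls, sub-threshold
  high-level calls, or mixed +2/−2 states, exercising every cleanup path.

The defaults (300 samples, 200 mRNA / 40 lncRNA / 60 miRNA, 10 drivers, 20
planted weakened pairs) are the package's standard study conditions: large
enough that the permutation test has ~45 aberrant vs ~255 neutral samples per
driver, comparable to a single-cohort tumor analysis, and small enough that
the full pipeline runs in well under a minute. `null_cohort()` keeps the CNV
calls and the whole ceRNA correlation structure but removes every
CNV-dependent effect; it is the basis of the calibration checks.

What the generator does **not** emulate: real marginal expression
distributions and library-size artefacts, batch effects, overdispersed
count noise, correlated CNV segments (each driver's carriers are drawn
independently), miRNA-target interaction errors, or genome coordinates.
Passing recovery tests therefore demonstrates correctness of the inference
machinery under the model's own assumptions, not robustness to the full
messiness of tumor data.

## Calibration and recovery (what the self-tests compute)

* On null cohorts the type-I error of the rank-sum driver test, pooled over
  three cohorts of 500 CNV-carrying genes, sits in the binomial band
  [0.03, 0.07] around α = 0.05. The full driver call additionally requires
  median concordance, which under the null passes about half of the p < α
  genes by symmetry, so the *call* rate is ≈ α/2; it is asserted ≤ 0.07.
* ΔR permutation p-values on 2000 independent null pairs are uniform
  (Kolmogorov–Smirnov p ≫ 0.01). Uniformity is measured on declared null
  pairs rather than on screen-passing candidates, because per-status
  screening selects on the same correlations that enter ΔR and would bias
  the conditional null distribution.
* Under the default planted conditions the pipeline recovers ≥ 90% of
  planted drivers and ≥ 80% of planted pairs, with the planted direction for
  ≥ 95% of recovered pairs; the mean recovered-pair count is monotone in the
  planted attenuation strength.
* Each small-sample statistic matches an independent brute-force oracle
  (rank enumeration, BH step-up by definition, hypergeometric draw
  enumeration, table enumeration, label-assignment enumeration). The
  oracle-sweep sizes are chosen for desk runtimes: exhaustive where the
  space is small (all rank-sum group sizes to n+m = 10; all 2×2 tables to
  total 30; all 2×3 tables to total 12) and seeded random sampling above
  that (2×3 totals to 40).

## Numerical and design notes

* All randomness flows from one run seed; per-pair permutation substreams
  are derived from (seed, driver id, pair id) via CRC32 into a
  `SeedSequence`, so results are reproducible regardless of execution order.
* Matrices are genes × samples; every module addresses cells by identifier,
  never position. Identifier matching is exact-string; no alias resolution.
* Missing expression stays missing (NaN) and is excluded pairwise from
  correlations; nothing is imputed.
* Cox fits use lifelines with Efron tie handling; duplicating every
  observation shifts the estimate only through the tie approximation
  (empirically < 1% relative).
* Community detection ties are broken by the seeded restarts; "largest
  community" means most nodes, ties broken deterministically by community id.
* Degenerate inputs are contracts, not crashes where the analysis can
  continue: small status groups produce reason-coded non-driver results or
  empty screens; constant vectors flag the triplet as undefined and skip it;
  an all-censored stratum warns and yields a flat survival curve.

## Known limitations

* The binomial "ambiguous mixed state" rule removes the whole gene; removing
  only the ambiguous state is a defensible alternative and the removal is
  flagged in the cleaned matrix so it can be audited.
* The BH family for the screen (per driver and status) is one of several
  defensible choices; a global family would be more conservative. It is a
  parameter of `find_candidate_triplets`, not a hard-coded policy.
* The r×c Fisher test is exact-enumeration only; tables beyond the budget
  need a Monte-Carlo extension that is not implemented.
* Cohort-scale biological conclusions (how many dysregulated pairs a given
  tumor type harbours) depend on real data and are out of scope; the
  package validates machinery, not biology.
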