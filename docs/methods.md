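# Methods

## CCF integration

Small variants and CNVs are compared on the cancer cell fraction scale.
For a variant with `a` alternate reads out of depth `d` (VAF `v = a/d`)
in a sample of purity `rho`, at a locus of tumor copy number `n_t`
(normal `n_n`, assumed 2) mutated on `m` copies, the expected VAF is
linear in the CCF `phi`:

    E[v] = c * phi,    c = m * rho / (rho * n_t + (1 - rho) * n_n)

`compute_snv_ccf` inverts this map and clamps to [0, 1]; raw values
above 1.1 raise a model-violation flag (they indicate a wrong
multiplicity, copy-number or purity assumption rather than noise).
Uncertainty is a Wilson interval on the binomial VAF (alpha = 0.05),
propagated through the linear map — Wilson rather than Wald because
panel depths vary and VAFs sit near 0.
Multiplicity is chosen per variant as the `m` in `1..n_t` whose implied
raw CCF is closest to the feasible [0, 1] range, ties toward `m = 1`.
Variants inside a CN ≠ 2 segment inherit that segment's `n_t`;
unsegmented loci assume `n_t = 2`; a variant inside a homozygous
deletion is flagged for review rather than assigned a CCF.

CNV cell fractions invert the mirrored-BAF allele model per class
(deletion, copy-neutral LOH, single-copy gain; see README formulas).
When logR is present it serves as a diagnostic only — BAF carries the
allele-specific information. These are single-class inversions: no joint
purity–ploidy grid search and no multi-state subclonal CN deconvolution
is attempted.

**Purity.** A metadata blast percentage overrides everything. Otherwise
the module-level estimator is the 95th percentile of 2·VAF over
CN-neutral variants, capped at 1 (deep panels lack genome-wide purity
estimators). The pipeline additionally exploits that every event's
implied `rho * phi` bounds purity from below, taking the maximum over
2·VAF of CN-neutral variants and the BAF-implied `rho * f` of CNV
segments — exact in the noise-free limit whenever any event is clonal,
and necessary when the founding clone carries only CNV events (the
2·VAF-only heuristic then underestimates purity and the SNV and CNV CCF
scales drift apart).

## Clone-tree reconstruction

1. **Clustering.** Events are clustered across the patient's timepoint
   grid with a mixture model over CCF space: binomial read-count
   likelihood for SNVs (through each event's linear coefficient `c`),
   Gaussian likelihood for CNV fractions (sd from the array noise level
   via the delta method, floored at 0.01). EM runs for k = 1..6 with 10
   deterministic restarts (first restart: quantiles of the per-event
   mean CCF; the rest seed cluster centers on actual event CCF profiles,
   which separates clones whose means cross between timepoints); the
   1-D M-step uses damped Newton on the score. k is selected by BIC with
   `k*T + (k-1)` parameters, and clusters closer than 0.05 mean CCF at
   all timepoints are merged. Everything is deterministic given the
   seed; assignment ties break toward the lower cluster index.
2. **Enumeration.** All rooted trees on the clusters under an implicit
   healthy-cell root are enumerated by recursive parent assignment with
   incremental sum-rule pruning (equivalent to decoding every Prüfer
   sequence on clusters + root, but infeasible branches are cut early).
   A hard cap of 8 clusters keeps enumeration exact; more clusters is an
   error instructing the user to raise the merge threshold.
3. **Sum rule.** At every node and timepoint the children's CCF sum may
   exceed the parent's CCF by at most `eps`; the root may not exceed
   1 + eps. Default `eps = max(0.05, 2 x mean Wilson half-width of the
   events' CCFs)` so the tolerance scales with depth. If no tree passes,
   `eps` is relaxed stepwise (x2, up to x8) before reporting a
   reconstruction failure with the best near-miss chain.
4. **Phasing constraints.** Same-gene variants covered by common read
   pairs (window 150 bp) yield allelic constraints: a set of mutually
   *different-allele* variants cannot all travel on one root-to-leaf
   lineage once they outnumber the locus's alleles (2 without a gain);
   *same-allele* pairs must be collinear. The tri-allelic PTEN
   configuration (three frameshifts, CCFs {a, a, b}, no chr10 gain) is
   the canonical worked case: the unique surviving topology puts the
   equal-CCF pair co-resident on one branch and the third variant on a
   parallel branch.
5. **Selection.** Minimal total sum-rule violation, then fewest leaves
   (parsimony prefers linear evolution), then lexicographic parent
   vector — fixed for reproducibility. The number of trees tied at the
   minimal violation is reported as the ambiguity; `n_co_optimal > 1`
   means the data do not determine the topology.

Clusters absent at a timepoint simply have CCF ~0 there: clones may
regress and re-expand, and the sum rule must hold at every timepoint
simultaneously. Events flagged as germline-level (e.g. LOH already
present in the germline) should be excluded before tree building.

## Trajectories and nested levels

A trajectory is an ordered tuple of 2–3 labels along *strict ancestor*
chains (any strict ancestor, not only parent–child, so
`A -> B -> C` contains `A -> C`; same-node pairs are excluded because
their order is unknowable). CNV labels are arm-scale
(`del_in_9p`, `LOH_in_9p`) when ≥ 90% of the segment lies in one arm of
the shipped centromere table (GRCh38 default, GRCh37 option), else
chromosome-scale (`dup20`). Cohort support counts each patient once;
frequency filters are inclusive: ≥ 10% of subgroup patients for length
2, ≥ 5% for length 3.

**Permutation test.** The null re-places each patient's event labels
uniformly over its tree nodes, preserving topology and per-node label
counts, and recomputes cohort support; `p = (1 + #{null >= observed}) /
(1 + n_perm)`. One set of shuffles per cohort is shared across all
tested trajectories (joint vectorized engine), and BH adjustment is
applied within one subgroup and length class. The shuffle null is the
package's own declared construction — the enrichment test itself, and
therefore exact p-values, need not match other implementations of the
same idea.

**Nested levels.** `level(event)` is the 1-based depth of the acquiring
node (founding clone = 1). The event-class statistic is the plain mean
level over all occurrences of the class in the subgroup; the tree-scope
statistic is the mean over patients of the deepest clone's level,
weighting each patient by its number of events. Both weightings are
declared choices recorded in the result object.

## Landscape statistics

Burden summaries use primary-timepoint samples only. Gene–age
associations use the two-sided Wilcoxon rank-sum (exact where sample
sizes permit) for genes mutated in ≥ 5% of the tested patients, BH
adjusted. Age-density curves divide a Gaussian KDE of mutated patients'
ages by a KDE of all ages with the same absolute bandwidth (Silverman
on the baseline), flooring the baseline at 1e-6 of its maximum; display
scaling is never applied to exported numbers. Mutual exclusivity reports
the sample odds ratio (0 when the genes never co-occur; an infinite OR
is flagged, not returned as a number) with a two-sided Fisher exact p,
deliberately unadjusted as an exploratory statistic. CNV frequency
tracks partition the genome into 1 Mb bins; per bin and class the
frequency is the fraction of patients with ≥ 1 overlapping segment
(splitting a segment into abutting pieces changes nothing), and
arm-level "weighted frequency" is the segment-length-weighted mean of
bin frequencies over the arm.

## Outcome models

The covariate is the NOTCH1-wild-type tumor fraction at diagnosis:
100 x (CCF of the largest clone − CCF of the largest marker-carrying
clone), clamped to [0, 100]; a clone carries the marker if it or any
ancestor acquired it, so under subtree-inclusive CCFs the largest
carrier already counts every mutant descendant. An alternative
`sum_branches` mode subtracts the summed CCF of maximal disjoint mutant
branches instead. Relapse-sample trees are not used for the covariate.

The Cox model maximizes the Efron-tie partial likelihood by damped
Newton (covariates centered; convergence at gradient max-norm < 1e-8;
ties matter because event times have day granularity). Wald CIs and
p-values come from the inverse information. Monotone likelihoods
(perfect separation) are detected by diverging, scale-adjusted
coefficients or exploding standard errors and refused rather than
reported. The model pools subgroups by default with an optional strata
argument. Status-based relapse-time comparisons use the two-sided
rank-sum by default with a log-rank alternative.

## Synthetic cohorts

The generator produces the structure the analysis assumes, per subgroup
(pediatric/adult x T-ALL/T-LBL):

* random recursive truth trees of 1–8 clones over 1–4 timepoints
  (diagnosis at day 0); the founding clone's CCF is 1 and children split
  a Dirichlet share of the parent per timepoint, so the sum rule holds
  exactly and clones can regress between timepoints;
* clones are rejection-sampled to be separated by ≥ `min_ccf_gap`
  (default 0.15, L-infinity over timepoints) and detectable somewhere;
  trees that cannot meet the gap are shrunk, skewing the effective clone
  count low — as in real panel data, where only resolvable clones are
  reported;
* event labels mirror the recurrent T-lymphoblastic loci (NOTCH1, PHF6,
  FBXW7, PTEN, BCL11B, USP7, KMT2D, TP53; del/LOH/dup_in_9p, dup20,
  del_in_6q) with NOTCH1 the most frequent. The patient's label multiset
  is drawn first (weighted, without replacement) and assigned to node
  slots by a uniform permutation, so placement is exchangeable and the
  label-shuffle permutation test is exactly calibrated on unbiased
  cohorts. A trajectory bias (default: 10x on `LOH_in_9p -> NOTCH1` in
  the pediatric subgroups) re-places the source/target pair on an
  ordered slot pair weighted toward ancestor -> descendant
  configurations; multiplier 1 reduces exactly to the uniform null;
* reads: depth ~ Poisson(500), alt ~ Binomial(depth, expected VAF) under
  the same forward model the CCF engine inverts; arrays: Gaussian noise
  (BAF sd 0.02, logR sd 0.05) around the class-specific allele model,
  with CNVs below 2% aberrant-cell signal left uncalled;
* purity ~ U(0.5, 1.0) per sample; outcomes: event time exponential with
  rate `5e-4 * exp(ln(1.032) * covariate)` per day (the planted hazard:
  +3.2% per percentage point of NOTCH1-WT fraction), censoring
  exponential at 5e-4/day (roughly 60% observed events), pediatric ages
  U(1.5, 18), adult U(18, 65);
* per-patient RNG substreams derive from the master seed, so cohorts are
  byte-identical under a fixed seed and adding patients never perturbs
  existing ones.

`require_identifiable=True` additionally rejection-samples truth CCFs
until the truth tree is the *unique* sum-rule-consistent tree on the
true clone CCFs — checked by pure enumeration on the truth, independent
of the inference code. Without this, observationally equivalent
topologies exist (a star whose children never cross in CCF is
indistinguishable from a chain) and no method could recover the truth
exactly.

**What the generator does not emulate.** Sequencing artifacts and
mapping bias, germline contamination, overlapping/nested CNV segments,
mutation loss (the infinite-sites assumption holds except for clone
regression to CCF 0), within-gene mutational hotspots, covariance
between burden and age, and the matched case–control sampling of real
relapse cohorts. Green tests on synthetic cohorts therefore demonstrate
the correctness and calibration of the machinery under its stated
model, not robustness to real-data artifacts.

## Test and verification regimes (problem sizes)

* CCF closed forms: exhaustive grid over purity x copy number x
  multiplicity x fraction, agreement ≤ 1e-9 (measured ~1e-16).
* Tree recovery: 100 identifiable patients of ≤ 5 clones, 2–3
  timepoints, purity U(0.9, 1.0) — the high-blast regime in which
  recoverability is claimed. Exact noise-free recovery uses clone gaps
  of 0.25: at 500x depth the method's own binomial noise model cannot
  (and should not) split clones ~3 sigma apart, so exactness is only
  guaranteed when gaps exceed the assumed noise; the noisy check keeps
  the 0.15 gap and requires ≥ 90% pairwise-relation accuracy. The
  noise-free run is told the array noise level of its data
  (`baf_sd = 1e-4`), a measurement-model input.
* Permutation calibration: 500 unbiased cohorts of 40 trees, an a-priori
  list of the 12 ordered pairs among the four most frequent labels (no
  per-cohort selection, which would bias the rate upward), n_perm = 199
  (p granularity 1/200 so the 0.05 level is attainable); pooled
  rejection fraction at 0.05 must lie in [0.03, 0.07] — slightly below
  nominal is expected from the discreteness of the support statistic.
* Power: 100 biased cohorts of 40 trees, n_perm = 1999 (BH needs raw
  p ~ 1e-3), BH-adjusted p < 0.05 required in ≥ 80%.
* Cox: planted beta = ln(1.032) per percentage point, n = 800, ~60%
  events; 95% CI coverage ≥ 90/100 over fresh outcome draws on a fixed
  covariate design, and agreement with an independent partial-likelihood
  implementation to |dbeta| ≤ 1e-6 on 50 random datasets with ties.

`scripts/acceptance.py` re-measures these quantities at moderately
reduced replicate counts (60 patients, 200 calibration cohorts, 40 power
replicates, 60 coverage replicates) so a full from-scratch run stays
around two minutes on one CPU.

## Known limitations

* Purity estimation assumes some clonal event exists; samples whose
  every event is subclonal get CCFs on a scale relative to the largest
  clone.
* Exhaustive enumeration caps at 8 clusters — appropriate for panel
  data, not whole-genome clone counts.
* The permutation null conditions on tree topology and per-node label
  counts; it tests ordering conservation, not event co-occurrence.
* Exploratory exclusivity is reported unadjusted by design; treat small
  p-values as hypothesis-generating.
* No multivariable adjustment (MRD, stage), no competing risks, and no
  reweighting for case–control enrichment of relapses: hazard ratios
  from enriched designs do not reflect population incidence.
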