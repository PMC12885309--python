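# Methods

`hrqolbn` implements a causal Bayesian-network analysis of health-related
quality of life (HRQoL) for cohort data of the KoGES Ansan type: SF-12
composite scoring, constraint-based structure learning under a life-course
blacklist, bootstrap model averaging, exact do-interventional effect
estimation on quartile-tail outcomes, and pairwise additive-interaction
analysis.  This note records the model, the conventions and tunables, the
synthetic-cohort bench, and the numerical choices, in that order.

## Model

The fifteen analysis variables — SEX, AGE, MARRY, JOB, INCOME, EXER, DRINK,
SMOKE, BMI, ACT (daily activity volume in MET-hours), INSOMNIA (ISI score),
PSS (perceived-stress score), nCNCD (chronic-disease count), and the SF-12
summaries PCS and MCS — are modeled as a discrete Bayesian network

    P(X1, ..., Xp) = prod_i P(Xi | Pa_i),

a DAG with per-node conditional probability tables (CPTs).  Interventions
follow do-calculus: do(X = x) severs X from its parents and clamps its value;
event probabilities under the mutilated network are computed by the
truncated factorization.  Inference is exact (dense-factor variable
elimination with a min-degree ordering); with 15 nodes of 2–3 levels a query
costs well under a millisecond, so no Monte-Carlo error enters the reported
effects.  A forward sampler over the mutilated network exists purely as an
independent test oracle.

Interpretation of the learned arcs as causal rests on the usual
identification assumptions (causal sufficiency, consistency, positivity);
positivity of every intervened level is checked against the observational
marginal at query time and violations raise a warning.

## SF-12 scoring

PCS and MCS are weighted sums of the 12 standardized item scores using the
published norm-based factor-score coefficients (e.g. 0.42402·GH for PCS,
−0.22999·GH for MCS), mapped to a T scale (location 50, scale 10).  The
per-item means/SDs of the 1998 U.S. reference population are proprietary
tables; the default standardizes items against the analyzed cohort itself,
and external norms can be supplied through `ScoringWeights.norm_params`.
Item polarity is assumed harmonized (higher = better health); a per-item
polarity flag is available for instruments delivered in raw orientation.
ACT is the MET-weighted sum of the five activity durations,
`1.0·sedentary + 1.5·very light + 2.5·light + 4.5·moderate + 7.0·vigorous`
hours/day, with the five durations constrained to sum to 24 h.

## Discretization conventions

Structure learning operates on categorical data.  Age uses fixed bins
[50,55), [55,70), [70,82); income uses <1, [1,4), ≥4 million KRW
(Low/Mid/High); the chronic-disease count maps 0 / 1 / 2+ to Low/Mid/High.
BMI, ACT, the insomnia and stress scores, PCS and MCS are cut at the
empirical 25th/75th percentiles (linear-interpolation quantiles) into
Low/Mid/High.  Interval closure follows risk orientation: a value lying
exactly on a cut is assigned to the lower-risk side (for ACT, BMI, PCS, MCS
larger values are favorable; for the symptom scales smaller ones are).  The
tail outcomes are the quartile categories of the scores: *poor* = Low
(below the 25th percentile), *good* = High (above the 75th).  All cut
points are logged and serialized with the run.

## Structure learning

* **Skeleton** — PC-stable: level-wise G² (log-likelihood-ratio) conditional
  independence tests with adjacency sets frozen per conditioning-set size,
  which makes the skeleton invariant to variable order.  Degrees of freedom
  are (|x|−1)(|y|−1) per non-empty stratum.  Default α = 0.05.  A
  sparse-table guard declares independence when the average cell count of a
  stratified table falls below 5 (configurable); this prevents spurious
  edges driven by nearly empty strata.
* **Blacklist** — five life-course layers (demographic → socioeconomic →
  behavioral/psychological → medical → HRQoL) prohibit every arc from a
  later to an earlier layer, plus both orientations of SEX–AGE; 81 ordered
  pairs in total.  A pair forbidden in both directions is excluded from the
  skeleton search; a pair forbidden one way only constrains orientation.
* **Orientation** — unshielded colliders x→z←y are oriented when z is
  outside the recorded separating set *and*, when data are available, a
  conservative confirmation test rejects x ⊥ y | sepset ∪ {z}.  The
  confirmation step guards against a finite-sample failure mode: a weakly
  dependent pair removed at conditioning level 0 records an empty sepset,
  and the plain rule then fabricates a collider.  Meek's rules R1–R4 close
  the orientation (R2 generalized to full directed-path cycle avoidance);
  every rule application skips blacklisted orientations, and edges with one
  forbidden direction are oriented the permitted way first.
* **DAG extension** — Dor–Tarsi consistent extension (no new v-structures,
  no cycles, blacklist respected).  Sink candidates are taken in
  reverse-lexicographic order, so an unconstrained edge a–b orients a→b
  with a the lexicographically smaller name; the choice is arbitrary but
  deterministic and documented.

## Bootstrap model averaging

B resamples (default 15,000 at 80% of the rows, with replacement; the test
and benchmark scale is B = 200) are each run through the full
skeleton–orientation–extension chain with per-replicate seeds spawned from
one root seed.  *Arc strength* is the fraction of replicates containing a
pair in either orientation; *arc direction* is the fraction of those
pair-containing replicates with a specific orientation, so the two
directions of a pair sum to 1 (consistent with direction weights like
0.56/0.44 summing to 1).  The consensus network keeps pairs with strength
strictly above the threshold (default 0.3), oriented by majority direction;
majority frequencies in the band [0.5, 0.6) are flagged directionally
uncertain and exported as dashed/undirected.  If the retained arcs ever form
a cycle, the weakest arcs on cycles are dropped and logged.  Arc counts
across a threshold grid (0.1–0.5) are reported so the sparsity/threshold
trade-off is visible in every run log.

Because a bootstrap resample reuses the cohort's own sampling noise,
borderline dependences persist across replicates; strengths near the
threshold should be read as "sensitive to this cohort", not as stable
discoveries.  This mirrors the behavior of bagged structure learning
generally and motivates the threshold sweep in the log.

## Effects, direction sensitivity, and interactions

CPTs are fitted on the consensus DAG by Laplace-smoothed counts
(pseudo-count 1 by default; empty strata fall back to uniform when
smoothing is off).  For each tail outcome and each variable, the effect
table reports P(outcome | do(X = level)) and the risk ratio against the
variable's most favorable level (Low insomnia, Low stress, High ACT,
exercise = Yes, ...); variables whose probabilities differ by less than
0.005 across levels are flagged negligible.

When a retained arc of designated sensitivity (INSOMNIA–PSS by default) is
directionally unstable, the pipeline fits the two networks differing only
in that arc's orientation and combines the per-network estimates as a
weighted average, using the observed direction frequencies as weights;
per-cell minima and maxima across the two networks are retained.  When the
pair has no parents, reversing the arc leaves every other node's parent set
— and, for unsmoothed fits, every other effect — exactly unchanged; this is
asserted in tests.

Pairwise interactions dichotomize each exposure so that level 1 is the
higher-risk quartile: cut at the 75th percentile in general, at the 25th
for ACT (low activity is the risk side) and for BMI when the outcome is
mental HRQoL (low BMI tracks frailty); binary variables take their adverse
side as level 1 (e.g. EXER = No).  The merged level 0 spans two categories;
it is intervened as a stochastic policy that distributes mass according to
the variable's restricted, renormalized observational marginal.  With
p_ab = P(outcome | do(Var1 = a, Var2 = b)),

    interaction = p11 − p10 − p01 + p00     (synergy > 0, antagonism < 0)
    total       = p11 − p00
    relative    = interaction / total       (undefined when |total| < 1e-12)

on the probability scale (narrative percentage points are these × 100).
Scans over all exposure pairs and the four tail outcomes report rows with
|interaction| > 0.01 and |total| > 0.01.  Because both members of a pair
are intervened simultaneously, all arcs into both nodes — including any
arc between them — are removed, so a pair's grid is invariant to the
orientation of an arc joining its members; pairs containing exactly one
endpoint of the sensitivity arc are direction-dependent and are averaged
across the two networks like the single-variable effects.

## Synthetic cohort bench

The generator samples person-level records from an explicit ground-truth
network whose categorical marginals track the reference cohort (49.5% male;
age bands 26/63/11%; 90% married; 60% employed; income 9/54/37%; 66%
regular exercisers; 53% drinkers; 38% smokers) and whose skeleton encodes
the expected epidemiology, including the pathways exercise → BMI →
morbidity → physical HRQoL, activity volume → physical HRQoL, and insomnia
and stress into both HRQoL factors, with *no* direct arc between the
physical and mental factor.  CPTs are built additively on the probability
scale with mean-centered parent effects (so each node's marginal equals its
design base exactly), and the mental-HRQoL CPT carries one planted synergy:
+0.05 on the probability of the poor tail under joint high insomnia and
high stress, exactly beyond additivity.  The registry
`STRONG_PLANTED_EFFECTS` lists the designed contrasts whose tail-probability
shift is at least 0.05; recovery benchmarks assert on these.

Raw measurements are then emitted per record: integer ages uniform within
band; income amounts inside the band intervals; BMI and ACT as truncated
normals within their quartile bands of the reference mean/SD; activity
durations by linear interpolation between a sedentary and an active day
profile (summing to 24 h and reproducing the ACT value exactly); integer
symptom scores on disjoint per-category supports with category masses
0.27/0.50/0.23, placing the empirical quartile cuts strictly inside the
support gaps so re-discretization recovers the generating category exactly;
and the 12 SF-12 items from two latent factors located at −1.6/0/+1.6 per
Low/Mid/High with within-level SD 0.15, item noise SD 0.10, staggered
per-item response thresholds, and cross-loadings (0.3427 on physical items,
0.3691 on mental items) calibrated so the published scoring weights cancel
the opposite factor *after* Likert coarsening.

What the bench does not emulate: survey design and attrition, item-level
nonresponse patterns, the 1998 norm tables, disease-specific morbidity, and
— deliberately — realistic measurement unreliability of the SF-12.  The
latent health classes are well separated, so the computed summaries are
highly reliable class indicators; passing recovery tests therefore
demonstrates correctness of the algorithms under faithful measurement, not
robustness to noisy instruments.  Two structural facts discovered while
designing the bench are worth recording: (i) both composite scores weight
the same 12 item residuals, and the cross-product of the published weight
vectors is ≈ −0.41, so item-local noise necessarily induces negatively
correlated score errors — a spurious PCS–MCS dependence that no common
"response-style" factor can cancel (dependences of opposite sign add, not
cancel, in G² terms) and that is suppressed here only by making item errors
small; and (ii) variable pairs whose independence rests on a single
separating set are fragile under bootstrap resampling, which recycles the
cohort's chance dependence; the bench therefore gives such pairs real arcs.

Benchmarks run at n = 5,000 (2,566, the reference cohort size, for pipeline
smoke tests) with B = 200 bootstrap replicates and a fixed seed; at that
scale the ±0.03 (effects) and ±0.02 (interaction) recovery tolerances sit
near two standard deviations of the cohort's own sampling noise, which is
why the benchmarks fix the seed and assert only the strong planted
contrasts.

## Numerical choices and degenerate inputs

* Quantiles: NumPy linear interpolation; ties to the lower-risk side.
* G² with zero cells: zero-count terms contribute 0; dof count only
  non-empty strata; a statistic of exactly 0 reports p = 1.
* CPT rows must sum to 1 within 1e-9 (1e-12 for the generator); fits with
  pseudo-count 0 put uniform rows on empty strata and log how many.
* Bootstrap replicates with a constant resampled column or no consistent
  extension are skipped and counted; an all-skipped run raises.
* Relative interaction is reported missing when |total| < 1e-12.
* All randomness flows from one integer seed through named SeedSequence
  spawns; the generator keys a stream per variable by a stable hash of the
  variable name, so output is invariant to column order.

## Known limitations

* The conservative collider confirmation trades a little orientation power
  for robustness; genuinely weak colliders may stay undirected.
* Arc directions inside Markov-equivalence classes (e.g. the insomnia–
  stress arc between two parentless nodes) are not identifiable from
  observational data; the bootstrap direction frequency for such arcs
  reflects tie-breaking and resampling noise, which is exactly why the
  direction-sensitivity machinery exists.
* Effect estimates carry no confidence intervals; point estimates only.
* Three-way interactions are supported by the same do-machinery in
  principle but are not part of the default reports.
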