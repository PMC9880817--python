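# Methods note

This note records the model implemented by `cofrac`, the parameter choices
and their rationale, what the synthetic-data generator does and does not
capture, and the numerical decisions that matter for reproducing results.

## 1. Data model

One co-fractionation experiment is a protein × fraction matrix of
non-negative integer spectral counts (`cofrac.profiles.ProfileMatrix`), with
fraction columns named `<experiment>_F<i>` in elution order. Experiments are
labeled by technique: SEC and SDGC separate by native size; IEX separates by
charge. A study is a set of such matrices over a shared protein universe.

### Identification filter

A protein is retained if it reaches at least `min_psm` (default **2**)
spectral counts in a single fraction of at least one experiment. One-count
identifications are overwhelmingly likely to be spurious matches; requiring
the two counts in the *same* fraction (rather than summed) keeps the filter
aligned with the single-species elution assumption.

### Normalization and smoothing

Before apex picking and feature computation each profile is divided by its
maximum (so experiments of different depth are comparable) and smoothed with
a centered moving average of width `smooth_window` (default **3**, truncated
at the edges). Smoothing suppresses single-fraction Poisson spikes that
would otherwise dominate argmax-based quantities.

## 2. SEC calibration and oligomer state

Within a column's working range, log10(mass) is linear in fraction index.
The calibration line is an ordinary least-squares fit (scipy
`linregress`) of log10(standard mass) on standard peak fraction; the default
standards are thyroglobulin (669 kDa), BSA (66.5), egg albumin (44.3), and
myoglobin (17). The apparent mass `Mapp` of a protein is the line evaluated
at its profile apex (1-based argmax after normalization and smoothing; ties
resolve to the earliest fraction). With `Mmono` the sequence-predicted
monomer mass,

* `Rapp = Mapp / Mmono >= 2` → **complexed** — the protein elutes at twice
  its monomer mass or more, which a monomer cannot do;
* `Rapp <= 0.5` → **degraded** — it elutes well below its own mass, i.e. the
  detected peptides come from a fragment; degraded proteins are excluded
  from pair scoring because fragment profiles carry no assembly signal;
* otherwise **monomeric**.

With several SEC experiments, a degraded call in any experiment dominates,
then a complexed call in any, else monomeric. A degraded call anywhere
indicates the protein's material is compromised, so exclusion is the
conservative merge; this rule is a package design choice.

Note the detectability limit: a heterodimer's mass is at most twice its
heavier member's mass, so size-based separation alone cannot certify the
heavier member of an uneven dimer as complexed. The generator and the
round-trip validation both respect this bound (§5).

## 3. Pair features and candidate set

Profiles are max-normalized **per experiment** and concatenated into one
long vector per protein; raw counts are concatenated in parallel for the
count-based features. Candidate pairs are unordered pairs of retained,
non-degraded proteins detected together in at least one experiment. Each
candidate gets five features:

| feature | definition | computed on |
|---|---|---|
| `pearson` | product-moment correlation | normalized, smoothed |
| `jaccard` | overlap of detection supports (count > 0) | raw counts |
| `apex` | 1 iff argmax fractions coincide (ties → earliest) | normalized |
| `mi` | mutual information, 5 equal-width bins over [0, max], base 2 | normalized |
| `bayes` | Pearson of Dirichlet-smoothed proportions (pseudocount α = 1) | raw counts |

Pairs whose Pearson similarity is not **strictly** above 0.5 are discarded
before classification; this prefilter removes the vast majority of the
~n²/2 pair space while keeping essentially all co-complex pairs.

**Design decision — concatenation instead of per-experiment aggregation.**
An alternative is to compute features per experiment and aggregate by
maximum. Under this data model that is provably lossy: IEX peak positions
are independent of mass, so distinct complexes collide in IEX at an
appreciable rate, and the max over experiments of any similarity makes such
cross-complex pairs indistinguishable from true pairs (their SEC/SDGC
similarity is already near 1). Concatenation requires a pair to track in
*every* experiment, which is exactly the physical signature of a shared
assembly; empirically it is the difference between a classifier AUC near
0.8 and above 0.95 on this generator.

## 4. Supervision, classifier, and network

Labels come from a reference complex set: a candidate pair is positive if
both members share a reference complex, negative if both are annotated but
never co-complexed, unlabeled otherwise. Negatives are subsampled (seeded)
to at most 5× the positives, the usual class-balance compromise.
Cross-validation folds are assigned to whole complexes (default **5**
folds), so no complex contributes pairs to both train and test — pair-level
folds would leak complex identity and inflate AUC.

The classifier is a scikit-learn random forest (**500** trees, fixed
`random_state`, single-threaded for determinism); a logistic baseline is
available. Reported performance is the pooled out-of-fold ROC/AUC.

**Edge threshold.** The network keeps pairs with predicted probability at or
above a threshold. The default policy (`threshold_policy: precision`)
chooses the smallest threshold whose pooled out-of-fold precision reaches
`target_precision` (default **0.9**), computed at run time from the
held-out predictions. A fixed cutoff (`threshold_policy: fixed`, default
0.5) is available, but at 0.5 roughly half the retained edges on synthetic
data are false — dominated by physically unresolvable "full collisions"
(pairs of complexes sharing both assembly-mass position and IEX fraction) —
and those edges glue distinct complexes into super-clusters downstream. The
precision policy is not a tuned constant: it adapts to whatever the
held-out data supports and degrades gracefully (with a warning) when the
target is unattainable.

## 5. Complex detection

Complexes are grown on the weighted network (edge weight = predicted
probability) by greedy maximization of cohesiveness
`f(V) = w_in / (w_in + w_bound + p·|V|)` with penalty `p = 2` (models
unobserved connections; keeps tiny sets from scoring well). Seeds are
uncovered nodes in decreasing weighted-degree order. Each step applies the
single strictly-improving move (add a boundary node / remove a member) with
the best score, ties broken by smallest node id — the procedure is fully
deterministic and, being greedy, attains the optimum over improving-move
sequences, not the global subset optimum. Clusters with overlap
`ω(A,B) = |A∩B|²/(|A||B|) ≥ 0.8` are merged to a fixed point; clusters with
fewer than 3 members or weighted density below 0.3 are discarded. Recovery
is evaluated against planted complexes of size ≥ 3 at member-set
Jaccard ≥ 0.5.

## 6. Synthetic-data generator: realism and limits

Captured:

* log-linear SEC/SDGC mass-to-fraction mapping, with calibration refit from
  standards rather than assumed;
* mass-independent IEX positions shared within a complex — the property
  that makes multi-technique designs informative;
* spectral-count noise: Poisson counting around a Gaussian elution kernel,
  log-normal complex abundance (μ = log 150, σ = 1), per-cell dropout
  (p = 0.2), Poisson background (rate 0.05);
* degraded proteins (5%) eluting at 0.4× monomer mass — inside the
  degraded region of the Rapp rule but still on-column;
* detectability: complexes of size ≥ 3 are resampled until assembly mass is
  ≥ 2.5× every member's monomer mass, so planted "complexed" states are
  recoverable on an integer fraction grid (the 0.5 margin over the
  theoretical 2× bound absorbs rounding). Heterodimers are exempt — they
  cannot satisfy the bound for their heavier member (sum of two masses
  ≤ 2× the maximum), which is a physical limit, not a generator artifact.

Not captured: stoichiometry beyond 1:1 (complex mass is the plain sum of
member masses), moonlighting proteins in several complexes, partially
assembled subcomplexes, peak tailing/skew, shared-peptide inference
ambiguity, batch effects between experiments, and abundance-correlated
dropout. These omissions make the task cleaner than real data; absolute
performance numbers should be read as upper bounds.

## 7. Numerical and reproducibility choices

* All randomness flows from `numpy.random.default_rng` seeded explicitly;
  ground truth and count matrices use separate streams (`(seed, 0)` and
  `(seed, 1)`) so the same population can be re-counted independently.
* Zero-variance profiles yield NaN correlations (never silently 0); pairs
  with undefined features are dropped from the candidate table.
* Mutual information uses equal-width bins over `[0, max]`; a constant
  profile occupies one bin and contributes zero information by convention.
* The random forest runs single-threaded with a fixed `random_state`;
  summaries round floats to 6 decimals and serialize with sorted keys, so
  reruns are byte-identical.
* Fraction indices are 1-based everywhere (column `F1` is fraction 1);
  argmax ties resolve to the earliest fraction.
* OLS calibration with 2 standards is reported with r² = 1 by definition;
  fewer than 2 distinct fractions is an error.
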