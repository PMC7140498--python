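# Methods

This note documents the models, parameter choices and numerical conventions
behind `cytostab`, and what the synthetic-data tests do and do not
demonstrate about real assay data.

## Half-life estimation

The substrate-depletion estimator assumes first-order loss of parent
compound: remaining(t) = 100·2^(−t/t½). The fit is ordinary least squares of
ln(remaining %) on time over the assay grid (0, 5, 10, 15, 30, 60 min), with
t½ = ln 2 / k from the negative slope.

Numerical conventions:

* Points with remaining ≤ 1% are excluded (their log values are dominated by
  LC/MS noise), provided at least 3 points survive; otherwise all positive
  points are used.
* A non-positive depletion rate, or a fitted t½ above 120 min, returns the
  capped value (120 min, capped) — the assay window cannot resolve slower
  turnover, so capped values are reported as ">120" and never extrapolated.
* Fewer than 3 usable points, or no positive measurement after t = 0, is an
  estimation error, not a silent cap.

Thresholds (minutes): **unstable** ⇔ t½ ≤ 30 (inclusive; capped values are
stable); **substrate** ⇔ t½ < 60 (strict); the low/high QC bands (<10 / >30)
used for plate controls are deliberately not reused as the classification
rule. A pair's shift is judged on the fold ratio right/left with capped
members entering as 120: ≥ 1.5 positive, ≤ 1/1.5 negative, both-capped
inconclusive, else no shift. The 1.5-fold band is symmetric because a
directional "within assay error" band is not separately quantifiable; the
same 1.5 bound therefore defines a significant negative shift.

## Structure standardization

Parse → functional-group normalization (nitro, N-oxide, azide and related
normal forms via the RDKit standardizer) → largest organic covalent fragment
(salt/solvent stripping) → charge neutralization by proton add/remove.
Tautomer canonicalization is intentionally omitted: it is unstable across
toolkits and would make identity keys irreproducible. Stereochemistry is
retained, and deduplication uses the full standard InChIKey, so
stereoisomers remain distinct compounds. Duplicate keys keep one record only
if all duplicates agree on the stability class (otherwise the key is
rejected outright — a disagreement means the measurements straddle the
30 min boundary and neither class is trustworthy); the representative t½ is
the geometric mean of uncapped duplicate values, with any capped member
forcing the cap (t½ is treated as log-normal, and the cap is not a number
that can be averaged).

## Matched molecular pairs

Fragmentation cuts every acyclic single bond between heavy atoms
(fragment-and-index strategy). The variable fragment must have ≤ 13 heavy
atoms and be no larger than the constant part — large enough to catch real
substituent swaps, small enough that transforms stay chemically
interpretable. Cuts to explicit hydrogens are not enumerated (no H-swap
rules). Single cuts are the default; two-bond cuts, where the variable
fragment is the linker carrying both attachment points, sit behind
`n_cuts=2`. Attachment points are written as map-numbered dummy atoms and
fragments are canonicalized afterwards, so symmetric cuts deduplicate.

Pairs are directional: every unordered pair of compounds sharing a constant
key with different variable fragments yields both A→B and B→A. Transforms
aggregate pairs by (left fragment, right fragment); the mirror-image
collapse is applied only when counting *unique* rules. Reported statistics
per transform: frequency, shift-category counts, arithmetic mean Δt½
(capped values as 120), and the geometric mean fold over pairs with neither
member capped (folds are ratios; their natural average is geometric).

The 70:30 train/test split is a pure function of the identity-key set, the
ratio and the seed — two species tables containing the same compounds split
identically, which is what makes cross-species comparisons of mined rules
meaningful. Prospective validation mines pairs from the held-out split,
keeps those supported by training-set transforms, and reports the fraction
of conclusive pairs with ≥ 1.5-fold gain plus the number of
unstable→stable conversions.

Verdict rules, applied in order to a transform's conclusive shifts
(inconclusive examples are excluded): all positive → valuable; ≥ 1 positive
and no negative → valuable; at least as many negatives as positives → not
useful; more no-shifts than negatives → neutral; otherwise not useful.
Negativity dominance is checked before the neutral rule so that profiles
like {+, 0, −, −} are disqualified rather than softened to neutral. A
transform with only inconclusive examples is undetermined.

Transform application re-enumerates a molecule's fragmentations and rewrites
every site whose variable fragment equals the transform's left side — one
product per site, never combinatorial multi-site rewrites, since an MMP
transform is single-site by definition. Products are standardized,
deduplicated by InChIKey, and invalid products (valence violations) are
dropped with a log line. Candidate pairs are library members whose InChIKey
matches a product; prioritization keeps pairs whose left member the QSAR
model scores ≥ 0.5 for instability, ranked by descending score with the
left−right score gap and then lexicographic keys as tie-breaks.

## QSAR models

Descriptor sets:

* `rdkit2d` — the standard 2D physicochemical/topological panel (~210 named
  descriptors). Z-normalized; constant columns removed; of any pair with
  r² > 0.9 the alphabetically later column is dropped (determinism is the
  only defensible tie-break).
* `qna` — 120 descriptors: per-atom P/Q values from tabulated atomic
  ionization potentials and electron affinities (eV, NIST values packaged in
  `descriptors.ATOMIC_IP_EA`) propagated through exp(−C/2) of the heavy-atom
  adjacency matrix C, with A = ½(IP+EA), B = (IP−EA)^(−1/2),
  P = B∘(exp(−C/2)B), Q = B∘(exp(−C/2)(A∘B)); summarized into the 110 joint
  moments mean(P^a·Q^b), a = 0..10, b = 0..9, plus 10 whole-molecule 2D
  descriptors. The exact published summarization of the QNA family is not
  fully specified in the open literature; this moment construction is a
  documented reconstruction, kept unnormalized (only constant columns are
  removed, which also disposes of the identically-1 (0,0) moment).

Classifiers (binary, positive class = unstable): random forest (300 trees);
RBF-kernel SVM with Platt-calibrated probabilities (C = 1, gamma scaled);
and a discrete Bayes-family model — decile (10-bin) quantile discretization
feeding a categorical naive Bayes. Decile binning was chosen so the
discretized model can still resolve the class boundary on continuous
descriptors; quantile (unsupervised) binning keeps the discretization
deterministic and label-free. Hyperparameters are deliberately stock: the
package's concern is the sampling/evaluation protocol, not model tuning.

Class imbalance (≈25% unstable in the human-like setting, ≈10% mouse-like)
is addressed inside `fit`, never outside it, so sklearn cross-validation
automatically confines under-sampling to training folds:

* *diversity under-sampling*: MaxMin picking on Morgan fingerprints
  (radius 2, 2048 bits) down to the minority size; in the pure-matrix
  estimator pathway, where no structures are available, a brute-force
  Euclidean MaxMin in descriptor space is used instead. Both are seeded.
* *multiple under-sampling*: a seeded permutation of the majority class cut
  into minority-sized blocks (the last block topped up by re-drawing from
  earlier ids), guaranteeing every majority compound appears in at least one
  member; one model per block, final score = mean positive-class
  probability across members (probability averaging, not majority vote).

Evaluation: stratified 5-fold cross-validation (fold count is a convention
choice; it is stated nowhere upstream), descriptor filter fit inside each
training fold, predictions pooled over folds; sensitivity = unstable recall,
specificity = stable recall, BACC their mean (an identity that holds exactly
on unrounded values), AUC by rank statistic. External evaluation refuses any
record whose identity key occurs in the training set (leakage guard). The
chemical-space overlap report projects train and external descriptor
matrices onto the training set's first two principal axes and reports the
external fraction inside the training bounding box and inside the 95%
Mahalanobis ellipse (χ², 2 df).

## Synthetic data generator

The generator emulates a lead-optimization screening collection:

* **Series structure** — 43 packaged aromatic/heteroaromatic cores × 48
  attachment-ready R-groups; each series is one core with a random
  substituent subset (default 20–40 per series), giving dense
  single-site-variation MMP structure by construction. A packaged vocabulary
  guarantees chemical validity; random graph generation would not.
* **Half-lives** — log-normal (default median 55 min, log-sd 0.9). A
  configurable fraction of the log variance (`structure_frac`, default 0.9)
  is structural, driven by a z-scored TPSA-minus-logP combination (polar
  compounds drift stable, lipophilic ones unstable) — within congeneric
  series, stability is largely structure-determined, which is what makes
  QSAR on such collections possible at all. The remainder is compound-level
  noise, plus multiplicative measurement noise (`noise_cv`, default 10%,
  log-normal).
* **Planted rules** — substructure triggers multiplying t½ by a known fold.
  Default: the aryl-aldehyde handle (a classic aldehyde oxidase substrate)
  destabilizes 4-fold, and every series carries both the aldehyde analogue
  and its primary-amide swap partner, so the aldehyde→amide transform is a
  planted, recoverable, stability-enhancing rule. Ground-truth pairs are
  oriented in the stability-enhancing direction (out of a destabilized
  analogue, into a stabilized one).
* **Prevalence calibration** — the log-scale location is set so the realized
  unstable fraction hits the target (default 25%, human-like; 10%
  mouse-like) exactly via the empirical quantile; the 120 min cap is applied
  afterwards and does not disturb the ≤ 30 min count.

Two named study conditions recur in the tests:

* the *rule-only* library (`structure_frac = 0`, log-sd 0.15, 40 series):
  baselines vary only by noise, so the planted transform is the only
  systematically positive rule — the regime for the transform-recovery
  oracle, mirroring a validation experiment where one causal rule is probed
  against assay noise;
* the *structural* library (defaults, 40 series, n ≈ 1150): stability is
  structure-determined — the regime for QSAR learnability, where
  cross-validated BACC ≥ 0.85 is achievable and demanded.

What passing these tests shows: the miner, verdict logic, split machinery,
samplers and metrics are correct, and the pipeline recovers a known causal
rule under assay-like noise and cap censoring. What it does not show:
performance on real chemistry — real collections have correlated series,
assay failures, tautomers and measurement artefacts the generator does not
emulate, and real structure–stability relationships are far weaker than the
planted ones. Synthetic BACC values say nothing quantitative about
prospective performance on proprietary screening data.

## Problem sizes and runtime

Default test and acceptance-script sizes were chosen to exercise every code
path at meaningful scale on a single CPU: libraries of ~350 (unit tests) to
~1150 compounds (end-to-end and acceptance runs), 500 replicate time-course
fits for noise-recovery statistics, and 5-fold cross-validation at n ≈ 1150.
The full suite runs in about a minute; the acceptance script in about half a
minute.

## Known limitations

* Tautomer handling is deliberately absent; inputs differing only by drawn
  tautomer produce distinct identity keys.
* Two-cut fragmentation is implemented but lightly exercised; three-cut
  fragmentation and environment-conditioned transforms are out of scope.
* The QNA reconstruction matches the family's inputs and spirit, not any
  reference implementation's exact values.
* `prioritize_pairs` ranks by predicted instability score with a fixed 0.5
  threshold; no probability calibration beyond the SVM's Platt scaling is
  attempted.
* The 70:30 split counts of any particular historical campaign are not
  reproducible from a ratio alone (a stated 70% share that disagrees with
  round(0.7·n) cannot be matched exactly); the implementation follows the
  ratio.
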