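# Methods

## Overview

pmedkit models a prospective personalized-medicine workflow for canine
tumors: sample quality gating, tumor-versus-normal z-score profiling,
cross-species identifier conversion, six drug-prediction algorithms, a
ranked per-patient report, sample clustering, and clinical turnaround
accounting. All computations live in `src/pmedkit/`; synthetic data
with planted ground truth stands in for the original microarray cohort,
so every claim the test suite makes is about the algorithms, not about
canine biology.

## Expression model and z-score profiling

Probe intensities are modelled on a log scale: probe $p$ has reference
mean $\mu_p \sim U(5, 11)$ and standard deviation
$\sigma_p \sim U(0.2, 0.6)$; a reference sample draws
$N(\mu_p, \sigma_p^2)$. A tumor adds (i) a cancer-type signature —
`type_effect` (default 2.5) z units on 50 genes per named type, chosen
disjointly per type; the "open" cohort carries none, emulating mixed
histologies — and (ii) patient-specific planted effects, all expressed
in multiples of $\sigma_p$, plus $N(0, \sigma_p^2)$ noise. The Gaussian
family is a deliberate stand-in: z-scores are the sole downstream
consumer, so microarray physics (probe saturation, batch structure,
MAS5 summarization) is out of scope, and nothing downstream would
distinguish it from heavier-tailed intensity noise of the same scale.

Profiling standardizes each tumor probe against the reference
($\sigma$ with the $n-1$ denominator; probes with $\sigma = 0$ are
dropped with a warning rather than floored, since an epsilon floor
manufactures arbitrarily large z), averages probe z-scores per canine
gene, maps canine→human genes through the homolog table keeping only
rows whose canine *and* human genes each occur exactly once, and keys
the result by human probesets. The default probeset projection is
strict one-to-one (mirroring the homolog clause); a `fanout` mode
replicates a gene's z across all its probesets for consumers that need
probe coverage. Identifiers are compared as exact strings after
whitespace trimming; mapping steps never alter z values, so identifier
sets can only shrink along the chain.

With a 40-sample reference the estimated $(\hat\mu, \hat\sigma)$ make
null z-scores slightly heavier-tailed than $N(0,1)$ (t-like with ~39
df; the tail mass at 3 roughly doubles). Method calibration is
therefore assessed on exact standard-normal null profiles — the
methods' model assumption — and the finite-reference inflation is a
property of small reference compendia that users should keep in mind
when interpreting $z \ge 3$ rule firings on real data.

## Quality gates

Four stages, each a conjunction of metric thresholds: histopathology
(tumor surface and nuclei in the top ordinal category "75–100%";
necrosis not in the worst category ">20%"), RNA (yield =
concentration × volume ≥ 20 ng at the default 14 µl, A260/A280 ≥ 1.8,
RIN ≥ 8.0), cDNA (≥ 5 µg at ratio ≥ 1.8), and array (background < 100,
present calls ≥ 30%, scale factor within a 3-fold band around 100 — a
strict equality gate on "scale factor 100" would be unusable, so the
band is configurable). Metrics never measured are *not-evaluated* and
do not veto: a stage unreached because an earlier stage failed cannot
fail a sample twice. The 31-record fixture carries the seven published
failure records (with not-measured cells substituted by passing values
where a category is needed to express the recorded failure) and yields
24/31 overall passes and 30/31 RNA passes by construction of its
inputs, not by assertion.

## Turnaround clock

All timestamps convert to US Eastern civil time (`America/New_York`;
the study window May–October 2011 falls in EDT, and a fixed UTC−5
variant was rejected because the study's own day arithmetic matches
civil time). Business hours are the wall-clock span minus every hour
falling on a weekend day or holiday date; a business day is the full
24 hours of a non-excluded day, fixed by the observation that
116.46 h ÷ 24 = 4.85 days exactly matches the published day
conversion. Holidays are a user-supplied date list (2011 US federal
holidays shipped as default); partial holidays are not modelled.
Rounding to two decimals happens only at reporting. The event-log
generator inverts the clock (`add_business_hours`), so requested
business-hour spans round-trip to ±0.01 h; cohort tables are
case-weighted means.

## Prediction methods

**Rule methods.** A drug-target rule fires on $z \ge$ threshold
(default +3, per-rule overridable); biomarker rules add direction
(over/under) and effect (sensitive → indicated, resistant →
contraindicated). The paper-level requirement on p is only
monotonicity in z; the one-sided standard-normal tail
$\bar\Phi(|z|)$ is used as the simplest map consistent with the
z-score's construction, and is pluggable. Several rules firing for one
drug keep the minimum p and list all triggering genes.

**Response signatures (connectivity).** Query sets are
$\{z \ge +2\}$ and $\{z \le -2\}$. Enrichment of a t-member set in an
n-long ranking uses the rank-based KS form: with ascending member
ranks $V_j$, $a = \max_j(j/t - V_j/n)$, $b = \max_j(V_j/n - (j-1)/t)$,
$ES = a$ if $a > b$ else $-b$ (equal to the one-sample KS $D^+/D^-$ of
$V_j/n$ against uniform, which is the independent oracle in the
tests). Connectivity is $s = (ES_{up} - ES_{down})/2$ when the two
enrichments disagree in sign, else 0; if only one query set intersects
the universe its enrichment carries the score. Significance for
inverse connectivity is a permutation test on random same-size queries
with the add-one estimator $p = (1 + \#\{s_{perm} \le s_{obs}\})/(n_{perm}+1)$,
so $p \ge 1/(n_{perm}+1)$ and is reproducible given a seed. Because a
random set against a fixed ranking is a uniform random rank set, the
null depends only on the query sizes and universe size and is cached
and shared across drugs. The same-sign-zero rule puts an atom of $s$
at 0, so the *full* null p distribution is not uniform; lower-tail
uniformity ($P(p \le x) = x$ below the atom), which is what α-level
reporting requires, holds and is tested. Signatures are per-drug
consensus rankings; a per-instance mode was considered and not built.

**Sensitivity signatures (PGSEA).** For a signed signature with
$m \ge 2$ genes present, $v_i = \text{sign}_i z_i$,
$t = \bar v / (s_v/\sqrt m)$, one-sided upper-tail p on $m-1$ df
(degenerate $s_v = 0$ maps to the smallest positive float, flagged).
One-sided toward sensitivity matches the reporting direction of the
workflow; a two-sided option exists in the p calculation's building
blocks but is not the default.

**Network target activity.** Seeds are all nodes with $z \ge 2$ or the
top-200 over-expressed (ties at the boundary break by higher z then
lexicographic id). The shortest-path network S is the union of all
shortest directed paths between ordered seed pairs (membership decided
by the distance identity $d(s,u) + 1 + d(v,t) = d(s,t)$, verified
against explicit path enumeration on all test graphs ≤ 12 nodes).
$K_{ij}$ counts seed pairs, $N_{ij}$ all connected ordered pairs, with
some shortest path traversing both $i$ and $j$ in either order
(unrestricted pairs by default; an adjacent-pair variant sits behind a
flag for sensitivity analysis). The reported probability is the
hypergeometric upper tail of drawing the seed-pair total from the
global pair total with $N_{ij}$ marked successes; per target the best
p over pairs containing it is kept, and targets with p < 0.05 map to
their drugs. The "reported above 0.05" phrasing in the source
description contradicts every other method and is treated as a typo
for below.

*Known limitation.* The hypergeometric null models seed pairs as
independent draws of connected pairs, but they are pairs among a small
random node set: any pair observed on a seed shortest path is
automatically deep in its own null's upper tail. Under null profiles
the per-target reporting rate measures ~0.13 (default network,
unrestricted pairs; ~0.07 adjacent) against a nominal 0.05 — the
statistic is anticonservative by construction, independent of
implementation (which is enumeration-verified). The corresponding
calibration test is left failing deliberately to document this; a
seed-label permutation null would calibrate but is a different
statistic. Treat network-method scores as rankings, not as calibrated
error rates.

## Report aggregation

Scores are $-\log_{10} p$ (base configurable; base only rescales).
Per drug, scores are summed over indicating methods — plain summation
implements "stronger indications for drugs predicted by multiple
methods"; a per-method cap was considered and rejected as
under-motivated. Duplicate calls from one method keep the best p. Any
resistance contraindication excludes the drug from the ranked list
into a separate section (exclusion, not a score penalty; a penalty
mode is a documented alternative). Ties break alphabetically so
rendering is deterministic; JSON serialization round-trips losslessly.

## Clustering

Sample distance is $1 - r$ (Pearson) over shared features; zero-variance
samples are an error naming the sample. Classical (Torgerson) MDS:
double-center $-\tfrac12 D^2$, eigendecompose, scale eigenvectors by
the root of the top-k non-negative eigenvalues; negative eigenvalues
(non-Euclidean input) are truncated, and each axis is signed so its
largest-magnitude coordinate is positive, making output deterministic.
k defaults to 2. Separation by a labelling is the mean silhouette in
the embedding. The drug-score matrix for clustering encodes absent
calls as 0. On default synthetic cohorts expression silhouette by
planted type is ~0.75–0.8 while the drug-score silhouette is near or
below zero — the comparative restatement of "expression clusters by
cancer type, drug reports are patient-specific".

## Synthetic study design

Defaults are the study conditions: 40 reference samples (the source
also mentions 39 in one place; the count is a parameter), cohorts of
5/4/5/10 passing tumors, 2,000 probes with 1–3 probes per gene
(probabilities 0.6/0.3/0.1, ~2% probes unannotated), 10% ambiguous
homologs split between one-canine→two-human and two-canine→one-human
flavours, and knowledge bases of 260 target rules / 123 drugs, 34
biomarker rules / 20 drugs, 107 response signatures, 11 sensitivity
signatures of 20 signed genes, a 184-drug pool, and a directed network
of the 260 targets plus 40 extra nodes at mean out-degree 1.5 (sparse
enough that exact global pair counting stays interactive). Gene and
drug names are synthetic tokens plus a few real exemplars (EGFR /
cetuximab target rule, ERCC1 / oxaliplatin resistance rule) to mirror
the workflow's published example rules.

Planting is closed under the knowledge bases by construction: planted
target genes always receive a rule; a planted response drug's ranking
places the sample's planted up-genes at the bottom and down-genes at
the top (±4 z on 25+25 reserved genes); a planted sensitivity drug
shifts its signature genes by +3·sign; a planted network drug gets a
bidirectional edge funnel from 12 reserved +3 z genes through one of
its rule targets. Reserved planting genes are excluded from rule/
signature gene pools so recovery is attributable. A fixed seed makes
every artifact bit-identical.

What the generator does not emulate — and hence what green tests do
not show about real data: correlated co-expression structure, breed or
batch covariates, annotation errors, probe-level cross-hybridization,
and real drug–gene biology. Passing planted-truth recovery
demonstrates that the algorithms detect the effects they are defined
to detect at the planted effect sizes, not that those effects exist in
real tumors.

## Problem sizes and determinism

The test suite runs one default-size world plus small worlds
(600–1,000 probes, scaled-down knowledge bases) for pipeline-shaped
tests; calibration uses 500 null profiles with the permutation count
reduced to 2,000; `scripts/acceptance.py` uses 200 null profiles and
the same 2,000 permutations, finishing in well under a minute. All
randomness flows from explicit seeds (numpy `default_rng`;
hypothesis-driven property tests are derandomized by pytest defaults),
and the acceptance script derives every sub-seed from its `--seed`
argument.
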