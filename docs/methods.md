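# Methods

`plauscomp` models human plausibility judgements for two-noun compounds
(*school bus*, *pants bike*) from distributional semantics.  This note
documents the model at each stage, the parameters that matter, the
numerical choices, what the synthetic test harness does and does not
emulate, and the known limitations.

## 1. Semantic space

Word meanings are vectors of windowed co-occurrence statistics.  The
corpus is lemmatized and sentence-segmented; a flat ±2-token window is
slid over each sentence (never across sentence boundaries) and every
(row-target, context-lemma) event increments one cell of a raw count
matrix.  Row targets are the most frequent lemmata plus designated
training bigrams ("moon walk"), treated like a single word: a bigram's
window extends two tokens beyond either end, and its own member tokens are
not its contexts (the member tokens still count as ordinary unigram
targets — both representations are maintained).

Counts are weighted with positive pointwise mutual information,

    PPMI(a, b) = max(0, log p(a,b) − log p(a) p(b)),

with all probabilities estimated from the same matrix (cell / total,
row-sum / total, column-sum / total) and natural logarithms (the log base
is a free choice; it only rescales a linear covariate downstream).  Zero
cells stay zero, so the weighting preserves sparsity.

The weighted matrix is reduced by non-negative matrix factorization
(`sklearn.decomposition.NMF`, seeded random initialization, iteration cap
400, tolerance 1e-4): the row-factor matrix *W* of the rank-*d*
factorization *W·H* is the semantic space.  *d* = 300 by default, matching
the standard setting for corpora of realistic size; the synthetic preset
uses *d* = 50 against its 500-lemma vocabulary.  Method, rank, seed and
achieved reconstruction error are recorded in the space's provenance.
All similarity is cosine; for the non-negative vectors produced by NMF it
lies in [0, 1].

Vocabulary truncation breaks frequency ties alphabetically so spaces are
reproducible.  Content-word filtering by part-of-speech tag is accepted as
an optional upstream step (the `lemma_pos` corpus dialect strips tags);
synthetic corpora carry no tags, a deliberate fidelity deviation.

## 2. Composition

The core compositional model treats the modifier as a *lexical function*:
a per-modifier matrix **M** of shape d × (d+1) (linear transform plus
intercept) mapping a head vector **h** to a compound vector
**c** = **M**·[**h**; 1].  **M** is estimated by ridge regression against
*observed* phrase vectors — the space rows of attested "modifier head"
bigrams:

    M = argmin Σᵢ ‖pᵢ − M[hᵢ; 1]‖² + λ‖M‖²_F.

Training pairs are adjacent corpus bigrams whose first token is an item
modifier, kept when they occur ≥ 20 times; modifiers with fewer than 50
distinct surviving pairs are dropped entirely (their items are excluded
from analysis), and pairs that are themselves rating items are withheld.
Pairs enter as types (one equation per distinct pair); a
frequency-weighting switch exists but is off by default.

λ is selected per modifier by generalized cross-validation over the log
grid 1e-6 … 1e2 (17 points), computed from one SVD of the design.  The
original work does not state its regularization; GCV is our substitute,
needed because fits with fewer pairs than d + 1 are otherwise ill-posed.
The selected λ, pair count and residual norm are stored as diagnostics.

A shared *full additive* model **c** = **A m** + **B h** (two d × d
matrices, no intercept, same ridge machinery on the stacked [m; h]
design) and the parameterless additive (**m** + **h**) and multiplicative
(**m** ⊙ **h**) baselines complete the menu.  Composed vectors from
trained models may contain negative entries; they are retained, and only
the entropy measure clips them (with a warning).

## 3. Plausibility measures and covariates

Per item (modifier, head) with composed vector **c**:

- head proximity = cos(**c**, **h**); modifier proximity = cos(**c**, **m**);
  constituent similarity = cos(**m**, **h**);
- neighbourhood density = mean cosine between **c** and its k = 20 nearest
  single-lemma rows (bigram rows never eligible; ties broken by row
  order; constituents are not excluded from the neighbourhood — a config
  switch exists);
- entropy = log(n) − (1/n) Σ pᵢ log pᵢ after clipping at zero and
  normalizing to the simplex, with 0·log 0 := 0.  The 1/n factor is
  nonstandard but implemented as printed in the source formulation; it is
  monotone in the standard entropy, so the uniform-vs-peaked contrast it
  is meant to capture is unaffected, and the maximum over the simplex is
  still attained at the uniform vector (property-tested).

Covariates: letter lengths of both lemmata; Laplace-transformed log
frequencies log(count + 1) of modifier, head, and the pair in both orders;
pointwise mutual information between the constituents (add-one counts for
the pair and unigrams against raw totals, so unattested pairs are
defined); and positional family sizes (distinct bigram types with the word
as first / second element).  The frequency source defaults to the training
corpus itself; any external unigram/bigram table can be substituted.  Raw
log(count + 1) is used rather than a per-million normalization — flagged
as an interpretation choice.

Items whose modifier has no trained lexical function, or with an undefined
measure, stay in the table flagged `excluded` with a reason.

## 4. The additive-model analysis

The response is the mean plausibility rating (0–4 scale).  The model is a
Gaussian penalized least-squares additive model

    y = Xβ + ε,   β̂ = argmin ‖y − Xβ‖² + Σⱼ λⱼ β'Sⱼβ,

whose design stacks: an intercept; linear covariate columns; cubic
B-spline bases for one-variable smooths (10 basis functions, interior
knots at data quantiles with a uniform fallback on ties, second-order
difference penalty, sum-to-zero constraint, plus a separate shrinkage
penalty on the penalty null space so a smooth can be penalized out
entirely); tensor-product bases for two-variable smooths (5 basis
functions per margin, one difference penalty per margin plus null-space
shrinkage); and indicator columns with identity penalty for random
intercepts (modifier and head nouns).

Smoothing parameters minimize GCV with the effective-df cost inflated by
γ = 1.4 — plain GCV undersmooths, which we measured to make downstream
model comparisons markedly anti-conservative.  The optimizer is
deterministic coordinate descent over a 9-point log-λ grid per penalty
(up to 3 sweeps).  Models containing a random-intercept factor with ≥ 40
levels are solved by Schur complement against that factor's diagonal
normal-equation block — exact, and roughly an order of magnitude faster
at several hundred levels (verified bit-identical to the dense path).

Inference uses the Bayesian posterior covariance σ²(X'X + S)⁻¹:
t-tests for linear terms (residual df = n − total edf) and rank-truncated
chi-square Wald statistics for smooth blocks (rank = rounded block edf).
Nested fits are compared by the Gaussian profile-likelihood ratio; the
reference distribution is chi-square with the *parametric*
(coefficient-count) df difference, not the effective-df difference.
This is a deliberate calibration choice: because the penalized fit of the
larger model can only lie below its unpenalized fit, the parametric-df
chi-square is a valid conservative reference even after the smoothing
parameters have been data-selected, whereas the Δedf reference rejected a
null smooth ~15–20% of the time at α = .05 in our simulations (GCV
undersmoothing plus selection).  Measured behaviour of the adopted test:
null rate 0.015, power 1.0 against a moderate planted smooth at n = 300.
AIC = −2·loglik + 2(edf + 1).

### Baseline construction

Candidate covariates are first screened for collinearity (walk the list in
order, drop any candidate with |r| > .6 to an already-retained one — the
threshold reproduces the family-size-vs-frequency exclusion logic of the
emulated analysis, which dropped at r = .68/.64); constant columns are
dropped up front.  The baseline starts from all remaining candidates as
linear terms plus both random-intercept factors, then iteratively drops
the least significant term with Wald p ≥ .05 and refits until all are
significant (iterative rather than single-pass; the trace makes the
difference auditable).  The result is verified by LRT — re-adding any
dropped term should not help, removing any kept term should hurt — with
outcomes and violations recorded in the trace.  Random intercepts are
never dropped.

### Stepwise measure selection

From the baseline, each step offers: a smooth main s(m) for every measure
not yet in the model; an interaction-specific tensor component ti(mᵢ, mⱼ)
for every pair of included measures; and ti(mᵢ, log pair frequency) for
every included measure.  Candidates are accepted when the LRT against the
current model has p < .05 *and* the AIC improves; among acceptable
candidates the lowest AIC wins; the procedure stops when none qualifies.
All candidates are re-offered at every step (order-free), and the full
trace (statistics, p-values, AICs, the accepted term) is returned.

Two design choices deserve explanation:

- *Interactions enter as ti components next to the retained mains*, not as
  full te surfaces replacing them.  A te term whose 5-basis margins
  replace 10-basis marginal smooths is not a superset model — we observed
  it fitting *worse* than the mains it replaced, clipping the LRT to zero
  and missing genuinely planted interactions.  With mains + ti the
  comparison is exactly nested, and the triple s + s + ti is the standard
  decomposition of the full tensor surface, so the final model still
  carries one tensor interaction per variable pair.
- *Linear mains are not offered as separate candidates* (a switch exists).
  The shrinkage-spline basis contains the linear trend, so a linear
  candidate adds no expressiveness, only a second null test per measure
  per step — which measurably inflated spurious inclusions.

### Model criticism

Three post-fit checks on the final model: (1) remove rows whose residual
exceeds 2.5 residual standard deviations, refit the same specification,
and record whether every term stays significant plus both
deviance-explained values; (2) for each tensor term, refit with the term
replaced by a plain product interaction (restoring linear mains when the
replaced term was a full te) and record the LRT for the tensor model's
superiority; (3) remove rows with negative modifier or head proximity and
refit.  Any refit that would use fewer than 50 rows aborts with a
diagnostic.

## 5. Synthetic data

The corpus generator is a topic-mixture model: V = 500 lemmata (plus 6
modifier lemmata), T = 8 topics with Dirichlet word distributions, 30,000
sentences (length 4 + Poisson(6)); each ordinary sentence samples one
topic and draws words i.i.d. from it, so windowed co-occurrence reflects
topic proximity.  With probability .15 a sentence instead embeds a
"modifier head" bigram: a modifier is drawn by weight (two dominant
modifiers at .46 each — sized so that exactly they accumulate enough
distinct, frequent pairs to survive the 20/50 training filters), a head is
drawn from that modifier's pool, and *all* other words in the sentence are
drawn from the distribution obtained by pushing the head's topic mixture
through the modifier's planted column-stochastic T × T transform (plus a
small intercept).  Observed phrase vectors therefore approximate a planted
linear map of the head representation.  A ledger records every unigram and
adjacent-bigram count at emission time (property-tested equal to a
recount), the transforms, and the designated item pairs: per dominant
modifier, 18 attested pairs (still emitted), their 18 reversals (never
emitted), and 400 novel pairs with heads outside the emission pool —
roughly 870 items in total, sized toward the scale of the rating study the
harness emulates (2,160 rated pairs, 1,699 analysable).

The ratings generator places rating = clamp(intercept + f(measures) +
b_modifier + b_head + ε, 0, 4) over any measure table, with factor
intercepts drawn once per level (SD 0.2), ε Gaussian (SD 0.35), and f a
named surface preset.  The default surface is a saturating ridge in head
proximity multiplied by a Gaussian peak in modifier proximity — genuinely
non-additive and non-bilinear.  Surfaces are defined on *empirical
quantile* scales of the measures: spaces of different sizes put the raw
measures on very different ranges, and a surface peaked at a fixed raw
value can fall entirely outside the observed range, planting no
recoverable signal.  Quantile scales guarantee the effect lives where the
data are, whatever the space.

What the harness does *not* emulate: real lexical statistics (only a mild
rank-frequency skew emerges from the Dirichlet draws), part-of-speech
structure, polysemy, and any dependence of ratings on covariates other
than through the planted surface.  Passing tests therefore demonstrate
that the machinery recovers known structure of this generative family —
not that English compound ratings follow it.

## 6. Default parameters

| parameter | default | role |
| --- | --- | --- |
| half_window | 2 | co-occurrence window (± tokens, within sentence) |
| n_content | 20,000 | frequency-ranked rows/columns of the space |
| dims | 300 | NMF rank (50 in the synthetic preset) |
| min_pair_freq | 20 | corpus occurrences for a training pair |
| min_pairs_per_modifier | 50 | distinct pairs to keep a modifier |
| ridge λ | GCV over 1e-6…1e2 | lexical-function regularization |
| k | 20 | density neighbourhood size (untuned) |
| smooth basis | 10 (5/margin for tensors) | spline dimensions |
| α | .05 | Wald and LRT significance level |
| outlier threshold | 2.5 SD | criticism refit |
| collinearity screen | r > .6 | baseline covariate exclusion |

## 7. Known limitations

- The LRT for penalized fits uses a conservative parametric-df reference;
  borderline interaction effects need more data to enter than they would
  under an exact (unknown) null distribution.
- Wald p-values for smooth blocks condition on the selected smoothing
  parameters, a standard approximation.
- The stepwise procedure tests several candidates per step at α = .05
  without multiplicity correction (by design, mirroring the emulated
  procedure); the measured whole-procedure spurious-inclusion rate on null
  data is bounded in the test suite but is not zero.
- GCV smoothing selection is deterministic but grid-based (9 points per
  decade-spanning axis, 3 sweeps); λ is resolved to about a factor of 20,
  which is immaterial for fits but means recorded λ values are coarse.
- Observed phrase vectors require the space to be built with the training
  bigrams as rows; spaces built without them cannot train lexical
  functions (a consistency error, not silent degradation).
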