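# Methods

## Model

The interaction matrix Y ∈ {0,1}^{m×n} records experimentally validated
lncRNA–protein pairs.  NRLMF models p_ij = σ(uᵢ·vⱼ) with latent factors
U ∈ ℝ^{m×r}, V ∈ ℝ^{n×r} and minimizes the weighted logistic loss plus ridge
and neighborhood-Laplacian penalties (see README for the objective).  The
weighting (1 + c·y − y) realizes the "each positive counts as c samples" idea
by weighting rather than replicating, which is the only form consistent with
the gradient expressions

    ∂L/∂U = P V + (c−1)(Y⊙P)V − c Y V + (λ_l I + α L_l)U

and its transpose-symmetric counterpart for V.

Assumptions worth stating: (1) unobserved pairs are treated as weakly negative
(weight 1), which is biased when coverage is very incomplete; (2) neighborhood
regularization presumes sequence-similar entities have similar interaction
profiles — the Laplacian term is exactly Σ a_iμ‖uᵢ−u_μ‖²; (3) one global rank
r captures the interaction structure.

## Similarity kernels

S(a,b) = sw(a,b)/max(sw(a,a), sw(b,b)), with sw the exact affine-gap
Smith–Waterman local alignment score (computed by Biopython's
`PairwiseAligner`, checked exactly against an independent Gotoh dynamic
program in the tests).  A gap of length L costs gap_open + (L−1)·gap_extend.
Because a local alignment cannot outscore the better self-alignment, S ≤ 1 by
construction, and S is symmetric with unit diagonal.  Normalizing by the
*maximum* of the two self-scores (rather than, say, the geometric mean) keeps
a short sequence from looking spuriously similar to a long one.

Scoring defaults, all overridable: nucleotides match +2 / mismatch −1,
gap_open 5, gap_extend 2; proteins BLOSUM62, gap_open 10, gap_extend 1.
Sequences are uppercased, RNA `U` is mapped to `T`, ambiguity codes are
accepted but always score as a mismatch (nucleotides) or as `X` (protein
residues outside the BLOSUM62 alphabet).  A sequence whose self-score is not
positive (e.g. all-ambiguous) makes the normalization ill-posed and raises an
explicit degenerate-input error naming the record.

## Parameters

| name | meaning | default | note |
|---|---|---|---|
| r | latent dimension | 50 | must be < min(m,n); use ~ the expected interaction rank |
| c | positive-pair importance weight | 5 | c ≥ 1; c = 1 degenerates to plain logistic MF |
| λ_l, λ_p | ridge (Gaussian-prior) strengths | 0.5 | inverse prior variances |
| α, β | neighborhood-regularization weights | 0.1 | 0 disables the Laplacian terms |
| K1 | training neighborhood size | 5 | the method's stated value |
| K2 | smoothing neighborhood size | 5 | the method's stated value |
| learning_rate | base step | 0.1 | scaled per-element by AdaGrad |
| max_iters | alternating iterations | 100 | see convergence note below |

Only K1 = K2 = 5 come from the method as published; the other defaults are
conventional for the logistic-MF family and were fixed before any evaluation.

## Optimization

Alternating updates (U with V fixed, then V with U fixed) along the negative
analytic gradient.  Per-element step scaling divides by the root of the
accumulated squared gradient (AdaGrad), the scheme used throughout the
logistic-MF lineage; plain fixed-step descent is available via
`optimizer="fixed"`.  Each half-step is *monitored*: the proposed step is
halved (up to 30 times) until the objective does not increase, and left
unapplied if that fails, so the training history is non-increasing by
construction and `fit` is deterministic given the seed.  Factors are
initialized from Normal(0, 1/√r) entries, keeping initial logit variance O(1).

Overflow safety: ln(1+eˣ) is computed as `logaddexp(0, x)` and the logistic
via `scipy.special.expit`; predicted probabilities are clipped into
(1e−12, 1−1e−12) so scores are strictly inside (0,1) even for |logits| ~ 10⁴.

Convergence note: on the 100×30 planted instances the monitored AdaGrad
schedule at learning rate 0.1 is still descending at 100 iterations; the
parameter-recovery experiments therefore fit with max_iters = 300, which is
within ~0.09 AUC of the planted-probability oracle ceiling on those instances.

## Cold-start smoothing

Entities with no positive in the training matrix (the cold-start set) get a
smoothed latent vector: the similarity-weighted mean of the latent vectors of
their K2 most similar entities *among those with positives*.  Neighbor
selection mirrors training: self excluded, ties broken by ascending entity
index, K truncated to the candidates available.  If all similarity weights in
the selected neighborhood are zero the smoothed vector is the zero vector
(scores 0.5).  Smoothing with an entirely cold entity set is an error — there
is nothing to smooth from.

## Evaluation protocol

LOOCV unit: each known positive pair.  For fold k the entry is zeroed, the
model retrained with a fold-specific seed (derived from the base seed through
a `SeedSequence([seed, counter])` counter scheme, counter 0 reserved for the
background model), and the held-out pair scored with the smoothed predictor.
Unknown pairs are scored once by the all-positives model and form the negative
background.  AUC uses the rank statistic (ties ½); AUPR the step-wise
non-interpolated precision-recall area.  ACC/SEN/PRE/F1 are reported at the
F1-maximizing threshold by default (prediction rule: score ≥ threshold), with
a `--threshold` override; a zero-denominator ratio is reported as 0 with a
warning flag rather than NaN.  `--fast-loocv` warm-starts each fold from the
full model and runs 10 iterations — an approximation for large fold counts;
the default is full retraining.

The degree filter (`min_degree=2` by default) iterates to a fixed point,
because removing a degree-1 lncRNA can drop a protein to degree 1 and vice
versa; single-pass removal can leave entities that LOOCV cannot evaluate.

## Synthetic data

`generate_planted_instance` draws rank-r factors whose first r−1 columns have
Normal(0, scale/√r) entries (scale 3 by default, i.e. strong low-rank signal)
and whose last column is the constant pair (1, b).  Because σ(s·X) has mean ½
for any symmetric zero-mean X, sparsity cannot be reached by rescaling
zero-mean factors; the intercept b is instead solved by bisection so the
expected density of Y = Bernoulli(σ(U_true V_trueᵀ)) matches the target
(default 0.15, matching the sparse regime of curated LPI collections, where a
lncRNA typically interacts with a handful of proteins).  Similarity matrices
come from row-cosine proximity of the planted factors mapped to [0,1] (plus
optional noise, re-symmetrized, clipped, unit diagonal), so the
neighborhood-regularization assumption holds by construction; sequence
fixtures for the alignment kernel are generated separately as mutant families
of a random ancestor.

What this does and does not show: passing the planted-recovery tests shows
the estimator recovers low-rank logistic structure when the model is
well-specified and similarities reflect latent proximity.  Real
interaction data violate both in unknown degree (hub proteins, study bias,
similarity only partially predictive of binding), so measured AUCs on
synthetic instances do not transfer to any particular real dataset.

## Numerical and design choices

- Diagonal entries of read similarity matrices must be within 1e−6 of 1 and
  asymmetry within 1e−6 (repaired by averaging, with a warning); anything
  worse is rejected.
- Similarities are written with 6 decimals; round-trips are exact at that
  precision.  The model bundle stores floats via `repr`, which round-trips
  bit-exactly through JSON text.
- c ≥ 1 is enforced (c = 1 allowed as the plain-LMF degenerate case); r <
  min(m,n), K1/K2 bounded by the entity counts, all checked at fit time.
- No timestamps appear in any output, so identical configs produce
  byte-identical artifacts.

## Limitations

- Full-gradient, dense training: fine for the hundreds-by-tens scale this
  problem lives at, not for matrices with 10⁵ entities.
- Full LOOCV retrains once per positive; thousands of positives make
  `--fast-loocv` the practical choice, at some fidelity cost.
- No expression-profile or structure-based similarity; sequence only.
- Scores are calibrated only in rank: the logistic outputs should not be read
  as frequentist interaction probabilities.
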