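# Methods

## Model

`pathfa` models a cells × genes expression matrix as a linear combination
of latent factors,

```
y_ng = Σ_k x_nk w_gk + ψ_ng ,            Y = X Wᵀ + ψ,
```

with K = C + A + H columns of X: C fixed covariate columns (known per-cell
quantities; under the Hurdle and Poisson noise models a per-gene intercept
is automatically added as an all-ones covariate, while the Gaussian model
mean-centers each gene instead and restores the offsets downstream), A
annotated factors — one per gene set — and H unannotated factors. Factor
states carry standard-normal priors.

**Weights.** Each weight has a coupled spike-and-slab prior:
w_gk ~ N(0, 1/α_k) when the regulatory indicator z_gk = 1, and a point
mass at zero otherwise. The indicator priors encode the factor taxonomy:
annotated factors use the uninformative Bernoulli(0.5); sparse unannotated
factors Bernoulli(0.01) (few active links — compact biological effects);
dense unannotated factors Bernoulli(0.99) (broad confounder-like effects,
effectively regularized only by ARD). Covariate weights have a fixed broad
Gaussian prior (precision 10⁻⁶) and z ≡ 1.

**Annotation evidence.** Database membership I_gk is treated as a noisy
observation of z_gk: P(I = 1 | z = 1) = 1 − FPR and
P(I = 1 | z = 0) = FNR, with defaults FNR = 0.001, FPR = 0.01. In the
indicator update this contributes fixed prior log-odds
±log((1 − FPR)/FNR) ≈ ±6.9 per gene — strong enough to pin the support of
an annotated factor to its pathway when the data are ambiguous, weak
enough that a gene with clear evidence on the wrong side is reassigned.
That reassignability is load-bearing: gene-set refinement *is* the event
of the data overruling the annotation, and the spike-versus-slab evidence
a no-signal gene can muster is only the Occam factor
½·log(α/(α + τ·Σ E[x²])) (a few nats, growing logarithmically with cell
count), so an annotation term that scaled linearly with N would make the
removal of falsely annotated genes impossible at any dataset size. The
`annotation_loglik` helper exposes the per-cell-replicated evidence
n·log Bernoulli(I | z) for calibration analysis; its log-odds are exactly
proportional to n by construction.

**ARD.** Each factor precision has a broad Gamma(a, b) prior with
a = b = 10⁻³ (the prior family is standard; the values make the prior
mean 1 with large variance). The posterior mean of 1/α_k is the factor's
relevance: the expected variance explained per regulated gene. Per-gene
residual precisions τ_g carry the same broad Gamma prior, giving
heteroscedastic noise that can absorb over-dispersed genes.

**Noise models.**
- *Gaussian*: log-scale values with per-gene variance σ_g² = 1/τ_g.
- *Hurdle*: zeros are not measurements but dropout candidates — a logistic
  Bernoulli process 1/(1+exp(f_ng)) on the latent value governs zeros,
  while nonzero entries follow N(log(y+1) | f_ng, σ_g²). On data without
  zeros the zero process is empty and the model *is* the Gaussian model on
  log(y+1); the implementation makes this reduction exact by construction
  (same code path, centering instead of the intercept factor).
- *Poisson*: raw counts with rate λ(f) = log(1 + e^f).

## Inference

Deterministic coordinate-ascent variational Bayes with the factorization
q(X) · Π_gk q(w_gk, z_gk) · Π_k q(α_k) · Π_g q(τ_g). The (w, z) blocks are
deliberately coupled: q(z=1) = γ_gk and the slab moments are the exact
joint optimum, with the indicator log-odds combining the data fit of slab
versus spike, the kind-specific prior, and the annotation evidence.

Each sweep runs: pseudo-data construction, weight updates, factor-state
updates, ARD, noise, and a factor rescaling step, at O(N·G·K) cost
against a running residual matrix.

**Update order.** Within a sweep, factors are visited in the order
covariates → dense → annotated → sparse. Dense factors go before annotated
ones so broad unwanted variance is absorbed where it belongs: when a
pathway's gene set overlaps a confounder's target genes, an
annotated-first schedule lets that factor claim the confounder and then
extend its indicator support across the confounder's genes (the data term
dwarfs the ±6.9 annotation odds for strong-signal genes), destroying its
pathway identity. Ordering is a schedule choice only; any fixed order is
valid coordinate ascent. A corollary worth knowing: if no confounder
exists and one biological program dominates total variance, a dense factor
will absorb it — fit with `n_dense=0` when no unwanted variation is
expected, and read dominant unannotated factors as the data's strongest
unexplained structure (they are reported, ranked and exportable like any
other factor).

**Non-conjugate terms.** The Hurdle zero process uses the Jaakkola–Jordan
quadratic bound for the logistic term, re-tightened at ξ² = E[f²] at the
start of every sweep; the Poisson likelihood uses a second-order expansion
at E[f] with curvature clipped to [10⁻⁴, ∞). Both turn each observation
into a Gaussian pseudo-observation (entry-specific target and precision),
so all updates reuse the conjugate path.

**Factor rescaling.** The likelihood constrains only X_k W_kᵀ, leaving a
scale ridge (X_k → sX_k, W_k → W_k/s, α_k → s²α_k) along which plain
coordinate ascent crawls. At the end of each sweep the scale of each free
factor is set to its closed-form ELBO optimum
s² = (N/2 + a) / (Σ_n E[x²]/2 + shape_k·b/rate_k), which anchors factor
states at unit scale. This is an exact coordinate-ascent move — the data
term is invariant and the spike-and-slab KL is invariant once α's rate is
rescaled with the weights — so the ELBO guarantee is untouched; it roughly
halves iteration counts and makes 1/α_k comparable across model sizes
(without it, relevances depend on where along the ridge the fit stops).

**ELBO and convergence.** The bound is evaluated every sweep (exact for
Gaussian, surrogate for Hurdle/Poisson). Under the Gaussian model the
trace is non-decreasing to machine precision; a sustained decrease raises.
Convergence requires a relative change below `tol` (default 10⁻⁵) on two
consecutive checks, after at least `min_iter` = 10 sweeps; default
`max_iter` = 1000. Numerical floors: γ clipped to [10⁻¹⁰, 1−10⁻¹⁰]
(keeping each update the constrained optimum of a concave problem, hence
still monotone), Gamma rates floored at 10⁻¹².

**Initialization** (all seeded; fitting itself is deterministic).
Annotated factor states start at the leading principal component of their
(centered) annotated-gene submatrix, unit variance, sign fixed so the
loading vector sums positive. Dense factors start at the successive
leading principal components of the whole matrix: broad variance then
lands on dense factors from sweep one instead of leaking into collinear
annotated factors — with random dense starts, a negative-control set
overlapping a confounder block reached relevance ~0.3 while the dense
factor died; with PC starts the same settings give negatives ~3·10⁻⁴.
Sparse factors start at seeded standard normals. Indicators start at the
annotation-implied posterior, α at its prior mean, τ at inverse empirical
gene variance.

## Downstream analyses

- **Relevance**: posterior mean of 1/α_k via the inverse-Gamma mean
  rate/(shape−1); when shape ≤ 1 (pathological, never after a normal fit)
  rate/shape with a warning. Covariate factors have no learned α; their
  reported relevance is the mean expected squared weight, the same
  quantity 1/α estimates for regulated genes, and they are flagged by
  kind. Ties break by assembly order.
- **Refinement** at the posterior threshold 0.5, strict inequalities:
  γ exactly 0.5 changes nothing.
- **Residual expression**: Y − Σ_{k∈remove} E[x_k]E[w_k]ᵀ on the input
  scale (gene means untouched). Under the Hurdle model zeros are first
  imputed by the posterior latent mean E[f], nonzeros mapped to log(y+1).
- **Churn diagnostic**: on a model without sparse factors, if any
  annotated factor's gains-plus-losses at the 0.5 threshold reach 100% of
  its set size (inclusive), the factor has lost its annotation identity
  and a refit with five sparse unannotated factors is recommended.

## Synthetic data

The generator mirrors a linear-additive simulation study: factor states
and nonzero weights i.i.d. standard normal; active pathway factors load
exactly on their annotated genes; confounders on a uniform-random 400–3000
gene block; residual noise Gaussian with sd 0.1; 6000 genes and 20–500
cells in the reference regime, gene-set sizes drawn uniformly from a
REACTOME-like 20–933 span (narrower ranges configurable). Annotations are
built sequentially, largest set first, each new set drawing
round(overlap·size) genes from the union of earlier sets (overlap 0–0.7)
and the rest from unused genes; 15 negative (inactive) sets accompany the
actives. Corruption deletes a fraction of each active set
(round(fnr_sim·size), up to 50%), inserts round(fpr_sim·size) genes drawn
from outside every active set (up to 10%), and swaps exclusive members
between consecutive pairs of active sets (round(swap_frac·min size) pairs,
up to 25%); every edit is recorded so evaluation can score false negatives
and false positives separately. Two dropout mechanisms: a deterministic
detection threshold, and exponential decay p_drop = exp(−λ·f²) in the
latent expression. Replicates derive child seeds from
SeedSequence((master, index)).

What the generator does *not* emulate: count-level realism
(negative-binomial library-size structure, UMI duplication), gene–gene
correlation beyond the factor structure, and annotation databases' true
size distribution beyond the uniform draw. Passing tests therefore show
the method recovers the generative structure it assumes, at the stated
noise and corruption levels — not performance on any particular real
protocol.

## Validation protocols and problem sizes

All validation inputs are synthetic or analytic and sized for a single
CPU:

- *Spike-and-slab oracle*: 20 random 1-gene × 1-factor problems; the
  coupled update, driven to its fixed point with factor states at point
  mass and α, τ held fixed, matches exact enumeration over z with
  conjugate integration over w to 10⁻⁸.
- *ELBO ascent*: 20 random Gaussian problems (N 15–50, G 30–120).
- *Hurdle reduction*: zero-free 60 × 300 dataset; Hurdle and Gaussian
  fits agree exactly (identical path).
- *Driver recovery*: N=100, G=2000, 5 active + 15 negative sets (sizes
  20–100, feasible for a 2000-gene universe), 2 confounders on 400–1000
  genes, noise sd 0.1, 10 replicates; median relevance-ranking AUC.
- *Annotation repair*: the weak-data, high-overlap regime — 20 cells
  (the low end of the reference cell range), G=1000, overlap 0.6,
  corruption rising (FNR, FPR, swaps) = (10%, 5%, 0) → (30%, 7.5%, 10%) →
  (50%, 10%, 25%), 10 replicates per level, fitted as the standard
  annotated-only model since no confounders are simulated (a dense factor
  on confounder-free data is collinear with the strongest pathway factor
  and absorbs deleted-gene signal). At larger N or without overlap both
  repair AUCs saturate near 1 at every corruption level; the decline with
  corruption only has room to appear here, and the added-gene decline is
  the robust one — removal difficulty is largely corruption-independent
  because inserted genes carry no signal by construction, so only the
  swap component degrades it.
- *Confounder handling and dense-count robustness*: single fits of the
  driver-recovery setting; dense factors may carry a rotation of the
  confounder pair, so confounder capture is judged by the R² of each
  confounder on the dense-factor span.
- *Scaling*: best-of-three per-sweep timings at (N, G) = (400, 1200)
  versus (800, 1200) and (400, 2400).

`scripts/acceptance.py` reruns these protocols from scratch under a
caller-provided master seed and reports every computed quantity.

## Known limitations

Factorized VB underestimates posterior variances and can settle in local
optima when factors are strongly collinear; the update order and PC
initialization above are mitigations, not guarantees. Relevance compares
factors within one fit; it is not calibrated across datasets. The Poisson
path uses an unbounded quadratic surrogate, so its ELBO trace is not
guaranteed monotone (the Gaussian and Hurdle traces are). Annotation
evidence assumes database errors are independent across genes. The Hurdle
model fixes the zero-process link at logistic(f) with no per-gene offset
beyond the intercept factor.
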