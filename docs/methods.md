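# Methods

## The two-part mutation model

A parent–child pair (PCP) is one edge of a clonal-family tree: two aligned,
equal-length nucleotide sequences with an optional branch length t ≥ 0.
Mutations at different sites are assumed independent given the parent
sequence, and all mutations on an edge are treated as simultaneous (contexts
are always read off the parent), so likelihoods do not depend on the order
of events along the branch.

* **Location part.** Site i mutates with probability 1 − exp(−t·λᵢ), where
  λᵢ > 0 is the model's per-site rate. The negative log-likelihood over
  unmasked sites is
  `−Σ [ yᵢ·log(1 − exp(−t·λᵢ)) − (1 − yᵢ)·t·λᵢ ]`,
  computed with `expm1` and a probability floor of 1e-12 inside logarithms
  (an indicated mutation with t·λ = 0 yields a large finite penalty and a
  warning rather than an infinity).
* **Substitution part.** Given a mutation, the new base follows the
  conditional substitution probability (CSP) row pᵢ over A,C,G,T, computed
  by softmax over 4 logits with the parent base's logit forced to −∞ (so its
  probability is exactly 0). The loss is the categorical cross-entropy of
  the observed child base at mutated, unmasked sites.
* **Combined loss.** `location NLL + w × CSP cross-entropy`, both as sums
  over the batch, with w = 0.01 to approximately balance the two terms'
  magnitudes. With w as a knob, w = 0 recovers pure location training.

The offset t enters only as a multiplier of λ, so the likelihood is
invariant under λ → cλ, t → t/c; the default offset (the pair's mutation
count divided by its unmasked-site count) pins the scale so that a well-fit
model has mean t·λ per site approximately equal to the observed mutation
frequency. The denominator is the count of unmasked sites rather than the
full length because masked sites carry no mutation information.

## Models

All models map a parent sequence to (λ₁..λ_L, p₁..p_L).

**Thrifty CNN.** Per-site 3-mer tokens (base-4 index of bases i−1,i,i+1 with
A=0,C=1,G=2,T=3; windows containing N or overhanging an end map to a single
wildcard token, 64) → trainable embedding (65 × embed_dim) → one
length-preserving 1-D convolution (kernel × embed_dim × filters, bias,
symmetric zero padding) → ReLU → dropout (training only) → per-site affine
heads. The rate head passes through an exponential link for positivity
(softplus available by config); the CSP head emits 4 logits with the
parent-base logit masked at prediction/loss time. Effective context is
kernel + 2 bases. Wirings: *joined* (shared embedding and convolution, two
heads), *hybrid* (shared embedding, separate convolutions and heads),
*independent* (two disjoint stacks trained jointly on the combined loss).
A single convolutional block only; depth is deliberately not a
hyperparameter. The nonlinearity is not dictated by the architecture's
motivation; ReLU is the default and is config-overridable.

Named presets (kernel, embed, filters, dropout): joined large (11, 7, 19,
0.3; 2,037 parameters), independent medium (9, 7, 16, 0.2), independent
large (11, 7, 19, 0.3), small (7, 6, 14, 0.1).

**k-mer table.** One trainable log rate and one 4-logit CSP row per k-mer
(4^k rows) plus a shared trainable wildcard row used by sites whose window
contains N or overhangs an end — ambiguous-flanked sites still receive
predictions but are typically masked from losses. Under this
parameterization a 5-mer table has 1,025 + 1,025×4 = 5,125 trainable
scalars; the classical accounting that stores one rate plus 3 substitution
probabilities per context gives 3,077. The joined thrifty preset undercuts
both while seeing 13 bases of context.

**Per-site wrapper.** Multiplies any base model's λᵢ by a trainable factor
exp(fᵢ) per absolute sequence position; CSP is unchanged. Training adds an
L2 penalty (default 1e-4 per position) pulling the log factors toward 0, so
positions with little or no coverage keep factor ≈ 1 instead of drifting to
extremes; as the penalty grows the wrapper collapses to the base model.

The networks are implemented directly in NumPy with analytic gradients
(verified against finite differences to ~1e-6 relative error); at these
sizes one CPU trains them in seconds, and the implementation has no
framework dependency.

## Training

Minibatch Adam (default learning rate 1e-3, batch 32 pairs, 100 epochs, no
early stopping by default; optional validation-loss early stopping behind a
flag). Pairs without a branch length get the normalized mutation count.
Optional joint branch-length optimization alternates one epoch of model
updates with one pass of per-pair 1-D likelihood maximization; it is off by
default. Training is bitwise reproducible given (seed, config, dataset
order); dropout and shuffling draw from a single seeded generator. Batch
construction is by pair; sequences in a batch are padded with N-coded sites
whose mask is false, so padding contributes nothing to losses or gradients.

**Branch-length fitting.** With rates fixed, the per-pair location
log-likelihood `Σ_mut log(1 − e^(−tλ)) − t·Σ_other λ` is maximized over
t ∈ (0, t_max] by bounded scalar minimization (tolerance 1e-6 in t;
t_max = 5 by default). Pairs with zero mutations get t = 0 exactly (the
analytic argmax); a t̂ at the upper bound — e.g. a pair whose every site
mutated — is logged.

## Evaluation

Metrics pool sites across all pairs of an evaluation set (per-pair
breakdowns are also emitted): AUROC (midrank tie handling — the
probability a random mutated site outscores a random unmutated one), AUPRC
(step-interpolated average precision, the conservative choice for
imbalanced data), R-precision (precision among the R top-scoring sites,
R = total observed mutations; ties at the cutoff break by stable input
order), and substitution accuracy (argmax CSP vs observed new base; argmax
ties break toward the first base in A,C,G,T order). The positive fraction ρ
is chance level for AUPRC and R-precision. AUROC/AUPRC are computed via
scikit-learn, whose conventions match the stated tie and interpolation
policies; the test suite checks both against independent brute-force
oracles at 1e-12.

**Binned fit and overlap.** Sites are binned by predicted mutation
probability into 30 log-spaced bins (count, spacing, and range are
configuration, recorded in output metadata); each bin's expected count is
the sum of its predicted probabilities and the observed count is the number
of mutations among its sites. The overlap statistic is
`Σ min(obs, exp) / ((Σ obs + Σ exp)/2)` — 1 exactly when the histograms
coincide. Sites with predicted probability 0 (pairs with t = 0) carry no
mass in either histogram and are excluded from binning. Held-out
log-likelihood reports the location and CSP terms separately plus their
sum, after branch-length optimization.

**Masking.** Sites where either sequence is N are always masked. Evaluation
can be restricted to a 0-based inclusive position window (the convention for
the bulk-repertoire coverage window [80, 319]; the origin is a config knob).
Synonymous-mutation analysis keeps only third codon positions whose parent
codon prefix is 4-fold degenerate under the standard nuclear code (prefixes
containing N are conservatively non-degenerate; incomplete terminal codons
are masked). Masks compose by intersection, so region restriction and
synonymous masking commute. Edges with ≥ 10 mutations can be dropped by the
standard long-branch filter (strictly-fewer-than semantics); removals are
recorded in dataset provenance.

## Synthetic data

The simulator generates the data regime of out-of-frame BCR repertoires:
equal-length parent–child pairs with rare, context-dependent mutations.
A ground truth is a k-mer rate table (log-rates i.i.d. Normal(0, 0.5²)),
boosted ×10 at contexts matching AID hotspot motifs (WRC anchored on its
focal C and GYW on its focal G, by default, applied when they fit the k-mer
window) and rescaled to mean rate 1, plus Dirichlet(1,1,1) CSP rows over
the three non-parent bases. Hotspot offsets are given as the motif's first
base relative to the focal site; a motif that does not fit inside the k-mer
window is an error. Parents are i.i.d. uniform over A,C,G,T; per-pair branch
lengths are LogNormal with median 0.01 and log-sd 1.0, chosen so a 300 nt
pair carries a median of ~3 mutations with the orders-of-magnitude spread
typical of phylogenetic branch lengths. Each site then mutates once,
independently, with probability 1 − exp(−t·λ), and mutated sites draw the
new base from the truth CSP — exactly the model family being fit, so
parameter recovery is well-posed. True branch lengths are recorded for
recovery experiments. All draws come from one seeded NumPy PCG64 generator,
named in the dataset provenance.

What the simulator does **not** emulate: real IgH base composition and
germline structure, position-dependent coverage, sequencing error,
insertions/deletions, within-branch context updating (a multi-round mode
exists behind a flag, off by default), and selection. Passing recovery and
calibration tests on this data therefore demonstrates correctness of the
estimators under the model's own assumptions, not predictive performance on
real repertoires.

## Problem sizes used in the test suite

The heavier checks run at sizes chosen to give each statistic real power on
one CPU in minutes: parameter recovery fits a 5-mer table to 2,000 pairs of
300 nt (100 epochs); the wide-context comparison trains a kernel-11 thrifty
model and a 5-mer table on 400 pairs (30 epochs) for each of 10 seeds, with
the hotspot placed at offsets +2..+4 from the focal site — outside any
5-mer window but inside the 13-mer receptive field; branch-length recovery
uses 40 pairs of 10,000 nt; calibration uses ~50,000 pooled sites. At the
recovery sizes a typical 5-mer context carries only ~10 observed mutations,
which bounds the attainable per-context log-rate accuracy (Fisher
information ≈ expected mutation count per context); correlations with the
truth are accordingly high but not perfect, and they sharpen with mutation
counts, as the mutation-rich-context checks show.

## Known limitations

* Rates for a context never observed mutating are driven by the optimizer
  toward the initialization (log-rate 0) rather than to 0: minibatch
  training for a fixed epoch budget leaves weakly-informed parameters
  partially shrunk, an implicit regularization that is beneficial for sparse
  tables but means the fitted table is not exactly the MLE.
* The wildcard token/row pools all ambiguous contexts; sites near sequence
  ends share one parameter set regardless of which side overhangs.
* Transformer variants and positional encodings are deliberately out of
  scope; the per-site wrapper is the only position-aware component.
* The evaluation window convention is 0-based inclusive; data using 1-based
  coordinates must be shifted by the caller.
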