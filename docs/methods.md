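# Methods

## The problem

A drug–target interaction (DTI) training table pairs small molecules
(SMILES strings) with protein targets (amino-acid sequences) under a
binary interaction label. In the widely used public benchmark releases,
individual targets tend to carry strongly imbalanced labels: a target
seen mostly with positives in training lets a model drive its loss down
by memorising the target, not by modelling the interaction. We call a
sequence's positive-label fraction its *prior tendency*; a model that
exploits it exhibits *target prior bias* and generalises poorly to new
pairs. Causally, the latent propensity structure of the training
sequences is a confounder that opens a backdoor path between the target
representation and the label.

## Bias diagnostics

For each unique sequence *i* on one axis (drugs or targets) with
occurrence count *n_i*, the tendency is `z_i = (positive count) / n_i`,
computed on exact ratios (one-decimal rounding appears only in
histogram displays). The dataset-wide score is

    Z = mean_i |z_i − 0.5| + 0.5  ∈ [0.5, 1.0],

the unweighted mean over unique sequences; an occurrence-weighted
variant (`weighted=True`) is available. A sum without normalisation
cannot stay in [0.5, 1.0], so the mean is the only reading consistent
with the stated range; we take the unweighted mean as the default
because the histograms it summarises are also per-unique-sequence.

Significance is assessed against a null in which labels are independent
of sequence identity. With the global positive proportion `g = ΣY/N`,
the statistic is the occurrence-weighted sum of squared deviations

    T = Σ_i n_i (z_i − g)²,

and the one-sided p-value comes from B label permutations (a shuffle
across all pairs, preserving the pair structure and the label multiset):
`p = (1 + #{T_b ≥ T_obs}) / (1 + B)`, so `p ≥ 1/(1+B)` always. B
defaults to 1000.

## Synthetic generator

No public generator exists for this structure, so the package ships
one. Each target receives a propensity θ_t that is extreme (ε or 1−ε,
fair coin; ε = 0.02) with probability `target_bias`, else drawn
U(0.35, 0.65); drugs analogously under `drug_bias`. Every entity also
carries a latent unit vector u (dimension 8); the *mechanism* label for
a pair is m(d,t) = 1 iff u_d·u_t > 0. A pair's label is Bernoulli with
success probability

    w·m(d,t) + (1 − w)·(θ_d + θ_t)/2,   w = mechanism_weight.

Defaults (200 drugs, 100 targets, 2000 distinct pairs, target_bias 0.9,
drug_bias 0.1, w = 0.5) emulate the published pattern: bimodal target
tendencies, centred drug tendencies, and a genuine interaction signal
a debiased model could in principle recover. Note one consequence of
mixing both axes' propensities: an extreme target (θ_t ≈ 1 − ε) paired
with centred drugs yields z_t near (0.5 + 1 − ε)/2 ≈ 0.75, so the
bimodal concentrations sit near 0.25 and 0.75 rather than at 0 and 1;
the qualitative audit contrast (target p-value at the permutation
floor, drug p-value non-significant) is unaffected. SMILES
are token-fragment concatenations and sequences are uniform random
20-letter strings of length 60–120 — deliberately desk-scale; real
sequences are longer and far from uniform, so passing tests show the
machinery is correct under the stated statistical structure, not that
any biological signal is captured.

Two caveats about what the generator does *not* emulate. The latent
vectors are attached to entity identities, not derivable from sequence
content, so the mechanism can only be learned by entity-level
memorisation plus bilinear generalisation — much harder at small scale
than in real data, where binding correlates with sequence features.
And with `target_bias = 0` the non-extreme propensities still spread
over U(0.35, 0.65): that setting removes the *extreme* bimodal prior
but is not an exchangeable-label null, and the permutation test
rightly detects the residual dispersion given enough data. Calibration
(type-I error) is therefore checked under an exact null obtained by
shuffling the generated labels once — precisely the test's own null
resampling scheme.

## Counter-prior constructions

From the seeded-shuffled positives a greedy pass selects S_p, a maximal
set of positive pairs in which every drug and every target appears
once. The *drug-biased* construction gives each S_p target exactly one
negative whose drug is drawn from the drugs outside S_p (cycled when
scarce, never duplicating an existing pair): the output is exactly 50%
positive, every target's tendency is exactly 0.5, and every drug's is 0
or 1. The *balanced* construction instead deranges the drug column of
S_p to form negatives (no fixed points, so no positive pair is
recreated), making every single drug and target carry one positive and
one negative label; Z is exactly 0.5 on both axes. The number of
negatives per construction and the derangement requirement are our
choices where the source procedure is underdetermined; both are the
minimal designs that guarantee the stated invariants.

## Randomization augmentations

Target features are augmented per epoch, not preprocessed once:
deletion removes a fixed fraction (default 70%) of non-special residue
rows — `round((1−ratio)·L)` kept, order preserved, [cls] always kept; a
per-residue Bernoulli mode is available behind a flag. Mutation then
replaces each surviving residue feature, independently with probability
0.2, by the dictionary vector of a uniformly drawn residue letter,
where the amino-acid dictionary holds the training-set mean feature per
letter. Drug token sequences get classic masked-language-model
corruption: `round(0.15·L)` non-special tokens selected, then 80%
[mask] / 10% keep / 10% random non-special token. Deterministic
per-sequence counts (rather than Bernoulli draws) implement the stated
fixed proportions exactly in expectation and reduce variance.

## Model

The drug encoder is a 3-layer transformer with rotary position
embeddings (base 10000, applied to queries and keys) over a
data-built atom-wise SMILES vocabulary. Target features come from a
pluggable provider with two implementations: an HDF5 store of
precomputed per-residue matrices (the interface a pretrained protein
language model's hidden states would be cached behind) and a
deterministic toy embedder (seeded per-letter vectors smoothed over a
±2 window) for desk-scale work.

The confounder dictionary C holds I K-Means centers of the pooled
training-target features, with cluster proportions as adjustment
weights P(c_i); it is fixed at build time, never recomputed per batch.
The confounder alignment module (CAM) splits the projected target
features into I query heads; head i attends to the projected center
c_i. Read literally, each head sees a singleton key, whose softmax
weight is identically 1, so head i's pre-residual output is the value
slice of c_i broadcast over positions; a variant where every head
attends over all I centers is available (`cam_full_dictionary`). Heads
are concatenated, added residually to the input features, and mapped
to model width.

The aggregator stacks three blocks of masked self-attention (with
rotary embeddings) over the drug track, cross-attention with query =
drug / key,value = target (H heads, H = I required), and a
feed-forward network, each with residual connection and layer
normalisation; the final block's per-head cross-attention maps are
retained for interpretability export. The fused feature F is split
channel-wise into I segments in head order (concatenation reconstructs
F bitwise); each masked-mean-pooled segment passes through one shared
two-class head to give P(Y|D,T,c_i), and the prediction is the exact
backdoor adjustment

    P(Y|D,do(T)) = Σ_i P(c_i) · P(Y|D,T,c_i)

— a weighted arithmetic sum, no geometric-mean approximation. The
partition defaults to the aggregator output after the last FFN; since
the FFN mixes channels across heads, a pre-FFN partition is exposed
(`partition_pre_ffn`). With I = 1 the backdoor row equals the single
conditional row, recovering plain conditioning.

Losses: cross-entropy on the (backdoor or plain) probability row with
the log clamped at 1e−12, plus, when enabled, the MLM loss of the
original tokens at selected positions under a token-prediction head on
the encoder output. Both terms are averaged (over batch and over
selected positions respectively) before the unit-weight sum, keeping
their scales comparable across batch compositions. Every debiasing
element — randomization, MLM, CAM, backdoor — has an independent
ablation switch; with all off the model is a plain dual-tower
P(Y|D,T) classifier.

The implementation is pure numpy on a small reverse-mode autodiff
engine (`tapb.autodiff`), single precision for model state, double
precision for reference quantities; gradients are verified numerically
in the test suite. Optimisation uses Adam (default lr 2e−3 for the
CLI; the desk-scale experiments use 5e−3), batch 32–64, and the
checkpoint with best validation AUROC is kept.

## Evaluation and probes

AUROC and AUPRC are computed from raw scores; accuracy, sensitivity
and specificity at the threshold maximising Youden's J = sensitivity +
specificity − 1 over observed score cut-points (ties toward the lower
threshold), fit on the calibration split — the validation set
in-domain. Runs repeat over five seeds and every per-seed value is
reported alongside mean ± sd.

The random-feature probe replaces exactly one branch's feature tensor
with standard-normal noise of matching shape: the (T,R) probe
(`mode="target_random"`) keeps the target branch and randomises the
drug features, so any residual score–label association measures how
much the model leans on targets; (D,R) (`mode="drug_random"`) is the
mirror image. Because the original work judged the probe visually, two
quantitative summaries are reported — the AUROC of probe scores
against true labels, and the normalised distance between class
centroids of the pooled classification features — with an optional 2-D
PCA export for visual inspection.

## Desk-scale experiment sizes

The directional debiasing experiment uses the generator defaults
(2000 pairs, 7:1:2 split), the tiny architecture (D_m = 32, H = I = 4),
five seeds, and evaluates on the balanced counter-prior re-split of the
held-out test share, where per-entity priors are exactly uninformative
and only the latent mechanism separates classes (its oracle AUROC
there is ~0.62, because deranged negatives can themselves be
mechanistic interactions). These sizes are the package's chosen desk
scale: large enough for the qualitative contrasts, small enough to run
on one CPU in minutes.

## Known limitations

The toy embedder carries no evolutionary or structural information;
absolute AUROCs here say nothing about benchmark performance. Backdoor
adjustment over raw sequences (summing over every training sequence)
is not implemented — the confounder dictionary is the tractable
adjustment set. The per-cluster segments after three channel-mixing
aggregator layers are approximations of cluster-conditioned features,
inherited from the architecture; the package does not attempt to prove
their fidelity. Duplicate pairs with conflicting labels are rejected
at read time by default (flag to keep); entity identity is the exact
string, with optional RDKit canonicalisation behind a flag.
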