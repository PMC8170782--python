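# Methods

## Problem and model

The package predicts the abundances of N surface proteins per cell from that
cell's (already denoised) RNA expression profile, treating the N proteins as
a jointly predicted multi-label target.  Two mechanisms couple the proteins:
a trainable dense graph over the protein panel, and a fixed-per-forward-pass
embedding of external PPI association scores.

Forward pass per cell: a two-layer encoder (G → h1 → h2, defaults
1024/128, PReLU slope 0.25 between the layers) produces the RNA
representation; N independent affine heads (h2 → d_r, default 64) produce
per-protein feature vectors V_r; the knowledge embedding V_k (below) is
concatenated row-wise, giving node matrix V ∈ R^{N×d}, d = d_r + N·d_c; one
propagation round V^e = σ(AVW) mixes the nodes through a trainable
adjacency A (N×N) and relation matrix W (d×d); a single shared affine map
d → 1 with a final PReLU yields the N predictions.  PReLU (negative slope
fixed at 0.25) rather than ReLU is used so predictions can be negative, as
CLR-transformed protein abundances are.

Assumptions worth stating: the input RNA is continuous and non-negative
(denoised, not raw counts); the protein target is on a log-like scale where
squared error is meaningful; the panel is small (tens of proteins), so a
dense N×N adjacency is learnable; prior channels are symmetric non-negative
scores on one shared panel.

## Knowledge embedding

Each of the M prior channels is a symmetric N×N score matrix C_i (scores in
0–1; 0–1000 integer exports are rescaled on input).  The embedding:

1. Column q of C_i is encoded by each of N shared one-layer networks
   (N → d_c, default 32): A_{c_i}[p,q,:] = W_p C_i[:,q] + b_p, giving M
   tensors N×N×d_c.
2. Channels are merged with scalar attention coefficients, a softmax over
   channels of the mean elu of each encoded tensor:
   A_c = elu((1/M) Σ_i a_i · (A_{c_i} W_{a_i})), with per-channel mixing
   matrices W_{a_i} ∈ R^{d_c×d_c} applied along the encoding axis.
3. A_c splits into N per-protein blocks (N×d_c).  A second softmax (over
   proteins, of the mean elu of each block) gives coefficients b_j; block j
   becomes elu(b_j · (A_c[j] W_{k_j})).
4. The N blocks are concatenated column-wise into V_k ∈ R^{N×(N·d_c)}.

Two indexing ambiguities in this construction were genuinely open and are
resolved as follows.  The channel-attention normalization runs over the M
channels (not the N proteins): a per-channel scalar summary — the mean of
elu over all N·N·d_c entries — is softmax-normalized, which is the only
reading under which the coefficients are comparable and the 1/M average is
meaningful.  The per-protein coefficients are computed from the blocks
*before* re-weighting; defining them from the re-weighted blocks would be
circular, and no fixed-point iteration is warranted for what is a single
attention pass.  Both coefficient vectors are non-negative and sum to 1 by
construction, which the tests assert for arbitrary inputs.

The N column-encoders are shared across channels (one set of N networks,
configurable to per-channel sets); all affine layers carry biases; weights
initialize uniform scaled by 1/√fan_in from the run seed.

## Training and evaluation

Loss: per-cell sum over proteins of squared error, averaged over the cells
of the batch, so the magnitude is batch-size independent.  Adam (defaults
lr 1e-6, batch 32, 350 epochs) updates all parameters, the knowledge
weights included — V_k is recomputed inside every forward pass during
training.  After each epoch the mean of its batch losses is compared to the
running best; the parameter snapshot of the minimum epoch is returned (ties
keep the earlier epoch).  There is no validation split; the best-epoch rule
is the only overfitting guard, and it is measured on training loss.

Evaluation reports per-protein MSE (mean over cells) and Pearson
correlation across cells, with mean and sample-SD (n−1) summaries over
proteins; a protein constant across test cells has undefined PCC, which is
reported missing with a warning and excluded from the summaries.
The best-of-k protocol picks, per protein, the minimum MSE and the maximum
PCC across k seeded runs — each metric independently, so they may come from
different runs.  The ablation runner compares no-prior, each single
channel, and all channels merged (default 450 epochs there, versus 350 for
plain training), summarizing each condition's repeated runs by the midpoint
of the max/min scores ± the half-range.

Quality control removes cells with mitochondrial read fraction ≥ 20%
(inclusive), then cells with ≤ 250 expressed genes (inclusive; "expressed"
means strictly positive after denoising), in that order, with removals
attributed to the first rule that fires.  Mitochondrial genes are a
caller-supplied identifier set (a helper matches the conventional "MT-"
prefix) for species portability.  The train/test split draws
floor(fraction·C) training cells uniformly without replacement from the
seed; the floor convention is a repository choice — published cell counts
for comparable data are consistent with no simple rounding rule, so exact
historical splits are not reconstructable and are not attempted.

## Differentiation

No deep-learning framework is used; the network is differentiated by a
small reverse-mode tape engine over numpy float64 arrays
(`citegraph._autodiff`) implementing exactly the operations the model
needs.  Gradients are verified against central finite differences in the
test suite (relative error ~1e-9 on the full model), and a dedicated test
asserts every trainable tensor receives a nonzero gradient on a generic
batch.

## Synthetic data

The generator draws, per cell, K latent gene-program activities
(log-normal, σ = 0.6).  RNA: each gene loads on exactly one program
(loading ~ U(0.5, 1.5)), plus Gaussian noise, clipped at zero — emulating
denoised continuous expression.  Proteins: each protein reads its own
program (weight 1) plus a weak random secondary one (≤ 0.3); the positive
base signals s are coupled through a symmetric zero-diagonal interaction
matrix (sampled at density 0.3, weights U(0.5, 1.0), unless supplied), then
y = log1p(s + coupling·s), centered per protein across cells — giving a
log-like, partly negative, approximately zero-mean target emulating CLR
scale without being a true compositional CLR (the model only requires a
log-like possibly-negative target).  Prior channels are |coupling| rescaled
to 0–1 with independent Gaussian perturbations (SD 0.1), symmetrized,
clipped to [0,1], zero diagonal — M correlated score channels.

Defaults: 2000 cells, 300 genes, 10 proteins, 10 programs, observation
noise SD 0.3 on both modalities, 5 prior channels.  What passing tests on
these data show: that the implementation recovers a learnable nonlinear
RNA→protein map, benefits directionally from informative priors, and
degrades monotonically with noise.  What they do not show: performance on
real CITE-seq data, whose dropout structure, overdispersion, batch effects
and 20k-gene dimensionality the generator deliberately does not emulate.

## Benchmark conditions and numerical choices

The published architecture is sized for ~20k genes; the repository's
benchmarks use a proportionally smaller model (hidden 256/64 or 128/32,
d_r 16/8, d_c 8/4) and a larger learning rate (1e-3, Adam) with 40–60
epochs, fixed once in `citegraph.presets` and shared by the test suite and
the reproduction script.  Repo-chosen thresholds: noiseless mean test
PCC > 0.95 (one run, 2000 cells); with default noise, mean test PCC > 0.5
in ≥ 4 of 5 seeds; the prior-direction comparison uses 10 paired seeds on a
500-cell, 8-protein, density-0.7 panel and asserts direction only (mean
PCC with priors ≥ without; across-seed variance without ≥ with), not
magnitudes.

Other numerical choices: softmaxes are max-shifted for stability; the
sigmoid propagation output lies strictly in (0,1); epoch-level loss for
checkpointing is the mean of batch losses; batch order reshuffles each
epoch from the run seed; learning-rate 0 is permitted and leaves parameters
bit-identical (used as an inertness test); duplicate prior edges keep the
maximum score; self-scores default to zero.

## Limitations

One propagation round only (a single mixing equation, no layer stack);
no dropout/regularization beyond best-epoch selection; the dense trainable
adjacency is unidentifiable up to rescaling against W (only predictions,
not A itself, should be interpreted); desk-scale benchmarks do not
demonstrate real-data accuracy; the CLR emulation is per-protein centering,
not compositional.
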