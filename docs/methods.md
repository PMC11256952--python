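# Methods

## Model

The package predicts how a chemical treatment perturbs a transcriptome, and
transfers that knowledge to cell-level drug response. A treatment condition is
c = (g0, S, d, t): basal expression profile g0 ∈ R^Ngene, compound structure S
(SMILES), dose d (µM) and exposure time t (h). The perturbed profile is
modelled as gc = p(θ|c)(g0), where the network parameters θ are themselves a
function of the condition — the defining idea of condition-specific gene–gene
attention.

**Chemical condition encoder.** The structure is embedded by a pluggable
encoder; the default is a hashed circular-substructure fingerprint (Morgan,
radius 2, 128 bits) over the canonicalised SMILES, so chemically identical
strings encode identically. Dose and time are rescaled by 100 µM and 72 h
respectively and each expanded to two dimensions by learned weights
(W_dose, W_time ∈ R^2). The concatenation [fingerprint, d′·W_dose, t′·W_time]
passes through a bias-free two-layer MLP (hidden width 512) to the gene-aligned
condition vector D ∈ R^Ngene.

**Attention as weights.** Each gene i carries its own expansion weights:
Q[i] = g0[i]·W_gene[i] + D[i]·W_comp[i] ∈ R^h (default h = 64). The raw dot
products A_QC[i,j] = Q[i]·Q[j] form a symmetric attention matrix. No softmax
and no 1/√h scaling are applied: the matrix is summed element-wise with a
binary protein-interaction prior, A = A_QC + A_PPI, and the sum is used
*directly* as the weights of a linear layer; any normalisation would destroy
the additive semantics of the prior. (A 1/√h flag exists for experimentation,
off by default.) The prediction is gc = W_final · dropout(act(A·g0)), with no
bias anywhere and W_final initialised near the identity so the untrained
network already approximates gc ≈ act(A·g0). One attention matrix is
materialised per sample and recomputed every forward pass — θ depends on the
input, so caching across samples would be incorrect. At the L1000 scale of
978 landmark genes this is ~1M entries per sample; mini-batching keeps it
within commodity-CPU memory.

**Pretraining** minimises MSE between predicted and measured perturbed
profiles on (g0, gc, condition) triples, with Adam, random validation split,
early stopping and best-validation-checkpoint selection.

**Frozen transfer to log IC50.** For cell-level response prediction the
pretrained network is frozen in its entirety (verified bitwise). Two additions
train: (i) a scaling layer g0′ = (g0 − μ)/σ with free per-gene latent vectors
μ, σ that re-align the new basal space with the pretraining expression space —
possible precisely because the network is bias-free, hence purely
multiplicative; and (ii) a bias-free prediction head mapping the concatenation
[gc_pred, D, g0′] (3·Ngene → 256 → 1) to the natural-log IC50. Viability
records carry no explicit treatment condition, so the conventional readout
condition of 10 µM and 72 h is injected. σ is parameterised as
softplus(ρ) + 10⁻⁴, so it is strictly positive by construction.

## Evaluation and interpretation

RMSE and the Pearson correlation coefficient in their standard forms score
response prediction. Four cross-validation schemes probe generalisation:
record-level **mixed**, **cell-blind** (whole cell lines held out),
**drug-blind** (whole compounds held out) and **disjoint** (both held out
jointly; records pairing a held-out entity with a retained one are dropped
from that fold — the only construction that keeps both sides pure).

Interpretation follows the attention matrix: per-sample maps are averaged per
drug; the top-k off-diagonal pairs (default 1000, ties broken by canonical
gene index so the output is stable) nominate gene sets; map similarity between
drugs is the Pearson correlation of strict upper-triangle entries (the
diagonal would inflate self-agreement, the lower triangle is redundant under
symmetry). The within- vs between-class contrast of mechanism-of-action (MoA)
groups is tested one-sided by Mann–Whitney — map-pair correlations are not
independent, so a rank test is the conservative choice. Differential
expression between low- and high-IC50 predicted profiles uses a per-gene
Welch t-test with Benjamini–Hochberg adjustment, the split defaulting to the
median with a "potent 25%" option; the over-representation test against
user-supplied gene sets is one-sided hypergeometric, BH-adjusted. Responder
vs non-responder separation uses a one-sided Welch t-test (responders lower);
the zero-shot analysis compares Euclidean distances ‖gc_pred − g0‖ between
sensitive and resistant groups the same way.

## Synthetic universe

Because the real training corpora are cluster-scale external resources, the
package ships a generator producing the statistical structure the method
assumes, at desk scale. A sparse symmetric gene network (default 50 genes,
edge density 0.1) carries signed edge weights (±U(0.3, 0.8); signed so
perturbation is not uniformly up-regulating). Each of 4 drug classes owns a
random *connected* subset of ~30% of the edges; each of 20 drugs inherits its
class mask with 5% edge jitter, so within-class mask similarity exceeds
between-class similarity by construction — the recoverable signal the MoA
analyses look for. Basal profiles for 30 cell lines come from a per-gene
location/scale model and are robust-z-scored across the panel. Perturbation is
single-step linear propagation, gc = g0 + s(d,t)·M_drug·g0 + ε with
s(d,t) = (d/100)·min(t/72, 1) and ε ~ N(0, 0.05²) — the simplest structure the
attention-as-weights model can represent exactly, which is what makes
recovery tests meaningful. Viability is log IC50 = β0 − β1·⟨e, |Δ|⟩ + η with
essentiality e ~ U(0,1), Δ the noiseless perturbation at 10 µM/72 h, β0 = 3,
β1 = 1, η ~ N(0, 0.3²), so stronger essential-gene perturbation means more
sensitivity. Drugs receive distinct valid small-molecule SMILES from a bundled
list; structure carries drug identity for the fingerprint encoder, with no
chemical-space realism intended. The generator does **not** emulate L1000
noise models, batch effects, replicate structure or realistic chemistry, so
passing tests demonstrate correctness and recoverability of the modelled
structure, not performance on real screens.

## Numerical and design choices

- **Implementation.** The network, encoder, scaling layer and head are NumPy
  with hand-written analytic gradients (batched matmul/einsum) and a NumPy
  Adam; the backward pass is validated against finite differences in the test
  suite (≤1e-3 relative error at sampled coordinates). Float64 throughout;
  all stochastic choices derive from a single integer seed, making runs
  bit-reproducible.
- **Activation: tanh by default.** The network is bias-free and its inputs
  and targets are robust-z profiles, roughly symmetric around 0. A bias-free
  ReLU stage truncates half of that space and cannot represent the
  sign-symmetric, near-linear perturbation dynamics; tanh is odd and
  near-identity at the origin. ReLU and identity remain available.
- **Optimisation defaults.** Pretraining: Adam lr 1e-3, batch 32, up to 200
  epochs, patience 20. Fine-tuning: lr 1e-3, up to 100 epochs, patience 10 —
  only ~40k scaling/head parameters train, so the higher rate is stable.
- **Scaling-layer initialisation.** μ and σ start at the per-gene mean and
  standard deviation of the fine-tuning basal matrix (standard
  normalisation-layer practice) and then train freely under the IC50 loss;
  they have no preassigned targets. An option disables this (μ=0, σ=1).
- **Robust z-score.** z = (x − median)/(1.4826·MAD) per gene across samples,
  MAD unscaled and the constant applied exactly once; zero-MAD genes map to 0
  with a warning so landmark panels containing constant genes still load.
- **Interaction prior.** STRING-style combined scores are kept strictly above
  900 ("greater than", not "at least"); the prior is binary with zero
  diagonal, since it enters as an adjacency, not a weight matrix.
- **Control pairing.** Each treated sample is paired with the element-wise
  mean of its batch's vehicle controls — the lowest-variance deterministic
  choice; a batch without controls is an error.
- **Gene ordering.** The pretraining matrix's gene order is canonical for a
  model's lifetime; later matrices are re-indexed to it, erroring on missing
  genes unless imputation (0 in robust-z units) is requested.
- **Dropout** (rate 0.1) applies to the activation output, following the
  layer order activation → dropout → final linear.
- **Ablation flags.** Pretraining on/off (`pretrained=None`), freezing on/off
  (`freeze_pretrained`), prior on/off (`use_ppi`), attention on/off
  (`attention=False` gives the plain additive core z = g0 + D), and sum
  instead of concatenation in the head (`fusion="sum"`).
- A fine-tuned model applies its scaling layer everywhere downstream,
  including attention-map extraction and perturbed-profile prediction.

## Problem sizes

The shipped experiments run the reference universe (50 genes, 20 drugs /
4 classes, 30 cells, 3000 triples, 600 response records), chosen so the full
pipeline — pretraining, paired fine-tuning runs over five seeds, attention
analysis and the statistical calibrations — completes in minutes on one CPU
core. The attention analysis reuses the single pretrained model and resamples
the basal profiles fed to it over five seeds rather than repeating
pretraining per seed.

## Limitations

- The default structure encoder is a fingerprint, not a learned molecular
  transformer; the `StructureEncoder` protocol is the extension point.
- Binary GCTX/HDF5 releases are out of scope; expression I/O is text
  (TSV/CSV/GCT 1.2).
- Cross-dataset batch correction is expected upstream.
- Enrichment is a generic hypergeometric test against user-supplied GMT sets;
  no external web services are called.
- Synthetic-world results certify the machinery, not clinical performance;
  absolute benchmark numbers on the real corpora require the full external
  datasets and long training.
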