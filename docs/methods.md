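# Methods

## Problem setting

A bulk chromatin-accessibility profile over `n` peaks is modelled as a
convex mixture of cell-type-specific accessibility signatures:
`B ≈ P · M`, with `P` the samples-by-k proportion matrix (rows on the
simplex) and `M` the k-by-n signature matrix. Both are estimated from a
labelled single-cell reference: pseudo-bulk mixtures with known `P` are
simulated from the reference and used as supervised training data, after
which the model can be refined per unlabelled bulk sample.

## Coordinate and format conventions

All genomic coordinates are 0-based half-open (BED convention); any
1-based input dialect must be converted at the I/O boundary. Peak sets are
sorted by (chromosome, start, end) under a natural chromosome order
(chr1..chr22, chrX, chrY, then lexicographic). Sparse cell-by-peak counts
travel as MatrixMarket triplets with sidecar `.rows`/`.cols` label files;
dense matrices as labelled TSV/CSV; contacts as BEDPE-like text whose
anchors are reduced to midpoints, dropping inter-chromosomal rows with a
logged count.

## Synthetic reference generator

The generator emulates an annotated scATAC atlas with k cell types over
`n` peaks laid round-robin across chromosomes (fixed width 500 bp, spacing
5,000 bp). Each type owns a disjoint, contiguous marker block of
`⌊marker_fraction · n / k⌋` peaks where its Poisson rate is
`base_rate · marker_fold`; all other peaks have rate `base_rate`. Counts
are independent Poisson draws per cell.

Defaults (`marker_fraction = 0.2`, `marker_fold = 10`, `base_rate = 0.1`)
give sparse counts (~90 % zeros at the background rate) with clearly
separable types, the regime in which real annotated atlases are usable for
deconvolution. The generator deliberately does **not** model
fragment-length structure, TSS enrichment, doublets, batch effects, or
peak-width variation; passing tests therefore demonstrate correctness of
the method's machinery and its behaviour under its own modelling
assumptions, not robustness to every artefact of real scATAC data.

The contiguous marker blocks make attention structure inspectable: marker
peaks of one type fall in adjacent patches.

## Pseudo-bulk simulation

Proportion vectors are Dirichlet draws (`alpha = 1`, i.e. uniform on the
simplex; the concentration is exposed) under four regimes:

* **Random** — the raw Dirichlet draw.
* **Dominant** — one uniformly chosen coordinate rescaled to
  U(0.5, 0.9], the rest renormalised; guarantees `max(p) > 0.5`
  deterministically rather than by rejection.
* **Rare** — one coordinate rescaled to U(0, 0.05); guarantees
  `min(p) < 0.05`.
* **Average** — `1/k` plus Dirichlet jitter shrunk until
  `max(p) − min(p) < 0.05` (target spread 0.049, with an extra shrink to
  keep entries non-negative at large k).

For each sample, cell counts per type are the largest-remainder rounding
of `p · n_cells` (ties to the lower type index), so realised proportions
are exact rationals summing to 1; cells are drawn with replacement, their
count rows summed, and the sum min-max normalised per sample. Default
`n_cells_per_sample = 500`: large enough for stable mixture profiles,
small enough for desk-scale experiments.

Min-max normalisation is applied **per sample** (row), since its purpose
is to remove sample-level sequencing-depth differences; constant rows map
to all zeros (deterministic degenerate convention, also used for
signature rows).

## Architecture

* Per-chromosome patches of `patch_size = 50` consecutive peaks; the last
  patch per chromosome may be short and is zero-padded at input time
  (dropping it would delete peaks from the output space).
* Each patch has its own LayerNorm (affine) + single-hidden-layer MLP
  (width d, GELU) projection into `R^d`. The j distinct projections break
  permutation symmetry between patches, so no additional positional
  embedding is added.
* A learnable class token is prepended; the encoder is `L = 2` pre-norm
  transformer layers with `h = 4` heads on `d = 64` (head width d/h),
  MSA and MLP blocks each wrapped in residual connections. With L = 0 or
  all block weights zero the encoder is exactly the identity.
* Proportion head: sigmoid(MLP(LN(class token))) in (0,1)^k, renormalised
  to the simplex for both loss and reporting (the sigmoid alone does not
  produce compositional vectors, and the evaluation metrics presume them).
* Decoder: `M = ReLU(W₁W₂W₃W₄W₅)` with hidden widths `[64, 128, 256,
  512]`, no biases, no intermediate activations.

All parameters are float64; forward/backward passes run on a small
in-repo reverse-mode autodiff engine (`deca.autodiff`) validated by a
central-difference gradient check (relative error ≤ 1e-4 on the full
composite loss).

### Decoder initialisation and projection

A negative pre-ReLU output entry receives zero gradient and can never
recover ("dead" entry). Two measures keep the ReLU transparent:

1. factors are initialised as |Xavier| (entrywise absolute values),
   rescaled so the product's mean matches a typical min-max signature
   level (0.15);
2. after every optimiser step the factors are clipped to ≥ 0
   (projected gradient).

Any non-negative k-by-n matrix factorises exactly with non-negative
factors (write it as Σᵢ eᵢ ⊗ rowᵢ), so the projection costs no
expressiveness; empirically it is the difference between the signature
loss stalling and converging to ~0.

## Training

Phase 1 minimises `w_P·MSE(P_true, P̂) + w_M·MSE(M_true, M̂) +
w_R·MSE(B, P̂·M̂)` jointly with Adam (lr 1e-3, batch 32, 12 epochs,
4,000 pseudo-bulks = 1,000 per regime by default). Weights default to
`(1, 5, 1)`: per-sample min-max scaling of a mixed profile is not the
same as mixing per-type min-maxed signatures, so exact reconstruction by
`P_true · M_true` is unattainable and an unweighted reconstruction term
systematically biases `M̂` away from the true signatures; up-weighting the
signature term restores accurate recovery while leaving proportion
accuracy unchanged. Both signature and reconstruction supervision are
kept because the decoder's output is itself a stated model output, not
only a reconstruction device.

The model's predictions on the training set after phase 1 are stored as
the anchors `P̃`, `M̃`.

### Adaptive refinement

At test time true proportions are unknown, so the anchor for an
unlabelled sample is the pre-adaptation model's own prediction on it —
its post-initial-training state. Per sample, up to `max_rounds = 2`
rounds of:

* **Step 1** — freeze encoder and head; minimise
  `MSE(B, P̂·M̂)` over the decoder until plateau. Since `P̂` is constant
  here, only the decoder product is recomputed per iteration. A plateau
  is accepted only if its loss does not exceed the step-entry loss
  (greedy descent); otherwise the step is rolled back.
* **Step 2** — freeze decoder; minimise `MSE(P̂, P̃) + MSE(B, P̂·M̂)` over
  the encoder/head, plateauing on the proportion term. With the decoder
  frozen the signature-anchor distance is constant, so the reconstruction
  term carries the data signal.

Plateau = no improvement of the running best by more than `tol = 1e-6`
over the last `patience = 5` iterations; each step is additionally capped
at 60 iterations. Adam lr 1e-4 (an order below phase 1: refinement, not
retraining). If the outer reconstruction loss exceeds 10× its initial
value the model reverts to its pre-adaptation state with a warning.

## Evaluation metrics

* CCC with population (1/n) moments, `2·cov / (var_X + var_Y + (X̄−Ȳ)²)`,
  returning 0 on a zero denominator (avoids NaN propagation).
* MAE = Σ|Δ| / (n·k).
* Spearman = Pearson correlation of average-rank transforms
  (scipy.stats.spearmanr); constant vectors yield 0 with a warning.

Reports cover per-sample metrics (over the k-vector), per-cell-type
metrics (over samples; reported as missing, not 0, when only one sample
exists), and overall metrics over all flattened entries. Flattened
overall Spearman is the headline number; per-sample aggregation is
available from the same report.

## Interpretability

Attention is harvested from a forward pass on a deterministic
cohort-mean probe (mean of the training pseudo-bulk profiles, re-min-max
scaled), averaged over heads of the last encoder layer by default (mean
over all layers optional), class token dropped, restricted to
within-chromosome blocks, and symmetrised `(W + Wᵀ)/2`.

Off-diagonal |weights| per chromosome are split at empirical tertiles
into Low/Median/High (ties to the lower category; fewer than 3 distinct
values ⇒ all Median with a warning).

The contact overlap test selects, per chromosome, the top 5 % of
off-diagonal pairs by |attention| and, separately, by contact strength
(zero-strength pairs are absent contacts and are never selected); the
observed statistic is the intersection size summed over chromosomes. The
null shifts each chromosome's selected contact pairs by a uniformly
random **non-zero** circular offset along the patch axis — preserving the
pair-distance structure, hence respecting distance decay of contacts — and
the add-one estimator `p = (1 + #{null ≥ obs}) / (1 + n_perm)` never
returns 0. Overlap is a patch-pair set intersection (rank-based, hence
invariant to monotone transforms of either map); 50,000 permutations by
default. A full-shuffle null is deliberately not the default: it destroys
distance decay and overstates significance.

## Problem sizes and numerical choices

The acceptance study uses k = 5 types, 600 peaks on 3 chromosomes, 100
cells/type, 4,000 training mixtures and 50 held-out mixtures — sizes
chosen so the full study (including the 200×500 permutation calibration)
completes in a few minutes on one CPU while leaving all qualitative
behaviour intact. Softmax subtracts the row max before exponentiation;
LayerNorm uses eps 1e-5; min-max and signature rows use the all-zeros
convention for constant input; largest-remainder ties go to the lower
type index; attention-pair selection breaks value ties deterministically
by pair index.

## Known limitations

* The generator's Poisson independence means no peak-peak covariance
  within a cell type; real co-accessibility structure is absent, so the
  attention/contact analysis on synthetic data validates the machinery,
  not a biological claim.
* Per-sample adaptation assumes each bulk sample is a mixture of the
  reference's cell types; unrepresented types are absorbed into the
  nearest represented ones.
* Reference and bulk must share a genome build; peak matching is
  any-overlap with largest-overlap tie-breaking and keeps reference
  coordinates (the training feature space stays fixed).
* The transformer is desk-scale (d=64, L=2); genome-wide peak sets
  (10⁵–10⁶ peaks) would need larger patches or sub-sampling.
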