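# deca

**Deconvolution of bulk chromatin accessibility with a patch-attention
transformer.**

Bulk ATAC-seq measures the average chromatin accessibility of a tissue, but
that average hides the mixture of cell types that produced it. Given a
labelled single-cell ATAC reference, `deca` estimates, for each bulk sample,

* the **cell-type proportion vector** `p` (a point on the k-simplex), and
* the **cell-type-by-peak signature matrix** `M`, so that the bulk profile is
  approximately reconstructed as `B ≈ P · M`.

It is aimed at epigenomics researchers who have bulk accessibility profiles
(patient cohorts, perturbation series, archival samples) and a labelled
scATAC atlas sharing the same genome build.

## Model

Peaks are grouped into **patches** of `s` consecutive peaks per chromosome —
each chromosome is a separate input channel, so no patch mixes chromosomes.
Each patch `P_j` has its own trainable projection into `R^d`:

```
N_j = MLP_j(LN(P_j); θ_j)              X_0 = [P_cls; N_1; …; N_j]
```

with a learnable class token `P_cls`. An `L`-layer pre-norm transformer
encoder mixes the tokens:

```
X'_l = MSA(LN(X_{l-1}); α) + X_{l-1}
X_l  = MLP(LN(X'_l); β) + X'_l
```

where MSA runs `h` scaled-dot-product attention heads,
`SA(X) = softmax(q kᵀ / √(d/h)) v`. Proportions are read from the class
token with a sigmoid head (renormalised to the simplex):

```
p = sigmoid(MLP(LN(X_L⁰); ω)),   p ← p / Σp
```

and the signature matrix is the **factorised non-negative decoder**

```
M = ReLU(W₁·W₂·W₃·W₄·W₅)
```

— no biases, no intermediate activations, so the accessibility matrix is
directly visible in the parameters.

Training is two-phase. Phase 1 fits everything jointly on simulated
pseudo-bulk mixtures (Dirichlet proportions under Random / Rare / Dominant /
Average regimes) with the loss
`w_P·MSE(P) + w_M·MSE(M) + w_R·MSE(B, P·M)`. Phase 2 (*adaptive
refinement*) tunes the model per unlabelled bulk sample by greedy
alternation: optimise the decoder on reconstruction error until it plateaus,
then the encoder against its anchored proportion prediction, and repeat.

Accuracy is reported as Lin's concordance correlation coefficient (CCC),
mean absolute error (MAE) and Spearman's rank correlation.

The encoder's within-chromosome patch-attention weights are an
interpretable by-product; `deca` can test their overlap with an external
chromatin-interaction map (Hi-C-style contact lists) using a
circular-shift permutation test.

## Worked example

`examples/deconvolve_synthetic_cohort.py` builds a 4-type synthetic
reference, trains on 1,000 pseudo-bulk mixtures, and deconvolves 20
held-out mixtures with per-sample adaptive refinement:

```
overall Spearman r = 0.989
overall CCC        = 0.993
overall MAE        = 0.0195
  type_A: CCC=0.995  MAE=0.0176
  type_B: CCC=0.991  MAE=0.0250
  type_C: CCC=0.989  MAE=0.0193
  type_D: CCC=0.995  MAE=0.0160
```

Spearman/CCC near 1 and MAE near 0 mean the predicted proportions track the
known mixing ground truth. The other examples show signature recovery from
the decoder (`signature_reconstruction.py`; per-type Spearman ≈ 0.98–0.99
against the true min-max mean profiles) and the attention/contact overlap
test (`attention_contact_overlap.py`; planted contacts on high-attention
pairs reach p ≈ 5·10⁻⁴ with 2,000 shifts).

## Command line

Every stage is also a subcommand of the `deca` CLI with a shared flat YAML
config and a single global seed:

```bash
deca simulate-ref --out-prefix ref             # synthetic labelled atlas
deca pseudobulk   --atlas ref --out-prefix pb  # mixtures + ground truth
deca train        --atlas ref --out model.deca
deca predict      --checkpoint model.deca --bulk pb_bulk.tsv --out-prefix out
deca eval         --truth pb_Ptrue.csv --pred out_proportions.csv --out report.csv
deca attention    --checkpoint model.deca --bulk pb_bulk.tsv --out att.tsv
deca overlap-test --checkpoint model.deca --bulk pb_bulk.tsv \
                  --contacts contacts.bedpe --out overlap.json
deca run-all      --outdir demo                # the whole pipeline + manifest
```

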