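"""The patch-attention deconvolution network.

Bulk accessibility profiles are cut into per-chromosome patches of
consecutive peaks; each patch passes through its own LayerNorm + MLP
projection into an embedding, a learnable class token is prepended, an
L-layer pre-norm transformer encoder (multi-head self-attention + MLP
blocks, residual connections) mixes the tokens, and two heads read the
result out:

* proportions — sigmoid(MLP(LN(class token))), renormalised to the
  k-simplex;
* signatures — ReLU(W1 W2 W3 W4 W5), a factorised non-negative
  cell-type-by-peak matrix with no biases or intermediate activations,
  so the accessibility matrix is directly visible in the parameters.

Predicted bulk is reconstructed as P_hat @ M_hat.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat, stack
from .preprocessing import PatchLayout
from .reference import SignatureMatrix

__all__ = [
    "ModelConfig",
    "DecaModel",
    "ProportionEstimate",
    "embed_patches",
    "self_attention",
    "msa",
    "encoder_forward",
    "proportion_head",
    "decode_signature",
    "reconstruct_bulk",
    "forward",
    "save_model",
    "load_model",
]


@dataclass
class ModelConfig:
    """Hyperparameters; ``d`` must be divisible by the head count ``h``."""

    k: int
    n_peaks: int
    patch_size: int = 50
    d: int = 64
    L: int = 2
    h: int = 4
    decoder_dims: list = field(default_factory=lambda: [64, 128, 256, 512])
    seed: int = 0

    def __post_init__(self):
        if self.d % self.h != 0:
            raise ValueError(f"embedding dim d={self.d} not divisible by h={self.h} heads")
        if len(self.decoder_dims) != 4:
            raise ValueError("decoder_dims must list exactly 4 hidden widths (five matrices)")


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, scale, size=shape or (fan_in, fan_out))


class DecaModel:
    """All trainable parameters, grouped the way the adaptive trainer freezes them.

    Groups: ``theta`` (per-patch projections), ``cls`` (class token),
    ``alpha`` (attention blocks), ``beta`` (encoder MLP blocks),
    ``omega`` (proportion head), ``gamma`` (decoder matrices W1..W5).
    """

    def __init__(self, config: ModelConfig, layout: PatchLayout):
        if layout.patch_size != config.patch_size:
            raise ValueError("layout patch size does not match model config")
        if len(layout.peak_to_patch) != config.n_peaks:
            raise ValueError(
                f"layout covers {len(layout.peak_to_patch)} peaks, config expects {config.n_peaks}"
            )
        self.config = config
        self.layout = layout
        rng = np.random.default_rng(config.seed)
        d, s, h, L, k = config.d, config.patch_size, config.h, config.L, config.k
        j = layout.n_patches

        def param(arr):
            return Tensor(arr, requires_grad=True)

        # per-patch projection: LN affine over s inputs, then s -> d -> d MLP (GELU)
        self.theta = []
        for _ in range(j):
            self.theta.append(
                {
                    "ln_g": param(np.ones(s)),
                    "ln_b": param(np.zeros(s)),
                    "W1": param(_xavier(rng, s, d)),
                    "b1": param(np.zeros(d)),
                    "W2": param(_xavier(rng, d, d)),
                    "b2": param(np.zeros(d)),
                }
            )
        self.cls = param(rng.normal(0.0, 0.02, size=d))

        # encoder blocks: pre-norm MSA (alpha) and pre-norm MLP (beta)
        self.alpha, self.beta = [], []
        for _ in range(L):
            self.alpha.append(
                {
                    "ln_g": param(np.ones(d)),
                    "ln_b": param(np.zeros(d)),
                    "Wqkv": param(_xavier(rng, d, 3 * d)),
                    "Wo": param(_xavier(rng, d, d)),
                    "bo": param(np.zeros(d)),
                }
            )
            self.beta.append(
                {
                    "ln_g": param(np.ones(d)),
                    "ln_b": param(np.zeros(d)),
                    "W1": param(_xavier(rng, d, 2 * d)),
                    "b1": param(np.zeros(2 * d)),
                    "W2": param(_xavier(rng, 2 * d, d)),
                    "b2": param(np.zeros(d)),
                }
            )

        # proportion head: LN affine + d -> d -> k MLP, sigmoid applied outside
        self.omega = {
            "ln_g": param(np.ones(d)),
            "ln_b": param(np.zeros(d)),
            "W1": param(_xavier(rng, d, d)),
            "b1": param(np.zeros(d)),
            "W2": param(_xavier(rng, d, k)),
            "b2": param(np.zeros(k)),
        }

        # factorised decoder, no biases, no intermediate activation.
        # Weights start non-negative (|Xavier| rescaled so the product's mean
        # matches a typical min-max signature level): with every factor >= 0
        # the ReLU is transparent at init, so no output entry is born dead.
        dims = [k, *config.decoder_dims, config.n_peaks]
        Ws = [np.abs(_xavier(rng, dims[i], dims[i + 1])) for i in range(5)]
        prod = Ws[0]
        for W in Ws[1:]:
            prod = prod @ W
        scale = (prod.mean() / 0.15) ** (1.0 / 5.0)
        self.gamma = {f"W{i + 1}": param(Ws[i] / scale) for i in range(5)}

        # patch -> column-slice bookkeeping for padding inputs
        lengths = layout.patch_lengths()
        self._starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
        self._lengths = lengths

    # -- parameter groups ---------------------------------------------

    def encoder_params(self) -> list[Tensor]:
        """theta + cls + alpha + beta + omega: everything the decoder is not."""
        out = [self.cls]
        for grp in self.theta + self.alpha + self.beta + [self.omega]:
            out.extend(grp.values())
        return out

    def decoder_params(self) -> list[Tensor]:
        return list(self.gamma.values())

    def project_decoder_nonneg(self) -> None:
        """Clip decoder factors to >= 0 (projected-gradient step).

        Keeps the ReLU in ``decode_signature`` transparent during
        optimisation: a negative pre-ReLU output entry receives zero
        gradient and can never recover, whereas any non-negative target
        admits an exact factorisation with non-negative factors, so the
        projection costs no expressiveness.
        """
        for p in self.gamma.values():
            np.clip(p.data, 0.0, None, out=p.data)

    def all_params(self) -> list[Tensor]:
        return self.encoder_params() + self.decoder_params()

    def named_params(self) -> dict[str, Tensor]:
        named = {"cls": self.cls}
        for i, grp in enumerate(self.theta):
            named.update({f"theta{i}.{k}": v for k, v in grp.items()})
        for i, grp in enumerate(self.alpha):
            named.update({f"alpha{i}.{k}": v for k, v in grp.items()})
        for i, grp in enumerate(self.beta):
            named.update({f"beta{i}.{k}": v for k, v in grp.items()})
        named.update({f"omega.{k}": v for k, v in self.omega.items()})
        named.update({f"gamma.{k}": v for k, v in self.gamma.items()})
        return named

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_params().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        named = self.named_params()
        for k, v in state.items():
            named[k].data = np.array(v, dtype=np.float64)

    # -- input shaping -------------------------------------------------

    def pad_input(self, x: np.ndarray) -> np.ndarray:
        """(B, n_peaks) -> (B, n_patches, patch_size), zero-padding short patches."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if x.shape[1] != self.config.n_peaks:
            raise ValueError(f"input has {x.shape[1]} peaks, model expects {self.config.n_peaks}")
        B = x.shape[0]
        out = np.zeros((B, self.layout.n_patches, self.config.patch_size))
        for p, (start, length) in enumerate(zip(self._starts, self._lengths)):
            out[:, p, :length] = x[:, start : start + length]
        return out


@dataclass
class ProportionEstimate:
    """Simplex-renormalised proportion predictions plus raw sigmoid outputs."""

    P_hat: np.ndarray
    raw: np.ndarray

    def __post_init__(self):
        if np.any(self.P_hat < 0) or np.any(np.abs(self.P_hat.sum(axis=1) - 1) > 1e-6):
            raise ValueError("P_hat rows must be non-negative and sum to 1")


def _affine_ln(x: Tensor, grp: dict) -> Tensor:
    return x.layernorm() * grp["ln_g"] + grp["ln_b"]


def embed_patches(x: np.ndarray, layout: PatchLayout, model: DecaModel) -> Tensor:
    """Project each (zero-padded) patch through its own LN+MLP into R^d.

    Returns X0 of shape (B, 1 + n_patches, d) with the class token first.
    """
    if layout is not model.layout and layout.peak_to_patch != model.layout.peak_to_patch:
        raise ValueError("layout does not match the one the model was built with")
    padded = model.pad_input(x)
    B = padded.shape[0]
    tokens = []
    for j, th in enumerate(model.theta):
        t = Tensor(padded[:, j, :])  # (B, s) leaf
        t = _affine_ln(t, th)
        t = (t @ th["W1"] + th["b1"]).gelu() @ th["W2"] + th["b2"]
        tokens.append(t)
    cls = stack([model.cls] * B, axis=0)  # (B, d)
    return stack([cls] + tokens, axis=1)  # (B, 1+j, d)


def _split_heads(t: Tensor, h: int) -> Tensor:
    B, T, d = t.shape
    return t.reshape(B, T, h, d // h).transpose(0, 2, 1, 3)  # (B, h, T, dh)


def self_attention(q: Tensor, k: Tensor, v: Tensor):
    """Scaled dot-product attention; returns (output, row-stochastic weights)."""
    dh = q.shape[-1]
    att = ((q @ k.transpose(*range(q.data.ndim - 2), -1, -2)) * (1.0 / np.sqrt(dh))).softmax()
    return att @ v, att


def msa(x: Tensor, grp: dict, h: int):
    """Multi-head self-attention block (post-LN input expected)."""
    B, T, d = x.shape
    qkv = x @ grp["Wqkv"]  # (B, T, 3d)
    q = _split_heads(qkv[:, :, :d], h)
    k = _split_heads(qkv[:, :, d : 2 * d], h)
    v = _split_heads(qkv[:, :, 2 * d :], h)
    out, att = self_attention(q, k, v)  # (B, h, T, dh), (B, h, T, T)
    out = out.transpose(0, 2, 1, 3).reshape(B, T, d)
    return out @ grp["Wo"] + grp["bo"], att


def encoder_forward(X0: Tensor, model: DecaModel, capture_attention: bool = False):
    """Pre-norm transformer encoder; optionally returns per-layer attention.

    Layer l: X' = MSA(LN(X)) + X; X = MLP(LN(X')) + X'.  With L=0 (or all
    block weights zero) the residuals make this the identity map.
    """
    x = X0
    attentions = []
    for a_grp, b_grp in zip(model.alpha, model.beta):
        msa_out, att = msa(_affine_ln(x, a_grp), a_grp, model.config.h)
        x = msa_out + x
        mlp_in = _affine_ln(x, b_grp)
        mlp_out = (mlp_in @ b_grp["W1"] + b_grp["b1"]).gelu() @ b_grp["W2"] + b_grp["b2"]
        x = mlp_out + x
        if capture_attention:
            attentions.append(att.data.copy())  # (B, h, T, T)
    if capture_attention:
        return x, attentions
    return x


def proportion_head(X_L: Tensor, model: DecaModel) -> tuple[Tensor, Tensor]:
    """sigmoid(MLP(LN(class token))) and its simplex renormalisation.

    Returns (P_hat, raw) as graph tensors; the sigmoid keeps raw in
    (0,1)^k so the renormalising sum can never underflow to 0.
    """
    cls = X_L[:, 0, :]  # (B, d)
    z = _affine_ln(cls, model.omega)
    z = (z @ model.omega["W1"] + model.omega["b1"]).gelu() @ model.omega["W2"] + model.omega["b2"]
    raw = z.sigmoid()
    total = raw.sum(axis=-1, keepdims=True)
    assert np.all(total.data > 0.0), "sigmoid outputs cannot sum to zero for finite logits"
    return raw / total, raw


def decode_signature(model: DecaModel) -> Tensor:
    """M_hat = ReLU(W1 W2 W3 W4 W5): non-negative k x n_peaks signatures."""
    g = model.gamma
    return (g["W1"] @ g["W2"] @ g["W3"] @ g["W4"] @ g["W5"]).relu()


def reconstruct_bulk(P_hat: Tensor | np.ndarray, M_hat: Tensor | np.ndarray):
    """Mixing identity: predicted bulk = proportions @ signatures."""
    if isinstance(P_hat, Tensor) or isinstance(M_hat, Tensor):
        return Tensor._lift(P_hat) @ Tensor._lift(M_hat)
    return np.asarray(P_hat) @ np.asarray(M_hat)


def forward(model: DecaModel, x: np.ndarray, capture_attention: bool = False):
    """Full forward pass on raw (normalised) bulk rows.

    Returns a dict of graph tensors: P_hat, raw, M_hat, B_hat, and
    optionally the per-layer attention arrays.
    """
    X0 = embed_patches(x, model.layout, model)
    if capture_attention:
        X_L, atts = encoder_forward(X0, model, capture_attention=True)
    else:
        X_L = encoder_forward(X0, model)
        atts = None
    P_hat, raw = proportion_head(X_L, model)
    M_hat = decode_signature(model)
    B_hat = reconstruct_bulk(P_hat, M_hat)
    out = {"P_hat": P_hat, "raw": raw, "M_hat": M_hat, "B_hat": B_hat}
    if capture_attention:
        out["attentions"] = atts
    return out


def predict_proportions(model: DecaModel, x: np.ndarray) -> ProportionEstimate:
    """Inference-only proportion estimate for (B, n_peaks) normalised input."""
    out = forward(model, x)
    return ProportionEstimate(P_hat=out["P_hat"].data.copy(), raw=out["raw"].data.copy())


def predicted_signatures(model: DecaModel) -> SignatureMatrix:
    values = decode_signature(model).data
    ids = model.layout.peaks.peak_ids if model.layout.peaks is not None else [
        str(i) for i in range(model.config.n_peaks)
    ]
    return SignatureMatrix(values, [f"type_{i}" for i in range(model.config.k)], ids)


def save_model(model: DecaModel, path: str | Path) -> None:
    """Serialise parameters + config + layout into one .npz-in-zip archive."""
    path = Path(path)
    cfg = asdict(model.config)
    layout = {
        "patch_size": model.layout.patch_size,
        "patches": model.layout.patches,
        "peaks": list(model.layout.peaks.records) if model.layout.peaks else None,
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("config.json", json.dumps({"config": cfg, "layout": layout}))
        import io as _io

        buf = _io.BytesIO()
        np.savez(buf, **model.state_dict())
        zf.writestr("params.npz", buf.getvalue())


def load_model(path: str | Path) -> DecaModel:
    from .io import PeakSet
    from .preprocessing import PatchLayout as _PL

    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("config.json"))
        import io as _io

        params = dict(np.load(_io.BytesIO(zf.read("params.npz"))))
    cfg = ModelConfig(**meta["config"])
    lay = meta["layout"]
    layout = _PL(patch_size=lay["patch_size"])
    for chrom, pi, ids in lay["patches"]:
        gidx = len(layout.patches)
        layout.patches.append((chrom, pi, list(ids)))
        for off, pid in enumerate(ids):
            layout.peak_to_patch[pid] = (gidx, off)
    if lay["peaks"]:
        layout.peaks = PeakSet(records=tuple(tuple(r) for r in lay["peaks"]))
    model = DecaModel(cfg, layout)
    model.load_state_dict(params)
    return model
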