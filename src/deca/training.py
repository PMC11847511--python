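"""Supervised training plus the greedy two-step adaptive refinement.

Phase 1 trains all parameters jointly on labelled pseudo-bulk batches
with the composite loss MSE(P) + MSE(M) + MSE(reconstruction).  Phase 2
(`adapt`) refines the model on a single unlabelled bulk sample: Step 1
freezes the encoder and optimises the decoder on reconstruction error
until it plateaus; Step 2 freezes the decoder and optimises the encoder
against the anchored proportion prediction plus reconstruction, until
the proportion term plateaus.  The anchors P~ and M~ are the model's
own predictions at adaptation entry — its post-initial-training state —
which regularises adaptation toward the supervised solution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor
from .model import (
    DecaModel,
    ProportionEstimate,
    decode_signature,
    embed_patches,
    encoder_forward,
    forward,
    proportion_head,
)
from .pseudobulk import PseudoBulkBatch
from .reference import SignatureMatrix

logger = logging.getLogger(__name__)

__all__ = ["TrainState", "mse", "train_initial", "adapt", "plateau"]


@dataclass
class TrainState:
    """Loss bookkeeping plus the post-initial-training anchors."""

    loss_history: list = field(default_factory=list)  # (epoch, mse_P, mse_M, mse_recon)
    P_tilde: np.ndarray | None = None
    M_tilde: np.ndarray | None = None
    patience: int = 5
    tol: float = 1e-6


def mse(A, B) -> float:
    """Mean of squared elementwise differences."""
    A, B = np.asarray(A, dtype=float), np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch {A.shape} vs {B.shape}")
    return float(np.mean((A - B) ** 2))


def plateau(history: list, patience: int, tol: float) -> bool:
    """True iff the running best has not improved by > tol over the last
    ``patience`` entries."""
    if not history:
        raise ValueError("plateau() requires a non-empty history")
    if len(history) <= patience:
        return False  # too few entries to witness a stall of length `patience`
    best_before = min(history[:-patience])
    recent_best = min(history[-patience:])
    return recent_best > best_before - tol


def _loss_terms(model: DecaModel, xb: np.ndarray, Pb: np.ndarray, Mb: np.ndarray):
    out = forward(model, xb)
    P_hat, M_hat, B_hat = out["P_hat"], out["M_hat"], out["B_hat"]
    loss_P = ((P_hat - Tensor(Pb)).pow(2.0)).mean()
    loss_M = ((M_hat - Tensor(Mb)).pow(2.0)).mean()
    loss_R = ((B_hat - Tensor(xb)).pow(2.0)).mean()
    return loss_P, loss_M, loss_R, out


def train_initial(
    model: DecaModel,
    batch: PseudoBulkBatch,
    epochs: int = 12,
    lr: float = 1e-3,
    batch_size: int = 32,
    seed: int = 0,
    weights: tuple = (1.0, 5.0, 1.0),
) -> tuple[DecaModel, TrainState]:
    """Joint mini-batch training of every parameter group.

    Minimises w_P MSE(P_true, P_hat) + w_M MSE(M_true, M_hat) +
    w_R MSE(bulk, P_hat M_hat) with Adam.  Stores the model's final
    predictions on the training batch as the anchors P~, M~.

    The signature term is up-weighted by default: per-sample min-max
    scaling of mixed bulk profiles makes exact reconstruction by
    P_true @ M_true unattainable, so an unweighted reconstruction term
    systematically biases M_hat away from the true signatures.
    """
    if batch.bulk.shape[1] != model.config.n_peaks:
        raise ValueError("batch feature space does not match model")
    state = TrainState()
    if epochs == 0:
        return model, state
    rng = np.random.default_rng(seed)
    opt = Adam(model.all_params(), lr=lr)
    X, P, M = batch.bulk, batch.P_true, batch.M_true.values
    n = X.shape[0]
    wP, wM, wR = weights
    for epoch in range(epochs):
        order = rng.permutation(n)
        ep_P = ep_M = ep_R = 0.0
        n_batches = 0
        for lo in range(0, n, batch_size):
            idx = order[lo : lo + batch_size]
            loss_P, loss_M, loss_R, _ = _loss_terms(model, X[idx], P[idx], M)
            loss = loss_P * wP + loss_M * wM + loss_R * wR
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; reduce lr (currently {lr})"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            model.project_decoder_nonneg()
            ep_P += float(loss_P.data)
            ep_M += float(loss_M.data)
            ep_R += float(loss_R.data)
            n_batches += 1
        state.loss_history.append(
            (epoch, ep_P / n_batches, ep_M / n_batches, ep_R / n_batches)
        )
        logger.info(
            "epoch %d: mse_P=%.5f mse_M=%.5f mse_recon=%.5f",
            epoch, ep_P / n_batches, ep_M / n_batches, ep_R / n_batches,
        )
    # anchors: predictions on the training set after initial training
    out = forward(model, X)
    state.P_tilde = out["P_hat"].data.copy()
    state.M_tilde = out["M_hat"].data.copy()
    return model, state


def _optimize_until_plateau(step_fn, patience: int, tol: float, max_iters: int) -> list:
    """Run step_fn() (returns the tracked loss) until plateau() fires."""
    history = []
    for _ in range(max_iters):
        history.append(step_fn())
        if len(history) > patience and plateau(history, patience, tol):
            break
    return history


def adapt(
    model: DecaModel,
    bulk_sample: np.ndarray,
    state: TrainState,
    max_rounds: int = 2,
    lr: float = 1e-4,
    patience: int = 5,
    tol: float = 1e-6,
    max_iters_per_step: int = 60,
    diagnostics: list | None = None,
) -> tuple[DecaModel, ProportionEstimate, SignatureMatrix]:
    """Greedy two-step adaptive refinement on one unlabelled bulk sample.

    Alternates decoder-only reconstruction descent (Step 1) with
    encoder-only descent on MSE(P, P~) + reconstruction (Step 2), where
    the anchors are the model's predictions at entry.  A Step-1 plateau
    is only accepted if its loss does not exceed the step-entry loss
    (greedy descent); divergence beyond 10x the initial loss reverts the
    model with a warning.
    """
    x = np.atleast_2d(np.asarray(bulk_sample, dtype=float))
    if x.shape[0] != 1:
        raise ValueError("adapt() refines one bulk sample at a time")

    entry_state = model.state_dict()
    out0 = forward(model, x)
    P_anchor = out0["P_hat"].data.copy()  # P~ for this sample (anchors are immutable)
    loss0 = mse(out0["B_hat"].data, x)

    if max_rounds == 0:
        return model, ProportionEstimate(out0["P_hat"].data.copy(), out0["raw"].data.copy()), \
            _signature(model)

    outer_history = [loss0]
    for _ in range(max_rounds):
        # Step 1: freeze encoder/head, optimise decoder on reconstruction.
        # With the encoder frozen P_hat is a constant, so only the decoder
        # product is recomputed per iteration.
        step_entry = model.state_dict()
        opt_dec = Adam(model.decoder_params(), lr=lr)
        entry_loss = _recon_loss(model, x)
        P_const = Tensor(forward(model, x)["P_hat"].data)

        def dec_step():
            M_hat = decode_signature(model)
            loss = ((P_const @ M_hat - Tensor(x)).pow(2.0)).mean()
            opt_dec.zero_grad()
            loss.backward()
            opt_dec.step()
            model.project_decoder_nonneg()
            return float(loss.data)

        _optimize_until_plateau(dec_step, patience, tol, max_iters_per_step)
        if _recon_loss(model, x) > entry_loss:  # reject a worse plateau
            model.load_state_dict(step_entry)
        if diagnostics is not None:
            diagnostics.append(
                {"step1_entry": entry_loss, "step1_accepted": _recon_loss(model, x)}
            )

        # Step 2: freeze decoder, optimise encoder/head on anchor +
        # reconstruction; M_hat is a constant here.
        opt_enc = Adam(model.encoder_params(), lr=lr)
        M_const = Tensor(decode_signature(model).data)

        def enc_step():
            X_L = encoder_forward(embed_patches(x, model.layout, model), model)
            P_hat, _ = proportion_head(X_L, model)
            loss_P = ((P_hat - Tensor(P_anchor)).pow(2.0)).mean()
            loss_R = ((P_hat @ M_const - Tensor(x)).pow(2.0)).mean()
            loss = loss_P + loss_R
            opt_enc.zero_grad()
            loss.backward()
            opt_enc.step()
            return float(loss_P.data)  # plateau on the proportion term

        _optimize_until_plateau(enc_step, patience, tol, max_iters_per_step)

        outer = _recon_loss(model, x)
        if outer > 10.0 * max(loss0, 1e-12):
            logger.warning("adaptation diverged (loss %.3g > 10x initial %.3g); reverting", outer, loss0)
            model.load_state_dict(entry_state)
            break
        outer_history.append(outer)
        if len(outer_history) > 1 and plateau(outer_history, 1, tol):
            break

    out = forward(model, x)
    est = ProportionEstimate(out["P_hat"].data.copy(), out["raw"].data.copy())
    return model, est, _signature(model)


def _recon_loss(model: DecaModel, x: np.ndarray) -> float:
    out = forward(model, x)
    return mse(out["B_hat"].data, x)


def _signature(model: DecaModel) -> SignatureMatrix:
    values = decode_signature(model).data
    ids = model.layout.peaks.peak_ids if model.layout.peaks is not None else [
        str(i) for i in range(model.config.n_peaks)
    ]
    celltypes = [f"type_{i}" for i in range(model.config.k)]
    return SignatureMatrix(values, celltypes, ids)
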