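"""Loss functions for reconstruction, classification and survival endpoints.

All losses are pure functions of numpy arrays and return Python floats.
Each loss has a companion ``*_grad`` returning the gradient with respect to
the model output, used by the training loops.

Conventions
-----------
Reconstruction losses average the squared error over *all* entries
(batch x features) so that losses are comparable across modalities of
different widths; for multi-modality losses the per-modality MSEs are then
summed. The Cox loss follows the Breslow convention: the risk set for an
event at time ``T_i`` is every sample with ``T_j >= T_i`` (including ``i``),
and tied event times share the full tied risk set.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp, softmax

__all__ = [
    "mse_recon", "mse_recon_grad",
    "cross_entropy_loss", "cross_entropy_grad",
    "cox_nll", "cox_nll_grad",
    "multi_recon_loss", "cross_recon_loss",
]


def mse_recon(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Mean squared reconstruction error, averaged over all entries."""
    x = np.asarray(x, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    return float(np.mean((x - x_hat) ** 2))


def mse_recon_grad(x: np.ndarray, x_hat: np.ndarray) -> np.ndarray:
    """d mse_recon / d x_hat."""
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    return (2.0 / x.size) * (x_hat - x)


def cross_entropy_loss(logits: np.ndarray, labels: np.ndarray) -> float:
    """Softmax cross-entropy, mean over the batch.

    ``-x[class] + log sum_j exp(x[j])`` per sample, for integer labels in
    ``{0..C-1}``.
    """
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels)
    n, c = logits.shape
    if labels.shape != (n,):
        raise ValueError("labels must be a vector matching the batch size")
    if labels.min() < 0 or labels.max() >= c:
        raise ValueError("label out of range")
    lse = logsumexp(logits, axis=1)
    return float(np.mean(lse - logits[np.arange(n), labels]))


def cross_entropy_grad(logits: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """d cross_entropy_loss / d logits: (softmax - onehot) / N."""
    n, c = logits.shape
    p = softmax(np.asarray(logits, dtype=np.float64), axis=1)
    p[np.arange(n), labels] -= 1.0
    return p / n


def _check_survival(h, times, events):
    h = np.asarray(h, dtype=np.float64).reshape(-1)
    times = np.asarray(times, dtype=np.float64).reshape(-1)
    events = np.asarray(events).reshape(-1).astype(int)
    if not (h.shape == times.shape == events.shape):
        raise ValueError("h, times and events must have equal lengths")
    if events.sum() == 0:
        raise ValueError("no observed events in batch: Cox loss undefined")
    return h, times, events


def cox_nll(h: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    """Negative log Cox partial likelihood.

    ``L = -(1/N_ob) * sum_{i: C_i=1} (h_i - log sum_{j: T_j >= T_i} exp(h_j))``

    where ``h`` are per-sample log relative hazards, ``N_ob`` the number of
    observed events. Shift-invariant in ``h`` and invariant to sample order.
    """
    h, times, events = _check_survival(h, times, events)
    # risk_mask[i, j] = 1 if T_j >= T_i
    risk_mask = times[None, :] >= times[:, None]
    # log sum over each risk set, computed stably
    hmax = h.max()
    log_risk = hmax + np.log((np.exp(h - hmax)[None, :] * risk_mask).sum(axis=1))
    ev = events == 1
    return float(-(h[ev] - log_risk[ev]).mean())


def cox_nll_grad(h: np.ndarray, times: np.ndarray, events: np.ndarray) -> np.ndarray:
    """d cox_nll / d h (length-N vector)."""
    h, times, events = _check_survival(h, times, events)
    n_ob = events.sum()
    risk_mask = (times[None, :] >= times[:, None]).astype(np.float64)
    e = np.exp(h - h.max())
    denom = risk_mask @ e  # denom[i] = sum over risk set of exp(h)
    ev = (events == 1).astype(np.float64)
    # for each sample k: sum over events i with T_k >= T_i of exp(h_k)/denom[i]
    occupancy = risk_mask.T @ (ev / denom)  # length N
    return (-(ev - e * occupancy)) / n_ob


def multi_recon_loss(xs: list[np.ndarray], x_hats: list[np.ndarray]) -> float:
    """Summed per-modality reconstruction MSE (ConcatAE reconstruction loss)."""
    if len(xs) != len(x_hats):
        raise ValueError("one reconstruction required per modality")
    return float(sum(mse_recon(x, xh) for x, xh in zip(xs, x_hats)))


def cross_recon_loss(x1: np.ndarray, x2: np.ndarray,
                     x_hat_12: np.ndarray, x_hat_21: np.ndarray) -> float:
    """Cross-modality reconstruction loss.

    ``x_hat_12`` reconstructs modality 1 from modality 2's latent and
    ``x_hat_21`` reconstructs modality 2 from modality 1's latent; the loss
    is the sum of the two cross MSEs.
    """
    return mse_recon(x1, x_hat_12) + mse_recon(x2, x_hat_21)
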