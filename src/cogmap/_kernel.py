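"""JIT-compiled mini-batch Adam training loop for the softmax network.

The network is tiny (tens of units) but is updated hundreds of thousands
of times per run, so the loop is compiled with numba; the math is plain
IEEE double precision (no fastmath reassociation) and fully deterministic
for a fixed shuffle seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["adam_train_loop"]


@njit(cache=True)
def adam_train_loop(  # noqa: PLR0915 - one flat numeric kernel
    X: np.ndarray,
    y: np.ndarray,
    Xv: np.ndarray,
    yv: np.ndarray,
    W1: np.ndarray,
    b1: np.ndarray,
    W2: np.ndarray,
    b2: np.ndarray,
    epochs: int,
    batch_size: int,
    lr: float,
    shuffle_seed: int,
) -> np.ndarray:
    """Train in place; return per-epoch (loss, acc, val_loss, val_acc).

    Mini-batches are drawn by reshuffling the training set each epoch.
    Gradients are for softmax + categorical cross-entropy; parameters are
    updated with bias-corrected Adam (beta1=0.9, beta2=0.999, eps=1e-7).
    """
    n = X.shape[0]
    h = W1.shape[1]
    c = W2.shape[1]
    mW1 = np.zeros_like(W1)
    vW1 = np.zeros_like(W1)
    mb1 = np.zeros_like(b1)
    vb1 = np.zeros_like(b1)
    mW2 = np.zeros_like(W2)
    vW2 = np.zeros_like(W2)
    mb2 = np.zeros_like(b2)
    vb2 = np.zeros_like(b2)
    beta1 = 0.9
    beta2 = 0.999
    eps = 1e-7
    history = np.zeros((epochs, 4))
    np.random.seed(shuffle_seed)
    step = 0
    for ep in range(epochs):
        order = np.random.permutation(n)
        epoch_loss = 0.0
        epoch_correct = 0
        for start in range(0, n, batch_size):
            end = min(start + batch_size, n)
            nb = end - start
            idx = order[start:end]
            Xb = X[idx]

            # forward
            H_pre = Xb @ W1 + b1
            H = np.maximum(H_pre, 0.0)
            Z = H @ W2 + b2
            P = np.empty((nb, c))
            for i in range(nb):
                zmax = Z[i].max()
                e = np.exp(Z[i] - zmax)
                P[i] = e / e.sum()

            # loss/accuracy bookkeeping and output-layer error
            dZ = P.copy()
            for i in range(nb):
                lab = y[idx[i]]
                epoch_loss += -np.log(P[i, lab] + 1e-12)
                if P[i].argmax() == lab:
                    epoch_correct += 1
                dZ[i, lab] -= 1.0
            dZ /= nb

            # backward
            gW2 = H.T @ dZ
            gb2 = dZ.sum(axis=0)
            dH = dZ @ W2.T
            for i in range(nb):
                for j in range(h):
                    if H_pre[i, j] <= 0.0:
                        dH[i, j] = 0.0
            gW1 = Xb.T @ dH
            gb1 = dH.sum(axis=0)

            # Adam update with bias correction
            step += 1
            bc1 = 1.0 - beta1**step
            bc2 = 1.0 - beta2**step
            mW1 = beta1 * mW1 + (1.0 - beta1) * gW1
            vW1 = beta2 * vW1 + (1.0 - beta2) * gW1 * gW1
            W1 -= lr * (mW1 / bc1) / (np.sqrt(vW1 / bc2) + eps)
            mb1 = beta1 * mb1 + (1.0 - beta1) * gb1
            vb1 = beta2 * vb1 + (1.0 - beta2) * gb1 * gb1
            b1 -= lr * (mb1 / bc1) / (np.sqrt(vb1 / bc2) + eps)
            mW2 = beta1 * mW2 + (1.0 - beta1) * gW2
            vW2 = beta2 * vW2 + (1.0 - beta2) * gW2 * gW2
            W2 -= lr * (mW2 / bc1) / (np.sqrt(vW2 / bc2) + eps)
            mb2 = beta1 * mb2 + (1.0 - beta1) * gb2
            vb2 = beta2 * vb2 + (1.0 - beta2) * gb2 * gb2
            b2 -= lr * (mb2 / bc1) / (np.sqrt(vb2 / bc2) + eps)

        history[ep, 0] = epoch_loss / n
        history[ep, 1] = epoch_correct / n
        if len(yv):
            Hv = np.maximum(Xv @ W1 + b1, 0.0)
            Zv = Hv @ W2 + b2
            val_loss = 0.0
            val_correct = 0
            for i in range(len(yv)):
                zmax = Zv[i].max()
                e = np.exp(Zv[i] - zmax)
                p = e / e.sum()
                val_loss += -np.log(p[yv[i]] + 1e-12)
                if p.argmax() == yv[i]:
                    val_correct += 1
            history[ep, 2] = val_loss / len(yv)
            history[ep, 3] = val_correct / len(yv)
    return history
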