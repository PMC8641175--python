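"""Class-asymmetric squared-log loss.

For a prediction p in [0, 1], a binary label y and a small offset a > 0:

    L(p, y; a) = (ln(p - y + 1 + a))^2

At y = 1 the argument is p + a, so a missed deletion (p -> 0) costs
(ln a)^2 — large, and growing as a shrinks.  At y = 0 the argument is
p + 1 + a, so a confident false positive (p -> 1) costs only
(ln(2 + a))^2 — small.  The asymmetry suits truth sets that are precise
but incomplete: unconfirmed predictions are penalised gently, missed
known deletions harshly.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def custom_loss(prediction, label, a: float = 0.001):
    """Elementwise squared-log loss; inputs broadcast like NumPy arrays."""
    if a <= 0:
        raise ValueError("loss offset a must be > 0")
    x = np.asarray(prediction, dtype=float) - np.asarray(label, dtype=float) + 1.0 + a
    x = np.maximum(x, _EPS)  # guard: cannot go non-positive under the contract
    return np.log(x) ** 2


def custom_loss_grad(prediction, label, a: float = 0.001):
    """d L / d prediction, elementwise: 2 ln(x) / x with x = p - y + 1 + a."""
    if a <= 0:
        raise ValueError("loss offset a must be > 0")
    x = np.asarray(prediction, dtype=float) - np.asarray(label, dtype=float) + 1.0 + a
    x = np.maximum(x, _EPS)
    return 2.0 * np.log(x) / x


def masked_mean_loss(predictions, labels, mask, a: float = 0.001):
    """Mean loss over unmasked windows; returns (loss, dL/dpredictions)."""
    mask = np.asarray(mask, dtype=bool)
    k = int(mask.sum())
    if k == 0:
        return 0.0, np.zeros_like(np.asarray(predictions, dtype=float))
    losses = custom_loss(predictions, labels, a)
    grad = custom_loss_grad(predictions, labels, a) * mask / k
    return float((losses * mask).sum() / k), grad
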