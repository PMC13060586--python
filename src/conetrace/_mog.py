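"""Per-pixel adaptive mixture-of-Gaussians background model (compiled core).

The update rule, applied independently at every pixel with value ``x``:

1. Rank the K components by fitness ``w_k / sqrt(var_k)``, descending
   (stable insertion sort; ties keep component order).
2. The background set is the shortest ranked prefix whose cumulative weight
   reaches ``T`` (the component that crosses ``T`` is included).
3. The matched component is the first in ranked order with
   ``|x - mu_k| <= lam * sqrt(var_k)``.  The pixel is foreground iff there
   is no match or the match lies outside the background set.
4. If matched (component m): ``w_k <- (1 - alpha) w_k`` for all k, then
   ``w_m <- w_m + alpha``; ``d = x - mu_m``; ``mu_m <- mu_m + alpha d``;
   ``d2 = x - mu_m``; ``var_m <- (1 - alpha) var_m + alpha d2^2``;
   ``var_m <- max(var_m, var_floor)``.
5. If unmatched: the lowest-weight component is replaced by
   ``(w0, x, init_var)`` and weights are renormalised to sum to 1.

The brute-force oracle in the test suite replicates exactly this operation
order; the two must agree bit-for-bit in float64.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def mog_update(frame, w, mu, var, alpha, T, lam, var_floor, w0, init_var, mask):
    h, width = frame.shape
    K = w.shape[2]
    order = np.empty(K, dtype=np.int64)
    for i in range(h):
        for j in range(width):
            x = frame[i, j]
            # stable insertion sort by w / sqrt(var), descending
            for k in range(K):
                order[k] = k
            for a in range(1, K):
                ka = order[a]
                key_a = w[i, j, ka] / np.sqrt(var[i, j, ka])
                b = a
                while b > 0:
                    kb = order[b - 1]
                    if w[i, j, kb] / np.sqrt(var[i, j, kb]) < key_a:
                        order[b] = kb
                        b -= 1
                    else:
                        break
                order[b] = ka

            # background set: shortest prefix with cumulative weight >= T
            cum = 0.0
            B = K
            for b in range(K):
                cum += w[i, j, order[b]]
                if cum >= T:
                    B = b + 1
                    break

            # first ranked component matching within lam standard deviations
            m = -1
            mpos = -1
            for b in range(K):
                k = order[b]
                if abs(x - mu[i, j, k]) <= lam * np.sqrt(var[i, j, k]):
                    m = k
                    mpos = b
                    break

            mask[i, j] = 1 if (m == -1 or mpos >= B) else 0

            if m >= 0:
                for k in range(K):
                    w[i, j, k] = (1.0 - alpha) * w[i, j, k]
                w[i, j, m] = w[i, j, m] + alpha
                d = x - mu[i, j, m]
                mu[i, j, m] = mu[i, j, m] + alpha * d
                d2 = x - mu[i, j, m]
                var[i, j, m] = (1.0 - alpha) * var[i, j, m] + alpha * d2 * d2
                if var[i, j, m] < var_floor:
                    var[i, j, m] = var_floor
            else:
                r = 0
                for k in range(1, K):
                    if w[i, j, k] < w[i, j, r]:
                        r = k
                mu[i, j, r] = x
                var[i, j, r] = init_var
                w[i, j, r] = w0
                s = 0.0
                for k in range(K):
                    s += w[i, j, k]
                for k in range(K):
                    w[i, j, k] = w[i, j, k] / s
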