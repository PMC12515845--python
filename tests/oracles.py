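"""Independent brute-force oracles used by the tests.

These are deliberately naive, literal transcriptions of the defining
formulas — plain Python loops, no sharing of code with the package — so
they can serve as an independent check of the optimized implementations.
"""

from __future__ import annotations

import math

import numpy as np


def sampen_naive(x, m: int, r: float) -> float:
    """Sample entropy by the literal double loop.

    Template vectors of length ``m`` (and ``m + 1``) are compared with the
    Chebyshev distance; the first ``Q - m`` templates are used at both
    dimensions and self-comparisons are skipped.  Returns
    ``-ln(B^{m+1} / B^m)``; degenerate zero counts yield
    ``ln((Q-m)(Q-m-1))``.
    """
    x = list(map(float, x))
    q = len(x)
    n_t = q - m

    def count(dim: int) -> int:
        total = 0
        for i in range(n_t):
            for j in range(n_t):
                if i == j:
                    continue
                d = 0.0
                for g in range(dim):
                    diff = abs(x[i + g] - x[j + g])
                    if diff > d:
                        d = diff
                if d <= r:
                    total += 1
        return total

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return math.log(n_t * (n_t - 1))
    return -math.log(a / b)


def vmd_naive(signal, K: int, alpha: float, tau: float, n_iter: int):
    """Literal frequency-domain ADMM iteration for VMD.

    Per-bin scalar loop over the one-sided spectrum:

        u_k(w) <- (f(w) - sum_{i != k} u_i(w) + lam(w)/2)
                  / (1 + 2*alpha*(w - w_k)^2)
        w_k    <- sum_w w |u_k(w)|^2 / sum_w |u_k(w)|^2
        lam(w) <- lam(w) + tau * (f(w) - sum_k u_k(w))

    Uses the same mirror extension, fftshifted one-sided spectrum and
    uniform [0, 1/4) initialization as the package so the iterates are
    directly comparable, but every update is written out as explicit
    loops.  Runs exactly ``n_iter`` iterations and returns the normalized
    center frequencies (cycles/sample), unsorted.
    """
    x = np.asarray(signal, dtype=float)
    n = len(x)
    h = n // 2
    mirr = np.concatenate([x[:h][::-1], x, x[h:][::-1]])
    T = len(mirr)
    half = T // 2
    freqs = (np.arange(1, T + 1) / T) - 0.5 - 1.0 / T
    w = freqs[half:]
    F = len(w)
    f_hat = np.fft.fftshift(np.fft.fft(mirr))[half:]

    u = [[0j] * F for _ in range(K)]
    omega = [(0.25 / K) * k for k in range(K)]
    lam = [0j] * F

    for _ in range(n_iter):
        for k in range(K):
            for b in range(F):
                others = 0j
                for i in range(K):
                    if i != k:
                        others += u[i][b]
                num = f_hat[b] - others + lam[b] / 2.0
                u[k][b] = num / (1.0 + 2.0 * alpha * (w[b] - omega[k]) ** 2)
            num_w = 0.0
            den = 0.0
            for b in range(F):
                p = abs(u[k][b]) ** 2
                num_w += w[b] * p
                den += p
            if den > 0:
                omega[k] = num_w / den
        for b in range(F):
            s = 0j
            for i in range(K):
                s += u[i][b]
            lam[b] = lam[b] + tau * (f_hat[b] - s)

    return np.array(omega)
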