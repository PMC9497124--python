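"""Numerically hot entropy kernels.

Approximate and sample entropy are O(n^2) template-matching statistics;
the double loops here are JIT-compiled with numba.  A pure-numpy
broadcast fallback keeps the package usable where JIT compilation is
unavailable — both paths implement the identical definitions (Chebyshev
distance, ``d <= r`` matching).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

if _HAVE_NUMBA:

    @njit(cache=True)
    def phi(x, m, r):
        """Average log of self-inclusive match fractions for length-m templates.

        This is the Phi_m(r) of the approximate-entropy definition:
        templates are x[i:i+m] for i = 0..n-m, matches are counted with
        the Chebyshev distance and include the template itself, so the
        count is never zero and the log is always defined.
        """
        n = x.shape[0]
        nt = n - m + 1
        total = 0.0
        for i in range(nt):
            count = 0
            for j in range(nt):
                d = 0.0
                for k in range(m):
                    dk = abs(x[i + k] - x[j + k])
                    if dk > d:
                        d = dk
                if d <= r:
                    count += 1
            total += np.log(count / nt)
        return total / nt

    @njit(cache=True)
    def sampen_counts(x, m, r):
        """Pair counts (A, B) for sample entropy.

        B counts length-m template pairs within r; A counts the subset
        whose (m+1)-th elements also match.  Templates are restricted to
        i = 0..n-m-1 so every m-template has an (m+1) extension, and
        self-matches are excluded (i < j only).
        """
        n = x.shape[0]
        nt = n - m
        a = 0
        b = 0
        for i in range(nt - 1):
            for j in range(i + 1, nt):
                d = 0.0
                for k in range(m):
                    dk = abs(x[i + k] - x[j + k])
                    if dk > d:
                        d = dk
                if d <= r:
                    b += 1
                    if abs(x[i + m] - x[j + m]) <= r:
                        a += 1
        return a, b

else:  # numpy broadcast fallback

    def _embed(x, m):
        n = x.shape[0] - m + 1
        idx = np.arange(m)[None, :] + np.arange(n)[:, None]
        return x[idx]

    def phi(x, m, r):
        emb = _embed(x, m)
        d = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=2)
        frac = np.mean(d <= r, axis=1)
        return float(np.mean(np.log(frac)))

    def sampen_counts(x, m, r):
        nt = x.shape[0] - m
        emb_m = _embed(x, m)[:nt]
        d = np.max(np.abs(emb_m[:, None, :] - emb_m[None, :, :]), axis=2)
        match_m = d <= r
        tail = np.abs(x[m : m + nt][:, None] - x[m : m + nt][None, :]) <= r
        iu = np.triu_indices(nt, k=1)
        b = int(np.count_nonzero(match_m[iu]))
        a = int(np.count_nonzero(match_m[iu] & tail[iu]))
        return a, b
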