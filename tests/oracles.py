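"""Independent brute-force reference implementations used by the tests.

These deliberately use a different code path from the package (scipy
cdist distance matrices and direct definition-level loops rather than
the package's JIT kernels and incremental parsers) so agreement is a
genuine cross-check.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def _templates(x: np.ndarray, m: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(x, m)


def phi_oracle(x: np.ndarray, m: int, r: float) -> float:
    """Phi_m(r): mean log of self-inclusive Chebyshev match fractions."""
    emb = _templates(np.asarray(x, float), m)
    d = cdist(emb, emb, metric="chebyshev")
    frac = np.mean(d <= r, axis=1)
    return float(np.mean(np.log(frac)))


def apen_oracle(x: np.ndarray, m: int, r: float) -> float:
    return phi_oracle(x, m, r) - phi_oracle(x, m + 1, r)


def sampen_oracle(x: np.ndarray, m: int, r: float) -> float:
    """Richman–Moorman sample entropy, self-matches excluded."""
    x = np.asarray(x, float)
    nt = x.size - m
    emb_m = _templates(x, m)[:nt]
    emb_m1 = _templates(x, m + 1)
    dm = cdist(emb_m, emb_m, metric="chebyshev") <= r
    dm1 = cdist(emb_m1, emb_m1, metric="chebyshev") <= r
    np.fill_diagonal(dm, False)
    np.fill_diagonal(dm1, False)
    b = dm.sum() / 2
    a = dm1.sum() / 2
    if a == 0 or b == 0:
        return np.nan
    return float(-np.log(a / b))


def msen_oracle(x: np.ndarray, m: int, r: float, max_scale: int) -> np.ndarray:
    x = np.asarray(x, float)
    out = []
    for tau in range(1, max_scale + 1):
        nc = x.size // tau
        coarse = x[: nc * tau].reshape(nc, tau).mean(axis=1)
        if np.ptp(coarse) == 0:
            out.append(0.0)
        else:
            out.append(sampen_oracle(coarse, m, r))
    return np.array(out)


def lz76_count_oracle(bits) -> int:
    """Definition-level LZ76 exhaustive-history parse, character loops only."""
    s = [int(b) for b in bits]
    n = len(s)

    def occurs(sub: list[int], text: list[int]) -> bool:
        L = len(sub)
        return any(text[k : k + L] == sub for k in range(len(text) - L + 1))

    i, c = 0, 0
    while i < n:
        length = 1
        while i + length <= n and occurs(s[i : i + length], s[: i + length - 1]):
            length += 1
        c += 1
        i += length
    return c


def lzc_oracle(x: np.ndarray, binarize: str = "median") -> float:
    x = np.asarray(x, float)
    thr = np.median(x) if binarize == "median" else np.mean(x)
    bits = (x > thr).astype(int)
    c = lz76_count_oracle(bits)
    return c * np.log2(x.size) / x.size


def discrete_mi_oracle(x, y) -> float:
    """Plug-in MI in bits via sklearn's contingency-based estimator."""
    from sklearn.metrics import mutual_info_score

    return float(mutual_info_score(x, y) / np.log(2))


def entropy_oracle(x) -> float:
    _, counts = np.unique(x, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))
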