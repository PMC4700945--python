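"""JIT-compiled kernel for the inference inner loop.

``attributes_kernel`` replays exactly the same stochastic process as the
pure-Python branch evolution in :mod:`indelfit.simulator` — consuming
random draws from the shared generator in the identical order — so the
two paths produce bit-identical attribute vectors from the same seed
(asserted in the test suite). The kernel exists purely for speed: one
objective evaluation runs N of these simulations, and a full search runs
tens of thousands.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn

        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def attributes_kernel(
    parent: np.ndarray,  # int64 (n_nodes,), -1 for root
    length: np.ndarray,  # float64 (n_nodes,)
    leaf_idx: np.ndarray,  # int64 (n_leaves,)
    rl: int,
    h: float,  # per-side indel rate per site
    cdf: np.ndarray,  # float64 (max_len,) cumulative length pmf
    rng,  # np.random.Generator
) -> np.ndarray:
    n_nodes = parent.shape[0]
    seqs = [np.empty(0, dtype=np.int64) for _ in range(n_nodes)]
    seqs[0] = np.arange(rl)
    master = np.arange(rl)
    next_id = rl
    for i in range(1, n_nodes):
        s = seqs[parent[i]].copy()
        t = length[i]
        elapsed = 0.0
        while True:
            L = s.shape[0]
            ins_rate = h * (L if L > 0 else 1)
            del_rate = h * L
            total = ins_rate + del_rate
            if total <= 0.0:
                break
            elapsed += rng.exponential() / total
            if elapsed > t:
                break
            u = rng.random() * total
            if u < ins_rate:
                ell = int(np.searchsorted(cdf, rng.random(), side="right")) + 1
                j = int(rng.integers(0, L + 1)) if L > 0 else 0
                new = np.arange(next_id, next_id + ell)
                next_id += ell
                if j > 0:
                    anchor = s[j - 1]
                    pos = 0
                    for q in range(master.shape[0]):
                        if master[q] == anchor:
                            pos = q + 1
                            break
                elif L > 0:
                    anchor = s[0]
                    pos = 0
                    for q in range(master.shape[0]):
                        if master[q] == anchor:
                            pos = q
                            break
                else:
                    pos = master.shape[0]
                master = np.concatenate((master[:pos], new, master[pos:]))
                s = np.concatenate((s[:j], new, s[j:]))
            else:
                ell = int(np.searchsorted(cdf, rng.random(), side="right")) + 1
                start = int(rng.integers(0, L))
                realized = min(ell, L - start)
                s = np.concatenate((s[:start], s[start + realized :]))
        seqs[i] = s

    present = np.zeros(next_id, dtype=np.bool_)
    for k in range(leaf_idx.shape[0]):
        ids = seqs[leaf_idx[k]]
        for q in range(ids.shape[0]):
            present[ids[q]] = True
    colidx = np.full(next_id, -1, dtype=np.int64)
    ncol = 0
    for q in range(master.shape[0]):
        m = master[q]
        if present[m]:
            colidx[m] = ncol
            ncol += 1
    out = np.zeros(5)
    if ncol == 0:
        return out
    n_blocks = 0
    n_gap_chars = 0
    min_len = ncol
    max_len = 0
    last = ncol - 1
    for k in range(leaf_idx.shape[0]):
        ids = seqs[leaf_idx[k]]
        L = ids.shape[0]
        if L < min_len:
            min_len = L
        if L > max_len:
            max_len = L
        n_gap_chars += ncol - L
        if L == 0:
            n_blocks += 1
            continue
        prev = colidx[ids[0]]
        blocks = 1 if prev > 0 else 0
        for q in range(1, L):
            pos = colidx[ids[q]]
            if pos - prev > 1:
                blocks += 1
            prev = pos
        if prev < last:
            blocks += 1
        n_blocks += blocks
    out[0] = ncol
    out[1] = n_blocks
    out[2] = n_gap_chars / n_blocks if n_blocks > 0 else 0.0
    out[3] = min_len
    out[4] = max_len
    return out
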