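"""Independent reference implementations used only as test oracles.

These deliberately take different algorithmic routes from the package:
the Euler simulator discretizes time instead of drawing exponential
waits, and the alignment replay reconstructs the gap matrix by column
expansion from an event log instead of the homology-id master ordering.
"""

from __future__ import annotations

import numpy as np


def truncated_power_pmf(a: float, max_len: int) -> np.ndarray:
    """Brute-force truncated power-law pmf via explicit summation."""
    total = 0.0
    for j in range(1, max_len + 1):
        total += j ** (-a)
    return np.array([k ** (-a) / total for k in range(1, max_len + 1)])


def euler_indel_counts(
    L0: int,
    t: float,
    ir: float,
    a: float,
    max_len: int,
    n_reps: int,
    rng: np.random.Generator,
    dt: float = 1e-4,
) -> np.ndarray:
    """Discrete-time (Euler) simulation of the indel event process.

    Tracks only sequence length and the number of indel events per
    replicate; in each step of size ``dt`` at most one event fires, with
    probability rate x dt. Vectorized over replicates.
    """
    h = ir / 2.0
    pmf = truncated_power_pmf(a, max_len)
    lengths_support = np.arange(1, max_len + 1)
    L = np.full(n_reps, float(L0))
    counts = np.zeros(n_reps)
    n_steps = int(round(t / dt))
    for _ in range(n_steps):
        ins_rate = h * np.maximum(L, 1.0)
        del_rate = h * L
        u = rng.random(n_reps)
        fire_ins = u < ins_rate * dt
        fire_del = (~fire_ins) & (u < (ins_rate + del_rate) * dt)
        n_ins = int(fire_ins.sum())
        n_del = int(fire_del.sum())
        if n_ins:
            L[fire_ins] += rng.choice(lengths_support, size=n_ins, p=pmf)
            counts[fire_ins] += 1
        if n_del:
            ell = rng.choice(lengths_support, size=n_del, p=pmf)
            Ld = L[fire_del]
            starts = np.floor(rng.random(n_del) * Ld)
            realized = np.minimum(ell, Ld - starts)
            L[fire_del] = Ld - realized
            counts[fire_del] += 1
    return counts


def replay_gap_matrix(ctree, rl: int, events) -> np.ndarray:
    """Rebuild the true-alignment gap pattern from an event log by
    column expansion.

    Each node's row is a 0/1 presence vector over a growing list of
    global alignment columns; an insertion splices new columns into
    *every* existing row (gap everywhere but the inserting lineage), a
    deletion zeroes the columns of the deleted residues. Events must be
    replayed in generation order (the simulator's preorder traversal),
    which is the order of the event log. Returns the boolean presence
    matrix over the columns observed in at least one leaf, rows in leaf
    preorder.
    """
    n_nodes = ctree.n_nodes
    by_node: dict[int, list] = {i: [] for i in range(n_nodes)}
    for ev in events:
        by_node[ev.node].append(ev)
    rows: list[list[int]] = [None] * n_nodes  # type: ignore[list-item]
    rows[0] = [1] * rl
    live: list[int] = [0]  # nodes whose rows must track column insertions
    for i in range(1, n_nodes):
        row = list(rows[ctree.parent[i]])
        live.append(i)
        rows[i] = row
        for ev in by_node[i]:
            if ev.kind == "substitution":
                continue
            present_cols = [c for c, bit in enumerate(row) if bit]
            L = len(present_cols)
            if ev.kind == "insertion":
                j = ev.position
                if L == 0:
                    col = len(row)
                elif j > 0:
                    col = present_cols[j - 1] + 1
                else:
                    col = present_cols[0]
                ell = ev.length
                for k in live:
                    rows[k][col:col] = [0] * ell
                row[col : col + ell] = [1] * ell
            else:  # deletion
                s = ev.position
                realized = min(ev.length, L - s)
                for c in present_cols[s : s + realized]:
                    row[c] = 0
    leaf_rows = np.array([rows[i] for i in ctree.leaf_indices], dtype=bool)
    observed = leaf_rows.any(axis=0)
    return leaf_rows[:, observed]
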