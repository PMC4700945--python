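"""Sequence evolution with insertions and deletions along a phylogeny.

The simulator implements a continuous-time (Gillespie) indel process.
With the substitution rate normalized to 1 per site per unit branch
length, indels occur at a total rate of ``IR`` per site, split equally
between insertions and deletions, and indel lengths follow a Zipf
(power-law) distribution ``Pr(k) ∝ k^(−a)`` truncated at ``max_len``.

Every residue carries a globally unique homology id, so the *true*
alignment of the leaf sequences is known exactly from the event history
rather than estimated: the columns of the output MSA are homology ids,
ordered consistently with the token order of every leaf.

Two output paths share one event core: :func:`simulate_true_msa` builds
a residue-level :class:`~indelfit.io_formats.MSA`, while
:func:`simulate_attributes` skips residues entirely and returns only the
five gap summary statistics (substitutions cannot change them, so the
inference loop never samples substitution events — dropping events that
do not alter the gap structure leaves the indel process exactly
distributed as in the full simulation).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _fastsim
from .io_formats import MSA, CompiledTree, PhyloTree

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "IndelParams",
    "IndelLengthDistribution",
    "EvolvingSequence",
    "EventRecord",
    "UniformReplacementSampler",
    "zipf_pmf",
    "sample_indel_length",
    "evolve_branch",
    "simulate_true_msa",
    "simulate_attributes",
]


@dataclass(frozen=True)
class IndelParams:
    """The indel dynamics parameter triple plus the fixed length cap.

    ir
        Indel-to-substitution rate ratio: total rate of indel events per
        site relative to a substitution rate of 1 per site per unit
        branch length. ``ir_split="total"`` divides it equally between
        insertions and deletions; ``"each"`` uses ``ir`` for both.
    a
        Slope of the truncated power-law (Zipf) indel length
        distribution; must exceed 1.
    rl
        Number of residues in the ancestral (root) sequence.
    max_len
        Truncation bound of the indel length distribution.
    """

    ir: float
    a: float
    rl: int
    max_len: int = 50
    ir_split: str = "total"

    def __post_init__(self) -> None:
        if self.ir < 0:
            raise ValueError("indel rate ratio must be >= 0")
        if not self.a > 1:
            raise ValueError("power-law slope a must exceed 1")
        if self.rl < 1:
            raise ValueError("root length must be a positive integer")
        if self.max_len < 1:
            raise ValueError("max indel length must be >= 1")
        if self.ir_split not in ("total", "each"):
            raise ValueError("ir_split must be 'total' or 'each'")

    @property
    def per_side_rate(self) -> float:
        """Per-site rate of insertions (= deletions) implied by the split."""
        return self.ir / 2.0 if self.ir_split == "total" else self.ir


def zipf_pmf(k: int, a: float, max_len: int) -> float:
    """Probability of indel length ``k`` under the truncated power law.

    ``Pr(k) = k^(−a) / Σ_{j=1..max_len} j^(−a)`` — the truncated
    analogue of the Riemann-zeta normalizer.
    """
    if not a > 1:
        raise ValueError("power-law slope a must exceed 1")
    if not 1 <= k <= max_len:
        raise ValueError(f"length {k} outside support [1, {max_len}]")
    j = np.arange(1, max_len + 1, dtype=np.float64)
    weights = j ** (-a)
    return float(k ** (-a) / weights.sum())


@dataclass(frozen=True)
class IndelLengthDistribution:
    """Truncated Zipf length distribution with precomputed pmf/cdf."""

    a: float
    max_len: int
    pmf: np.ndarray = field(repr=False, default=None)
    cdf: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not self.a > 1:
            raise ValueError("power-law slope a must exceed 1")
        if self.max_len < 1:
            raise ValueError("max indel length must be >= 1")
        k = np.arange(1, self.max_len + 1, dtype=np.float64)
        w = k ** (-self.a)
        pmf = w / w.sum()
        object.__setattr__(self, "pmf", pmf)
        object.__setattr__(self, "cdf", np.cumsum(pmf))
        object.__setattr__(self, "_cdf_list", np.cumsum(pmf).tolist())

    @property
    def normalizer(self) -> float:
        """Σ k^(−a) over the support (truncated zeta)."""
        k = np.arange(1, self.max_len + 1, dtype=np.float64)
        return float((k ** (-self.a)).sum())

    def sample(self, rng: np.random.Generator) -> int:
        return bisect.bisect_right(self._cdf_list, rng.random()) + 1

    @classmethod
    def from_params(cls, params: IndelParams) -> "IndelLengthDistribution":
        return cls(a=params.a, max_len=params.max_len)


def sample_indel_length(
    dist: IndelLengthDistribution, rng: np.random.Generator
) -> int:
    """Draw one indel length in ``[1, max_len]`` from ``dist``."""
    return dist.sample(rng)


@dataclass
class EventRecord:
    """One mutation event: positions are 0-based in the *ungapped*
    coordinates of the evolving sequence at the moment the event fired;
    ``length`` is the drawn indel length (deletions may truncate at the
    sequence end when applied)."""

    kind: str  # "insertion" | "deletion" | "substitution"
    node: int  # preorder node index of the branch's child node
    position: int
    length: int
    time: float


class SimulationContext:
    """Per-simulation global state: the master column ordering and the
    homology-id counter. The master list contains every id ever created,
    in an order consistent with the token order of every sequence that
    ever existed in the simulation."""

    __slots__ = ("master", "next_id")

    def __init__(self, root_length: int):
        self.master: list[int] = list(range(root_length))
        self.next_id: int = root_length


@dataclass
class EvolvingSequence:
    """An ordered sequence of (homology id, residue) tokens tied to the
    simulation context that owns its ids."""

    ids: list[int]
    ctx: SimulationContext
    residues: Optional[list[str]] = None

    @classmethod
    def root(
        cls,
        length: int,
        residues: Optional[list[str]] = None,
    ) -> "EvolvingSequence":
        return cls(ids=list(range(length)), ctx=SimulationContext(length), residues=residues)

    @property
    def length(self) -> int:
        return len(self.ids)

    def copy(self) -> "EvolvingSequence":
        return EvolvingSequence(
            ids=list(self.ids),
            ctx=self.ctx,
            residues=None if self.residues is None else list(self.residues),
        )


class UniformReplacementSampler:
    """Simplest substitution layer: replacement drawn uniformly over the
    20 amino acids (never returning the current residue). Residue
    identity does not enter any summary statistic; this layer only makes
    simulated FASTA output look like protein data."""

    alphabet = AMINO_ACIDS

    def draw(self, rng: np.random.Generator, n: int) -> list[str]:
        idx = rng.integers(0, len(self.alphabet), size=n)
        return [self.alphabet[i] for i in idx]

    def replace(self, rng: np.random.Generator, current: str) -> str:
        while True:
            c = self.alphabet[int(rng.integers(0, len(self.alphabet)))]
            if c != current:
                return c


def _evolve_inplace(
    ids: list[int],
    residues: Optional[list[str]],
    t: float,
    params: IndelParams,
    dist: IndelLengthDistribution,
    ctx: SimulationContext,
    rng: np.random.Generator,
    record: Optional[list[EventRecord]],
    node: int,
    sampler: Optional[UniformReplacementSampler],
) -> None:
    """Exact Gillespie evolution of one branch, mutating ``ids`` (and
    ``residues``) in place.

    Rates at sequence length L: substitutions L (only when a sampler is
    supplied — they never change the gap structure), insertions
    ``per_side_rate * max(L, 1)`` spread over the L+1 junctions (an
    empty sequence keeps its single junction so it can regrow), and
    deletions ``per_side_rate * L`` with a uniformly drawn start site,
    truncated at the sequence end.
    """
    h = params.per_side_rate
    master = ctx.master
    elapsed = 0.0
    while True:
        L = len(ids)
        ins_rate = h * (L if L > 0 else 1)
        del_rate = h * L
        sub_rate = float(L) if sampler is not None else 0.0
        total = ins_rate + del_rate + sub_rate
        if total <= 0.0:
            return
        elapsed += rng.exponential() / total
        if elapsed > t:
            return
        u = rng.random() * total
        if u < ins_rate:
            ell = dist.sample(rng)
            j = int(rng.integers(0, L + 1)) if L > 0 else 0
            new = list(range(ctx.next_id, ctx.next_id + ell))
            ctx.next_id += ell
            # master position: anywhere between the flanking ids of the
            # junction is order-consistent with every sequence (ids in
            # that window are absent from this lineage and its
            # descendants); we insert right after the left flank.
            if j > 0:
                pos = master.index(ids[j - 1]) + 1
            elif ids:
                pos = master.index(ids[0])
            else:
                pos = len(master)
            master[pos:pos] = new
            ids[j:j] = new
            if residues is not None:
                residues[j:j] = sampler.draw(rng, ell) if sampler else ["A"] * ell
            if record is not None:
                record.append(EventRecord("insertion", node, j, ell, elapsed))
        elif u < ins_rate + del_rate:
            ell = dist.sample(rng)
            s = int(rng.integers(0, L))
            realized = min(ell, L - s)
            del ids[s : s + realized]
            if residues is not None:
                del residues[s : s + realized]
            if record is not None:
                record.append(EventRecord("deletion", node, s, ell, elapsed))
        else:
            site = int(rng.integers(0, L))
            residues[site] = sampler.replace(rng, residues[site])
            if record is not None:
                record.append(EventRecord("substitution", node, site, 1, elapsed))


def evolve_branch(
    seq: EvolvingSequence,
    t: float,
    params: IndelParams,
    rng: np.random.Generator,
    record: Optional[list[EventRecord]] = None,
    node: int = -1,
    sampler: Optional[UniformReplacementSampler] = None,
) -> EvolvingSequence:
    """Evolve ``seq`` for branch length ``t``; the input is unchanged.

    Substitution events are only simulated when ``sampler`` is given
    (and ``seq`` carries residues); otherwise only the indel process is
    drawn, which leaves the gap structure identically distributed.
    """
    if t < 0:
        raise ValueError("branch length must be >= 0")
    out = seq.copy()
    dist = IndelLengthDistribution.from_params(params)
    _evolve_inplace(
        out.ids, out.residues, t, params, dist, out.ctx, rng, record, node, sampler
    )
    return out


def _simulate_leaf_ids(
    ctree: CompiledTree,
    params: IndelParams,
    rng: np.random.Generator,
    dist: IndelLengthDistribution,
    record: Optional[list[EventRecord]] = None,
    sampler: Optional[UniformReplacementSampler] = None,
    with_residues: bool = False,
) -> tuple[list[list[int]], Optional[list[list[str]]], SimulationContext]:
    """Run the indel process over every edge in fixed preorder and
    return the leaf token lists (and residues when requested)."""
    ctx = SimulationContext(params.rl)
    n = ctree.n_nodes
    seqs: list[Optional[list[int]]] = [None] * n
    seqs[0] = list(range(params.rl))
    res: list[Optional[list[str]]] = [None] * n
    if with_residues:
        root_sampler = sampler or UniformReplacementSampler()
        res[0] = root_sampler.draw(rng, params.rl)
    parent = ctree.parent
    length = ctree.length
    for i in range(1, n):
        p = parent[i]
        ids = list(seqs[p])
        r = list(res[p]) if with_residues else None
        _evolve_inplace(
            ids, r, length[i], params, dist, ctx, rng, record, i, sampler
        )
        seqs[i] = ids
        res[i] = r
    leaf_seqs = [seqs[i] for i in ctree.leaf_indices]
    leaf_res = [res[i] for i in ctree.leaf_indices] if with_residues else None
    return leaf_seqs, leaf_res, ctx


def _column_order(
    leaf_seqs: Sequence[list[int]], ctx: SimulationContext
) -> np.ndarray:
    """Homology ids present in at least one leaf, in master order."""
    present = np.zeros(ctx.next_id, dtype=bool)
    for ids in leaf_seqs:
        if ids:
            present[np.asarray(ids, dtype=np.int64)] = True
    master = np.asarray(ctx.master, dtype=np.int64)
    return master[present[master]]


def simulate_true_msa(
    tree: PhyloTree,
    params: IndelParams,
    rng: np.random.Generator,
    sampler: Optional[UniformReplacementSampler] = None,
    record: Optional[list[EventRecord]] = None,
) -> MSA:
    """Simulate evolution along ``tree`` and return the true alignment.

    Columns are the homology ids observed in at least one leaf, ordered
    consistently with every leaf's token order; a leaf lacking an id
    shows ``'-'``. All-gap columns cannot occur by construction.

    With a ``sampler``, substitution events compete with indels in the
    Gillespie process and residues mutate along branches. Without one
    (the default), no substitution events are drawn: each homology id
    receives one uniformly drawn amino acid, perfectly conserved down
    the tree, and the indel process consumes the random stream exactly
    as :func:`simulate_attributes` does (same seed, same gap pattern).
    """
    ctree = tree.compile()
    dist = IndelLengthDistribution.from_params(params)
    leaf_seqs, leaf_res, ctx = _simulate_leaf_ids(
        ctree,
        params,
        rng,
        dist,
        record=record,
        sampler=sampler,
        with_residues=sampler is not None,
    )
    cols = _column_order(leaf_seqs, ctx)
    colidx = np.full(ctx.next_id, -1, dtype=np.int64)
    colidx[cols] = np.arange(cols.shape[0])
    ncol = cols.shape[0]
    if sampler is None:
        # residues drawn per homology id after the fact (no substitutions)
        id_residues = UniformReplacementSampler().draw(rng, ctx.next_id)
        leaf_res = [[id_residues[hid] for hid in ids] for ids in leaf_seqs]
    rows = []
    for ids, residues in zip(leaf_seqs, leaf_res):
        row = ["-"] * ncol
        for hid, ch in zip(ids, residues):
            row[colidx[hid]] = ch
        rows.append("".join(row))
    return MSA(names=ctree.leaf_labels, rows=tuple(rows))


def simulate_attributes(
    tree: PhyloTree,
    params: IndelParams,
    rng: np.random.Generator,
    dist: Optional[IndelLengthDistribution] = None,
) -> np.ndarray:
    """Simulate one replicate and return its five-attribute vector
    directly, without materializing residues or row strings.

    Returns ``[msa_length, n_gap_blocks, avg_gap_block_len,
    min_seq_len, max_seq_len]``. Dispatches to a JIT-compiled kernel
    that reproduces the reference Python path bit-for-bit.
    """
    ctree = tree.compile()
    if dist is None:
        dist = IndelLengthDistribution.from_params(params)
    if _fastsim.HAVE_NUMBA:
        return _fastsim.attributes_kernel(
            ctree.parent,
            ctree.length,
            ctree.leaf_indices,
            params.rl,
            params.per_side_rate,
            dist.cdf,
            rng,
        )
    return _simulate_attributes_py(tree, params, rng, dist)


def _simulate_attributes_py(
    tree: PhyloTree,
    params: IndelParams,
    rng: np.random.Generator,
    dist: Optional[IndelLengthDistribution] = None,
) -> np.ndarray:
    """Pure-Python reference for :func:`simulate_attributes`."""
    ctree = tree.compile()
    if dist is None:
        dist = IndelLengthDistribution.from_params(params)
    leaf_seqs, _, ctx = _simulate_leaf_ids(ctree, params, rng, dist)
    leaf_arrs = [np.asarray(ids, dtype=np.int64) for ids in leaf_seqs]
    present = np.zeros(ctx.next_id, dtype=bool)
    for arr in leaf_arrs:
        if arr.shape[0]:
            present[arr] = True
    master = np.asarray(ctx.master, dtype=np.int64)
    cols = master[present[master]]
    ncol = int(cols.shape[0])
    if ncol == 0:  # every leaf went extinct; degenerate but well-defined
        return np.zeros(5)
    colidx = np.full(ctx.next_id, -1, dtype=np.int64)
    colidx[cols] = np.arange(ncol)
    n_blocks = 0
    n_gap_chars = 0
    min_len = ncol
    max_len = 0
    last = ncol - 1
    for arr in leaf_arrs:
        L = arr.shape[0]
        min_len = min(min_len, L)
        max_len = max(max_len, L)
        n_gap_chars += ncol - L
        if L == 0:
            n_blocks += 1
            continue
        pos = colidx[arr]
        blocks = int(pos[0] > 0) + int(pos[-1] < last)
        if L > 1:
            blocks += int(np.count_nonzero(pos[1:] - pos[:-1] > 1))
        n_blocks += blocks
    avg = n_gap_chars / n_blocks if n_blocks else 0.0
    return np.array([ncol, n_blocks, avg, min_len, max_len], dtype=np.float64)
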