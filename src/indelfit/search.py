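"""Parameter inference: coordinate-wise golden-section minimization of
the squared Mahalanobis distance over (RL, IR, a).

Each objective evaluation simulates N alignments under the candidate
parameters on the fixed input tree, computes ensemble moments of the
five summary statistics, and measures the distance of the input MSA's
attribute vector from that ensemble. The three coordinates are searched
in the order RL → IR → a, starting from the root length, with three RL
multi-starts (shortest sequence, longest sequence, number of columns)
to avoid local minima; IR starts at 0.075 and a at 1.55, with search
intervals IR ∈ [0, 0.16], a ∈ [1, 2], RL ∈ [50, 1800].

By default the N simulation seeds are a fixed function of the search
seed and the replicate index — common random numbers — so that the
objective is a deterministic function of the parameters and the
golden-section steps are not chasing Monte-Carlo noise. Identical
parameter triples are therefore memoized instead of re-simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from .io_formats import MSA, PhyloTree
from .simulator import IndelLengthDistribution, IndelParams, simulate_attributes
from .stats import (
    AttributeVector,
    EnsembleMoments,
    compute_attributes,
    ensemble_moments,
    fit_pvalue,
    mahalanobis_sq,
)

_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0

# seed-stream tags separating search-time from confirmation ensembles
_TAG_SEARCH = 0
_TAG_CONFIRM = 1
_TAG_FRESH = 2


@dataclass(frozen=True)
class SearchConfig:
    """Settings for one inference run.

    ``n_sims`` is N, the number of simulated alignments per objective
    evaluation (accuracy rises with N; 100 is the standard choice, and
    smaller values trade accuracy for speed). The interval bounds,
    starting points, and the maximum indel length of 50 are the
    method's fixed search conventions. Per-coordinate golden-section
    tolerances sit roughly an order of magnitude below the sampling
    error of the corresponding estimates.
    """

    n_sims: int = 100
    seed: int = 0
    ir_bounds: tuple[float, float] = (0.0, 0.16)
    a_bounds: tuple[float, float] = (1.0, 2.0)
    rl_bounds: tuple[float, float] = (50.0, 1800.0)
    ir_start: float = 0.075
    a_start: float = 1.55
    tol_rl: float = 1.0
    tol_ir: float = 5e-4
    tol_a: float = 5e-3
    max_cycles: int = 5
    rel_tol: float = 1e-2
    crn: bool = True
    confirm_factor: int = 10
    max_indel_len: int = 50
    ir_split: str = "total"

    def __post_init__(self) -> None:
        if self.n_sims < 2:
            raise ValueError("n_sims must be at least 2")
        for lo, hi in (self.ir_bounds, self.a_bounds, self.rl_bounds):
            if not lo < hi:
                raise ValueError("interval bounds must satisfy lo < hi")


@dataclass
class GoldenResult:
    x: float
    fx: float
    n_evals: int
    trace: list[tuple[float, float]] = field(default_factory=list)


def golden_section_1d(
    objective: Callable[[float], float],
    lo: float,
    hi: float,
    tol: float,
    max_iter: int = 200,
) -> GoldenResult:
    """Minimize a scalar function on [lo, hi] by golden-section search.

    The interval shrinks by the inverse golden ratio per step until its
    width is ≤ tol (or ``max_iter`` evaluations are spent); the best
    *evaluated* point is returned, not the interval midpoint. For a
    multimodal objective this yields a local minimum — a documented
    property of the search, not an error.
    """
    if not lo < hi:
        raise ValueError("need lo < hi")
    if tol <= 0:
        raise ValueError("tol must be positive")
    trace: list[tuple[float, float]] = []

    def f(u: float) -> float:
        val = objective(u)
        trace.append((u, val))
        return val

    a, b = lo, hi
    x1 = b - _INVPHI * (b - a)
    x2 = a + _INVPHI * (b - a)
    f1, f2 = f(x1), f(x2)
    n = 2
    while b - a > tol and n < max_iter:
        if f1 <= f2:
            b, x2, f2 = x2, x1, f1
            x1 = b - _INVPHI * (b - a)
            f1 = f(x1)
        else:
            a, x1, f1 = x1, x2, f2
            x2 = a + _INVPHI * (b - a)
            f2 = f(x2)
        n += 1
    best_x, best_f = min(trace, key=lambda uf: uf[1])
    return GoldenResult(x=best_x, fx=best_f, n_evals=n, trace=trace)


@dataclass
class StartTrace:
    """Search history of one RL multi-start."""

    rl_start: float
    evaluations: list[tuple[int, float, float, float]]  # (rl, ir, a, d2)
    best: tuple[int, float, float]
    d2: float
    cycles: int


@dataclass
class InferenceResult:
    """Outcome of one full parameter search."""

    ir: float
    a: float
    rl: int
    d2: float  # confirmation-ensemble squared distance at the optimum
    pvalue: float
    d2_search: float  # best search-time squared distance
    moments: EnsembleMoments  # confirmation-ensemble moments
    target: AttributeVector
    starts: list[StartTrace]
    n_simulations: int
    seed: int

    @property
    def params(self) -> IndelParams:
        return IndelParams(ir=self.ir, a=self.a, rl=self.rl)


class _Evaluator:
    """Shared objective: simulate N alignments at a parameter triple and
    return the squared Mahalanobis distance of the target attributes.

    Under common random numbers, the seed of replicate i is a fixed
    function of (cfg.seed, i), independent of the parameters, and
    distances for repeated triples are served from a memo table.
    """

    def __init__(
        self, target: np.ndarray, tree: PhyloTree, cfg: SearchConfig
    ):
        self.target = target
        self.tree = tree
        self.cfg = cfg
        self.n_simulations = 0
        self._fresh_counter = 0
        self._cache: dict[tuple[int, float, float], float] = {}
        if cfg.crn:
            self._seed_seqs = [
                np.random.SeedSequence(entropy=(cfg.seed, _TAG_SEARCH, i))
                for i in range(cfg.n_sims)
            ]

    def _ensemble(
        self, params: IndelParams, n: int, tag: int
    ) -> np.ndarray:
        dist = IndelLengthDistribution.from_params(params)
        attrs = np.empty((n, 5))
        if tag == _TAG_SEARCH and self.cfg.crn:
            seqs = self._seed_seqs
        else:
            base = self._fresh_counter if tag == _TAG_FRESH else 0
            seqs = [
                np.random.SeedSequence(entropy=(self.cfg.seed, tag, base, i))
                for i in range(n)
            ]
        for i, ss in enumerate(seqs):
            rng = np.random.Generator(np.random.PCG64(ss))
            attrs[i] = simulate_attributes(self.tree, params, rng, dist)
        self.n_simulations += n
        return attrs

    def _make_params(self, rl: int, ir: float, a: float) -> IndelParams:
        return IndelParams(
            ir=ir,
            a=a,
            rl=rl,
            max_len=self.cfg.max_indel_len,
            ir_split=self.cfg.ir_split,
        )

    def d2(
        self,
        rl: float,
        ir: float,
        a: float,
        sink: Optional[list[tuple[int, float, float, float]]] = None,
    ) -> float:
        rl_i = int(round(rl))
        key = (rl_i, round(ir, 12), round(a, 12))
        if self.cfg.crn and key in self._cache:
            return self._cache[key]
        if not self.cfg.crn:
            self._fresh_counter += 1
        attrs = self._ensemble(self._make_params(rl_i, ir, a), self.cfg.n_sims, _TAG_SEARCH if self.cfg.crn else _TAG_FRESH)
        moments = ensemble_moments(attrs)
        val = mahalanobis_sq(self.target, moments)
        if self.cfg.crn:
            self._cache[key] = val
        if sink is not None:
            sink.append((rl_i, ir, a, val))
        return val

    def confirm(
        self, rl: int, ir: float, a: float
    ) -> tuple[float, float, EnsembleMoments]:
        n = self.cfg.confirm_factor * self.cfg.n_sims
        attrs = self._ensemble(self._make_params(rl, ir, a), n, _TAG_CONFIRM)
        moments = ensemble_moments(attrs)
        d2 = mahalanobis_sq(self.target, moments)
        return d2, fit_pvalue(d2, v=5), moments


def evaluate_params(
    params: IndelParams,
    target: AttributeVector,
    tree: PhyloTree,
    cfg: SearchConfig,
) -> tuple[float, EnsembleMoments]:
    """Simulate ``cfg.n_sims`` alignments under ``params`` and return
    the squared Mahalanobis distance of ``target`` plus the ensemble
    moments. Under common random numbers the result is a deterministic
    function of (params, cfg.seed)."""
    ev = _Evaluator(target.as_array(), tree, cfg)
    attrs = ev._ensemble(params, cfg.n_sims, _TAG_SEARCH)
    moments = ensemble_moments(attrs)
    return mahalanobis_sq(target.as_array(), moments), moments


def _clamp(x: float, lo: float, hi: float) -> float:
    return min(max(x, lo), hi)


def infer_parameters(
    msa: MSA, tree: PhyloTree, cfg: Optional[SearchConfig] = None
) -> InferenceResult:
    """Infer (IR, a, RL) for an input alignment on a fixed tree.

    Runs the three RL multi-starts, each cycling golden-section searches
    over RL, then IR, then a until the cycle's improvement in D² falls
    below ``cfg.rel_tol`` (relative) or ``cfg.max_cycles`` is reached.
    The best start wins (ties broken by smaller RL), and the reported D²
    and p-value are recomputed at the optimum with a confirmation
    ensemble of ``confirm_factor × n_sims`` fresh simulations.
    """
    if cfg is None:
        cfg = SearchConfig()
    target = compute_attributes(msa)
    x = target.as_array()
    ev = _Evaluator(x, tree, cfg)

    rl_lo, rl_hi = cfg.rl_bounds
    raw_starts = [target.min_seq_len, target.max_seq_len, target.msa_length]
    rl_starts: list[float] = []
    for s in raw_starts:
        s = _clamp(float(s), rl_lo, rl_hi)
        if s not in rl_starts:
            rl_starts.append(s)

    coords = (
        ("rl", cfg.rl_bounds, cfg.tol_rl),
        ("ir", cfg.ir_bounds, cfg.tol_ir),
        ("a", cfg.a_bounds, cfg.tol_a),
    )
    traces: list[StartTrace] = []
    finished: list[dict[str, float]] = []
    tols = {"rl": cfg.tol_rl, "ir": cfg.tol_ir, "a": cfg.tol_a}
    for rl0 in rl_starts:
        state = {"rl": rl0, "ir": cfg.ir_start, "a": cfg.a_start}
        sink: list[tuple[int, float, float, float]] = []
        best = ev.d2(state["rl"], state["ir"], state["a"], sink)
        cycles = 0
        for cycle in range(cfg.max_cycles):
            cycles += 1
            prev = best
            # the first cycle holds RL at its starting value while IR and
            # a adapt to it; re-optimizing RL over the full interval with
            # IR and a still at their generic starts would send all three
            # multi-starts down the same trajectory, defeating their
            # purpose of escaping local minima
            active = coords[1:] if cycle == 0 else coords
            for name, (lo, hi), tol in active:
                if cycle >= 2:
                    # late cycles only refine: search a local window
                    # around the incumbent instead of the full interval
                    w = max(25.0 * tol, 0.02 * (hi - lo))
                    lo = max(lo, state[name] - w)
                    hi = min(hi, state[name] + w)

                def obj(u: float, _name=name) -> float:
                    trial = dict(state)
                    trial[_name] = u
                    return ev.d2(trial["rl"], trial["ir"], trial["a"], sink)

                res = golden_section_1d(obj, lo, hi, tol)
                if res.fx <= best:
                    state[name] = res.x
                    best = res.fx
            if prev - best < cfg.rel_tol * max(prev, 1e-300):
                break
            # a start that has drifted within tolerance of an already
            # finished start will follow the same refinement; stop early
            if any(
                all(abs(state[k] - f[k]) <= 2.0 * tols[k] for k in state)
                for f in finished
            ):
                break
        finished.append(dict(state))
        traces.append(
            StartTrace(
                rl_start=rl0,
                evaluations=sink,
                best=(int(round(state["rl"])), state["ir"], state["a"]),
                d2=best,
                cycles=cycles,
            )
        )

    winner = min(traces, key=lambda t: (t.d2, t.best[0]))
    rl_best, ir_best, a_best = winner.best
    d2_conf, pval, moments = ev.confirm(rl_best, ir_best, a_best)
    return InferenceResult(
        ir=ir_best,
        a=a_best,
        rl=rl_best,
        d2=d2_conf,
        pvalue=pval,
        d2_search=winner.d2,
        moments=moments,
        target=target,
        starts=traces,
        n_simulations=ev.n_simulations,
        seed=cfg.seed,
    )
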