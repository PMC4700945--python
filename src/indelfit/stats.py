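"""MSA summary statistics, ensemble moments, Mahalanobis distance, and
the chi-squared goodness-of-fit p-value.

Five attributes summarize an alignment's indel footprint:

1. MSA length — the number of columns;
2. total number of gap blocks — maximal runs of ``'-'`` within rows,
   summed over rows (a proxy for the number of indel events);
3. average gap block length — total gap characters / total blocks
   (a proxy for the average indel length; 0 when there are no blocks);
4. minimal ungapped sequence length;
5. maximal ungapped sequence length.

The fit of an alignment to a parameter triple is the squared
Mahalanobis distance D² = (x−μ)ᵀ S⁻¹ (x−μ) of its attribute vector x
from the ensemble moments (μ, S) of N simulated alignments, and the
p-value is 1 − CDF_{χ²(v−1)}(D²) with v = 5 attributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np
from scipy import stats as sps

from .io_formats import GAP, MSA

N_ATTRIBUTES = 5
ATTRIBUTE_NAMES = (
    "msa_length",
    "n_gap_blocks",
    "avg_gap_block_len",
    "min_seq_len",
    "max_seq_len",
)

_COND_LIMIT = 1e12
_RIDGE_EPS0 = 1e-8


@dataclass(frozen=True)
class AttributeVector:
    """The five summary statistics of one alignment (v = 5)."""

    msa_length: float
    n_gap_blocks: float
    avg_gap_block_len: float
    min_seq_len: float
    max_seq_len: float

    v = N_ATTRIBUTES

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.msa_length,
                self.n_gap_blocks,
                self.avg_gap_block_len,
                self.min_seq_len,
                self.max_seq_len,
            ],
            dtype=np.float64,
        )

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "AttributeVector":
        x = np.asarray(x, dtype=np.float64)
        if x.shape != (N_ATTRIBUTES,):
            raise ValueError(f"attribute vector must have length {N_ATTRIBUTES}")
        return cls(*map(float, x))


def compute_attributes(msa: MSA) -> AttributeVector:
    """Compute the five-attribute summary of an alignment.

    Gap blocks are maximal runs of ``'-'`` within each row, totaled over
    rows; the average block length is total gap characters over total
    blocks (0 for a gapless alignment).
    """
    gap_byte = ord(GAP)
    ncol = msa.n_cols
    n_blocks = 0
    n_gap_chars = 0
    lengths = []
    for row in msa.rows:
        arr = np.frombuffer(row.encode("ascii"), dtype=np.uint8) == gap_byte
        gaps = int(arr.sum())
        n_gap_chars += gaps
        lengths.append(ncol - gaps)
        if gaps:
            # a block starts where a gap is not preceded by a gap
            starts = int(arr[0]) + int(np.count_nonzero(arr[1:] & ~arr[:-1]))
            n_blocks += starts
    avg = n_gap_chars / n_blocks if n_blocks else 0.0
    return AttributeVector(
        msa_length=float(ncol),
        n_gap_blocks=float(n_blocks),
        avg_gap_block_len=float(avg),
        min_seq_len=float(min(lengths)),
        max_seq_len=float(max(lengths)),
    )


@dataclass(frozen=True)
class EnsembleMoments:
    """Mean vector and covariance of N simulated attribute vectors.

    ``ridge`` records the diagonal regularization (if any) applied to
    make the covariance invertible; it is 0 for well-conditioned
    ensembles.
    """

    mu: np.ndarray
    S: np.ndarray
    n: int
    ridge: float = 0.0

    @property
    def v(self) -> int:
        return self.mu.shape[0]


def ensemble_moments(
    attrs: Union[np.ndarray, Iterable[AttributeVector]],
) -> EnsembleMoments:
    """Mean and unbiased sample covariance of an attribute ensemble.

    If the covariance is singular or its condition number exceeds 1e12
    (near-collinear attributes are common, e.g. min/max length under
    tiny indel rates), a ridge ``ε·tr(S)/v·I`` is added with ε = 1e−8,
    escalating tenfold until the matrix is comfortably invertible.
    """
    if not isinstance(attrs, np.ndarray):
        attrs = np.array(
            [a.as_array() if isinstance(a, AttributeVector) else a for a in attrs]
        )
    attrs = np.asarray(attrs, dtype=np.float64)
    if attrs.ndim != 2:
        raise ValueError("expected a 2-D array of attribute vectors")
    n = attrs.shape[0]
    if n < 2:
        raise ValueError("at least 2 attribute vectors are required")
    mu = attrs.mean(axis=0)
    S = np.cov(attrs, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    v = S.shape[0]
    ridge = 0.0
    if not _well_conditioned(S):
        scale = np.trace(S) / v
        if scale <= 0.0:
            scale = 1.0  # zero covariance: fall back to unit ridge scale
        eps = _RIDGE_EPS0
        while True:
            candidate = S + eps * scale * np.eye(v)
            if _well_conditioned(candidate):
                S = candidate
                ridge = eps * scale
                break
            eps *= 10.0
    return EnsembleMoments(mu=mu, S=S, n=n, ridge=ridge)


def _well_conditioned(S: np.ndarray) -> bool:
    try:
        eig = np.linalg.eigvalsh(S)
    except np.linalg.LinAlgError:
        return False
    if eig[-1] <= 0.0:
        return False
    return eig[0] > 0.0 and eig[-1] / eig[0] < _COND_LIMIT


def mahalanobis_sq(
    x: Union[AttributeVector, np.ndarray], m: EnsembleMoments
) -> float:
    """Squared Mahalanobis distance (x−μ)ᵀ S⁻¹ (x−μ).

    This quadratic form is the statistic fed to the chi-squared fit
    test; the (unsquared) distance is only ever its square root for
    display.
    """
    if isinstance(x, AttributeVector):
        x = x.as_array()
    x = np.asarray(x, dtype=np.float64)
    if x.shape != m.mu.shape:
        raise ValueError(
            f"dimension mismatch: x has shape {x.shape}, mu {m.mu.shape}"
        )
    d = x - m.mu
    z = np.linalg.solve(m.S, d)
    return float(max(d @ z, 0.0))


def fit_pvalue(d2: float, v: int = N_ATTRIBUTES) -> float:
    """Goodness-of-fit p-value: 1 − CDF_{χ²(v−1)}(D²).

    A small p-value means the observed attribute vector is unlikely to
    come from the multivariate distribution of the simulated ensemble,
    i.e. the assumed indel model misses some aspect of the data.
    """
    if d2 < 0:
        raise ValueError("squared distance must be >= 0")
    if v < 2:
        raise ValueError("need at least 2 summary statistics")
    return float(sps.chi2.sf(d2, df=v - 1))
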