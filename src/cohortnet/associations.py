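"""Pairwise dependence estimation with permutation-test significance.

All statistics are computed on pairwise-complete observations: exactly the
subjects with both values present for the pair at hand. Mutual information is
the plug-in (histogram) estimate

    I(X;Y) = sum_ij p(i,j) log[ p(i,j) / (p_x(i) p_y(j)) ]

with p(i,j) = n(i,j)/N from joint bin counts; it is reported in **nats**.
Continuous variables are partitioned into equal-width bins over the observed
pairwise-complete range; discrete (binary / categorical / ordinal) variables
use their observed levels as bins. Cells with n(i,j) = 0 contribute 0.

Normalized mutual information uses the geometric-mean form
NMI = I(X;Y) / sqrt(H(X) H(Y)) on the same binning, clipped to [0, 1], and is
defined as 0 when either marginal entropy is 0.

Significance is assessed by permuting one variable over the pairwise-complete
rows and recomputing the statistic; the p-value uses the add-one estimator
p = (1 + #{permuted >= observed}) / (1 + n_perm), one-tailed for MI
(dependence only) and two-tailed (on |r|) for Pearson.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import derive_seed
from .synthetic import CohortTable

__all__ = [
    "AssociationResult",
    "InsufficientDataError",
    "UndefinedCorrelationError",
    "pairwise_complete",
    "default_n_bins",
    "mutual_information_binned",
    "normalized_mi",
    "pearson",
    "permutation_pvalue",
    "pair_association",
    "association_table",
]

_TIE_EPS = 1e-12  # float-safe ">=" in permutation counts


class InsufficientDataError(ValueError):
    """Fewer than two pairwise-complete observations."""


class UndefinedCorrelationError(ValueError):
    """Pearson correlation requested for a constant vector."""


@dataclass(frozen=True)
class AssociationResult:
    """All pair statistics for one variable pair (symmetric in the pair)."""

    var_a: str
    var_b: str
    n_complete: int
    mi: float  # nats
    nmi: float
    r: float
    p_mi: float
    p_r: float


def pairwise_complete(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Rows where both values are present, as float arrays."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def default_n_bins(n_complete: int) -> int:
    """Default bin count for continuous variables: ceil(sqrt(n/5)), in [2, 10]."""
    return int(min(10, max(2, math.ceil(math.sqrt(n_complete / 5)))))


def _codes(v: np.ndarray, discrete: bool, n_bins: int) -> tuple[np.ndarray, int]:
    """Map values to integer bin codes; constant input maps to one bin."""
    if discrete:
        _, codes = np.unique(v, return_inverse=True)
        return codes, int(codes.max()) + 1
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        return np.zeros(len(v), dtype=np.intp), 1
    # equal-width bins over the observed range; right edge closed
    codes = np.minimum((n_bins * (v - lo) / (hi - lo)).astype(np.intp), n_bins - 1)
    return codes, n_bins


def _contingency(ix: np.ndarray, iy: np.ndarray, kx: int, ky: int) -> np.ndarray:
    return np.bincount(ix * ky + iy, minlength=kx * ky).reshape(kx, ky).astype(float)


def _mi_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p / (px * py)), 0.0)
    return float(terms.sum())


def _entropy_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def _prepare_codes(
    x: Sequence[float],
    y: Sequence[float],
    n_bins: int | None,
    discrete: tuple[bool, bool],
) -> tuple[np.ndarray, np.ndarray, int, int]:
    xc, yc = pairwise_complete(x, y)
    if len(xc) < 2:
        raise InsufficientDataError(
            f"need >= 2 pairwise-complete observations, got {len(xc)}"
        )
    nb = n_bins if n_bins is not None else default_n_bins(len(xc))
    ix, kx = _codes(xc, discrete[0], nb)
    iy, ky = _codes(yc, discrete[1], nb)
    return ix, iy, kx, ky


def mutual_information_binned(
    x: Sequence[float],
    y: Sequence[float],
    n_bins: int | None = None,
    discrete: tuple[bool, bool] = (False, False),
) -> float:
    """Plug-in binned mutual information in nats (>= 0; 0 for constant input)."""
    ix, iy, kx, ky = _prepare_codes(x, y, n_bins, discrete)
    return max(0.0, _mi_from_counts(_contingency(ix, iy, kx, ky)))


def normalized_mi(
    x: Sequence[float],
    y: Sequence[float],
    n_bins: int | None = None,
    discrete: tuple[bool, bool] = (False, False),
) -> float:
    """Geometric-mean normalized MI, I / sqrt(HxHy), clipped to [0, 1]."""
    ix, iy, kx, ky = _prepare_codes(x, y, n_bins, discrete)
    counts = _contingency(ix, iy, kx, ky)
    hx = _entropy_from_counts(counts.sum(axis=1))
    hy = _entropy_from_counts(counts.sum(axis=0))
    if hx <= 0.0 or hy <= 0.0:
        return 0.0
    return float(np.clip(_mi_from_counts(counts) / math.sqrt(hx * hy), 0.0, 1.0))


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation on pairwise-complete rows, in [-1, 1]."""
    xc, yc = pairwise_complete(x, y)
    if len(xc) < 2:
        raise InsufficientDataError(
            f"need >= 2 pairwise-complete observations, got {len(xc)}"
        )
    xd = xc - xc.mean()
    yd = yc - yc.mean()
    denom = math.sqrt(float(xd @ xd) * float(yd @ yd))
    if denom == 0.0:
        raise UndefinedCorrelationError("constant vector has no correlation")
    return float(np.clip(xd @ yd / denom, -1.0, 1.0))


# ---------------------------------------------------------------------------
# permutation tests


def _perm_matrix(v: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    m = np.broadcast_to(v, (n_perm, len(v))).copy()
    return rng.permuted(m, axis=1)


def _mi_null(
    ix: np.ndarray, iy: np.ndarray, kx: int, ky: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised null distribution of the binned MI under row permutation."""
    n = len(ix)
    perm = _perm_matrix(iy.astype(np.intp), n_perm, rng)
    flat = ix[None, :] * ky + perm
    idx = (np.arange(n_perm, dtype=np.intp)[:, None] * (kx * ky) + flat).ravel()
    counts = (
        np.bincount(idx, minlength=n_perm * kx * ky)
        .reshape(n_perm, kx, ky)
        .astype(float)
    )
    p = counts / n
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p / (px * py)), 0.0)
    return terms.sum(axis=(1, 2))


def _pearson_null(
    xc: np.ndarray, yc: np.ndarray, n_perm: int, rng: np.random.Generator
) -> tuple[float, np.ndarray]:
    xd = xc - xc.mean()
    yd = yc - yc.mean()
    denom = math.sqrt(float(xd @ xd) * float(yd @ yd))
    if denom == 0.0:
        raise UndefinedCorrelationError("constant vector has no correlation")
    obs = float(xd @ yd / denom)
    null = _perm_matrix(yd, n_perm, rng) @ xd / denom
    return obs, null


def permutation_pvalue(
    stat: str | Callable[[np.ndarray, np.ndarray], float],
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 1000,
    tails: str | None = None,
    seed: int = 0,
    n_bins: int | None = None,
    discrete: tuple[bool, bool] = (False, False),
) -> float:
    """Permutation p-value for a pair statistic.

    ``stat`` is ``"mi"`` (one-tailed by default), ``"pearson"`` (two-tailed by
    default) or any callable of two complete vectors. y is permuted over the
    pairwise-complete rows ``n_perm`` times; the add-one estimator
    (1 + #{null >= obs}) / (1 + n_perm) guarantees p > 0. Deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    if stat == "mi":
        tails = tails or "one"
        ix, iy, kx, ky = _prepare_codes(x, y, n_bins, discrete)
        obs = _mi_from_counts(_contingency(ix, iy, kx, ky))
        null = _mi_null(ix, iy, kx, ky, n_perm, rng)
    elif stat == "pearson":
        tails = tails or "two"
        xc, yc = pairwise_complete(x, y)
        if len(xc) < 2:
            raise InsufficientDataError("need >= 2 pairwise-complete observations")
        obs, null = _pearson_null(xc, yc, n_perm, rng)
    else:
        if not callable(stat):
            raise ValueError(f"unknown statistic {stat!r}")
        tails = tails or "one"
        xc, yc = pairwise_complete(x, y)
        obs = float(stat(xc, yc))
        null = np.array([float(stat(xc, rng.permutation(yc))) for _ in range(n_perm)])
    if tails == "two":
        exceed = np.abs(null) >= abs(obs) - _TIE_EPS
    elif tails == "one":
        exceed = null >= obs - _TIE_EPS
    else:
        raise ValueError(f"tails must be 'one' or 'two', got {tails!r}")
    return float((1 + int(exceed.sum())) / (1 + n_perm))


def pair_association(
    x: Sequence[float],
    y: Sequence[float],
    var_a: str = "x",
    var_b: str = "y",
    n_bins: int | None = None,
    discrete: tuple[bool, bool] = (False, False),
    n_perm: int = 1000,
    seed: int = 0,
) -> AssociationResult:
    """MI, NMI, Pearson and both permutation p-values for one pair.

    Pearson quantities are NaN when either vector is constant on the
    pairwise-complete rows.
    """
    xc, yc = pairwise_complete(x, y)
    if len(xc) < 2:
        raise InsufficientDataError("need >= 2 pairwise-complete observations")
    ix, iy, kx, ky = _prepare_codes(x, y, n_bins, discrete)
    counts = _contingency(ix, iy, kx, ky)
    mi = max(0.0, _mi_from_counts(counts))
    hx = _entropy_from_counts(counts.sum(axis=1))
    hy = _entropy_from_counts(counts.sum(axis=0))
    nmi = float(np.clip(mi / math.sqrt(hx * hy), 0.0, 1.0)) if hx > 0 and hy > 0 else 0.0
    rng_mi = np.random.default_rng(derive_seed(seed, "mi", var_a, var_b))
    null_mi = _mi_null(ix, iy, kx, ky, n_perm, rng_mi)
    p_mi = float((1 + int((null_mi >= mi - _TIE_EPS).sum())) / (1 + n_perm))
    try:
        rng_r = np.random.default_rng(derive_seed(seed, "r", var_a, var_b))
        r, null_r = _pearson_null(xc, yc, n_perm, rng_r)
        p_r = float((1 + int((np.abs(null_r) >= abs(r) - _TIE_EPS).sum())) / (1 + n_perm))
    except UndefinedCorrelationError:
        r, p_r = float("nan"), float("nan")
    return AssociationResult(
        var_a=var_a, var_b=var_b, n_complete=len(xc),
        mi=mi, nmi=nmi, r=float(np.clip(r, -1, 1)) if not math.isnan(r) else r,
        p_mi=p_mi, p_r=p_r,
    )


def association_table(
    table: CohortTable,
    pairs: Iterable[tuple[str, str]] | None = None,
    n_bins: int | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    min_complete: int = 2,
) -> pd.DataFrame:
    """Association statistics for variable pairs of a cohort table.

    ``pairs`` defaults to all unordered pairs. Pairs with fewer than
    ``min_complete`` pairwise-complete subjects are skipped. Columns:
    var_a, var_b, layer_a, layer_b, n_complete, mi, nmi, r, p_mi, p_r.
    """
    if pairs is None:
        varnames = table.variables()
        pairs = [
            (varnames[i], varnames[j])
            for i in range(len(varnames))
            for j in range(i + 1, len(varnames))
        ]
    rows = []
    for a, b in pairs:
        xa = table.data[a].to_numpy(dtype=float)
        xb = table.data[b].to_numpy(dtype=float)
        xc, _ = pairwise_complete(xa, xb)
        if len(xc) < max(2, min_complete):
            continue
        res = pair_association(
            xa, xb, var_a=a, var_b=b, n_bins=n_bins,
            discrete=(table.is_discrete(a), table.is_discrete(b)),
            n_perm=n_perm, seed=seed,
        )
        rows.append(
            (a, b, table.layer_of(a), table.layer_of(b), res.n_complete,
             res.mi, res.nmi, res.r, res.p_mi, res.p_r)
        )
    return pd.DataFrame(
        rows,
        columns=["var_a", "var_b", "layer_a", "layer_b", "n_complete",
                 "mi", "nmi", "r", "p_mi", "p_r"],
    )
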