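"""Adaptive rank truncated product (ARTP) resampling engine.

ARTP aggregates association evidence across q correlated components
(SNPs within a gene, or genes within a pathway) against the global null
that no component is associated with the outcome.  For each candidate
truncation threshold c_k it forms the negative-log-product statistic
over the c_k smallest component p-values, converts each statistic to an
empirical p-value against M null replicates, takes the minimum of those
empirical p-values over thresholds (the minP statistic), and calibrates
the minP statistic against the same replicates.

All empirical p-values are counting quantities on the grid
{0, 1, ..., M}/(M+1); comparisons are carried out with leave-self-out
tie-inclusive counting, never with an analytic approximation.  The
replicate-level minP p-values are returned alongside the observed one
so that a higher aggregation level (gene -> pathway) can reuse the same
M replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ArtpConfig",
    "ArtpResult",
    "artp",
    "batched_artp_taus",
    "default_gene_thresholds",
    "default_snp_thresholds",
    "empirical_pvalues",
    "floor_pvalues",
    "nlp_statistics",
    "replicate_minp_pvalues",
]

#: Minimum number of null replicates; below this the p-value grid
#: 1/(M+1) is too coarse for a meaningful test.
MIN_REPLICATES = 100


def default_snp_thresholds(q: int) -> np.ndarray:
    """SNP-level truncation points: c = (1, 2), capped at q."""
    return np.unique(np.minimum([1, 2], max(q, 1)))


def default_gene_thresholds(n_genes: int, n_points: int = 10) -> np.ndarray:
    """Gene-level truncation points d_k = k * max(1, ceil(J/20)).

    K' = 10 points by default, capped at J and deduplicated.
    """
    step = max(1, int(np.ceil(n_genes / 20)))
    d = step * np.arange(1, n_points + 1)
    return np.unique(np.minimum(d, max(n_genes, 1)))


@dataclass
class ArtpConfig:
    """Settings for one ARTP run.

    Parameters
    ----------
    thresholds
        Strictly increasing truncation points c_1 < ... < c_K.  Values
        exceeding the component count are capped and deduplicated at
        run time.
    n_replicates
        Number M of null replicas of the component p-value vector.
    seed
        Master seed recorded for provenance; the engine itself is
        deterministic given its inputs, randomness lives upstream.
    """

    thresholds: np.ndarray = field(default_factory=lambda: np.array([1, 2]))
    n_replicates: int = 10_000
    seed: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=int)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("thresholds must be a non-empty 1-D sequence")
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be strictly increasing positive integers")
        self.thresholds = t
        if self.n_replicates < MIN_REPLICATES:
            raise ValueError(
                f"n_replicates must be >= {MIN_REPLICATES}; the empirical "
                f"p-value grid 1/(M+1) is otherwise too coarse"
            )


@dataclass
class ArtpResult:
    """Outcome of one ARTP run.

    ``tau`` holds the observed minP p-value at index 0 followed by the
    M replicate-level minP p-values, all on the grid {0..M}/(M+1).
    """

    p0: np.ndarray
    thresholds: np.ndarray
    w0: np.ndarray
    xi0: np.ndarray
    minp0: float
    tau: np.ndarray
    best_threshold_index: int
    selected_components: np.ndarray

    @property
    def tau0(self) -> float:
        """The calibrated p-value of the observed minP statistic."""
        return float(self.tau[0])

    @property
    def tau_m(self) -> np.ndarray:
        """Replicate minP p-values: null replicas of ``tau0``."""
        return self.tau[1:]

    @property
    def best_threshold(self) -> int:
        return int(self.thresholds[self.best_threshold_index])


def floor_pvalues(p: np.ndarray, n_replicates: int) -> np.ndarray:
    """Replace empirical p-values of exactly 0 by half a grid step.

    Counting p-values #/(M+1) can be exactly 0; -log 0 is infinite, so
    a half-grid floor 0.5/(M+1) is applied before any log transform at
    the next aggregation level.  Ordering among the floored values is
    preserved because 0 is the unique minimum of the grid.
    """
    return np.maximum(np.asarray(p, dtype=float), 0.5 / (n_replicates + 1))


def nlp_statistics(p: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Negative-log-product statistics w_k = -sum of the c_k smallest log p.

    Parameters
    ----------
    p
        Component p-values, shape (q,) or (R, q) for R stacked vectors
        (row 0 conventionally the observed vector).
    thresholds
        Truncation points c_k, each <= q after capping by the caller.

    Returns
    -------
    Array of shape (K,) or (R, K).
    """
    arr = np.asarray(p, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[None, :]
    if np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("component p-values must lie in (0, 1]")
    t = np.asarray(thresholds, dtype=int)
    if np.any(t > arr.shape[1]):
        raise ValueError("truncation threshold exceeds component count")
    nl = -np.log(np.sort(arr, axis=1))
    w = np.cumsum(nl, axis=1)[:, t - 1]
    return w[0] if squeeze else w


def _count_less(a: np.ndarray) -> np.ndarray:
    """Per column: number of elements strictly less than each element.

    Ties share the count of their first sorted occurrence, which is
    exactly the strictly-less count; one stable argsort plus a running
    maximum, fully vectorized over columns.
    """
    R, C = a.shape
    sidx = np.argsort(a, axis=0, kind="stable")
    srt = np.take_along_axis(a, sidx, axis=0)
    newgrp = np.ones((R, C), dtype=bool)
    newgrp[1:] = srt[1:] != srt[:-1]
    idx = np.broadcast_to(np.arange(R, dtype=np.int64)[:, None], (R, C)).copy()
    idx[~newgrp] = 0
    np.maximum.accumulate(idx, axis=0, out=idx)
    out = np.empty((R, C), dtype=np.int64)
    np.put_along_axis(out, sidx, idx, axis=0)
    return out


def empirical_pvalues(w: np.ndarray) -> np.ndarray:
    """Leave-self-out empirical p-values for stacked NLP statistics.

    Row 0 of ``w`` is the observed statistic vector and rows 1..M the
    replicates.  For every row j and threshold k the empirical p-value
    is #{j' != j : w[j', k] >= w[j, k]} / (M + 1): ties count, larger
    statistics are more significant, and each row is excluded from its
    own reference set.  Row 0's value coincides with the textbook
    definition #{m in 1..M : w_m >= w_0}/(M+1).
    """
    w = np.asarray(w, dtype=float)
    if w.ndim != 2:
        raise ValueError("w must be 2-D (replicates x thresholds)")
    if np.any(~np.isfinite(w)):
        raise ValueError("non-finite NLP statistic encountered")
    n_rows = w.shape[0]
    # rows >= self excluding self: (n_rows - n_less) counts self once
    return (n_rows - 1 - _count_less(w)) / n_rows


def replicate_minp_pvalues(T: np.ndarray) -> np.ndarray:
    """Leave-self-out p-values of the minP statistics T_0..T_M.

    Small T is significant, so for each j the p-value is
    #{j' != j : T[j'] <= T[j]} / (M + 1), ties included.  Index 0 gives
    the calibrated p-value of the observed minP statistic; indices
    1..M are simulated instances of it under the null, reused by the
    next aggregation level.
    """
    T = np.asarray(T, dtype=float)
    if T.ndim != 1:
        raise ValueError("T must be 1-D")
    n_rows = T.shape[0]
    order = np.sort(T)
    n_le = np.searchsorted(order, T, side="right")
    return (n_le - 1) / n_rows


def batched_artp_taus(
    p_stack: np.ndarray, component_cols: Sequence[np.ndarray],
    thresholds: np.ndarray,
) -> tuple[np.ndarray, list[np.ndarray], list[int]]:
    """Run ARTP for many component sets sharing one replicate stack.

    ``p_stack`` is (M+1) x P with the observed p-values in row 0;
    ``component_cols[g]`` indexes the columns belonging to set g (a
    gene's SNPs, typically).  Equivalent to calling :func:`artp` per
    set, but the empirical-p-value counting for all sets and
    thresholds runs in one vectorized pass.

    Returns (tau, xi0_list, best_index_list) where tau is (M+1) x G
    with row 0 the observed minP p-values.
    """
    R = p_stack.shape[0]
    w_cols: list[np.ndarray] = []
    starts: list[int] = []
    for cols in component_cols:
        thr = np.unique(np.minimum(np.asarray(thresholds, dtype=int), cols.size))
        nl = -np.log(np.sort(p_stack[:, cols], axis=1))
        starts.append(sum(w.shape[1] for w in w_cols))
        w_cols.append(np.cumsum(nl, axis=1)[:, thr - 1])
    W = np.concatenate(w_cols, axis=1)
    xi = (R - 1 - _count_less(W)) / R
    T = np.minimum.reduceat(xi, np.asarray(starts), axis=1)
    tau = (R - 1 - _count_less(-T)) / R
    xi0_list, best = [], []
    for g, s in enumerate(starts):
        e = starts[g + 1] if g + 1 < len(starts) else W.shape[1]
        xi0_list.append(xi[0, s:e])
        best.append(int(np.argmin(xi[0, s:e])))
    return tau, xi0_list, best


def artp(p0: np.ndarray, null_p: np.ndarray, config: ArtpConfig) -> ArtpResult:
    """Run the full ARTP procedure for one component set.

    Parameters
    ----------
    p0
        Observed component p-values, shape (q,), each in (0, 1].
    null_p
        M x q matrix of null replicas of ``p0``, columns aligned with
        ``p0`` and generated upstream under the global null.
    config
        Thresholds and replicate count; ``config.n_replicates`` must
        match the number of rows of ``null_p``.

    Returns
    -------
    ArtpResult with the calibrated minP p-value, per-threshold
    empirical p-values, replicate-level minP p-values and the selected
    component subset at the best threshold.
    """
    p0 = np.asarray(p0, dtype=float)
    null_p = np.asarray(null_p, dtype=float)
    if null_p.ndim != 2 or null_p.shape[1] != p0.shape[0]:
        raise ValueError("null_p must be M x q with columns aligned to p0")
    if np.any(~np.isfinite(null_p)) or np.any(~np.isfinite(p0)):
        raise ValueError("NaN/inf in ARTP inputs")
    M = null_p.shape[0]
    if M < MIN_REPLICATES:
        raise ValueError(f"need at least {MIN_REPLICATES} null replicates, got {M}")
    q = p0.shape[0]
    thresholds = np.unique(np.minimum(config.thresholds, q))
    stacked = np.vstack([p0[None, :], null_p])
    w = nlp_statistics(stacked, thresholds)
    xi = empirical_pvalues(w)
    T = xi.min(axis=1)
    tau = replicate_minp_pvalues(T)
    best_k = int(np.argmin(xi[0]))
    c_best = int(thresholds[best_k])
    selected = np.argsort(p0, kind="stable")[:c_best]
    return ArtpResult(
        p0=p0,
        thresholds=thresholds,
        w0=w[0],
        xi0=xi[0],
        minp0=float(T[0]),
        tau=tau,
        best_threshold_index=best_k,
        selected_components=selected,
    )
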