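"""LD estimation from reference panels and null z-score covariance.

Under the global null the vector of GWAS z-scores for SNPs in a gene is
approximately multivariate normal with covariance equal to the genotype
correlation matrix of those SNPs in the study population.  That matrix
is estimated here from a per-ancestry reference panel, repaired to
positive definiteness, and used as the covariance V^(l) for the null
z-score replicates.  When the IVW statistic is used, the covariance of
the combined statistics can be assembled directly across ancestries
(cov(s_i, s_i') = sum_l w_i^(l) w_i'^(l) cov(z_i^(l), z_i'^(l))),
avoiding per-ancestry sampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["LdMatrix", "estimate_ld", "ivw_stat_cov", "regularize_correlation", "zscore_null_cov"]


@dataclass
class LdMatrix:
    """Pairwise genotype correlations for an ordered set of SNPs."""

    ancestry_label: str
    snp_ids: list[str]
    R: np.ndarray
    shrinkage_applied: float = 0.0

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        if R.shape != (len(self.snp_ids), len(self.snp_ids)):
            raise ValueError("R must be square and aligned with snp_ids")
        if not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("R must be symmetric")
        if np.any(np.abs(R) > 1 + 1e-10):
            raise ValueError("correlations must lie in [-1, 1]")
        self.R = R


def _pairwise_complete_corr(g: np.ndarray) -> np.ndarray:
    """Pearson correlation of columns using pairwise-complete rows.

    ``g`` is individuals x SNPs with NaN marking missing genotypes.
    Each pairwise correlation uses every individual observed at both
    SNPs; with complete data this is exactly ``np.corrcoef``.
    """
    if g.shape[1] == 1:
        return np.ones((1, 1))
    finite = np.isfinite(g)
    if finite.all():
        return np.corrcoef(g, rowvar=False)
    x = np.where(finite, g, 0.0)
    m = finite.astype(float)
    n = m.T @ m
    sx = x.T @ m
    sxx = (x * x).T @ m
    sxy = x.T @ x
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy / n - (sx / n) * (sx.T / n)
        var = sxx / n - (sx / n) ** 2
        r = cov / np.sqrt(var * var.T)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def regularize_correlation(R: np.ndarray, eps0: float = 1e-8) -> tuple[np.ndarray, float]:
    """Repair a correlation matrix to positive definiteness.

    Adds ``eps`` to the diagonal, doubling from ``eps0`` until a
    Cholesky factorization succeeds, then renormalizes the diagonal
    back to exactly 1 (a congruence, so definiteness is preserved).
    Returns the repaired matrix and the eps finally applied (0 when the
    input already admitted a Cholesky factorization).
    """
    R = np.asarray(R, dtype=float)
    eps = 0.0
    work = R.copy()
    trial = eps0
    while True:
        try:
            np.linalg.cholesky(work)
            break
        except np.linalg.LinAlgError:
            eps = trial
            work = R + eps * np.eye(R.shape[0])
            trial *= 2.0
            if eps > 1.0:
                raise np.linalg.LinAlgError(
                    "correlation matrix could not be repaired to positive definite"
                )
    if eps > 0.0:
        d = 1.0 / np.sqrt(np.diag(work))
        work = work * np.outer(d, d)
        np.fill_diagonal(work, 1.0)
        # renormalization can nudge the smallest eigenvalue back below
        # zero in pathological cases; verify and retry with a larger eps
        try:
            np.linalg.cholesky(work)
        except np.linalg.LinAlgError:
            return regularize_correlation(R, eps0=trial)
    return work, eps


def estimate_ld(panel, snp_ids: Sequence[str], regularize: bool = True) -> LdMatrix:
    """Estimate the LD correlation matrix for ``snp_ids`` from a panel.

    SNPs absent from the panel, or monomorphic among the panel
    individuals (undefined correlation), are dropped with a warning.
    Missing genotypes are handled by pairwise-complete correlation.

    Parameters
    ----------
    panel
        A ``gwas_io.ReferencePanel``.
    snp_ids
        SNPs requested, in the order the returned matrix should use.
    regularize
        Repair the matrix to positive definiteness (default).  Disable
        only to inspect the raw empirical correlations.
    """
    if panel.n_individuals < 2:
        raise ValueError("need at least 2 reference individuals to estimate LD")
    pos = {s: i for i, s in enumerate(panel.snp_index["snp"])}
    keep: list[str] = []
    cols: list[int] = []
    for s in snp_ids:
        if s not in pos:
            logger.warning("SNP %s absent from %s panel; dropped", s, panel.ancestry_label)
            continue
        keep.append(s)
        cols.append(pos[s])
    g = panel.dosages(cols)
    with np.errstate(invalid="ignore"):
        var = np.nanvar(g, axis=0)
    poly = var > 0
    if not poly.all():
        for s in np.asarray(keep)[~poly]:
            logger.warning(
                "SNP %s monomorphic in %s panel; dropped from LD matrix",
                s, panel.ancestry_label,
            )
        keep = [s for s, ok in zip(keep, poly) if ok]
        g = g[:, poly]
    if not keep:
        raise ValueError("no polymorphic panel SNPs among those requested")
    R = _pairwise_complete_corr(g)
    eps = 0.0
    if regularize:
        R, eps = regularize_correlation(R)
    return LdMatrix(panel.ancestry_label, keep, R, shrinkage_applied=eps)


def zscore_null_cov(ld: LdMatrix) -> np.ndarray:
    """Null covariance V^(l) of the z-score vector for one ancestry.

    The standard summary-statistic approximation equates the null
    z-score correlation with the genotype correlation, so V^(l) is the
    (regularized) LD matrix itself.
    """
    V, _ = regularize_correlation(ld.R)
    return V


def ivw_stat_cov(
    lds: Sequence[LdMatrix], weights: Sequence[np.ndarray]
) -> np.ndarray:
    """Null covariance of the IVW statistics across L ancestries.

    ``lds[l]`` is that ancestry's LD matrix over the q SNPs of a gene
    (or cluster) and ``weights[l]`` the aligned IVW weight vector, with
    0 entries for SNPs missing from that study.  The entries are
    cov(s_i, s_i') = sum_l w_i^(l) w_i'^(l) V^(l)_{i i'}.
    """
    if len(lds) != len(weights):
        raise ValueError("need one weight vector per ancestry")
    q = len(lds[0].snp_ids)
    C = np.zeros((q, q))
    for ld, w in zip(lds, weights):
        w = np.asarray(w, dtype=float)
        if ld.R.shape != (q, q) or w.shape != (q,):
            raise ValueError("LD matrix / weight vector dimension mismatch")
        C += np.outer(w, w) * ld.R
    return C
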