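"""End-to-end trans-ancestry pathway analysis strategies.

Given per-ancestry summary statistics, reference panels, and a
SNP-to-gene assignment for one pathway, this module runs:

* SNP-centric tests (SNP-IVW, SNP-max, SNP-wFisher): per-SNP evidence
  is combined across ancestries first, aggregated to genes by ARTP,
  then to the pathway by a second ARTP pass;
* gene-centric tests (Gene-wFisher, Gene-minP): ARTP gene p-values are
  computed within each ancestry and combined across ancestries at the
  gene level before the pathway ARTP pass;
* single-ancestry ARTP per population (Path-<label>) and their
  weighted-Fisher combination (Path-joint);
* the ACAT composite of SNP-IVW and Gene-wFisher.

All strategies share one set of M multivariate-normal null z-score
replicates per ancestry, drawn from the LD-derived covariance V^(l),
with SNPs from correlated genes drawn jointly; the replicate-level minP
p-values of each ARTP level feed the next level, so a single pool of
replicates calibrates the whole hierarchy.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from tapa import artp_engine, stat_combine
from tapa.artp_engine import (
    default_gene_thresholds,
    default_snp_thresholds,
    empirical_pvalues,
    floor_pvalues,
    nlp_statistics,
    replicate_minp_pvalues,
)
from tapa.gwas_io import GeneSnpMap, ReferencePanel, StudySummary
from tapa.ld_reference import estimate_ld, regularize_correlation
from tapa.stat_combine import EffectiveSampleSizes, acat_combine, two_sided_p

__all__ = [
    "GeneCluster",
    "PathwayAnalyzer",
    "PathwayResult",
    "acat_composite",
    "gene_centric_gene_p",
    "path_joint",
    "pathway_p",
    "sample_null_z",
    "snp_centric_gene_p",
]

SNP_CENTRIC = ("SNP-IVW", "SNP-max", "SNP-wFisher")
GENE_CENTRIC = ("Gene-wFisher", "Gene-minP")
ALL_METHODS = SNP_CENTRIC + GENE_CENTRIC + ("Path-joint", "ACAT-IVW-wFisher")


@dataclass
class PathwayResult:
    """One method's verdict on one pathway."""

    pathway_name: str
    method: str
    p_value: float
    J_effective: int
    n_replicates: int
    seed: int | None = None
    gene_pvalues: dict[str, float] = field(default_factory=dict)
    selected_genes: list[str] = field(default_factory=list)
    best_threshold: int | None = None


@dataclass
class GeneCluster:
    """Genes whose SNP z-scores are drawn jointly.

    Two genes share a cluster when they share a SNP or when any
    cross-gene SNP pair exceeds the correlation threshold in any
    ancestry; clusters are the connected components of that relation.
    """

    genes: list[str]
    snp_indices: np.ndarray  # into the union SNP list


def _child_rng(seed: int, *keys: str | int) -> np.random.Generator:
    """Deterministic child RNG independent of evaluation order."""
    entropy = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        entropy.append(zlib.crc32(str(k).encode()))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def sample_null_z(
    covs: Mapping[str, np.ndarray], n_replicates: int, seed: int
) -> dict[str, np.ndarray]:
    """Draw M null z-score replicates per ancestry from N(0, V^(l)).

    Draws are independent across ancestries and deterministic under
    ``seed`` (independent of dict iteration order).  Each V must be
    positive definite after regularization; failure is fatal.
    """
    out: dict[str, np.ndarray] = {}
    for label in covs:
        V, _ = regularize_correlation(np.asarray(covs[label], dtype=float))
        chol = np.linalg.cholesky(V)
        rng = _child_rng(seed, label)
        out[label] = rng.standard_normal((n_replicates, V.shape[0])) @ chol.T
    return out


def path_joint(
    sa_pathway_p: Sequence[float], ess: EffectiveSampleSizes, available=None
) -> float:
    """Weighted-Fisher combination of single-ancestry pathway p-values."""
    return stat_combine.wfisher_combine(sa_pathway_p, ess, available).p


def acat_composite(p_snp_ivw: float, p_gene_wfisher: float,
                   n_replicates: int | None = None) -> float:
    """Equal-weight ACAT of the SNP-IVW and Gene-wFisher p-values.

    Resampling p-values of exactly 0 are floored to half a grid step
    first when the replicate count is supplied.
    """
    p = np.array([p_snp_ivw, p_gene_wfisher], dtype=float)
    if n_replicates is not None:
        p = floor_pvalues(p, n_replicates)
    return acat_combine(p)


def snp_centric_gene_p(
    p_stack: np.ndarray, thresholds: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """ARTP over one gene's TA-SNP p-values.

    ``p_stack`` is (M+1) x q with the observed vector in row 0 and the
    null replicas below.  Returns the gene-level p-value tau0 and the
    M replicate-level counterparts.
    """
    q = p_stack.shape[1]
    if thresholds is None:
        thresholds = default_snp_thresholds(q)
    tau, _, _ = _artp_stack(p_stack, thresholds)
    return float(tau[0]), tau[1:]


def gene_centric_gene_p(
    tau_stacks: np.ndarray,
    available: np.ndarray,
    method: str,
    ess: EffectiveSampleSizes,
) -> np.ndarray:
    """Combine per-ancestry gene p-value stacks into TA-gene stacks.

    ``tau_stacks`` is (L, M+1, J); ``available`` (L, J) marks genes
    with data in each ancestry.  Combination is applied identically to
    the observed row and every replicate row, aligning replicates by
    index across ancestries.
    """
    M1 = tau_stacks.shape[1]
    p = floor_pvalues(tau_stacks, M1 - 1)
    if method == "wfisher":
        return stat_combine.wfisher_pvalues(p, available, ess)
    if method == "minp":
        masked = np.where(available[:, None, :], p, np.inf)
        return masked.min(axis=0)
    raise ValueError(f"unknown gene-centric combiner {method!r}")


def pathway_p(
    gene_tau_stack: np.ndarray,
    gene_ids: Sequence[str],
    n_thresholds: int = 10,
    pathway_name: str = "pathway",
    method: str = "pathway-ARTP",
    seed: int | None = None,
) -> PathwayResult:
    """Gene-level ARTP over a stacked (M+1) x J TA-gene p-value matrix.

    Row 0 holds the observed gene p-values and rows 1..M their null
    replicas; thresholds default to d_k = k * max(1, ceil(J/20)),
    k = 1..10, capped at J.  Grid zeros are floored before the log
    transform.  Returns the pathway p-value together with the best
    truncation threshold and the gene subset attaining it (ties broken
    by ascending p, then gene id).
    """
    J = len(gene_ids)
    if J == 0 or gene_tau_stack.shape[1] != J:
        raise ValueError("gene_tau_stack must have one column per gene")
    M = gene_tau_stack.shape[0] - 1
    stack = floor_pvalues(gene_tau_stack, M)
    thr = default_gene_thresholds(J, n_thresholds)
    tau, xi0, best_k = _artp_stack(stack, thr)
    d_best = int(np.unique(np.minimum(thr, J))[best_k])
    order = np.lexsort((np.asarray(gene_ids), stack[0]))
    return PathwayResult(
        pathway_name=pathway_name,
        method=method,
        p_value=float(tau[0]),
        J_effective=J,
        n_replicates=M,
        seed=seed,
        gene_pvalues={g: float(stack[0, j]) for j, g in enumerate(gene_ids)},
        selected_genes=[gene_ids[i] for i in order[:d_best]],
        best_threshold=d_best,
    )


def _artp_stack(
    p_stack: np.ndarray, thresholds: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """Run ARTP on a stacked (M+1) x q p-value matrix.

    Returns (tau, xi0, best_threshold_index) where tau[0] is the
    observed minP p-value and tau[1:] the replicate-level ones.
    """
    thresholds = np.unique(np.minimum(thresholds, p_stack.shape[1]))
    w = nlp_statistics(p_stack, thresholds)
    xi = empirical_pvalues(w)
    T = xi.min(axis=1)
    tau = replicate_minp_pvalues(T)
    return tau, xi[0], int(np.argmin(xi[0]))


class PathwayAnalyzer:
    """Runs every trans-ancestry strategy for one pathway.

    The analyzer is constructed once per pathway from the SNP-to-gene
    assignment, the per-ancestry reference panels and the effective
    sample sizes; :meth:`run` is then called with the per-ancestry
    summary statistics (repeatedly so in simulation studies -- LD
    matrices, gene clusters and Cholesky factors are cached across
    calls with identical SNP availability).

    Parameters
    ----------
    gene_map
        SNP-to-gene assignment for the pathway.
    panels
        Per-ancestry reference panels keyed by ancestry label.
    ess
        Effective sample sizes of the studies (wFisher weights).
    n_replicates
        Number M of null replicates shared by every ARTP level.
    seed
        Master seed; per-run draws are derived from it and the
        ``dataset`` key passed to :meth:`run`.
    snp_thresholds, n_gene_thresholds
        ARTP truncation points: c = (1, 2) at the SNP level and
        K' = 10 points d_k = k * max(1, ceil(J/20)) at the gene level
        by default.
    cluster_r_threshold
        Cross-gene SNP correlation above which two genes are drawn
        jointly (they always are when they share a SNP).
    """

    def __init__(
        self,
        gene_map: GeneSnpMap,
        panels: Mapping[str, ReferencePanel],
        ess: EffectiveSampleSizes,
        n_replicates: int = 10_000,
        seed: int = 0,
        snp_thresholds: Sequence[int] = (1, 2),
        n_gene_thresholds: int = 10,
        cluster_r_threshold: float = 0.1,
        ivw_route: str = "shortcut",
        pathway_name: str | None = None,
    ) -> None:
        if n_replicates < artp_engine.MIN_REPLICATES:
            raise ValueError("n_replicates too small for a meaningful grid")
        if ivw_route not in ("shortcut", "per-ancestry"):
            raise ValueError("ivw_route must be 'shortcut' or 'per-ancestry'")
        self.gene_map = gene_map
        self.labels = tuple(sorted(panels))
        self.panels = {k: panels[k] for k in self.labels}
        if tuple(ess.labels) != self.labels:
            order = [ess.labels.index(l) for l in self.labels]
            ess = EffectiveSampleSizes(self.labels, ess.n[order])
        self.ess = ess
        self.M = n_replicates
        self.seed = seed
        self.snp_thresholds = np.asarray(snp_thresholds, dtype=int)
        self.n_gene_thresholds = n_gene_thresholds
        self.cluster_r_threshold = cluster_r_threshold
        self.ivw_route = ivw_route
        self.pathway_name = pathway_name or (gene_map.pathway_name or "pathway")
        self._prepared: dict[bytes, dict] = {}

    # -- preparation -------------------------------------------------------

    def _prepare(self, studies: Mapping[str, StudySummary]) -> dict:
        """Resolve availability, clusters and per-cluster LD factors."""
        gene_ids = sorted(g for g in self.gene_map.assignments)
        study_snps = {l: set(studies[l].snp_ids) for l in self.labels}
        key = b"|".join(
            ",".join(sorted(study_snps[l])).encode() for l in self.labels
        )
        cached = self._prepared.get(key)
        if cached is not None:
            return cached
        union: dict[str, None] = {}
        for g in gene_ids:
            for s in self.gene_map.assignments[g]:
                if any(s in study_snps[l] for l in self.labels):
                    union.setdefault(s)
        snp_ids = sorted(union)
        if not snp_ids:
            raise ValueError(f"{self.pathway_name}: no pathway SNP has summary data")
        # one LD matrix per ancestry over the union (panels are small);
        # SNPs missing or monomorphic in a panel are unavailable there
        panel_ld: dict[str, object] = {}
        for l in self.labels:
            panel_ld[l] = estimate_ld(self.panels[l], snp_ids)
        idx = {s: i for i, s in enumerate(snp_ids)}
        P = len(snp_ids)
        avail = np.zeros((len(self.labels), P), dtype=bool)
        for li, l in enumerate(self.labels):
            in_ld = set(panel_ld[l].snp_ids)
            for s, i in idx.items():
                avail[li, i] = (s in study_snps[l]) and (s in in_ld)

        gene_snp_idx = {}
        for g in gene_ids:
            cols = [idx[s] for s in self.gene_map.assignments[g]
                    if s in idx and avail[:, idx[s]].any()]
            if cols:
                gene_snp_idx[g] = np.asarray(sorted(set(cols)), dtype=int)
        genes = sorted(gene_snp_idx)
        if not genes:
            raise ValueError(f"{self.pathway_name}: no gene has analyzable SNPs")

        clusters = self._build_clusters(genes, gene_snp_idx, panel_ld, idx, avail)
        # per ancestry, per cluster: available columns and Cholesky of V
        chols: dict[str, list[tuple[np.ndarray, np.ndarray, np.ndarray]]] = {}
        for li, l in enumerate(self.labels):
            ld = panel_ld[l]
            ld_pos = {s: i for i, s in enumerate(ld.snp_ids)}
            per_cluster = []
            for cl in clusters:
                cols = cl.snp_indices[avail[li, cl.snp_indices]]
                if cols.size == 0:
                    per_cluster.append((cols, np.empty((0, 0)), np.empty((0, 0))))
                    continue
                sub = np.asarray([[ld.R[ld_pos[snp_ids[a]], ld_pos[snp_ids[b]]]
                                   for b in cols] for a in cols])
                V, _ = regularize_correlation(sub)
                per_cluster.append((cols, np.linalg.cholesky(V), V))
            chols[l] = per_cluster

        prepared = {
            "snp_ids": snp_ids,
            "idx": idx,
            "avail": avail,
            "genes": genes,
            "gene_snp_idx": gene_snp_idx,
            "clusters": clusters,
            "chols": chols,
        }
        self._prepared[key] = prepared
        return prepared

    def _build_clusters(self, genes, gene_snp_idx, panel_ld, idx, avail):
        """Connected components of the shared-SNP / high-LD relation."""
        snp_ids = sorted(idx, key=idx.get)
        n = len(genes)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i, j):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)

        sets = [set(gene_snp_idx[g].tolist()) for g in genes]
        abs_r = {}
        for li, l in enumerate(self.labels):
            ld = panel_ld[l]
            ld_pos = {s: i for i, s in enumerate(ld.snp_ids)}
            abs_r[l] = (np.abs(ld.R), ld_pos)
        for i in range(n):
            for j in range(i + 1, n):
                if sets[i] & sets[j]:
                    union(i, j)
                    continue
                linked = False
                for l in self.labels:
                    R, ld_pos = abs_r[l]
                    rows = [ld_pos[snp_ids[a]] for a in sets[i] if snp_ids[a] in ld_pos]
                    cols = [ld_pos[snp_ids[b]] for b in sets[j] if snp_ids[b] in ld_pos]
                    if rows and cols and R[np.ix_(rows, cols)].max() > self.cluster_r_threshold:
                        linked = True
                        break
                if linked:
                    union(i, j)
        groups: dict[int, list[int]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(i)
        clusters = []
        for root in sorted(groups):
            members = [genes[i] for i in groups[root]]
            cols = sorted({c for g in members for c in gene_snp_idx[g].tolist()})
            clusters.append(GeneCluster(members, np.asarray(cols, dtype=int)))
        return clusters

    # -- running -----------------------------------------------------------

    def run(
        self,
        studies: Mapping[str, StudySummary],
        methods: Sequence[str] | None = None,
        dataset: int | str = 0,
    ) -> dict[str, PathwayResult]:
        """Analyze one dataset (set of per-ancestry summaries).

        Parameters
        ----------
        studies
            StudySummary per ancestry label (must cover every panel).
        methods
            Subset of {SNP-IVW, SNP-max, SNP-wFisher, Gene-wFisher,
            Gene-minP, Path-joint, ACAT-IVW-wFisher}; single-ancestry
            results Path-<label> are included whenever a gene- or
            pathway-centric method is requested.  Default: all.
        dataset
            Key mixed into the master seed so repeated runs over
            simulated datasets use independent replicate draws.
        """
        requested = list(methods) if methods is not None else list(ALL_METHODS)
        unknown = set(requested) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if "ACAT-IVW-wFisher" in requested:
            for dep in ("SNP-IVW", "Gene-wFisher"):
                if dep not in requested:
                    requested.append(dep)
        prep = self._prepare(studies)
        labels, M = self.labels, self.M
        avail = prep["avail"]
        P = len(prep["snp_ids"])
        genes = prep["genes"]

        z_obs = np.zeros((len(labels), P))
        se_obs = np.ones((len(labels), P))
        p_obs = np.ones((len(labels), P))
        for li, l in enumerate(labels):
            t = studies[l].table
            cols = t["snp"].map(prep["idx"])
            ok = cols.notna().to_numpy()
            ci = cols[ok].astype(int).to_numpy()
            z_obs[li, ci] = (t["beta"] / t["se"]).to_numpy()[ok]
            se_obs[li, ci] = t["se"].to_numpy()[ok]
            p_obs[li, ci] = t["p"].to_numpy()[ok]
        z_obs[~avail] = 0.0
        p_obs[~avail] = 1.0

        # shared per-ancestry null z draws, jointly across cluster SNPs
        need_sa = any(m in requested for m in GENE_CENTRIC + ("Path-joint",))
        need_per_ancestry = need_sa or any(
            m in requested for m in ("SNP-max", "SNP-wFisher")
        ) or ("SNP-IVW" in requested and self.ivw_route == "per-ancestry")
        z_stack = None
        if need_per_ancestry:
            z_stack = np.zeros((len(labels), M + 1, P))
            for li, l in enumerate(labels):
                z_stack[li, 0] = z_obs[li]
                for cj, (cols, chol, _) in enumerate(prep["chols"][l]):
                    if cols.size == 0:
                        continue
                    rng = _child_rng(self.seed, dataset, l, f"cluster{cj}")
                    z_stack[li, 1:, cols] = (
                        rng.standard_normal((M, cols.size)) @ chol.T
                    ).T

        results: dict[str, PathwayResult] = {}
        p_anc = None  # per-ancestry p stack, shared by wFisher and SA paths
        if z_stack is not None:
            p_anc = two_sided_p(z_stack)
            p_anc[:, 0, :] = p_obs  # observed rows use reported p-values

        def pathway_level(tau_gene_stack: np.ndarray, method: str,
                          gene_list: list[str]) -> PathwayResult:
            return pathway_p(
                tau_gene_stack, gene_list,
                n_thresholds=self.n_gene_thresholds,
                pathway_name=self.pathway_name, method=method, seed=self.seed,
            )

        # ---- SNP-centric ------------------------------------------------
        def ta_snp_pvalues(kind: str) -> np.ndarray:
            if kind == "SNP-IVW":
                w, sd = stat_combine.ivw_weights(se_obs, avail)
                if self.ivw_route == "shortcut":
                    s = self._ivw_shortcut_draws(prep, w, sd, dataset)
                    s[0] = np.einsum("lp,lp->p", w, z_obs) / sd
                    return two_sided_p(s)
                return stat_combine.ivw_pvalues(z_stack, w, sd)
            if kind == "SNP-max":
                return stat_combine.max_pvalues(z_stack, avail)
            if kind == "SNP-wFisher":
                return stat_combine.wfisher_pvalues(p_anc, avail, self.ess)
            raise AssertionError(kind)

        for method in SNP_CENTRIC:
            if method not in requested:
                continue
            ta_p = ta_snp_pvalues(method)  # (M+1, P)
            tau_gene, _, _ = artp_engine.batched_artp_taus(
                ta_p, [prep["gene_snp_idx"][g] for g in genes], self.snp_thresholds
            )
            results[method] = pathway_level(tau_gene, method, genes)

        # ---- single-ancestry + gene-centric -----------------------------
        if need_sa:
            p_sa = p_anc
            gene_avail = np.zeros((len(labels), len(genes)), dtype=bool)
            tau_sa = np.full((len(labels), M + 1, len(genes)), 1.0)
            for li, l in enumerate(labels):
                cols_per_gene, gsel = [], []
                for j, g in enumerate(genes):
                    cols = prep["gene_snp_idx"][g]
                    cols = cols[avail[li, cols]]
                    if cols.size == 0:
                        continue
                    gene_avail[li, j] = True
                    cols_per_gene.append(cols)
                    gsel.append(j)
                if gsel:
                    taus, _, _ = artp_engine.batched_artp_taus(
                        p_sa[li], cols_per_gene, self.snp_thresholds
                    )
                    tau_sa[li][:, gsel] = taus
            sa_path_p = np.ones(len(labels))
            for li, l in enumerate(labels):
                gsel = np.flatnonzero(gene_avail[li])
                gene_list = [genes[j] for j in gsel]
                res = pathway_level(tau_sa[li][:, gsel], f"Path-{l}", gene_list)
                results[f"Path-{l}"] = res
                sa_path_p[li] = res.p_value
            if "Path-joint" in requested:
                pj = path_joint(
                    floor_pvalues(sa_path_p, M), self.ess, gene_avail.any(axis=1)
                )
                results["Path-joint"] = PathwayResult(
                    pathway_name=self.pathway_name, method="Path-joint",
                    p_value=pj, J_effective=len(genes), n_replicates=M,
                    seed=self.seed,
                )
            for method, comb in (("Gene-wFisher", "wfisher"), ("Gene-minP", "minp")):
                if method not in requested:
                    continue
                ta_gene = gene_centric_gene_p(tau_sa, gene_avail, comb, self.ess)
                results[method] = pathway_level(ta_gene, method, genes)

        # ---- composite ---------------------------------------------------
        if "ACAT-IVW-wFisher" in requested:
            results["ACAT-IVW-wFisher"] = PathwayResult(
                pathway_name=self.pathway_name, method="ACAT-IVW-wFisher",
                p_value=acat_composite(
                    results["SNP-IVW"].p_value,
                    results["Gene-wFisher"].p_value,
                    n_replicates=M,
                ),
                J_effective=len(genes), n_replicates=M, seed=self.seed,
            )
        if methods is not None:
            keep = set(requested) | {f"Path-{l}" for l in labels if need_sa}
            results = {k: v for k, v in results.items() if k in keep}
        return results

    def _ivw_shortcut_draws(
        self, prep: dict, w: np.ndarray, sd: np.ndarray, dataset
    ) -> np.ndarray:
        """Draw standardized IVW statistics directly from their null cov.

        cov(s_i, s_i') = sum_l w_i^(l) w_i'^(l) V^(l)_{i i'}; each
        cluster's covariance is assembled across ancestries, normalized
        to a correlation matrix, repaired to positive definite and
        sampled once -- no per-ancestry z draws are needed.
        """
        M, P = self.M, len(prep["snp_ids"])
        s = np.empty((M + 1, P))
        for cj, cl in enumerate(prep["clusters"]):
            cols = cl.snp_indices
            C = np.zeros((cols.size, cols.size))
            local = {c: i for i, c in enumerate(cols)}
            for li, l in enumerate(self.labels):
                csub, _, V = prep["chols"][l][cj]
                if csub.size == 0:
                    continue
                loc = np.asarray([local[c] for c in csub])
                C[np.ix_(loc, loc)] += np.outer(w[li, csub], w[li, csub]) * V
            d = np.sqrt(np.diag(C))
            corr = C / np.outer(d, d)
            np.fill_diagonal(corr, 1.0)
            corr, _ = regularize_correlation(corr)
            chol = np.linalg.cholesky(corr)
            rng = _child_rng(self.seed, dataset, "ivw", f"cluster{cj}")
            s[1:, cols] = rng.standard_normal((M, cols.size)) @ chol.T
        return s
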