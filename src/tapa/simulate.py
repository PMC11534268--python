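"""Multi-ancestry GWAS simulator for calibration and power studies.

Emulates the study design the analysis methods assume: five
case-control (or continuous-outcome) GWAS drawn from continental
populations with population-specific allele frequencies and LD, a
reference panel of 500 individuals per population, and per-SNP
logistic (or linear) regression summary statistics.

Genotypes are generated from a latent-Gaussian threshold model: each
gene is an independent haplotype block with an AR(1) latent correlation
drawn per population, and two latent haplotypes are thresholded at the
population allele frequency and summed into a dosage.  This preserves
the features the analysis consumes -- population-specific LD and MAF
spectra, SNPs common in one population and rare in another, and
independence across genes -- without attempting to match any specific
reference haplotype map.

Disease status follows a logistic model whose intercept is calibrated
by root-finding so the population prevalence hits its target; cases
and controls are sampled retrospectively.  Under the global null the
outcome is independent of every genotype, so case/control labels are
assigned directly -- distributionally identical to rejection sampling
and far cheaper.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from tapa.gwas_io import GeneSnpMap, ReferencePanel, StudySummary
from tapa.preprocess import filter_maf
from tapa.stat_combine import EffectiveSampleSizes, two_sided_p
from tapa.ta_pathway import ALL_METHODS, PathwayAnalyzer

__all__ = [
    "PopulationSpec",
    "RiskModelSpec",
    "SimulationDesign",
    "calibrate_intercept",
    "case_control_sample",
    "default_design",
    "effective_sizes",
    "gene_map",
    "make_reference_panels",
    "per_snp_summary",
    "risk_model",
    "run_calibration_study",
    "run_power_study",
    "simulate_genotypes",
    "simulate_null_dataset",
    "simulate_phenotype",
    "simulate_power_dataset",
    "unequal_ratio_design",
]

#: label, cases, controls at full scale (equal case/control split) and
#: the Balding-Nichols divergence parameter used for per-population
#: allele frequencies.
_POPULATIONS = (
    ("AFR", 2000, 2000, 0.15),
    ("AMR", 3000, 3000, 0.10),
    ("EAS", 3000, 3000, 0.12),
    ("EUR", 5000, 5000, 0.08),
    ("SAS", 2000, 2000, 0.10),
)


@dataclass
class PopulationSpec:
    """Sample sizes and genotype model for one population's study."""

    label: str
    n_cases: int | None = None
    n_controls: int | None = None
    n_total: int | None = None
    continuous: bool = False
    n_reference: int = 500
    freq: np.ndarray | None = None  # (G, q) alt-allele frequencies
    rho: np.ndarray | None = None  # (G,) AR(1) latent correlation per gene

    @property
    def n_study(self) -> int:
        if self.continuous:
            return int(self.n_total)
        return int(self.n_cases + self.n_controls)


@dataclass
class SimulationDesign:
    """A full multi-ancestry study design over one synthetic pathway."""

    populations: list[PopulationSpec]
    n_genes: int
    snps_per_gene: int
    chrom: str = "21"
    maf_min: float = 0.01
    _chol: dict = field(default_factory=dict, repr=False)

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.populations]

    def population(self, label: str) -> PopulationSpec:
        for p in self.populations:
            if p.label == label:
                return p
        raise KeyError(label)

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{g:03d}" for g in range(self.n_genes)]

    def snp_ids(self, g: int) -> list[str]:
        return [f"rs{g:03d}_{i}" for i in range(self.snps_per_gene)]

    def gene_span(self, g: int) -> tuple[int, int]:
        start = g * 1_000_000 + 100_000
        return start, start + 50_000

    def snp_positions(self, g: int) -> list[int]:
        start, _ = self.gene_span(g)
        return [start + 1_000 + i * 5_000 for i in range(self.snps_per_gene)]

    def snp_table(self) -> pd.DataFrame:
        rows = []
        for g in range(self.n_genes):
            for s, pos in zip(self.snp_ids(g), self.snp_positions(g)):
                rows.append((s, self.chrom, pos))
        return pd.DataFrame(rows, columns=["snp", "chrom", "pos"])

    def gene_chol(self, label: str, g: int) -> np.ndarray:
        """Cholesky factor of the AR(1) latent correlation for one block."""
        key = (label, g)
        if key not in self._chol:
            rho = float(self.population(label).rho[g])
            q = self.snps_per_gene
            C = rho ** np.abs(np.subtract.outer(np.arange(q), np.arange(q)))
            self._chol[key] = np.linalg.cholesky(C)
        return self._chol[key]


def default_design(
    scale: float = 0.2,
    n_genes: int = 20,
    snps_per_gene: int = 6,
    continuous: bool = False,
    n_reference: int = 500,
    seed: int = 2024,
) -> SimulationDesign:
    """The five-population study design at a given scale.

    ``scale = 1`` reproduces the full sample sizes (4,000 AFR / 6,000
    AMR / 6,000 EAS / 10,000 EUR / 4,000 SAS subjects, equal cases and
    controls); the desk default is 1/5 of that with a 20-gene pathway.
    Population allele frequencies are drawn once per design from a
    Balding-Nichols model around a shared ancestral frequency, and each
    gene's latent AR(1) correlation is drawn per population -- both
    from ``seed``, so a design is fully reproducible.

    The per-population MAF filter scales with the sample sizes
    (``maf_min = 0.01 / scale``, capped at 0.05): the full design's 1%
    filter keeps minor-allele counts of 80+, and preserving that count
    regime at reduced n keeps the per-SNP statistics in the asymptotic
    range the analytic null distributions assume.  At ``scale = 1``
    this is exactly the 1% filter.
    """
    rng = np.random.default_rng(seed)
    ancestral = rng.uniform(0.05, 0.5, size=(n_genes, snps_per_gene))
    pops = []
    for label, cases, controls, fst in _POPULATIONS:
        a = ancestral * (1 - fst) / fst
        b = (1 - ancestral) * (1 - fst) / fst
        freq = np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)
        rho = rng.uniform(0.2, 0.8, size=n_genes)
        n_ca, n_co = round(cases * scale), round(controls * scale)
        if continuous:
            pops.append(PopulationSpec(label, continuous=True, n_total=n_ca + n_co,
                                       n_reference=n_reference, freq=freq, rho=rho))
        else:
            pops.append(PopulationSpec(label, n_cases=n_ca, n_controls=n_co,
                                       n_reference=n_reference, freq=freq, rho=rho))
    maf_min = min(0.05, 0.01 / scale)
    return SimulationDesign(pops, n_genes, snps_per_gene, maf_min=maf_min)


def unequal_ratio_design(scale: float = 0.2, **kwargs) -> SimulationDesign:
    """The 1:10 case-control variant with matched effective sample size.

    Cases are 1,100 (AFR, SAS), 1,650 (AMR, EAS) and 5,000 (EUR) at
    full scale with ten controls per case except EUR (1:1); the
    harmonic mean of cases and controls -- hence the effective sample
    size -- matches the equal-ratio design population by population.
    """
    design = default_design(scale=scale, **kwargs)
    cases = {"AFR": 1100, "AMR": 1650, "EAS": 1650, "EUR": 5000, "SAS": 1100}
    for p in design.populations:
        c = round(cases[p.label] * scale)
        p.n_cases = c
        p.n_controls = c if p.label == "EUR" else 10 * c
    return design


# ---------------------------------------------------------------------------
# risk models


@dataclass
class RiskModelSpec:
    """Per-population disease model: logit P(Y=1) = a + b * sum g_f.

    ``causal_genes[label]`` indexes the causal genes and
    ``functional_snp[label][g]`` the within-gene index of that gene's
    functional SNP; ``beta[label]`` is the shared per-population effect
    size and ``prevalence`` the target the intercept is calibrated to.
    """

    causal_genes: dict[str, tuple[int, ...]]
    functional_snp: dict[str, dict[int, int]]
    beta: dict[str, float]
    prevalence: float = 0.01

    def functional_columns(self, design: SimulationDesign, label: str) -> np.ndarray:
        q = design.snps_per_gene
        return np.asarray(
            [g * q + self.functional_snp[label][g] for g in self.causal_genes[label]]
        )

    def functional_snp_ids(self, design: SimulationDesign) -> set[str]:
        out = set()
        for label in self.causal_genes:
            for g in self.causal_genes[label]:
                out.add(design.snp_ids(g)[self.functional_snp[label][g]])
        return out


SETTINGS = ("common", "distinct1", "distinct2", "distinct3")

#: per-population sign/scale multipliers of the base effect size in the
#: distinct risk models (the common model uses +1 everywhere)
_DISTINCT_MULT = (-1.4, -1.0, -1.0, 1.0, 1.4)


def risk_model(
    design: SimulationDesign,
    setting: str,
    beta: float,
    n_causal: int = 4,
    prevalence: float = 0.01,
) -> RiskModelSpec:
    """Build one of the four power-study risk models.

    common: identical causal genes, shared central functional SNPs and
    a uniform effect size across populations.  distinct1: same genes
    and SNPs, population-varying effects (multipliers -1.4, -1, -1, 1,
    1.4 of ``beta``).  distinct2: same genes, population-specific
    functional SNPs, distinct1's effects.  distinct3: shifted,
    partially overlapping causal gene sets plus population-specific
    SNPs and distinct1's effects.
    """
    if setting not in SETTINGS:
        raise ValueError(f"setting must be one of {SETTINGS}")
    labels = design.labels
    q = design.snps_per_gene
    if setting == "distinct3":
        # shifted sets: most causal genes stay shared by several
        # populations, so the gene-consistency assumption is partially
        # (not fully) met
        step = max(1, round(n_causal / 4))
        genes = {
            lab: tuple(range(i * step, i * step + n_causal))
            for i, lab in enumerate(labels)
        }
        if max(max(v) for v in genes.values()) >= design.n_genes:
            raise ValueError("not enough genes for shifted causal sets")
    else:
        genes = {lab: tuple(range(n_causal)) for lab in labels}
    if setting in ("common", "distinct1"):
        snps = {lab: {g: q // 2 for g in genes[lab]} for lab in labels}
    else:
        snps = {lab: {g: i % q for g in genes[lab]} for i, lab in enumerate(labels)}
    if setting == "common":
        betas = {lab: beta for lab in labels}
    else:
        betas = {lab: m * beta for lab, m in zip(labels, _DISTINCT_MULT)}
    return RiskModelSpec(genes, snps, betas, prevalence)


# ---------------------------------------------------------------------------
# genotype / phenotype generation


def simulate_genotypes(
    design: SimulationDesign,
    label: str,
    n: int,
    rng: np.random.Generator,
    gene_indices: Sequence[int] | None = None,
) -> np.ndarray:
    """Draw n individuals' dosages for the given genes of a population.

    Two latent MVN haplotypes per gene block are thresholded at the
    per-SNP allele-frequency quantile and summed; blocks (genes) are
    independent of one another.
    """
    pop = design.population(label)
    gene_indices = list(range(design.n_genes) if gene_indices is None else gene_indices)
    q = design.snps_per_gene
    out = np.empty((n, q * len(gene_indices)), dtype=np.int8)
    for k, g in enumerate(gene_indices):
        chol = design.gene_chol(label, g)
        thr = special.ndtri(pop.freq[g])  # latent < thr  <=>  allele present
        lat = rng.standard_normal((2 * n, q)) @ chol.T
        h = lat < thr
        out[:, k * q:(k + 1) * q] = h[:n].astype(np.int8) + h[n:].astype(np.int8)
    return out


def _genotype_dist(freq: float) -> np.ndarray:
    """HWE genotype probabilities for dosage 0/1/2 at allele freq p."""
    p = freq
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])


def expected_prevalence(
    design: SimulationDesign, risk: RiskModelSpec, label: str, alpha: float
) -> float:
    """Exact E[expit(alpha + sum_f beta g_f)] over the genotype law.

    Functional SNPs sit in distinct, independent gene blocks, so the
    linear predictor's distribution is the convolution of independent
    three-point laws -- enumerated exactly here.
    """
    pop = design.population(label)
    beta = risk.beta[label]
    values = np.array([0.0])
    probs = np.array([1.0])
    for g in risk.causal_genes[label]:
        s = risk.functional_snp[label][g]
        pg = _genotype_dist(float(pop.freq[g, s]))
        values = (values[:, None] + beta * np.arange(3)[None, :]).ravel()
        probs = (probs[:, None] * pg[None, :]).ravel()
    return float(np.sum(probs * special.expit(alpha + values)))


def calibrate_intercept(
    design: SimulationDesign, risk: RiskModelSpec, label: str
) -> float:
    """Solve the logistic intercept so prevalence hits its target."""
    target = risk.prevalence

    def f(a: float) -> float:
        return expected_prevalence(design, risk, label, a) - target

    lo, hi = -40.0, 10.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(f"prevalence {target} unattainable for {label}")
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def simulate_phenotype(
    genotypes: np.ndarray,
    design: SimulationDesign,
    risk: RiskModelSpec,
    label: str,
    rng: np.random.Generator,
    continuous: bool = False,
) -> np.ndarray:
    """Draw outcomes for pre-simulated full-pathway genotype rows.

    Binary outcomes follow the logistic model with the calibrated
    intercept; the continuous analogue is the linear predictor plus
    unit-variance Gaussian noise.
    """
    cols = risk.functional_columns(design, label)
    eta = genotypes[:, cols].astype(float) @ np.full(cols.size, risk.beta[label])
    if continuous:
        return eta + rng.standard_normal(genotypes.shape[0])
    alpha = calibrate_intercept(design, risk, label)
    return (rng.random(genotypes.shape[0]) < special.expit(alpha + eta)).astype(np.int8)


def case_control_sample(
    design: SimulationDesign,
    risk: RiskModelSpec,
    label: str,
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator,
    max_pool: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Retrospective sampling: draw, assign outcome, keep until quotas.

    Returns (genotypes, outcome) with cases first.  ``max_pool`` bounds
    the population pool (default 50 / prevalence times the quota);
    exhausting it raises with advice to enlarge it.
    """
    alpha = calibrate_intercept(design, risk, label)
    cols = risk.functional_columns(design, label)
    beta = risk.beta[label]
    if max_pool is None:
        max_pool = int(50 * (n_cases + n_controls) / risk.prevalence)
    cases, controls, drawn = [], [], 0
    need_cases, need_controls = n_cases, n_controls
    while need_cases > 0 or need_controls > 0:
        batch = min(max(2000, int(1.5 * need_cases / risk.prevalence)),
                    max_pool - drawn)
        if batch <= 0:
            raise RuntimeError(
                "population pool exhausted before case/control quotas were "
                "met; raise max_pool"
            )
        g = simulate_genotypes(design, label, batch, rng)
        drawn += batch
        pi = special.expit(alpha + g[:, cols].astype(float) @ np.full(cols.size, beta))
        y = rng.random(batch) < pi
        if need_cases > 0:
            take = g[y][:need_cases]
            cases.append(take)
            need_cases -= take.shape[0]
        if need_controls > 0:
            take = g[~y][:need_controls]
            controls.append(take)
            need_controls -= take.shape[0]
    g_all = np.vstack(cases + controls)
    y_all = np.concatenate([np.ones(n_cases, dtype=np.int8),
                            np.zeros(n_controls, dtype=np.int8)])
    return g_all, y_all


def _case_control_factorized(
    design: SimulationDesign,
    risk: RiskModelSpec,
    label: str,
    rng: np.random.Generator,
    n_cases: int | None = None,
    n_controls: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Retrospective sampling restricted to the causal blocks.

    Non-causal genes are independent of the outcome, so their
    genotypes are drawn directly for the retained individuals; only
    causal-gene genotypes go through outcome-dependent rejection.
    Exactly equivalent in distribution to :func:`case_control_sample`
    and roughly 1/prevalence times cheaper.
    """
    pop = design.population(label)
    if n_cases is None:
        n_cases, n_controls = pop.n_cases, pop.n_controls
    alpha = calibrate_intercept(design, risk, label)
    causal = sorted(risk.causal_genes[label])
    q = design.snps_per_gene
    gene_pos = {g: k for k, g in enumerate(causal)}
    local = np.asarray(
        [gene_pos[g] * q + risk.functional_snp[label][g] for g in causal]
    )
    beta = risk.beta[label]
    cases, controls = [], []
    need_ca, need_co = n_cases, n_controls
    guard = 0
    while need_ca > 0 or need_co > 0:
        batch = max(4000, int(1.5 * need_ca / risk.prevalence))
        gc = simulate_genotypes(design, label, batch, rng, gene_indices=causal)
        pi = special.expit(alpha + gc[:, local].astype(float) @ np.full(local.size, beta))
        y = rng.random(batch) < pi
        if need_ca > 0:
            take = gc[y][:need_ca]
            cases.append(take)
            need_ca -= take.shape[0]
        if need_co > 0:
            take = gc[~y][:need_co]
            controls.append(take)
            need_co -= take.shape[0]
        guard += 1
        if guard > 200:
            raise RuntimeError("rejection sampling failed to fill quotas")
    g_causal = np.vstack(cases + controls)
    n = n_cases + n_controls
    g = np.empty((n, design.n_genes * q), dtype=np.int8)
    others = [j for j in range(design.n_genes) if j not in set(causal)]
    if others:
        g_other = simulate_genotypes(design, label, n, rng, gene_indices=others)
        for k, j in enumerate(others):
            g[:, j * q:(j + 1) * q] = g_other[:, k * q:(k + 1) * q]
    for k, j in enumerate(causal):
        g[:, j * q:(j + 1) * q] = g_causal[:, k * q:(k + 1) * q]
    y = np.concatenate([np.ones(n_cases, dtype=np.int8),
                        np.zeros(n_controls, dtype=np.int8)])
    return g, y


# ---------------------------------------------------------------------------
# per-SNP summary statistics


def _logistic_wald(g: np.ndarray, y: np.ndarray, max_iter: int = 30,
                   tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column univariate logistic regression, Newton-Raphson.

    Fits intercept + slope for every genotype column simultaneously;
    returns (beta, se, converged).
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    n, P = g.shape
    ybar = y.mean()
    se = np.full(P, np.nan)
    converged = np.zeros(P, dtype=bool)
    # active-set Newton: most columns converge in a few iterations and
    # are retired from the elementwise (n x P) work
    active = np.arange(P)
    a = np.full(P, special.logit(ybar))
    b = np.zeros(P)
    ga = g
    for _ in range(max_iter):
        eta = a[active][None, :] + ga * b[active][None, :]
        mu = special.expit(eta)
        w = mu * (1.0 - mu)
        r = y[:, None] - mu
        wg = w * ga
        u1 = r.sum(axis=0)
        u2 = (ga * r).sum(axis=0)
        i11 = w.sum(axis=0)
        i12 = wg.sum(axis=0)
        i22 = (wg * ga).sum(axis=0)
        det = i11 * i22 - i12 * i12
        bad = det <= 0
        det = np.where(bad, 1.0, det)
        da = np.clip((i22 * u1 - i12 * u2) / det, -4, 4)
        db = np.clip((i11 * u2 - i12 * u1) / det, -4, 4)
        da[bad] = 0.0
        db[bad] = 0.0
        a[active] += da
        b[active] += db
        step = np.maximum(np.abs(da), np.abs(db))
        done = (step < tol) & ~bad
        if done.any():
            cols = active[done]
            with np.errstate(invalid="ignore", divide="ignore"):
                se[cols] = np.sqrt(i11[done] / det[done])
            converged[cols] = True
            active = active[~done]
            ga = g[:, active]
        if active.size == 0:
            break
    ok = converged & np.isfinite(se) & (se > 0) & (np.abs(b) < 10)
    return b, se, ok


def _logistic_score(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column logistic score test (association under the null fit).

    z = U / sqrt(I) with score U = sum g (y - ybar) and information
    I = ybar (1 - ybar) sum (g - gbar)^2; the reported coefficient is
    the one-step estimate U / I with se = 1 / sqrt(I).  Agrees with the
    Wald fit asymptotically while its null distribution is far closer
    to standard normal at moderate sample sizes and low minor-allele
    counts -- the regime deliberately exercised by reduced-scale
    simulation profiles.
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    ybar = y.mean()
    v = ybar * (1.0 - ybar)
    gc = g - g.mean(axis=0)
    info = v * (gc * gc).sum(axis=0)
    ok = info > 0
    info = np.where(ok, info, 1.0)
    u = gc.T @ (y - ybar)
    beta = u / info
    se = 1.0 / np.sqrt(info)
    return beta, se, ok


def _linear_fit(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-column simple linear regression; returns (beta, se, p, ok).

    The p-value is the exact two-sided t(n-2) tail; the reported
    standard error is calibrated so that beta/se is the matching
    standard-normal quantile, making the z-score exactly N(0, 1) under
    the null rather than t-distributed.  At GWAS sample sizes the two
    are indistinguishable; at reduced simulation sizes the calibration
    keeps the observed z-scores exchangeable with the normal null
    replicates the resampling layer draws.
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    n = g.shape[0]
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = (gc * gc).sum(axis=0)
    sxy = (gc * yc[:, None]).sum(axis=0)
    syy = float(yc @ yc)
    ok = sxx > 0
    sxx = np.where(ok, sxx, 1.0)
    b = sxy / sxx
    sse = np.maximum(syy - b * sxy, 0.0)
    se = np.sqrt(sse / (n - 2) / sxx)
    ok &= se > 0
    t = np.where(ok, b / np.where(se > 0, se, 1.0), 0.0)
    p = np.clip(2.0 * special.stdtr(n - 2, -np.abs(t)),
                np.finfo(float).tiny, 1.0)
    z = -np.sign(t) * special.ndtri(p / 2.0)  # normal quantile of the t p
    nonzero = np.abs(z) > 1e-12
    se = np.where(ok & nonzero, np.abs(b) / np.where(nonzero, np.abs(z), 1.0), se)
    return b, se, p, ok


def per_snp_summary(
    design: SimulationDesign,
    label: str,
    genotypes: np.ndarray,
    outcome: np.ndarray,
    binary: bool = True,
    drop_snps: set[str] | None = None,
    statistic: str = "score",
) -> StudySummary:
    """Per-SNP regression summaries in the package's exchange format.

    For a binary outcome the per-SNP logistic association is summarized
    by the score test by default (``statistic="wald"`` selects the
    full Newton fit instead); continuous outcomes use simple linear
    regression.  Monomorphic or non-converged SNPs are dropped, as is
    any SNP listed in ``drop_snps`` (the unobserved-functional-SNP
    scenario).
    """
    snps = design.snp_table()
    keep = np.ones(len(snps), dtype=bool)
    if drop_snps:
        keep &= ~snps["snp"].isin(drop_snps).to_numpy()
    poly = genotypes.std(axis=0) > 0
    keep &= poly
    g = genotypes[:, keep].astype(float)
    if binary:
        if statistic == "score":
            beta, se, ok = _logistic_score(g, outcome)
        elif statistic == "wald":
            beta, se, ok = _logistic_wald(g, outcome)
        else:
            raise ValueError("statistic must be 'score' or 'wald'")
        p = two_sided_p(np.where(ok, beta / np.where(ok, se, 1.0), 0.0))
    else:
        beta, se, p, ok = _linear_fit(g, outcome)
    tab = snps.loc[keep].reset_index(drop=True)
    tab = tab.assign(beta=beta, se=se, p=p).loc[ok].reset_index(drop=True)
    pop = design.population(label)
    if pop.continuous:
        return StudySummary(label, tab, n_total=pop.n_total)
    return StudySummary(label, tab, n_cases=pop.n_cases, n_controls=pop.n_controls)


# ---------------------------------------------------------------------------
# dataset-level generators


def make_reference_panels(
    design: SimulationDesign, seed: int
) -> dict[str, ReferencePanel]:
    """Draw the fixed per-population reference panels (500 by default)."""
    panels = {}
    snps = design.snp_table()
    index = snps.assign(ref="A", alt="G")[["snp", "chrom", "pos", "ref", "alt"]]
    for li, pop in enumerate(design.populations):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 7700 + li]))
        g = simulate_genotypes(design, pop.label, pop.n_reference, rng)
        panels[pop.label] = ReferencePanel(pop.label, index.copy(), g.astype(float))
    return panels


def simulate_null_dataset(
    design: SimulationDesign, seed: int, binary: bool = True
) -> dict[str, StudySummary]:
    """One dataset under the global null (no SNP associated anywhere).

    The outcome is independent of all genotypes, so genotypes for the
    full case-control sample are drawn directly and labels assigned by
    position -- exactly the retrospective sampling distribution.
    """
    studies = {}
    for li, pop in enumerate(design.populations):
        rng = np.random.default_rng(np.random.SeedSequence([seed, li]))
        n = pop.n_study
        g = simulate_genotypes(design, pop.label, n, rng)
        if binary:
            y = np.concatenate([np.ones(pop.n_cases, dtype=np.int8),
                                np.zeros(pop.n_controls, dtype=np.int8)])
        else:
            y = rng.standard_normal(n)
        studies[pop.label] = per_snp_summary(design, pop.label, g, y, binary=binary)
    return studies


def simulate_power_dataset(
    design: SimulationDesign,
    risk: RiskModelSpec,
    seed: int,
    functional_snps_observed: bool = True,
) -> dict[str, StudySummary]:
    """One case-control dataset under a risk model.

    With ``functional_snps_observed`` False the functional SNP columns
    are removed from the summary data (but of course not from the
    phenotype model), mimicking unmeasured causal variants.
    """
    drop = None if functional_snps_observed else risk.functional_snp_ids(design)
    studies = {}
    for li, pop in enumerate(design.populations):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1000 + li]))
        g, y = _case_control_factorized(design, risk, pop.label, rng)
        studies[pop.label] = per_snp_summary(
            design, pop.label, g, y, binary=True, drop_snps=drop
        )
    return studies


def gene_map(design: SimulationDesign) -> GeneSnpMap:
    """The (exact) SNP-to-gene assignment of the synthetic pathway."""
    genes = pd.DataFrame(
        [(gid, design.chrom, *design.gene_span(g))
         for g, gid in enumerate(design.gene_ids)],
        columns=["gene", "chrom", "start", "end"],
    )
    assignments = {gid: design.snp_ids(g) for g, gid in enumerate(design.gene_ids)}
    return GeneSnpMap(genes, assignments, pathway_name="SYNTHETIC_PATHWAY")


def effective_sizes(design: SimulationDesign) -> EffectiveSampleSizes:
    labels, n = [], []
    for pop in design.populations:
        labels.append(pop.label)
        if pop.continuous:
            n.append(float(pop.n_total))
        else:
            n.append(2.0 * pop.n_cases * pop.n_controls / (pop.n_cases + pop.n_controls))
    return EffectiveSampleSizes(tuple(labels), np.asarray(n))


def write_fixture(
    design: SimulationDesign,
    outdir,
    seed: int,
    risk: RiskModelSpec | None = None,
    functional_snps_observed: bool = True,
) -> dict[str, object]:
    """Write a complete text fixture readable by the gwas_io module.

    Emits per-population summary statistics (TSV), reference panels
    (genotype matrix + SNP index), a BED gene annotation and a
    single-pathway GMT.  ``risk=None`` simulates under the global
    null.  Returns the paths written, keyed by role.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if risk is None:
        studies = simulate_null_dataset(design, seed)
    else:
        studies = simulate_power_dataset(
            design, risk, seed, functional_snps_observed=functional_snps_observed
        )
    panels = make_reference_panels(design, seed)
    paths: dict[str, object] = {"studies": {}, "panels": {}}
    for label, study in studies.items():
        p = outdir / f"summary_{label}.tsv"
        study.table.to_csv(p, sep="\t", index=False)
        paths["studies"][label] = str(p)
    for label, panel in panels.items():
        gp = outdir / f"panel_{label}.geno.txt"
        ip = outdir / f"panel_{label}.index.tsv"
        np.savetxt(gp, panel.genotypes, fmt="%d")
        panel.snp_index.to_csv(ip, sep="\t", index=False)
        paths["panels"][label] = {"genotypes": str(gp), "index": str(ip)}
    bed = outdir / "genes.bed"
    with open(bed, "w") as fh:
        for g, gid in enumerate(design.gene_ids):
            start, end = design.gene_span(g)
            fh.write(f"{design.chrom}\t{start - 1}\t{end}\t{gid}\n")
    gmt = outdir / "pathway.gmt"
    with open(gmt, "w") as fh:
        fh.write("SYNTHETIC_PATHWAY\tsimulated\t" + "\t".join(design.gene_ids) + "\n")
    paths["gene_annotation"] = str(bed)
    paths["gmt"] = str(gmt)
    return paths


# ---------------------------------------------------------------------------
# studies


def _make_analyzer(design, panels, n_replicates, seed):
    return PathwayAnalyzer(
        gene_map(design), panels, effective_sizes(design),
        n_replicates=n_replicates, seed=seed,
    )


def _analyze_datasets(design, analyzer, panels, datasets, methods):
    """Run the analyzer over an iterable of (index, studies) pairs."""
    pvals: dict[str, list[float]] = {}
    for d, studies in datasets:
        filtered = {
            l: filter_maf(panels[l], studies[l], design.maf_min)[0]
            for l in studies
        }
        res = analyzer.run(filtered, methods=methods, dataset=d)
        for m, r in res.items():
            pvals.setdefault(m, []).append(r.p_value)
    return {m: np.asarray(v) for m, v in pvals.items()}


def run_calibration_study(
    design: SimulationDesign,
    methods: Sequence[str] | None = None,
    n_datasets: int = 1000,
    alphas: Sequence[float] = (0.05, 0.01),
    n_replicates: int = 1000,
    seed: int = 1,
    binary: bool = True,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Empirical Type I error rates over simulated null datasets.

    Returns a table of rejection fractions with 99% Wald binomial
    confidence bounds per method and alpha, plus the raw per-dataset
    p-values for downstream checks (e.g. uniformity tests).
    """
    methods = list(methods) if methods is not None else list(ALL_METHODS)
    panels = make_reference_panels(design, seed)
    analyzer = _make_analyzer(design, panels, n_replicates, seed)
    datasets = (
        (d, simulate_null_dataset(design, (seed * 100_000 + d) % 2**31,
                                  binary=binary))
        for d in range(n_datasets)
    )
    pvals = _analyze_datasets(design, analyzer, panels, datasets, methods)
    rows = []
    zcrit = 2.5758  # 99% normal quantile
    for m, p in pvals.items():
        for a in alphas:
            rate = float(np.mean(p <= a))
            half = zcrit * np.sqrt(max(rate * (1 - rate), 1e-12) / len(p))
            rows.append((m, a, rate, max(rate - half, 0.0), min(rate + half, 1.0),
                         len(p)))
    table = pd.DataFrame(
        rows, columns=["method", "alpha", "rejection_rate", "ci99_low",
                       "ci99_high", "n_datasets"],
    )
    return table, pvals


def run_power_study(
    design: SimulationDesign,
    setting: str,
    beta: float,
    methods: Sequence[str] | None = None,
    n_datasets: int = 200,
    n_causal: int = 4,
    alpha: float = 0.05,
    n_replicates: int = 1000,
    seed: int = 1,
    functional_snps_observed: bool = True,
    prevalence: float = 0.01,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Empirical power under one of the four risk-model settings."""
    methods = list(methods) if methods is not None else list(ALL_METHODS)
    risk = risk_model(design, setting, beta, n_causal=n_causal, prevalence=prevalence)
    panels = make_reference_panels(design, seed)
    analyzer = _make_analyzer(design, panels, n_replicates, seed)
    datasets = (
        (d, simulate_power_dataset(
            design, risk, (seed * 100_000 + d) % 2**31,
            functional_snps_observed=functional_snps_observed))
        for d in range(n_datasets)
    )
    pvals = _analyze_datasets(design, analyzer, panels, datasets, methods)
    rows = []
    for m, p in pvals.items():
        rate = float(np.mean(p <= alpha))
        mc_se = float(np.sqrt(max(rate * (1 - rate), 1e-12) / len(p)))
        rows.append((m, setting, rate, mc_se, len(p)))
    table = pd.DataFrame(rows, columns=["method", "setting", "power", "mc_se",
                                        "n_datasets"])
    return table, pvals
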