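"""Input readers and SNP/gene bookkeeping.

Reads per-ancestry GWAS summary statistics (delimited text), reference
genotype panels (VCF or plain matrix with a sidecar index), gene
annotation (BED-like), pathway gene sets (GMT), and optional external
SNP-gene assignment files; harmonizes allele orientation between
summary data and panels; and resolves the SNP-to-gene assignment used
by the analysis (50 kb distance rule by default).

Coordinates are 1-based inclusive throughout (the GWAS summary-data
convention); BED input is converted on read.  SNPs are matched across
studies and panels by (chrom, pos, unordered allele pair), falling back
to the SNP identifier when alleles are not supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from tapa.stat_combine import two_sided_p

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSnpMap",
    "Pathway",
    "ReferencePanel",
    "StudySummary",
    "assign_snps_to_genes",
    "harmonize_study_with_panel",
    "read_assignment_file",
    "read_gene_annotation",
    "read_gmt",
    "read_panel_text",
    "read_panel_vcf",
    "read_summary",
]

#: Complementary base pairs whose strand cannot be resolved from the
#: alleles alone.
_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


# ---------------------------------------------------------------------------
# study summary statistics


@dataclass
class StudySummary:
    """One ancestry group's GWAS summary statistics.

    ``table`` has columns ``snp, chrom, pos, beta, se, p`` and
    optionally ``effect_allele, other_allele``; z-scores are derived as
    beta/se.  Sample-size metadata feeds the effective-sample-size
    weights of the wFisher combiner.
    """

    ancestry_label: str
    table: pd.DataFrame
    n_cases: int | None = None
    n_controls: int | None = None
    n_total: int | None = None
    lambda_gc: float = 1.0

    def __post_init__(self) -> None:
        t = self.table
        required = {"snp", "chrom", "pos", "beta", "se", "p"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"summary table missing columns: {sorted(missing)}")
        if t["snp"].duplicated().any():
            raise ValueError("duplicate SNP ids within a study")
        if (t["se"] <= 0).any():
            raise ValueError("all standard errors must be positive")
        if ((t["p"] <= 0) | (t["p"] > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")
        if self.lambda_gc < 1.0:
            raise ValueError("genomic-control lambda must be >= 1")
        self.table = t.reset_index(drop=True)

    @property
    def z(self) -> np.ndarray:
        return (self.table["beta"] / self.table["se"]).to_numpy()

    @property
    def snp_ids(self) -> pd.Series:
        return self.table["snp"]

    @property
    def effective_n(self) -> float:
        """Harmonic mean of cases/controls, or the total for continuous."""
        if self.n_cases is not None and self.n_controls is not None:
            return 2.0 * self.n_cases * self.n_controls / (self.n_cases + self.n_controls)
        if self.n_total is not None:
            return float(self.n_total)
        raise ValueError(f"study {self.ancestry_label} lacks sample-size metadata")

    def replace_table(self, table: pd.DataFrame) -> "StudySummary":
        return StudySummary(
            self.ancestry_label, table, self.n_cases, self.n_controls,
            self.n_total, self.lambda_gc,
        )


def read_summary(
    path: str | Path,
    column_map: Mapping[str, str],
    ancestry_label: str | None = None,
    n_cases: int | None = None,
    n_controls: int | None = None,
    n_total: int | None = None,
    lambda_gc: float = 1.0,
) -> StudySummary:
    """Read delimited summary statistics into a :class:`StudySummary`.

    ``column_map`` maps canonical names (``snp, chrom, pos, beta, se,
    p, z, effect_allele, other_allele``) to the file's column headers.
    Either ``beta`` + ``se`` or ``z`` must be resolvable; a file with
    only a p-value column is rejected.  Rows failing numeric parsing or
    violating se > 0 / p in (0,1] are dropped with a logged count.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=None, engine="python")
    for key in ("snp", "chrom", "pos"):
        if key not in column_map or column_map[key] not in raw.columns:
            raise ValueError(f"required column {key!r} not resolvable via column_map")
    have = {k: v for k, v in column_map.items() if v in raw.columns}
    has_beta = "beta" in have and "se" in have
    if not has_beta and "z" not in have:
        raise ValueError("need beta+se columns, or a z column, in the summary file")

    df = pd.DataFrame({"snp": raw[have["snp"]].astype(str),
                       "chrom": raw[have["chrom"]].astype(str)})
    df["pos"] = pd.to_numeric(raw[have["pos"]], errors="coerce")
    if has_beta:
        df["beta"] = pd.to_numeric(raw[have["beta"]], errors="coerce")
        df["se"] = pd.to_numeric(raw[have["se"]], errors="coerce")
    else:
        df["beta"] = pd.to_numeric(raw[have["z"]], errors="coerce")
        df["se"] = 1.0
    if "p" in have:
        df["p"] = pd.to_numeric(raw[have["p"]], errors="coerce")
    else:
        df["p"] = two_sided_p(df["beta"] / df["se"])
    for allele in ("effect_allele", "other_allele"):
        if allele in have:
            df[allele] = raw[have[allele]].astype(str).str.upper()

    n0 = len(df)
    ok = (
        df[["pos", "beta", "se", "p"]].notna().all(axis=1)
        & (df["se"] > 0)
        & (df["p"] > 0)
        & (df["p"] <= 1)
    )
    dropped = int(n0 - ok.sum())
    if dropped:
        logger.warning("%s: dropped %d/%d malformed summary rows", path.name, dropped, n0)
    df = df.loc[ok].copy()
    df["pos"] = df["pos"].astype(int)
    if len(df) == 0:
        raise ValueError(f"{path}: no valid summary rows")
    df = df.drop_duplicates(subset="snp", keep="first")

    # consistency of the reported p with the normal p implied by beta/se
    if "p" in have and has_beta:
        implied = two_sided_p(df["beta"] / df["se"])
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(np.log(df["p"]) - np.log(implied)) / np.abs(np.log(implied))
        bad = int((rel[np.isfinite(rel)] > 0.10).sum())
        if bad:
            logger.warning(
                "%s: %d SNPs where the reported p deviates >10%% from the "
                "two-sided normal p of beta/se", path.name, bad,
            )
    return StudySummary(
        ancestry_label or path.stem, df, n_cases=n_cases,
        n_controls=n_controls, n_total=n_total, lambda_gc=lambda_gc,
    )


# ---------------------------------------------------------------------------
# reference panels


@dataclass
class ReferencePanel:
    """Individual-level genotypes for one ancestry's reference set.

    ``genotypes`` is individuals x SNPs with allele dosages in
    {0, 1, 2} and NaN for missing; ``snp_index`` has columns
    ``snp, chrom, pos, ref, alt`` aligned with the columns.
    """

    ancestry_label: str
    snp_index: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=float)
        if g.ndim != 2 or g.shape[1] != len(self.snp_index):
            raise ValueError("genotype matrix misaligned with snp_index")
        vals = g[np.isfinite(g)]
        if vals.size and not np.isin(vals, [0.0, 1.0, 2.0]).all():
            raise ValueError("dosages must be 0/1/2 or missing")
        self.genotypes = g
        self.snp_index = self.snp_index.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    def dosages(self, columns: Sequence[int]) -> np.ndarray:
        return self.genotypes[:, list(columns)]

    def maf(self) -> np.ndarray:
        """Empirical minor allele frequency per SNP (missing ignored)."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.genotypes, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)


def read_panel_vcf(path: str | Path, ancestry_label: str) -> ReferencePanel:
    """Read a reference panel from a VCF (biallelic SNVs, GT field)."""
    from cyvcf2 import VCF  # deferred: only needed for VCF input

    rows, cols = [], []
    vcf = VCF(str(path))
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            continue  # biallelic SNVs only
        rows.append((var.ID or f"{var.CHROM}:{var.POS}", str(var.CHROM),
                     int(var.POS), var.REF.upper(), var.ALT[0].upper()))
        gt = np.asarray(var.genotype.array())[:, :2].astype(float)
        gt[gt < 0] = np.nan
        cols.append(gt.sum(axis=1))
    if not rows:
        raise ValueError(f"{path}: no biallelic SNVs found")
    index = pd.DataFrame(rows, columns=["snp", "chrom", "pos", "ref", "alt"])
    return ReferencePanel(ancestry_label, index, np.column_stack(cols))


def read_panel_text(
    genotype_path: str | Path, index_path: str | Path, ancestry_label: str
) -> ReferencePanel:
    """Read a panel from a plain genotype matrix plus a SNP index.

    The matrix file is whitespace/tab-delimited, one row per
    individual, one column per SNP, entries 0/1/2 or NA; the index file
    is a TSV with columns ``snp chrom pos ref alt`` in column order.
    """
    g = pd.read_csv(genotype_path, sep=r"\s+", header=None, na_values=["NA", "."])
    index = pd.read_csv(index_path, sep="\t")
    index.columns = [c.lower() for c in index.columns]
    return ReferencePanel(ancestry_label, index, g.to_numpy(dtype=float))


def _is_ambiguous(a1: str, a2: str) -> bool:
    return (a1, a2) in _AMBIGUOUS_PAIRS


def harmonize_study_with_panel(
    study: StudySummary, panel: ReferencePanel, drop_ambiguous: bool = False
) -> StudySummary:
    """Align the study's effect alleles to the panel's ALT alleles.

    Where the study's (effect, other) pair equals the panel's
    (ref, alt) pair the sign of beta is flipped so the effect allele is
    the panel ALT; matching pairs are left untouched; mismatching
    allele pairs are dropped with a warning.  Strand-ambiguous SNPs
    (A/T, C/G) are kept and flagged in an ``ambiguous`` column unless
    ``drop_ambiguous`` is set.  The operation is involutive: a second
    harmonization is a no-op.
    """
    t = study.table
    if "effect_allele" not in t.columns or "other_allele" not in t.columns:
        return study
    panel_alleles = {
        r.snp: (r.ref, r.alt) for r in panel.snp_index.itertuples()
    }
    t = t.copy()
    flip = np.zeros(len(t), dtype=bool)
    keep = np.ones(len(t), dtype=bool)
    ambiguous = np.zeros(len(t), dtype=bool)
    for i, row in enumerate(t.itertuples()):
        alleles = panel_alleles.get(row.snp)
        if alleles is None:
            continue
        ref, alt = alleles
        ea, oa = row.effect_allele, row.other_allele
        ambiguous[i] = _is_ambiguous(ea, oa)
        if (ea, oa) == (alt, ref):
            continue
        if (ea, oa) == (ref, alt):
            flip[i] = True
        else:
            keep[i] = False
    n_mismatch = int((~keep).sum())
    if n_mismatch:
        logger.warning(
            "%s vs %s panel: %d SNPs with irreconcilable alleles dropped",
            study.ancestry_label, panel.ancestry_label, n_mismatch,
        )
    t.loc[flip, "beta"] = -t.loc[flip, "beta"]
    ea = t.loc[flip, "effect_allele"].copy()
    t.loc[flip, "effect_allele"] = t.loc[flip, "other_allele"].to_numpy()
    t.loc[flip, "other_allele"] = ea.to_numpy()
    t["ambiguous"] = ambiguous
    if drop_ambiguous:
        keep &= ~ambiguous
    return study.replace_table(t.loc[keep])


# ---------------------------------------------------------------------------
# genes, pathways and SNP assignment


@dataclass(frozen=True)
class Pathway:
    name: str
    genes: tuple[str, ...]


@dataclass
class GeneSnpMap:
    """Resolved SNP-to-gene assignment for one pathway.

    ``assignments`` maps gene id to the ordered list of assigned SNP
    ids; a SNP may appear under several genes.  Genes with no assigned
    SNP are retained (flagged empty) but excluded from the effective
    gene count J.
    """

    genes: pd.DataFrame
    assignments: dict[str, list[str]] = field(default_factory=dict)
    pathway_name: str | None = None

    @property
    def snp_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for snps in self.assignments.values():
            for s in snps:
                seen.setdefault(s)
        return list(seen)

    @property
    def nonempty_genes(self) -> list[str]:
        return [g for g, snps in self.assignments.items() if snps]

    @property
    def J(self) -> int:
        return len(self.nonempty_genes)

    def restrict_snps(self, keep: set[str]) -> "GeneSnpMap":
        """Drop assigned SNPs outside ``keep`` (e.g. not in any study)."""
        new = {g: [s for s in snps if s in keep] for g, snps in self.assignments.items()}
        return GeneSnpMap(self.genes, new, self.pathway_name)


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read BED-like 4-column gene annotation (chrom, start, end, gene).

    BED is 0-based half-open; coordinates are converted to the 1-based
    inclusive convention used everywhere else in the package.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["chrom", "start", "end", "gene"], comment="#")
    out = pd.DataFrame({
        "gene": df["gene"].astype(str),
        "chrom": df["chrom"].astype(str),
        "start": df["start"].astype(int) + 1,
        "end": df["end"].astype(int),
    })
    return out


def assign_snps_to_genes(
    genes: pd.DataFrame, snps: pd.DataFrame, window: int = 50_000
) -> GeneSnpMap:
    """Assign SNPs to genes within ``window`` bp of the gene boundary.

    ``genes`` has columns ``gene, chrom, start, end`` (1-based
    inclusive) and ``snps`` columns ``snp, chrom, pos``.  A SNP is
    assigned to every gene whose extended interval
    [start - window, end + window] contains it (both ends inclusive);
    assignment is deterministic and monotone in ``window``.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    assignments: dict[str, list[str]] = {}
    snps = snps.drop_duplicates(subset="snp")
    by_chrom = {
        str(ch): sub.sort_values("pos", kind="stable")
        for ch, sub in snps.groupby("chrom")
    }
    for row in genes.itertuples():
        sub = by_chrom.get(str(row.chrom))
        if sub is None:
            assignments[row.gene] = []
            continue
        pos = sub["pos"].to_numpy()
        lo = np.searchsorted(pos, row.start - window, side="left")
        hi = np.searchsorted(pos, row.end + window, side="right")
        assignments[row.gene] = sub["snp"].iloc[lo:hi].tolist()
    return GeneSnpMap(genes.reset_index(drop=True), assignments)


def read_assignment_file(
    path: str | Path,
    genes: pd.DataFrame | None = None,
    known_snps: set[str] | None = None,
) -> GeneSnpMap:
    """Read an external two-column (gene_id, snp_id) assignment.

    Bypasses the distance rule (e.g. expression-model-based
    assignments).  Duplicate pairs are deduplicated; SNPs absent from
    every study (when ``known_snps`` is given) are dropped with a
    warning; an empty file is fatal.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["gene", "snp"],
                     dtype=str, comment="#")
    if len(df) == 0:
        raise ValueError(f"{path}: empty assignment file")
    df = df.drop_duplicates()
    if known_snps is not None:
        unknown = ~df["snp"].isin(known_snps)
        if unknown.any():
            logger.warning(
                "%s: %d assigned SNPs absent from every study; dropped",
                Path(path).name, int(unknown.sum()),
            )
            df = df.loc[~unknown]
    assignments = {g: sub["snp"].tolist() for g, sub in df.groupby("gene", sort=False)}
    if genes is None:
        genes = pd.DataFrame({
            "gene": list(assignments), "chrom": "NA", "start": 0, "end": 0,
        })
    else:
        for g in assignments:
            if g not in set(genes["gene"]):
                logger.warning("assigned gene %s missing from annotation", g)
    return GeneSnpMap(genes.reset_index(drop=True), assignments)


def read_gmt(path: str | Path, max_genes: int | None = None) -> list[Pathway]:
    """Read pathways from a GMT file (name, description, gene ids...).

    Malformed lines (< 3 tab-separated fields) are skipped with a
    warning; duplicate genes within a line are counted once; pathways
    with ``max_genes`` or more members are filtered out when a cap is
    given.
    """
    pathways: list[Pathway] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                logger.warning("%s:%d: malformed GMT line skipped", Path(path).name, ln)
                continue
            name = fields[0]
            genes: dict[str, None] = {}
            for g in fields[2:]:
                if g:
                    genes.setdefault(g)
            pathways.append(Pathway(name, tuple(genes)))
    if max_genes is not None:
        pathways = [pw for pw in pathways if len(pw.genes) < max_genes]
    return pathways
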