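"""Summary-statistic preprocessing applied before any combination.

Three steps mirror standard practice for pathway analysis of published
GWAS: removal of genome-wide significant loci (the significant SNP and
every SNP within a radius of it) so pathway signal is not dominated by
established hits; genomic-control rescaling of the coefficient
standard errors by sqrt(lambda) to correct test-statistic inflation
from population stratification; and a per-ancestry minor-allele-
frequency filter based on the reference panel, because a SNP common in
one population may be rare in another.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from tapa.gwas_io import ReferencePanel, StudySummary
from tapa.stat_combine import two_sided_p

logger = logging.getLogger(__name__)

__all__ = ["FilterReport", "exclude_gws_loci", "exclude_gws_loci_union",
           "filter_maf", "genomic_control_rescale"]


@dataclass
class FilterReport:
    """Bookkeeping for SNP filtering, serializable into the run log."""

    n_input: int
    n_removed_gws: int = 0
    n_removed_maf: int = 0
    removed_regions: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def n_output(self) -> int:
        return self.n_input - self.n_removed_gws - self.n_removed_maf

    def to_json(self) -> str:
        return json.dumps({
            "n_input": self.n_input,
            "n_removed_gws": self.n_removed_gws,
            "n_removed_maf": self.n_removed_maf,
            "n_output": self.n_output,
            "removed_regions": [list(r) for r in self.removed_regions],
        })


def exclude_gws_loci(
    study: StudySummary, p_threshold: float = 5e-8, radius: int = 500_000
) -> tuple[StudySummary, FilterReport]:
    """Remove genome-wide significant SNPs and their neighborhoods.

    Every SNP with p < ``p_threshold`` is removed, along with every SNP
    on the same chromosome within ``radius`` bp of it (exclusion zones
    of nearby significant SNPs union).  The operation is idempotent and
    an empty result is allowed.
    """
    t = study.table
    sig = t["p"].to_numpy() < p_threshold
    report = FilterReport(n_input=len(t))
    if not sig.any():
        return study, report
    remove = np.zeros(len(t), dtype=bool)
    for ch in t.loc[sig, "chrom"].unique():
        on_chrom = (t["chrom"] == ch).to_numpy()
        pos = t["pos"].to_numpy()
        centers = pos[sig & on_chrom]
        near = np.zeros(len(t), dtype=bool)
        for c in centers:
            near |= on_chrom & (np.abs(pos - c) <= radius)
            report.removed_regions.append((str(ch), int(c), radius))
        remove |= near
    report.n_removed_gws = int(remove.sum())
    kept = t.loc[~remove]
    if len(kept) == 0:
        logger.warning("%s: GWS exclusion removed every SNP", study.ancestry_label)
    return study.replace_table(kept), report


def exclude_gws_loci_union(
    studies: dict[str, StudySummary],
    p_threshold: float = 5e-8,
    radius: int = 500_000,
) -> tuple[dict[str, StudySummary], dict[str, FilterReport]]:
    """GWS exclusion with zones pooled across studies.

    Any ancestry's genome-wide significant SNP defines an exclusion
    zone applied to every study (the default, per-study variant only
    excises each study's own hits).
    """
    centers: list[tuple[str, int]] = []
    for s in studies.values():
        t = s.table
        sig = t["p"].to_numpy() < p_threshold
        centers.extend(zip(t.loc[sig, "chrom"].astype(str), t.loc[sig, "pos"]))
    out, reports = {}, {}
    for label, s in studies.items():
        t = s.table
        remove = np.zeros(len(t), dtype=bool)
        pos = t["pos"].to_numpy()
        chrom = t["chrom"].astype(str).to_numpy()
        for ch, c in centers:
            remove |= (chrom == ch) & (np.abs(pos - c) <= radius)
        rep = FilterReport(n_input=len(t), n_removed_gws=int(remove.sum()),
                           removed_regions=[(ch, int(c), radius)
                                            for ch, c in centers])
        out[label] = s.replace_table(t.loc[~remove])
        reports[label] = rep
    return out, reports


def genomic_control_rescale(study: StudySummary, lambda_gc: float | None = None) -> StudySummary:
    """Rescale standard errors by sqrt(lambda) (genomic control).

    se' = se * sqrt(lambda), hence z' = z / sqrt(lambda); the p-value
    is recomputed from z' as a two-sided normal tail.  lambda = 1 is an
    identity (up to the p recomputation being skipped); lambda < 1 is
    rejected.  Preserves z signs and p-value ordering.
    """
    lam = study.lambda_gc if lambda_gc is None else lambda_gc
    if lam < 1.0:
        raise ValueError("genomic-control lambda must be >= 1")
    if lam == 1.0:
        return study
    t = study.table.copy()
    t["se"] = t["se"] * np.sqrt(lam)
    t["p"] = two_sided_p(t["beta"] / t["se"])
    out = study.replace_table(t)
    out.lambda_gc = 1.0  # correction now folded into se
    return out


def filter_maf(
    panel: ReferencePanel, study: StudySummary, maf_min: float = 0.01
) -> tuple[StudySummary, FilterReport]:
    """Drop study SNPs whose panel MAF is below ``maf_min``.

    The filter is per ancestry: the same SNP may survive in one
    population and be removed from another.  The boundary is
    non-strict (MAF exactly ``maf_min`` is kept): with a finite panel
    the MAF estimate is noisy and the non-strict convention is
    standard.  SNPs not covered by the panel are dropped with a
    warning, counted with the MAF removals.
    """
    t = study.table
    maf = dict(zip(panel.snp_index["snp"], panel.maf()))
    in_panel = t["snp"].map(maf)
    uncovered = in_panel.isna()
    if uncovered.any():
        logger.warning(
            "%s: %d study SNPs not in the %s panel; dropped",
            study.ancestry_label, int(uncovered.sum()), panel.ancestry_label,
        )
    keep = (~uncovered) & (in_panel >= maf_min)
    report = FilterReport(n_input=len(t), n_removed_maf=int((~keep).sum()))
    return study.replace_table(t.loc[keep]), report
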