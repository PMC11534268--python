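"""Shared fixtures.

The session-scoped simulation-study fixtures at the bottom are
expensive (minutes each) and are only materialized when the acceptance
tests request them; unit tests rely on the small fixtures above.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pytest

from tapa import simulate
from tapa.gwas_io import ReferencePanel, StudySummary

logging.getLogger("tapa").setLevel(logging.ERROR)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_study(label="EUR", snps=None, beta=None, se=None, chrom="1",
               pos=None, p=None, n_cases=500, n_controls=500, **kwargs):
    """Small StudySummary builder for unit tests."""
    snps = snps or ["rs1", "rs2", "rs3"]
    k = len(snps)
    beta = np.asarray(beta if beta is not None else np.full(k, 0.1), dtype=float)
    se = np.asarray(se if se is not None else np.full(k, 0.05), dtype=float)
    pos = pos if pos is not None else (1000 + 100 * np.arange(k))
    from tapa.stat_combine import two_sided_p
    table = pd.DataFrame({
        "snp": snps, "chrom": chrom, "pos": pos, "beta": beta, "se": se,
        "p": p if p is not None else two_sided_p(beta / se),
    })
    return StudySummary(label, table, n_cases=n_cases, n_controls=n_controls,
                        **kwargs)


def make_panel(label="EUR", snps=None, genotypes=None, chrom="1", pos=None,
               seed=0, n=200, maf=0.3):
    snps = snps or ["rs1", "rs2", "rs3"]
    k = len(snps)
    if genotypes is None:
        r = np.random.default_rng(seed)
        genotypes = r.binomial(2, maf, size=(n, k)).astype(float)
    pos = pos if pos is not None else (1000 + 100 * np.arange(k))
    index = pd.DataFrame({"snp": snps, "chrom": chrom, "pos": pos,
                          "ref": "A", "alt": "G"})
    return ReferencePanel(label, index, np.asarray(genotypes, dtype=float))


@pytest.fixture()
def study():
    return make_study()


@pytest.fixture()
def panel():
    return make_panel()


# ---------------------------------------------------------------------------
# session-scoped simulation studies (acceptance tests only)

CAL_N_DATASETS = 1000
CAL_M = 1000
POWER_N_DATASETS = 120
POWER_M = 1000
POWER_BETAS = {"common": 0.12, "distinct2": 0.16, "distinct3": 0.18}


@pytest.fixture(scope="session")
def null_binary_study():
    """Type I error study, binary outcome, all methods."""
    design = simulate.default_design()
    return simulate.run_calibration_study(
        design, n_datasets=CAL_N_DATASETS, n_replicates=CAL_M, seed=1
    )


@pytest.fixture(scope="session")
def null_continuous_study():
    """Type I error study, continuous outcome, all methods."""
    design = simulate.default_design(continuous=True)
    return simulate.run_calibration_study(
        design, n_datasets=CAL_N_DATASETS, n_replicates=CAL_M, seed=1,
        binary=False,
    )


def _power(setting: str, design=None, seed: int = 7):
    design = design or simulate.default_design()
    return simulate.run_power_study(
        design, setting, POWER_BETAS[setting], n_datasets=POWER_N_DATASETS,
        n_replicates=POWER_M, seed=seed,
    )


@pytest.fixture(scope="session")
def power_common():
    return _power("common")


@pytest.fixture(scope="session")
def power_distinct2():
    return _power("distinct2")


@pytest.fixture(scope="session")
def power_distinct3():
    return _power("distinct3")


@pytest.fixture(scope="session")
def power_common_unequal():
    """Common risk model on the 1:10 design with matched effective n."""
    return _power("common", design=simulate.unequal_ratio_design())
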