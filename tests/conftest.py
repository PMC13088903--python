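"""Shared fixtures: synthetic panels and studies reused across test modules.

Session-scoped fixtures hold the expensive objects (panels, simulated
studies, LDSC fits) so each is built once per test run.
"""

from __future__ import annotations

import numpy as np
import pytest

from gsemkit import (
    GsemModel,
    TruthModel,
    build_ld_panel,
    common_factor_model,
    multivariate_ldsc,
    simulate_study,
)

EUR_TRAITS = ["AUD", "CanUD", "TUD", "OUD", "SCZ", "BD", "MDD", "ANX"]
EUR_LOADINGS = np.array(
    [
        [0.8, 0.0, 0.0],
        [0.7, 0.0, 0.0],
        [0.6, 0.0, 0.0],
        [0.5, 0.0, 0.0],
        [0.0, 0.9, 0.0],
        [0.0, 0.8, 0.0],
        [0.0, 0.0, 0.85],
        [0.0, 0.0, 0.7],
    ]
)
EUR_PSI = np.array([[1.0, 0.4, 0.45], [0.4, 1.0, 0.3], [0.45, 0.3, 1.0]])
EUR_FACTORS = {"F1": EUR_TRAITS[:4], "F2": EUR_TRAITS[4:6], "F3": EUR_TRAITS[6:8]}


def eur_truth(n: float = 50_000.0, h2: float = 0.3, polygenicity: float = 0.2) -> TruthModel:
    return TruthModel(
        trait_names=EUR_TRAITS,
        loadings=EUR_LOADINGS,
        factor_corr=EUR_PSI,
        h2=np.full(8, h2),
        n=np.full(8, n),
        polygenicity=polygenicity,
    )


@pytest.fixture(scope="session")
def small_panel():
    """2,000-SNP panel with AR(1) blocks of varying LD."""
    return build_ld_panel(n_blocks=100, snps_per_block=20, rho=(0.0, 0.9), seed=42)


@pytest.fixture(scope="session")
def noldpanel():
    """1,200-SNP panel with no LD (independent test variants)."""
    return build_ld_panel(n_blocks=60, snps_per_block=20, rho=0.0, seed=43)


@pytest.fixture(scope="session")
def big_panel():
    """20,000-SNP panel used by the recovery studies."""
    return build_ld_panel(n_blocks=500, snps_per_block=40, rho=(0.0, 0.9), seed=44)


@pytest.fixture(scope="session")
def single_factor_study(big_panel):
    """Simulated 4-trait single-factor study with its LDSC fit and CFA."""
    names = ["A", "B", "C", "T"]
    truth = TruthModel(
        trait_names=names,
        loadings=np.array([[0.85], [0.8], [0.75], [np.sqrt(0.5)]]),
        factor_corr=np.eye(1),
        h2=[0.4, 0.4, 0.35, 0.4],
        n=[50_000.0] * 4,
        polygenicity=0.2,
    )
    fx, tables = simulate_study(truth, big_panel, seed=101)
    gcov = multivariate_ldsc(tables, big_panel)
    cfa = GsemModel(gcov, common_factor_model({"F": names})).fit()
    return {"truth": truth, "fx": fx, "tables": tables, "gcov": gcov, "cfa": cfa}


@pytest.fixture(scope="session")
def eur_study(big_panel):
    """Simulated 8-trait, 3-factor study with its full LDSC fit."""
    truth = eur_truth()
    fx, tables = simulate_study(truth, big_panel, seed=202)
    gcov = multivariate_ldsc(tables, big_panel)
    return {"truth": truth, "fx": fx, "tables": tables, "gcov": gcov}
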