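"""Generate multi-trait GWAS summary statistics from a known latent factor model.

The generator is the ground-truth side of the package: k traits share q
latent genetic factors with standardized loadings Lambda and factor
correlations Psi, plus trait-specific residual genetic variance, so the
implied genetic correlation matrix is Lambda Psi Lambda' + diag(u).  True
per-SNP effects follow a spike-and-slab (polygenicity pi) architecture, and
observed z-statistics follow the standard summary-statistics likelihood that
LD score regression assumes: within an LD block, z is multivariate normal
with mean sqrt(N) * R * beta and noise covariance R, with cross-trait noise
correlation equal to the sample-overlap term C (so the joint noise
covariance over a block is the Kronecker product of C and R).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import LDPanel
from .sumstats import CANONICAL_COLUMNS, SumstatsTable, TraitMeta
from .utils import ConfigurationError, nearest_psd

logger = logging.getLogger(__name__)


@dataclass
class TruthModel:
    """A latent factor model over trait-level genetic architecture.

    ``loadings`` is the k x q standardized loading matrix on the genetic
    correlation scale: the implied genetic correlation matrix
    loadings @ factor_corr @ loadings.T + diag(residual) must have unit
    diagonal, with residual variance u_i = 1 - communality_i.  ``h2`` carries
    the total (liability-scale) SNP heritability per trait, ``n`` the GWAS
    sample size per trait (effective N for case-control), ``overlap`` the
    k x k sample-overlap noise-correlation matrix C (diagonal 1), and
    ``polygenicity`` the causal fraction pi shared across factors.
    """

    trait_names: list[str]
    loadings: np.ndarray
    factor_corr: np.ndarray
    h2: np.ndarray
    n: np.ndarray
    polygenicity: float = 0.2
    overlap: np.ndarray | None = None
    trait_meta: list[TraitMeta] | None = None

    def __post_init__(self):
        self.loadings = np.atleast_2d(np.asarray(self.loadings, dtype=float))
        self.factor_corr = np.atleast_2d(np.asarray(self.factor_corr, dtype=float))
        self.h2 = np.asarray(self.h2, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        k, q = self.loadings.shape
        if len(self.trait_names) != k or self.factor_corr.shape != (q, q):
            raise ConfigurationError("inconsistent dimensions in TruthModel")
        if self.overlap is None:
            self.overlap = np.eye(k)
        self.overlap = np.asarray(self.overlap, dtype=float)
        if not np.allclose(np.diag(self.overlap), 1.0):
            raise ConfigurationError("overlap matrix must have unit diagonal")
        if np.linalg.eigvalsh(self.overlap).min() < -1e-8:
            raise ConfigurationError("overlap matrix must be positive semidefinite")
        if not (0.0 < self.polygenicity <= 1.0):
            raise ConfigurationError("polygenicity must be in (0, 1]")
        if np.any(self.communality > 1.0 + 1e-9):
            raise ConfigurationError("standardized loadings imply communality > 1")

    @property
    def k(self) -> int:
        return self.loadings.shape[0]

    @property
    def q(self) -> int:
        return self.loadings.shape[1]

    @property
    def communality(self) -> np.ndarray:
        return np.diag(self.loadings @ self.factor_corr @ self.loadings.T)

    @property
    def residual(self) -> np.ndarray:
        """Standardized residual genetic variance u_i per trait."""
        return 1.0 - self.communality

    @property
    def genetic_corr(self) -> np.ndarray:
        g = self.loadings @ self.factor_corr @ self.loadings.T
        np.fill_diagonal(g, 1.0)
        return g

    @property
    def genetic_cov(self) -> np.ndarray:
        """Implied genetic covariance matrix S on the heritability scale."""
        scale = np.sqrt(self.h2)
        return self.genetic_corr * np.outer(scale, scale)


@dataclass
class SimulationTruth:
    """True per-SNP effects, reproducible from the TruthModel and seed."""

    truth: TruthModel
    seed: int
    snp_ids: np.ndarray
    gamma: np.ndarray  # M x q standardized factor effect vectors
    delta: np.ndarray  # M x k standardized residual effect vectors
    beta: np.ndarray = field(default=None)  # M x k per-SD trait effects

    def __post_init__(self):
        if self.beta is None:
            lam = self.truth.loadings
            self.beta = (self.gamma @ lam.T + self.delta) * np.sqrt(self.truth.h2)[None, :]


def simulate_truth_effects(
    truth: TruthModel,
    panel: LDPanel,
    seed: int = 0,
    common_pathway_only: bool = False,
    residual_traits: list[str] | None = None,
) -> SimulationTruth:
    """Draw true standardized SNP effect vectors under the factor model.

    Causal SNPs for the factor pathway are a single draw without replacement
    shared across factors (a shared support is required for the factor effect
    vectors to carry the Psi correlation); per-factor effects at causal sites
    are jointly normal with covariance Psi / n_causal so each factor's effect
    vector has unit total variance on the genetic-correlation scale.
    Trait-residual effects use independent causal draws per trait with per-SNP
    variance u_i / n_causal.  Trait effects are
    beta_i = sqrt(h2_i) * (Lambda_i . gamma + delta_i).

    With ``common_pathway_only=True`` the residual effect vectors are zeroed:
    every SNP's trait effects are exactly proportional to the loadings, the
    null condition of the per-SNP heterogeneity (Q) statistic.
    ``residual_traits`` restricts the residual pathway to a subset of traits
    (e.g. only a subtraction target), leaving the rest purely factor-driven.
    """
    frame = panel.snp_frame()
    snp_ids = frame["SNP"].to_numpy(dtype=object)
    m = len(snp_ids)
    n_causal = int(round(truth.polygenicity * m))
    if n_causal < 1:
        raise ConfigurationError(f"polygenicity {truth.polygenicity} with M={m} yields no causal SNPs")
    rng = np.random.default_rng(seed)

    gamma = np.zeros((m, truth.q))
    causal = rng.choice(m, size=n_causal, replace=False)
    # eigendecomposition square root: exact even for singular Psi (r_g = 1)
    w, q_vec = np.linalg.eigh(nearest_psd(truth.factor_corr, eps=0.0))
    root = q_vec * np.sqrt(np.maximum(w, 0.0))[None, :]
    gamma[causal] = (rng.standard_normal((n_causal, truth.q)) @ root.T) / np.sqrt(n_causal)

    delta = np.zeros((m, truth.k))
    if not common_pathway_only:
        u = truth.residual
        allowed = (
            set(range(truth.k))
            if residual_traits is None
            else {truth.trait_names.index(t) for t in residual_traits}
        )
        for i in range(truth.k):
            if u[i] <= 1e-12 or i not in allowed:
                continue
            causal_i = rng.choice(m, size=n_causal, replace=False)
            delta[causal_i, i] = rng.standard_normal(n_causal) * np.sqrt(u[i] / n_causal)

    return SimulationTruth(truth=truth, seed=seed, snp_ids=snp_ids, gamma=gamma, delta=delta)


def simulate_sumstats(
    truthfx: SimulationTruth,
    panel: LDPanel,
    truth: TruthModel | None = None,
    seed: int = 1,
) -> list[SumstatsTable]:
    """Draw observed summary statistics given true effects and an LD panel.

    Tables come back already in canonical munged orientation (panel alleles,
    panel frequencies, per-SNP SE = 1/sqrt(2 p (1-p) N)).
    """
    truth = truth or truthfx.truth
    rng = np.random.default_rng(seed)
    k = truth.k
    sqrt_n = np.sqrt(truth.n)

    overlap = truth.overlap
    if np.linalg.eigvalsh(overlap).min() < 0:
        logger.warning("simulate_sumstats: overlap matrix smoothed to nearest PSD")
        overlap = nearest_psd(overlap, eps=0.0)
    l_c = np.linalg.cholesky(overlap + 1e-12 * np.eye(k))

    beta_by_id = dict(zip(truthfx.snp_ids, range(len(truthfx.snp_ids))))
    chol_cache: dict[int, np.ndarray] = {}

    records = {i: [] for i in range(k)}
    for block in panel.blocks:
        m_b = block.n_snps
        rows = np.array([beta_by_id[s] for s in block.snp_ids])
        b_blk = truthfx.beta[rows]  # m_b x k
        key = hash(block.R.tobytes())
        l_b = chol_cache.get(key)
        if l_b is None:
            l_b = np.linalg.cholesky(block.R + 1e-10 * np.eye(m_b))
            chol_cache[key] = l_b
        mean = (block.R @ b_blk) * sqrt_n[None, :]
        noise = l_b @ rng.standard_normal((m_b, k)) @ l_c.T
        z = mean + noise
        se = 1.0 / np.sqrt(2.0 * block.maf * (1.0 - block.maf))[:, None] / sqrt_n[None, :]
        for i in range(k):
            records[i].append(
                pd.DataFrame(
                    {
                        "SNP": block.snp_ids,
                        "CHR": block.chrom,
                        "POS": block.pos,
                        "A1": block.a1,
                        "A2": block.a2,
                        "BETA": z[:, i] * se[:, i],
                        "SE": se[:, i],
                        "Z": z[:, i],
                        "P": np.clip(2.0 * stats.norm.sf(np.abs(z[:, i])), np.finfo(float).tiny, 1.0),
                        "FRQ": block.maf,
                        "N": truth.n[i],
                    }
                )
            )

    tables = []
    for i, name in enumerate(truth.trait_names):
        df = pd.concat(records[i], ignore_index=True)
        df = df.sort_values(["CHR", "POS", "SNP"], kind="mergesort").reset_index(drop=True)
        meta = truth.trait_meta[i] if truth.trait_meta else None
        tables.append(SumstatsTable(name, df[CANONICAL_COLUMNS], meta))
    return tables


def simulate_study(
    truth: TruthModel, panel: LDPanel, seed: int = 0
) -> tuple[SimulationTruth, list[SumstatsTable]]:
    """Convenience wrapper: effects then sumstats, with derived sub-seeds."""
    fx = simulate_truth_effects(truth, panel, seed=seed)
    tables = simulate_sumstats(fx, panel, truth, seed=seed + 1)
    return fx, tables
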