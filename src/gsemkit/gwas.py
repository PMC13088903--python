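"""Per-SNP association with latent genetic factors.

Each SNP is appended to the genetic covariance matrix as an extra
pseudo-variable (its trait covariances come from the per-SNP effect
estimates, its sampling covariances from the SEs and the cross-trait
intercepts), and the SNP -> factor regression paths are re-estimated by DWLS
with the measurement model held at its full-data estimates.  Heterogeneity
is quantified per SNP by Q_SNP: the chi-square difference between the
common-pathway model (SNP acts only through the factors) and the
independent-pathways model (SNP acts directly on every indicator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ldsc import GenomicCovariance
from .panel import LDPanel
from .sem import FIXED_MOMENT_VARIANCE, GsemModel, GsemResults, SemModel
from .sumstats import SumstatsTable
from .utils import InputError, nearest_psd, vech, vech_index, vech_indices

logger = logging.getLogger(__name__)

SNP_NAME = "SNP_"  # pseudo-variable name for the tested variant

DEFAULT_QSNP_THRESHOLD = 5e-28  # heterogeneous-SNP removal rule


def _overlap_correlation(I_mat: np.ndarray) -> np.ndarray:
    """Sampling correlation of per-SNP noise across traits, from the
    intercept matrix: rho_ij = I_ij / sqrt(I_ii I_jj).

    The intercepts are themselves regression estimates; the true quantity is
    a correlation matrix, so implausible estimates (non-positive diagonal,
    off-diagonals beyond 1) are clipped and the matrix projected to positive
    semidefinite rather than propagated.
    """
    diag = np.diag(I_mat)
    if np.any(diag <= 0):
        logger.warning(
            "non-positive univariate intercepts %s; treating per-SNP sampling "
            "noise as independent across traits", np.round(diag, 3)
        )
        return np.eye(len(diag))
    rho = I_mat / np.sqrt(np.outer(diag, diag))
    rho = np.clip(rho, -0.98, 0.98)
    np.fill_diagonal(rho, 1.0)
    rho = nearest_psd(rho, eps=1e-9)
    d = np.sqrt(np.diag(rho))
    rho = rho / np.outer(d, d)
    return rho


def expand_with_snp(
    gcov: GenomicCovariance,
    beta: np.ndarray,
    se: np.ndarray,
    snp_var: float,
    snp_name: str = SNP_NAME,
) -> GenomicCovariance:
    """Append one SNP to (S, V) as a fixed-variance pseudo-variable.

    ``beta``/``se`` are the per-trait SNP effects and their SEs on the scale
    whose product with ``snp_var`` gives the SNP-trait covariance (per-allele
    effects on the standardized trait with snp_var = 2p(1-p), or per-SD
    effects with snp_var = 1).  The SNP's own variance is treated as known:
    its sampling variance is set to zero, which marks the moment as fixed so
    the fit function and chi-square skip it.  Sampling correlations between
    SNP-trait covariance estimates for two traits use the cross-trait
    intercept ratio I_ij / sqrt(I_ii I_jj); covariances between SNP moments
    and trait-trait moments are taken as zero.
    """
    k = gcov.k
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    S_full = np.zeros((k + 1, k + 1))
    S_full[:k, :k] = gcov.S
    S_full[k, :k] = S_full[:k, k] = beta * snp_var
    S_full[k, k] = snp_var

    rho = _overlap_correlation(gcov.I)
    se_cov = se * snp_var

    d_full = (k + 1) * (k + 2) // 2
    V_full = np.zeros((d_full, d_full))
    pos_old = {ij: p for p, ij in enumerate(vech_indices(k))}
    idx_new = vech_indices(k + 1)
    for p_new, (i, j) in enumerate(idx_new):
        if i < k and j < k:
            for p2_new, (a, b) in enumerate(idx_new):
                if a < k and b < k:
                    V_full[p_new, p2_new] = gcov.V[pos_old[(i, j)], pos_old[(a, b)]]
    for ti in range(k):
        pi = vech_index(k, ti, k + 1)
        for tj in range(k):
            pj = vech_index(k, tj, k + 1)
            V_full[pi, pj] = se_cov[ti] * se_cov[tj] * rho[ti, tj]
    # var(SNP) sampling variance stays exactly 0: fixed moment

    return GenomicCovariance(
        trait_names=gcov.trait_names + [snp_name],
        S=S_full,
        I=np.pad(gcov.I, ((0, 1), (0, 1))),
        V=V_full,
        M=gcov.M,
        n_blocks=gcov.n_blocks,
        mean_l2=gcov.mean_l2,
    )


def _fixed_measurement_model(results: GsemResults) -> SemModel:
    """The fitted measurement model with every parameter fixed at its estimate."""
    fixed = SemModel()
    for r in results.model.rows_resolved(results.params):
        fixed.add(r.lhs, r.op, r.rhs, free=False, value=r.value)
    return fixed


class _PerSnpFitter:
    """Compiled per-SNP DWLS problems reused across the genome.

    Two models share one expanded-covariance template: the common-pathway
    model (SNP -> factors) and the independent-pathways model
    (SNP -> every indicator).  Per SNP only the SNP-row moments of s and V
    change, so compilation happens once.
    """

    def __init__(
        self,
        meas: GsemResults,
        factors: list[str],
        refit_measurement: bool = False,
    ):
        gcov = meas.model.gcov
        self.k = gcov.k
        self.factors = factors
        if refit_measurement:
            from dataclasses import replace

            base = SemModel(rows=[replace(r) for r in meas.model.model.rows])
        else:
            base = _fixed_measurement_model(meas)
        template = expand_with_snp(gcov, np.zeros(self.k), np.full(self.k, 0.01), 1.0)

        common = SemModel(rows=list(base.rows))
        for f in factors:
            common.add(f, "~", SNP_NAME)
        common.add(SNP_NAME, "~~", SNP_NAME, free=False, value=1.0)
        self.common = GsemModel(template, common)

        indep = SemModel(rows=list(base.rows))
        for ind in gcov.trait_names:
            indep.add(ind, "~", SNP_NAME)
        indep.add(SNP_NAME, "~~", SNP_NAME, free=False, value=1.0)
        self.indep = GsemModel(template, indep)

        self.q_df = self.k - len(factors)
        k1 = self.k + 1
        self._snp_pos = np.array([vech_index(self.k, t, k1) for t in range(self.k)])
        # sampling correlation between SNP-moment estimates from overlap
        self._rho = _overlap_correlation(gcov.I)

    def update(self, beta_std: np.ndarray, se_std: np.ndarray) -> None:
        for m in (self.common, self.indep):
            m.s_obs[self._snp_pos] = beta_std
            block = np.outer(se_std, se_std) * self._rho
            m.V[np.ix_(self._snp_pos, self._snp_pos)] = block

    def fit_snp(self, beta_std, se_std, fit_independent=True):
        self.update(beta_std, se_std)
        res_c = self.common.fit_fast()
        res_i = self.indep.fit_fast(start=None) if fit_independent else None
        return res_c, res_i


def snp_factor_gwas(
    meas: GsemResults,
    tables: list[SumstatsTable],
    panel: LDPanel,
    factors: list[str] | None = None,
    qsnp_threshold: float = DEFAULT_QSNP_THRESHOLD,
    refit_measurement: bool = False,
    compute_qsnp: bool = True,
) -> pd.DataFrame:
    """GWAS of the latent factors: per-SNP DWLS estimates plus Q_SNP.

    ``meas`` is the fitted measurement model on the same traits (its
    parameters are held fixed per SNP unless ``refit_measurement``).
    Returns one row per SNP shared by all trait tables, with per-allele
    BETA/SE/Z/P columns per factor, the Q_SNP statistic with its df and
    p-value, and flags.  The Q_SNP degrees of freedom equal
    (number of indicators) - (number of factors tested); for a single common
    factor over k indicators that is k - 1.
    """
    gcov = meas.model.gcov
    names = gcov.trait_names
    order = {t.trait_name: t for t in tables}
    missing = [n for n in names if n not in order]
    if missing:
        raise InputError(f"missing sumstats for traits {missing}")
    tables = [order[n] for n in names]
    factors = factors or meas.model.model.latents

    merged = None
    for t in tables:
        d = t.df.set_index("SNP")[["CHR", "POS", "A1", "A2", "FRQ", "BETA", "SE", "Z", "N"]]
        merged = d.index if merged is None else merged.intersection(d.index)
    snp_ids = list(merged)
    frames = [t.df.set_index("SNP").loc[snp_ids] for t in tables]
    base = frames[0]
    order_idx = np.argsort(base["POS"].to_numpy() + base["CHR"].to_numpy() * 10**10, kind="mergesort")
    snp_ids = [snp_ids[i] for i in order_idx]
    frames = [f.iloc[order_idx] for f in frames]

    k = gcov.k
    frq = frames[0]["FRQ"].to_numpy(dtype=float)
    scale = np.sqrt(2.0 * frq * (1.0 - frq))  # per-SD <- per-allele conversion
    beta_std = np.column_stack([f["BETA"].to_numpy(dtype=float) for f in frames]) * scale[:, None]
    se_std = np.column_stack([f["SE"].to_numpy(dtype=float) for f in frames]) * scale[:, None]

    fitter = _PerSnpFitter(meas, factors, refit_measurement)
    n_snps = len(snp_ids)
    out = {
        "SNP": snp_ids,
        "CHR": frames[0]["CHR"].to_numpy(),
        "POS": frames[0]["POS"].to_numpy(),
        "A1": frames[0]["A1"].to_numpy(),
        "A2": frames[0]["A2"].to_numpy(),
        "FRQ": frq,
    }
    betas = {f: np.full(n_snps, np.nan) for f in factors}
    ses = {f: np.full(n_snps, np.nan) for f in factors}
    q = np.full(n_snps, np.nan)
    qp = np.full(n_snps, np.nan)
    converged = np.zeros(n_snps, dtype=bool)

    for j in range(n_snps):
        res_c, res_i = fitter.fit_snp(beta_std[j], se_std[j], fit_independent=compute_qsnp)
        ok = res_c.converged and (res_i is None or res_i.converged)
        converged[j] = ok
        if not ok:
            continue
        for f in factors:
            b = res_c.params[f"{f}~{SNP_NAME}"]
            se_b = res_c.bse[f"{f}~{SNP_NAME}"]
            betas[f][j] = b / scale[j]
            ses[f][j] = se_b / scale[j]
        if compute_qsnp:
            q_stat = res_c.chi2 - res_i.chi2
            if q_stat < -1e-6:
                logger.warning("negative Q_SNP %.3g at %s flagged as numerical failure", q_stat, snp_ids[j])
                converged[j] = False
                continue
            q[j] = max(q_stat, 0.0)
            qp[j] = stats.chi2.sf(q[j], fitter.q_df) if fitter.q_df > 0 else np.nan

    for f in factors:
        z = betas[f] / ses[f]
        out[f"BETA_{f}"] = betas[f]
        out[f"SE_{f}"] = ses[f]
        out[f"Z_{f}"] = z
        out[f"P_{f}"] = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    out["Q"] = q
    out["QDF"] = fitter.q_df
    out["QP"] = qp
    out["CONVERGED"] = converged
    out["HET_REMOVED"] = np.where(np.isnan(qp), False, qp < qsnp_threshold)
    return pd.DataFrame(out)


def write_factor_gwas(df: pd.DataFrame, factor: str, path) -> None:
    """Write the per-factor tab-delimited GWAS table the CLI emits."""
    cols = {
        "SNP": df["SNP"], "CHR": df["CHR"], "POS": df["POS"],
        "A1": df["A1"], "A2": df["A2"], "FRQ": df["FRQ"],
        "BETA": df[f"BETA_{factor}"], "SE": df[f"SE_{factor}"],
        "Z": df[f"Z_{factor}"], "P": df[f"P_{factor}"],
        "Q": df["Q"], "QDF": df["QDF"], "QP": df["QP"],
        "FLAG": np.where(~df["CONVERGED"], "nonconverged",
                         np.where(df["HET_REMOVED"], "het_removed", "ok")),
    }
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def effective_n(
    rows: pd.DataFrame,
    maf_window: tuple[float, float] = (0.1, 0.4),
    beta_col: str = "BETA",
    se_col: str = "SE",
) -> float:
    """Effective sample size implied by the factor GWAS standard errors.

    N_eff = mean over SNPs with MAF in ``maf_window`` of
    1 / (2 p (1-p) se^2), with se the per-allele SE on the standardized
    scale.  Restricting to mid-frequency SNPs avoids the unstable tails.
    """
    frq = rows["FRQ"].to_numpy(dtype=float)
    maf = np.minimum(frq, 1.0 - frq)
    lo, hi = maf_window
    mask = (maf >= lo) & (maf <= hi) & np.isfinite(rows[se_col].to_numpy(dtype=float))
    if mask.sum() == 0:
        raise InputError("no SNPs inside the MAF window")
    if mask.sum() < 100:
        logger.warning("effective_n: only %d SNPs in the MAF window", int(mask.sum()))
    se = rows.loc[mask, se_col].to_numpy(dtype=float)
    p = frq[mask]
    return float(np.mean(1.0 / (2.0 * p * (1.0 - p) * se**2)))


@dataclass
class ClumpResult:
    """Greedy LD-clumping output: lead SNPs and their assigned members."""

    leads: pd.DataFrame  # SNP CHR POS P N_MEMBERS
    members: dict[str, list[str]]
    p1: float
    r2: float
    window_kb: float

    @property
    def n_leads(self) -> int:
        return len(self.leads)


def clump(
    rows: pd.DataFrame,
    panel: LDPanel,
    p1: float = 5e-8,
    r2: float = 0.1,
    window_kb: float = 250.0,
    p_col: str = "P",
) -> ClumpResult:
    """Greedy LD clumping as PLINK-style index-variant selection.

    Repeatedly take the smallest-p unassigned SNP with p <= p1 as a lead and
    assign every unassigned SNP within ``window_kb`` on the same chromosome
    whose LD r-square with the lead is >= ``r2``.  Heterogeneity-removed and
    non-converged rows must be excluded by the caller or via the flag
    columns, which are honored when present.
    """
    df = rows
    if "HET_REMOVED" in df.columns:
        df = df[~df["HET_REMOVED"].astype(bool)]
    if "CONVERGED" in df.columns:
        df = df[df["CONVERGED"].astype(bool)]
    df = df[np.isfinite(df[p_col].to_numpy(dtype=float))]

    snp = df["SNP"].to_numpy(dtype=object)
    chrom = df["CHR"].to_numpy()
    pos = df["POS"].to_numpy(dtype=float)
    pvals = df[p_col].to_numpy(dtype=float)

    missing = [s for s in snp if panel.locate(s) is None]
    if missing:
        logger.info("clump: %d SNPs absent from panel treated as LD-independent", len(missing))

    cand = np.where(pvals <= p1)[0]
    cand = cand[np.lexsort((snp[cand], pvals[cand]))]  # smallest p, ties by id
    assigned = np.zeros(len(df), dtype=bool)
    leads = []
    members: dict[str, list[str]] = {}
    window = window_kb * 1000.0

    for lead_idx in cand:
        if assigned[lead_idx]:
            continue
        assigned[lead_idx] = True
        lead_id = snp[lead_idx]
        close = np.where(
            (~assigned)
            & (chrom == chrom[lead_idx])
            & (np.abs(pos - pos[lead_idx]) <= window)
        )[0]
        mem = []
        for j in close:
            if panel.ld_r2(lead_id, snp[j]) >= r2:
                assigned[j] = True
                mem.append(snp[j])
        members[lead_id] = mem
        leads.append(
            {"SNP": lead_id, "CHR": chrom[lead_idx], "POS": int(pos[lead_idx]),
             "P": pvals[lead_idx], "N_MEMBERS": len(mem)}
        )

    leads_df = pd.DataFrame(leads, columns=["SNP", "CHR", "POS", "P", "N_MEMBERS"])
    return ClumpResult(leads=leads_df, members=members, p1=p1, r2=r2, window_kb=window_kb)
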