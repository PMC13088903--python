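"""GWAS-by-subtraction: split a target trait's per-SNP genetic signal into
the part mediated by its class's common factor and the part independent of it.

The model is the two-latent Cholesky construction: a Common latent loaded on
by every indicator of the target's first-order factor (loadings re-estimated
jointly), and an Independent latent loaded on only by the target, absorbing
the target's residual genetic variance (the target's unique variance is
fixed to zero so the decomposition is exhaustive).  Both latents have unit
variance and are uncorrelated; each SNP regresses on both.  Per-target
effects are path-traced: the effect through the common pathway is
(SNP -> Common) x (Common -> target), the independent effect is
(SNP -> Independent) x (Independent -> target), and their sum is the
implied total SNP -> target effect.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .gwas import SNP_NAME, _PerSnpFitter, effective_n
from .ldsc import GenomicCovariance
from .panel import LDPanel
from .sem import GsemModel, GsemResults, SemModel
from .sumstats import SumstatsTable
from .utils import ConfigurationError, InputError

logger = logging.getLogger(__name__)

COMMON = "Common"
INDEPENDENT = "Independent"

# minimum standardized unexplained variance for an informative decomposition
DEFAULT_RESIDUAL_GATE = 0.30


def build_subtraction_model(
    first_order: GsemResults,
    target: str,
    gate: float = DEFAULT_RESIDUAL_GATE,
) -> tuple[SemModel, GenomicCovariance]:
    """Construct the Common/Independent model for one target trait.

    The target must be an indicator of exactly one first-order factor and
    must carry standardized residual variance above ``gate`` in the fitted
    first-order model — a target that the common factor already explains
    almost fully leaves the independent stream too weakly identified to be
    informative.  Returns the model plus the genetic covariance restricted
    to the factor's indicators (the subtraction model is fitted on those).
    """
    model = first_order.model.model
    owners = [r.lhs for r in model.rows if r.op == "=~" and r.rhs == target]
    if len(owners) != 1:
        raise ConfigurationError(
            f"target {target!r} must load on exactly one first-order factor, found {owners}"
        )
    factor = owners[0]
    resid = first_order.residual_variance(target, standardized=True)
    if not resid > gate:
        raise InputError(
            f"target {target!r} has standardized residual variance {resid:.4f}, "
            f"not above the gate {gate:.2f}; subtraction refused"
        )

    indicators = [r.rhs for r in model.rows if r.op == "=~" and r.lhs == factor]
    sub_gcov = first_order.model.gcov.subset(indicators)

    sub = SemModel()
    loading_rows = [r for r in model.rows if r.op == "=~" and r.lhs == factor]
    for r in loading_rows:
        start = float(first_order.params.get(r.name, r.value if r.value is not None else 0.5))
        # equality labels carry over so constrained measurement structures
        # (e.g. two-indicator factors) stay identified in the subtraction model
        label = f"c_{r.label}" if r.label else None
        sub.add(COMMON, "=~", r.rhs, free=r.free, value=start, label=label)
    sub.add(COMMON, "~~", COMMON, free=False, value=1.0)
    sub.add(INDEPENDENT, "=~", target, free=True, value=max(np.sqrt(max(resid, 0.05)), 0.1))
    sub.add(INDEPENDENT, "~~", INDEPENDENT, free=False, value=1.0)
    sub.add(COMMON, "~~", INDEPENDENT, free=False, value=0.0)
    sub.add(target, "~~", target, free=False, value=0.0)  # fully decomposed
    tied = any(r.label for r in loading_rows)
    if len(indicators) == 2 and not tied:
        # untied two-indicator factor: only the pure Cholesky is identified,
        # so the co-indicator is also fully explained by Common (its stream
        # then reads "shared with the co-indicator" rather than "through the
        # factor"); an equality-constrained measurement model keeps the
        # factor reading and leaves the co-indicator's residual free
        other = next(i for i in indicators if i != target)
        sub.add(other, "~~", other, free=False, value=0.0)
    return sub, sub_gcov


def eligible_targets(first_order: GsemResults, gate: float = DEFAULT_RESIDUAL_GATE) -> list[str]:
    """Indicators whose standardized residual variance exceeds the gate."""
    model = first_order.model.model
    out = []
    for ind in first_order.model.observed:
        owners = [r.lhs for r in model.rows if r.op == "=~" and r.rhs == ind]
        if len(owners) != 1:
            continue
        if first_order.residual_variance(ind, standardized=True) > gate:
            out.append(ind)
    return out


def run_subtraction_gwas(
    model: SemModel,
    gcov: GenomicCovariance,
    tables: list[SumstatsTable],
    panel: LDPanel | None = None,
    target: str | None = None,
) -> pd.DataFrame:
    """Per-SNP DWLS estimates of the common and independent pathways.

    ``gcov`` and ``tables`` cover the subtraction model's indicators (see
    :func:`build_subtraction_model`).  Returns one row per shared SNP with
    per-allele effects on the target through each pathway, their SEs, and
    the path-tracing identity total = beta_common + beta_indep recorded in
    ``TOTAL_CHECK``.
    """
    target = target or next(r.rhs for r in model.rows if r.op == "=~" and r.lhs == INDEPENDENT)
    meas_model = GsemModel(gcov, model)
    meas = meas_model.fit()
    if not meas.converged:
        raise InputError("subtraction measurement model did not converge")
    resolved = meas.model.rows_resolved(meas.params)
    lam_c = next(r.value for r in resolved if r.op == "=~" and r.lhs == COMMON and r.rhs == target)
    lam_i = next(r.value for r in resolved if r.op == "=~" and r.lhs == INDEPENDENT and r.rhs == target)

    order = {t.trait_name: t for t in tables}
    tables = [order[n] for n in gcov.trait_names]
    common_ids = None
    for t in tables:
        d = t.df.set_index("SNP")
        common_ids = d.index if common_ids is None else common_ids.intersection(d.index)
    snp_ids = list(common_ids)
    frames = [t.df.set_index("SNP").loc[snp_ids] for t in tables]
    base = frames[0]
    order_idx = np.argsort(base["POS"].to_numpy() + base["CHR"].to_numpy() * 10**10, kind="mergesort")
    snp_ids = [snp_ids[i] for i in order_idx]
    frames = [f.iloc[order_idx] for f in frames]

    frq = frames[0]["FRQ"].to_numpy(dtype=float)
    scale = np.sqrt(2.0 * frq * (1.0 - frq))
    beta_std = np.column_stack([f["BETA"].to_numpy(dtype=float) for f in frames]) * scale[:, None]
    se_std = np.column_stack([f["SE"].to_numpy(dtype=float) for f in frames]) * scale[:, None]

    fitter = _PerSnpFitter(meas, [COMMON, INDEPENDENT])
    n = len(snp_ids)
    b_c = np.full(n, np.nan)
    s_c = np.full(n, np.nan)
    b_i = np.full(n, np.nan)
    s_i = np.full(n, np.nan)
    converged = np.zeros(n, dtype=bool)
    for j in range(n):
        res_c, _ = fitter.fit_snp(beta_std[j], se_std[j], fit_independent=False)
        converged[j] = res_c.converged
        if not res_c.converged:
            continue
        b_c[j] = res_c.params[f"{COMMON}~{SNP_NAME}"]
        s_c[j] = res_c.bse[f"{COMMON}~{SNP_NAME}"]
        b_i[j] = res_c.params[f"{INDEPENDENT}~{SNP_NAME}"]
        s_i[j] = res_c.bse[f"{INDEPENDENT}~{SNP_NAME}"]
    n_bad = int((~converged).sum())
    if n_bad:
        logger.warning("run_subtraction_gwas: %d SNPs flagged nonconverged", n_bad)

    # path-traced per-target effects, back on the per-allele scale
    beta_common = b_c * lam_c / scale
    se_common = s_c * abs(lam_c) / scale
    beta_indep = b_i * lam_i / scale
    se_indep = s_i * abs(lam_i) / scale
    z_c = beta_common / se_common
    z_i = beta_indep / se_indep
    out = pd.DataFrame(
        {
            "SNP": snp_ids,
            "CHR": frames[0]["CHR"].to_numpy(),
            "POS": frames[0]["POS"].to_numpy(),
            "A1": frames[0]["A1"].to_numpy(),
            "A2": frames[0]["A2"].to_numpy(),
            "FRQ": frq,
            "BETA_COMMON": beta_common,
            "SE_COMMON": se_common,
            "Z_COMMON": z_c,
            "P_COMMON": np.clip(2.0 * stats.norm.sf(np.abs(z_c)), np.finfo(float).tiny, 1.0),
            "BETA_INDEP": beta_indep,
            "SE_INDEP": se_indep,
            "Z_INDEP": z_i,
            "P_INDEP": np.clip(2.0 * stats.norm.sf(np.abs(z_i)), np.finfo(float).tiny, 1.0),
            "TOTAL_CHECK": beta_common + beta_indep,
            "CONVERGED": converged,
        }
    )
    out.attrs["target"] = target
    out.attrs["lambda_common"] = lam_c
    out.attrs["lambda_independent"] = lam_i
    out.attrs["variance_share_common"] = lam_c**2 / (lam_c**2 + lam_i**2)
    out.attrs["variance_share_independent"] = lam_i**2 / (lam_c**2 + lam_i**2)
    return out


def subtraction_effective_n(
    rows: pd.DataFrame,
    maf_window: tuple[float, float] = (0.1, 0.4),
    variance_share: dict[str, float] | None = None,
) -> dict[str, float]:
    """Effective sample sizes of the two streams, adjusted for the share of
    the target's heritability each latent carries.

    The SE-implied estimator is applied per stream and multiplied by that
    stream's variance share — a GWAS of a latent holding only (say) 40% of
    the target's genetic variance is equivalent in power to a GWAS of the
    full trait in a correspondingly smaller sample.
    """
    if variance_share is None:
        variance_share = {
            "common": rows.attrs.get("variance_share_common", 1.0),
            "independent": rows.attrs.get("variance_share_independent", 1.0),
        }
    for key, share in variance_share.items():
        if not (0.0 < share <= 1.0):
            raise InputError(f"variance share for {key} must be in (0,1], got {share}")
    conv = rows[rows["CONVERGED"].astype(bool)]
    n_common = effective_n(conv, maf_window, se_col="SE_COMMON")
    n_indep = effective_n(conv, maf_window, se_col="SE_INDEP")
    return {
        "N_eff_common": n_common * variance_share["common"],
        "N_eff_indep": n_indep * variance_share["independent"],
    }
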