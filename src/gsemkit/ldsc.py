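"""LD score regression: heritability, genetic covariance, intercepts, and the
jackknife sampling covariance V that the SEM layer consumes.

Univariate regression follows E[chi2_j] = 1 + N*a + (N*h2/M) * l_j; the
cross-trait version regresses z1*z2 on sqrt(N1*N2) * l_j / M, whose intercept
absorbs sample overlap times phenotypic correlation.  Standard errors and the
full sampling covariance of vech(S) come from a delete-a-block jackknife over
contiguous SNP blocks, recomputing every entry of S per deleted block so the
entries' sampling covariances are captured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import LDPanel
from .sumstats import SumstatsTable, TraitMeta
from .utils import InputError, contiguous_blocks, nearest_psd, unvech, vech_indices

logger = logging.getLogger(__name__)


@dataclass
class GenomicCovariance:
    """Genetic covariance matrix S, intercept matrix I, and jackknife V.

    ``V`` is the sampling covariance of vech(S), with vech fixed package-wide
    as the lower triangle in column-major order (see :func:`gsemkit.utils.vech`).
    """

    trait_names: list[str]
    S: np.ndarray
    I: np.ndarray
    V: np.ndarray
    M: int
    n_blocks: int
    mean_l2: float = 1.0
    se_S: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.se_S is None:
            self.se_S = unvech(np.sqrt(np.maximum(np.diag(self.V), 0.0)), self.k)

    @property
    def k(self) -> int:
        return len(self.trait_names)

    def subset(self, names: list[str]) -> "GenomicCovariance":
        """Restrict to a subset of traits, remapping V consistently."""
        idx = [self.trait_names.index(n) for n in names]
        k_old, k_new = self.k, len(idx)
        old_pos = {ij: pos for pos, ij in enumerate(vech_indices(k_old))}
        sel = []
        for i_new, j_new in vech_indices(k_new):
            a, b = idx[i_new], idx[j_new]
            sel.append(old_pos[(max(a, b), min(a, b))])
        return GenomicCovariance(
            trait_names=list(names),
            S=self.S[np.ix_(idx, idx)],
            I=self.I[np.ix_(idx, idx)],
            V=self.V[np.ix_(sel, sel)],
            M=self.M,
            n_blocks=self.n_blocks,
            mean_l2=self.mean_l2,
        )


def liability_conversion(h2_obs: float, P: float, K: float) -> float:
    """Observed-scale to liability-scale heritability for case-control designs.

    h2_liab = h2_obs * K^2 (1-K)^2 / (z^2 * P (1-P)) with z the standard
    normal density at the threshold Phi^{-1}(1-K).
    """
    if not (0.0 < P < 1.0 and 0.0 < K < 1.0):
        raise InputError(f"prevalences must be in (0,1), got P={P}, K={K}")
    return h2_obs * liability_multiplier(P, K)


def liability_multiplier(P: float, K: float) -> float:
    z = stats.norm.pdf(stats.norm.ppf(1.0 - K))
    return K**2 * (1.0 - K) ** 2 / (z**2 * P * (1.0 - P))


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least squares of y on [x, 1]; returns (slope, intercept)."""
    sw = w.sum()
    sx = (w * x).sum()
    sy = (w * y).sum()
    sxx = (w * x * x).sum()
    sxy = (w * x * y).sum()
    det = sw * sxx - sx * sx
    if not det > 1e-12 * sw * sxx:
        raise InputError(
            "LD-score regressor has (almost) no spread; the regression is unidentified"
        )
    slope = (sw * sxy - sx * sy) / det
    intercept = (sy - slope * sx) / sw
    return slope, intercept


def _wls_jackknife(
    x: np.ndarray, y: np.ndarray, w: np.ndarray, block_ids: np.ndarray, n_blocks: int,
    fixed_intercept: float | None = None,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """WLS fit plus delete-one-block estimates of (slope, intercept).

    Returns (slope, intercept, slopes_del, intercepts_del) where the delete
    arrays have one entry per jackknife block.
    """
    if fixed_intercept is not None:
        y = y - fixed_intercept
        tot = np.array([(w * x * x).sum(), (w * x * y).sum()])
        per = np.zeros((n_blocks, 2))
        np.add.at(per[:, 0], block_ids, w * x * x)
        np.add.at(per[:, 1], block_ids, w * x * y)
        slope = tot[1] / tot[0]
        deltas = (tot[None, :] - per)
        slopes_del = deltas[:, 1] / deltas[:, 0]
        return slope, fixed_intercept, slopes_del, np.full(n_blocks, fixed_intercept)

    cols = np.column_stack([w, w * x, w * y, w * x * x, w * x * y])
    tot = cols.sum(axis=0)
    per = np.zeros((n_blocks, 5))
    np.add.at(per, block_ids, cols)
    sw, sx, sy, sxx, sxy = tot
    det = sw * sxx - sx * sx
    slope = (sw * sxy - sx * sy) / det
    intercept = (sy - slope * sx) / sw

    d = tot[None, :] - per
    det_d = d[:, 0] * d[:, 3] - d[:, 1] ** 2
    slopes_del = (d[:, 0] * d[:, 4] - d[:, 1] * d[:, 2]) / det_d
    intercepts_del = (d[:, 2] - slopes_del * d[:, 1]) / d[:, 0]
    return slope, intercept, slopes_del, intercepts_del


def _jackknife_se(deletes: np.ndarray) -> float:
    g = len(deletes)
    return float(np.sqrt((g - 1) / g * ((deletes - deletes.mean()) ** 2).sum()))


def _merge_to_panel(table: SumstatsTable, panel_frame: pd.DataFrame) -> pd.DataFrame:
    df = table.df.merge(panel_frame[["SNP", "L2"]], on="SNP", how="inner")
    return df.sort_values(["CHR", "POS", "SNP"], kind="mergesort").reset_index(drop=True)


def _uni_weights(l2, n, h2, intercept, m):
    het = (intercept + n * h2 * l2 / m) ** 2
    return 1.0 / (np.maximum(l2, 1.0) * np.maximum(het, 1e-6))


def _bi_weights(l2, n1, n2, h1, h2_, int1, int2, rho_g, cross_int, m):
    v1 = int1 + n1 * h1 * l2 / m
    v2 = int2 + n2 * h2_ * l2 / m
    c12 = cross_int + np.sqrt(n1 * n2) * rho_g * l2 / m
    het = v1 * v2 + c12**2
    return 1.0 / (np.maximum(l2, 1.0) * np.maximum(het, 1e-6))


def _uni_fit(z, l2, n, m, block_ids, n_blocks, two_step_threshold=None, n_iter=2,
             fixed_intercept=None):
    """Core univariate regression; returns estimates plus delete-block slopes."""
    chi2 = z**2
    x = n * l2 / m
    h2_0 = max(m * (chi2.mean() - 1.0) / (n * l2).mean(), 0.0)
    w = _uni_weights(l2, n, h2_0, 1.0, m)
    if fixed_intercept is not None:
        slope, _, _, _ = _wls_jackknife(x, chi2, w, block_ids, n_blocks,
                                        fixed_intercept=fixed_intercept)
        w = _uni_weights(l2, n, max(slope, 0.0), fixed_intercept, m)
        return _wls_jackknife(x, chi2, w, block_ids, n_blocks,
                              fixed_intercept=fixed_intercept) + (w,)
    slope, intercept = _wls(x, y=chi2, w=w)
    for _ in range(n_iter - 1):
        w = _uni_weights(l2, n, max(slope, 0.0), max(intercept, 0.05), m)
        slope, intercept = _wls(x, chi2, w)

    if two_step_threshold is not None:
        # step 1: intercept from low-chi2 SNPs; step 2: slope with fixed intercept
        mask = chi2 < two_step_threshold
        _, intercept = _wls(x[mask], chi2[mask], w[mask])
        slope, intercept, slopes_del, ints_del = _wls_jackknife(
            x, chi2, w, block_ids, n_blocks, fixed_intercept=intercept
        )
    else:
        slope, intercept, slopes_del, ints_del = _wls_jackknife(x, chi2, w, block_ids, n_blocks)
    return slope, intercept, slopes_del, ints_del, w


def univariate_ldsc(
    table: SumstatsTable,
    panel: LDPanel,
    n_blocks: int = 200,
    two_step_threshold: float | None = None,
    fixed_intercept: float | None = None,
) -> dict:
    """Estimate SNP heritability and the confounding intercept for one trait.

    ``fixed_intercept`` constrains the intercept (to 1 when the analysis
    asserts no confounding or miscalibration); the default leaves it free.
    Over a reference panel with a narrow LD-score range the free intercept is
    nearly collinear with the slope, so constraining it where the design
    justifies it buys a large precision gain.
    """
    df = _merge_to_panel(table, panel.snp_frame())
    if len(df) < 200:
        raise InputError(f"univariate_ldsc needs >= 200 SNPs, got {len(df)}")
    m = len(df)
    if n_blocks > m:
        logger.warning("univariate_ldsc: reducing n_blocks from %d to %d", n_blocks, m)
        n_blocks = m
    block_ids = contiguous_blocks(m, n_blocks)
    z = df["Z"].to_numpy(dtype=float)
    l2 = df["L2"].to_numpy(dtype=float)
    n = df["N"].to_numpy(dtype=float)
    h2, intercept, h2_del, int_del, _ = _uni_fit(
        z, l2, n, m, block_ids, n_blocks, two_step_threshold, fixed_intercept=fixed_intercept
    )
    if h2 < 0:
        logger.warning("univariate_ldsc(%s): negative h2 estimate %.4g reported as-is", table.trait_name, h2)
    return {
        "h2": float(h2),
        "intercept": float(intercept),
        "se_h2": _jackknife_se(h2_del),
        "se_intercept": _jackknife_se(int_del),
        "m": m,
        "h2_delete": h2_del,
        "intercept_delete": int_del,
    }


def bivariate_ldsc(
    t1: SumstatsTable,
    t2: SumstatsTable,
    panel: LDPanel,
    n_blocks: int = 200,
) -> dict:
    """Genetic covariance, cross-trait intercept and genetic correlation."""
    pf = panel.snp_frame()
    d1 = _merge_to_panel(t1, pf).set_index("SNP")
    d2 = _merge_to_panel(t2, pf).set_index("SNP")
    common = d1.index.intersection(d2.index)
    d1, d2 = d1.loc[common], d2.loc[common]
    order = np.argsort(d1["POS"].to_numpy() + d1["CHR"].to_numpy() * 10**10, kind="mergesort")
    d1, d2 = d1.iloc[order], d2.iloc[order]
    m = len(common)
    if m < 200:
        raise InputError(f"bivariate_ldsc needs >= 200 shared SNPs, got {m}")
    n_blocks = min(n_blocks, m)
    block_ids = contiguous_blocks(m, n_blocks)

    l2 = d1["L2"].to_numpy(dtype=float)
    z1, z2 = d1["Z"].to_numpy(dtype=float), d2["Z"].to_numpy(dtype=float)
    n1, n2 = d1["N"].to_numpy(dtype=float), d2["N"].to_numpy(dtype=float)

    u1 = _uni_fit(z1, l2, n1, m, block_ids, n_blocks)
    u2 = _uni_fit(z2, l2, n2, m, block_ids, n_blocks)
    h1, int1 = max(u1[0], 0.0), u1[1]
    h2_, int2 = max(u2[0], 0.0), u2[1]

    y = z1 * z2
    x = np.sqrt(n1 * n2) * l2 / m
    w = _bi_weights(l2, n1, n2, h1, h2_, int1, int2, 0.0, 0.0, m)
    rho_g, cross_int = _wls(x, y, w)
    w = _bi_weights(l2, n1, n2, h1, h2_, int1, int2, rho_g, cross_int, m)
    rho_g, cross_int, rho_del, ci_del = _wls_jackknife(x, y, w, block_ids, n_blocks)

    out = {
        "rho_g": float(rho_g),
        "cross_intercept": float(cross_int),
        "se_rho_g": _jackknife_se(rho_del),
        "se_cross_intercept": _jackknife_se(ci_del),
        "m": m,
        "rho_delete": rho_del,
        "cross_intercept_delete": ci_del,
        "h2_1": float(u1[0]),
        "h2_2": float(u2[0]),
    }
    if u1[0] > 0 and u2[0] > 0:
        rg = rho_g / np.sqrt(u1[0] * u2[0])
        rg_del = rho_del / np.sqrt(np.maximum(u1[2] * u2[2], 1e-12))
        out["r_g"] = float(rg)
        out["se_r_g"] = _jackknife_se(rg_del)
    else:
        logger.warning("bivariate_ldsc: non-positive h2, r_g undefined")
        out["r_g"] = np.nan
        out["se_r_g"] = np.nan
    return out


def multivariate_ldsc(
    tables: list[SumstatsTable],
    panel: LDPanel,
    n_blocks: int = 200,
    chrom_subset: str = "all",
    two_step_threshold: float | None = None,
    fixed_intercepts: bool = False,
) -> GenomicCovariance:
    """Assemble S, the intercept matrix I, and the joint jackknife V.

    All univariate and bivariate regressions run on the single intersected
    SNP set (optionally restricted to odd or even chromosomes), sharing one
    contiguous-block partition, and every entry of vech(S) is recomputed per
    deleted block so V captures the entries' sampling covariances.  When a
    trait's metadata carries sample and population prevalences, its entries
    of S (and V) are rescaled to the liability scale.

    ``fixed_intercepts=True`` constrains every univariate intercept to 1 and
    every cross-trait intercept to 0 — appropriate only for analyses whose
    design rules out confounding and sample overlap (e.g. simulation studies
    that declare both absent); I is then reported as the identity.
    """
    if len(tables) < 2:
        raise InputError("multivariate_ldsc needs >= 2 traits")
    if chrom_subset not in ("all", "odd", "even"):
        raise InputError(f"chrom_subset must be all|odd|even, got {chrom_subset!r}")
    k = len(tables)
    names = [t.trait_name for t in tables]
    pf = panel.snp_frame()

    frames = []
    common = None
    for t in tables:
        d = _merge_to_panel(t, pf).set_index("SNP")
        common = d.index if common is None else common.intersection(d.index)
        frames.append(d)
    frames = [f.loc[common] for f in frames]
    base = frames[0]
    keep = np.ones(len(base), dtype=bool)
    if chrom_subset != "all":
        parity = 1 if chrom_subset == "odd" else 0
        keep = (base["CHR"].to_numpy() % 2) == parity
    order = np.argsort(
        base["POS"].to_numpy()[keep] + base["CHR"].to_numpy()[keep] * 10**10, kind="mergesort"
    )
    frames = [f.loc[keep].iloc[order] for f in frames]
    m = len(frames[0])
    if m < 200 * k:
        raise InputError(f"intersected SNP set has {m} SNPs; need >= {200 * k}")
    n_blocks = min(n_blocks, m)
    block_ids = contiguous_blocks(m, n_blocks)

    l2 = frames[0]["L2"].to_numpy(dtype=float)
    zs = [f["Z"].to_numpy(dtype=float) for f in frames]
    ns = [f["N"].to_numpy(dtype=float) for f in frames]

    # liability-scale multipliers (sqrt scale per trait)
    scale = np.ones(k)
    for i, t in enumerate(tables):
        meta = t.meta
        if (
            meta is not None
            and meta.measurement == "case-control"
            and meta.sample_prevalence is not None
            and meta.population_prevalence is not None
        ):
            scale[i] = np.sqrt(liability_multiplier(meta.sample_prevalence, meta.population_prevalence))

    uni = [
        _uni_fit(zs[i], l2, ns[i], m, block_ids, n_blocks, two_step_threshold,
                 fixed_intercept=1.0 if fixed_intercepts else None)
        for i in range(k)
    ]

    S = np.zeros((k, k))
    I_mat = np.eye(k)
    deletes = np.zeros((n_blocks, k * (k + 1) // 2))
    from .utils import vech_index

    for i in range(k):
        S[i, i] = uni[i][0] * scale[i] ** 2
        I_mat[i, i] = uni[i][1]
        deletes[:, vech_index(i, i, k)] = uni[i][2] * scale[i] ** 2

    for i in range(k):
        for j in range(i + 1, k):
            h_i, h_j = max(uni[i][0], 0.0), max(uni[j][0], 0.0)
            y = zs[i] * zs[j]
            x = np.sqrt(ns[i] * ns[j]) * l2 / m
            fix_c = 0.0 if fixed_intercepts else None
            w = _bi_weights(l2, ns[i], ns[j], h_i, h_j, uni[i][1], uni[j][1], 0.0, 0.0, m)
            if fix_c is None:
                rho_g, cross_int = _wls(x, y, w)
            else:
                rho_g, cross_int = _wls_jackknife(x, y, w, block_ids, n_blocks, fixed_intercept=fix_c)[:2]
            w = _bi_weights(l2, ns[i], ns[j], h_i, h_j, uni[i][1], uni[j][1], rho_g, cross_int, m)
            rho_g, cross_int, rho_del, _ = _wls_jackknife(
                x, y, w, block_ids, n_blocks, fixed_intercept=fix_c
            )
            S[i, j] = S[j, i] = rho_g * scale[i] * scale[j]
            I_mat[i, j] = I_mat[j, i] = cross_int
            deletes[:, vech_index(j, i, k)] = rho_del * scale[i] * scale[j]

    centered = deletes - deletes.mean(axis=0, keepdims=True)
    V = (n_blocks - 1) / n_blocks * (centered.T @ centered)
    V = (V + V.T) / 2.0

    return GenomicCovariance(
        trait_names=names,
        S=S,
        I=I_mat,
        V=V,
        M=m,
        n_blocks=n_blocks,
        mean_l2=float(l2.mean()),
    )
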