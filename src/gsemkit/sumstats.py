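"""Reading, validating, harmonizing and MTAG-combining GWAS summary statistics.

The canonical in-memory form is a :class:`SumstatsTable`: a pandas DataFrame
with columns SNP CHR POS A1 A2 BETA SE Z P FRQ N, one row per variant, with
effects on the analysis scale (log-odds for case-control GWASs) and A1 as the
effect allele.  Everything downstream — LD score regression, factor models,
factor GWAS — consumes this form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .panel import LDPanel
from .utils import COMPLEMENT, ConfigurationError, InputError, is_ambiguous, nearest_psd

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = ["SNP", "CHR", "POS", "A1", "A2", "BETA", "SE", "Z", "P", "FRQ", "N"]


@dataclass
class TraitMeta:
    """Study-design metadata for one trait."""

    trait_name: str
    measurement: str = "continuous"  # "continuous" or "case-control"
    n_cases: int | None = None
    n_controls: int | None = None
    sample_prevalence: float | None = None
    population_prevalence: float | None = None

    def __post_init__(self):
        if self.measurement not in ("continuous", "case-control"):
            raise ConfigurationError(f"unknown measurement type {self.measurement!r}")
        if self.sample_prevalence is None and self.n_cases and self.n_controls:
            self.sample_prevalence = self.n_cases / (self.n_cases + self.n_controls)

    @property
    def n_effective(self) -> float | None:
        """Effective N for a case-control design: 4 / (1/cases + 1/controls)."""
        if self.n_cases and self.n_controls:
            return 4.0 / (1.0 / self.n_cases + 1.0 / self.n_controls)
        return None


@dataclass
class SumstatsTable:
    """Harmonized per-SNP association records for one trait."""

    trait_name: str
    df: pd.DataFrame
    meta: TraitMeta | None = None

    def __post_init__(self):
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise InputError(f"sumstats for {self.trait_name} missing columns {missing}")

    @property
    def n_snps(self) -> int:
        return len(self.df)

    def sorted(self) -> "SumstatsTable":
        df = self.df.sort_values(["CHR", "POS", "SNP"], kind="mergesort").reset_index(drop=True)
        return SumstatsTable(self.trait_name, df, self.meta)

    def write(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path, trait_name: str | None = None, meta: TraitMeta | None = None):
        df = pd.read_csv(path, sep="\t")
        name = trait_name or Path(path).stem.removesuffix(".sumstats")
        return cls(name, df, meta)


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(z))
    # a true null effect must report p = 1, and p = 0 underflow is clipped
    return np.clip(p, np.finfo(float).tiny, 1.0)


def read_sumstats(
    path: str | Path,
    column_map: dict[str, str],
    trait_meta: TraitMeta | None = None,
    odds_ratio: bool = False,
    sep: str | None = None,
) -> SumstatsTable:
    """Read delimited summary statistics into canonical form.

    ``column_map`` maps file column names to canonical fields (lowercase):
    snp_id, chrom, pos, a1, a2, beta (or odds ratio with ``odds_ratio=True``),
    se, z, p, frq, n, info.  At minimum snp_id, a1, a2 and either (beta, se)
    or (z, n, frq) must be mapped.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=sep or r"\s+", engine="python")
    inv = {}
    for file_col, canon in column_map.items():
        if file_col not in raw.columns:
            raise ConfigurationError(f"mapped column {file_col!r} not present in {path.name}")
        inv[canon.lower()] = file_col

    for required in ("snp_id", "a1", "a2"):
        if required not in inv:
            raise ConfigurationError(f"column map must cover {required!r}")
    has_beta = "beta" in inv and "se" in inv
    has_z = "z" in inv and "n" in inv and "frq" in inv
    if not (has_beta or has_z):
        raise ConfigurationError("column map must cover (beta, se) or (z, n, frq)")

    out = pd.DataFrame()
    out["SNP"] = raw[inv["snp_id"]].astype(str)
    out["CHR"] = pd.to_numeric(raw[inv["chrom"]], errors="coerce") if "chrom" in inv else np.nan
    out["POS"] = pd.to_numeric(raw[inv["pos"]], errors="coerce") if "pos" in inv else np.nan
    out["A1"] = raw[inv["a1"]].astype(str).str.upper()
    out["A2"] = raw[inv["a2"]].astype(str).str.upper()
    out["FRQ"] = pd.to_numeric(raw[inv["frq"]], errors="coerce") if "frq" in inv else np.nan

    if "n" in inv:
        out["N"] = pd.to_numeric(raw[inv["n"]], errors="coerce")
    elif trait_meta is not None and trait_meta.n_effective is not None:
        out["N"] = trait_meta.n_effective
    else:
        out["N"] = np.nan

    if has_beta:
        beta = pd.to_numeric(raw[inv["beta"]], errors="coerce").to_numpy(dtype=float)
        if odds_ratio:
            with np.errstate(invalid="ignore", divide="ignore"):
                beta = np.log(beta)
        se = pd.to_numeric(raw[inv["se"]], errors="coerce").to_numpy(dtype=float)
    else:
        z = pd.to_numeric(raw[inv["z"]], errors="coerce").to_numpy(dtype=float)
        frq = out["FRQ"].to_numpy(dtype=float)
        n = out["N"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            se = 1.0 / np.sqrt(2.0 * frq * (1.0 - frq) * n)
        beta = z * se
    out["BETA"] = beta
    out["SE"] = se

    with np.errstate(invalid="ignore", divide="ignore"):
        z_filled = out["BETA"].to_numpy() / out["SE"].to_numpy()
    if "z" in inv:
        z_col = pd.to_numeric(raw[inv["z"]], errors="coerce").to_numpy(dtype=float)
        z_filled = np.where(np.isfinite(z_col), z_col, z_filled)
    out["Z"] = z_filled
    out["P"] = (
        pd.to_numeric(raw[inv["p"]], errors="coerce").to_numpy(dtype=float)
        if "p" in inv
        else _two_sided_p(out["Z"].to_numpy())
    )
    out["P"] = np.where(np.isfinite(out["P"]), out["P"], _two_sided_p(out["Z"].to_numpy()))
    if "info" in inv:
        out["INFO"] = pd.to_numeric(raw[inv["info"]], errors="coerce")

    required_finite = out[["BETA", "SE", "Z"]].to_numpy(dtype=float)
    keep = np.isfinite(required_finite).all(axis=1) & (out["SE"].to_numpy() > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("read_sumstats(%s): dropped %d rows with non-finite required fields", path.name, n_dropped)
    out = out.loc[keep].reset_index(drop=True)
    if len(out) == 0:
        raise InputError(f"no parseable rows in {path}")

    name = trait_meta.trait_name if trait_meta is not None else path.stem
    cols = CANONICAL_COLUMNS + (["INFO"] if "INFO" in out.columns else [])
    return SumstatsTable(name, out[cols], trait_meta)


def munge(
    table: SumstatsTable,
    panel: LDPanel,
    maf_min: float = 0.01,
    info_min: float = 0.9,
    drop_ambiguous: bool = True,
) -> SumstatsTable:
    """Restrict to the panel, align alleles to panel orientation, apply QC filters.

    Variants whose alleles are swapped relative to the panel have BETA and Z
    negated; strand flips (complements) are resolved before comparison;
    irreconcilable allele pairs are dropped and logged.  The panel's alleles,
    frequencies and coordinates become authoritative.
    """
    ref = panel.snp_frame().rename(
        columns={"CHR": "CHR_ref", "POS": "POS_ref", "A1": "A1_ref", "A2": "A2_ref", "MAF": "MAF_ref"}
    )
    merged = table.df.merge(ref[["SNP", "CHR_ref", "POS_ref", "A1_ref", "A2_ref", "MAF_ref"]], on="SNP", how="inner")
    if len(merged) == 0:
        raise InputError(f"no overlap between {table.trait_name} and the panel")

    a1 = merged["A1"].to_numpy(dtype=object)
    a2 = merged["A2"].to_numpy(dtype=object)
    r1 = merged["A1_ref"].to_numpy(dtype=object)
    r2 = merged["A2_ref"].to_numpy(dtype=object)

    c1 = np.array([COMPLEMENT.get(a, "N") for a in a1], dtype=object)
    c2 = np.array([COMPLEMENT.get(a, "N") for a in a2], dtype=object)

    same = (a1 == r1) & (a2 == r2)
    swap = (a1 == r2) & (a2 == r1)
    same_c = (c1 == r1) & (c2 == r2)
    swap_c = (c1 == r2) & (c2 == r1)

    keep_same = same | (~same & ~swap & same_c)
    keep_swap = (~keep_same) & (swap | (~swap & swap_c))
    matched = keep_same | keep_swap
    n_bad = int((~matched).sum())
    if n_bad:
        logger.info("munge(%s): dropped %d variants with irreconcilable alleles", table.trait_name, n_bad)

    ambiguous = np.array([is_ambiguous(x, y) for x, y in zip(a1, a2)])
    keep = matched & (~ambiguous if drop_ambiguous else True)

    maf = merged["MAF_ref"].to_numpy(dtype=float)
    keep &= np.minimum(maf, 1.0 - maf) >= maf_min
    if "INFO" in merged.columns:
        info = merged["INFO"].to_numpy(dtype=float)
        keep &= ~(np.isfinite(info) & (info < info_min))

    out = merged.loc[keep].copy()
    flip = keep_swap[keep]
    sign = np.where(flip, -1.0, 1.0)
    out["BETA"] = out["BETA"].to_numpy() * sign
    out["A1"] = out["A1_ref"]
    out["A2"] = out["A2_ref"]
    out["CHR"] = out["CHR_ref"].astype(int)
    out["POS"] = out["POS_ref"].astype(np.int64)
    out["FRQ"] = out["MAF_ref"]
    out["Z"] = out["BETA"].to_numpy() / out["SE"].to_numpy()
    out["P"] = _two_sided_p(out["Z"].to_numpy())
    out = out[CANONICAL_COLUMNS]
    if out["SNP"].duplicated().any():
        out = out.drop_duplicates(subset="SNP", keep="first")
    result = SumstatsTable(table.trait_name, out.reset_index(drop=True), table.meta)
    return result.sorted()


def mtag_combine(tables: list[SumstatsTable], gcov, target: str) -> SumstatsTable:
    """Multi-trait GLS combination of summary statistics for one target trait.

    Per-SNP marginal standardized effects across traits are modeled as draws
    from a common genome-wide effect-size covariance Omega (moment estimate
    from the LD score regression genetic covariance S, scaled by the mean LD
    score over the analysis SNP set), with per-SNP sampling covariance built
    from the standardized SEs and the cross-trait intercepts.  The target
    trait's effect is re-estimated by generalized least squares.
    """
    if len(tables) < 2:
        if len(tables) == 1 and tables[0].trait_name == target:
            return tables[0]
        raise InputError("mtag_combine needs >= 2 tables (or the single target table)")
    names = [t.trait_name for t in tables]
    if target not in names:
        raise ConfigurationError(f"target {target!r} not among inputs {names}")
    t_idx = names.index(target)
    order = [gcov.trait_names.index(n) for n in names]
    S = gcov.S[np.ix_(order, order)]
    I_mat = gcov.I[np.ix_(order, order)]
    k = len(names)

    common = None
    frames = []
    for t in tables:
        d = t.df.set_index("SNP")
        common = d.index if common is None else common.intersection(d.index)
        frames.append(d)
    common = sorted(common)
    if len(common) == 0:
        raise InputError("no shared SNPs across input tables")

    # standardized per-SD effects and their sampling SDs
    b = np.column_stack([f.loc[common, "Z"].to_numpy() / np.sqrt(f.loc[common, "N"].to_numpy()) for f in frames])
    s = np.column_stack([1.0 / np.sqrt(f.loc[common, "N"].to_numpy()) for f in frames])

    ell_bar = getattr(gcov, "mean_l2", 1.0) or 1.0
    omega = nearest_psd(S * ell_bar / gcov.M, eps=0.0)

    rho = I_mat / np.sqrt(np.outer(np.diag(I_mat), np.diag(I_mat)))
    np.fill_diagonal(rho, 1.0)

    w = omega[:, t_idx] / omega[t_idx, t_idx]
    omega_res = omega - np.outer(omega[:, t_idx], omega[:, t_idx]) / omega[t_idx, t_idx]

    tgt = frames[t_idx].loc[common]
    n_snps = len(common)
    beta_new = np.full(n_snps, np.nan)
    se_new = np.full(n_snps, np.nan)
    skipped = 0
    for j in range(n_snps):
        sigma_j = rho * np.outer(s[j], s[j])
        mid = omega_res + sigma_j
        try:
            mi = np.linalg.solve(mid, np.column_stack([w, b[j]]))
        except np.linalg.LinAlgError:
            skipped += 1
            continue
        denom = float(w @ mi[:, 0])
        if denom <= 0:
            skipped += 1
            continue
        beta_new[j] = float(w @ mi[:, 1]) / denom
        se_new[j] = np.sqrt(1.0 / denom)
    if skipped:
        logger.warning("mtag_combine: skipped %d SNPs with singular sampling covariance", skipped)

    frq = tgt["FRQ"].to_numpy(dtype=float)
    scale = np.sqrt(2.0 * frq * (1.0 - frq))
    z = beta_new / se_new
    out = pd.DataFrame(
        {
            "SNP": common,
            "CHR": tgt["CHR"].to_numpy(),
            "POS": tgt["POS"].to_numpy(),
            "A1": tgt["A1"].to_numpy(),
            "A2": tgt["A2"].to_numpy(),
            "BETA": beta_new / scale,
            "SE": se_new / scale,
            "Z": z,
            "P": _two_sided_p(z),
            "FRQ": frq,
            "N": 1.0 / se_new**2,
        }
    )
    keep = np.isfinite(out["BETA"].to_numpy())
    out = out.loc[keep].reset_index(drop=True)
    result = SumstatsTable(target, out, tables[t_idx].meta)
    return result.sorted()
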