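"""End-to-end orchestration: simulate/ingest -> munge -> LDSC -> EFA/CFA ->
factor GWAS -> subtraction -> clump -> genetic-correlation profile.

One :class:`PipelineConfig` carries every path, threshold and seed; a run
writes tab-delimited stage outputs plus a manifest recording versions, seeds,
input digests and per-stage SNP counts, sufficient to reproduce the run.
The exploratory/confirmatory split follows the odd/even-chromosome design:
EFA sees the odd-chromosome genetic covariance, the CFA is fitted on the
even chromosomes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import __version__
from .gwas import DEFAULT_QSNP_THRESHOLD, clump, effective_n, snp_factor_gwas, write_factor_gwas
from .ldsc import bivariate_ldsc, multivariate_ldsc
from .panel import LDPanel, build_ld_panel
from .sem import GsemModel, common_factor_model, efa, suggest_n_factors
from .simulate import TruthModel, simulate_sumstats, simulate_truth_effects
from .subtraction import (
    DEFAULT_RESIDUAL_GATE,
    build_subtraction_model,
    eligible_targets,
    run_subtraction_gwas,
    subtraction_effective_n,
)
from .sumstats import SumstatsTable, TraitMeta, munge, read_sumstats
from .utils import ConfigurationError, stage_seed

logger = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "munge", "ldsc", "efa", "cfa", "gwas", "subtraction", "clump", "rg_profile"]


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run.

    Defaults equal the values documented in the owning modules (munging
    filters, 200 jackknife blocks, Q_SNP threshold 5e-28, clumping
    p1=5e-8 / r2=0.1 / 250 kb, subtraction gate 0.30).
    """

    outdir: str = "gsemkit_run"
    seed: int = 0
    stages: dict = field(
        default_factory=lambda: {s: True for s in STAGE_ORDER}
    )
    # synthetic inputs (simulate stage) -- either this or sumstats paths
    simulate: dict | None = None
    # real inputs
    sumstats_files: list[dict] | None = None
    panel_dir: str | None = None
    # thresholds
    maf_min: float = 0.01
    info_min: float = 0.9
    drop_ambiguous: bool = True
    n_blocks: int = 200
    fixed_intercepts: bool = False  # constrain LDSC intercepts (no-overlap designs only)
    split_chromosomes: bool = True
    n_factors: int | None = None
    cfa_model: str | None = None
    qsnp_threshold: float = DEFAULT_QSNP_THRESHOLD
    clump_p1: float = 5e-8
    clump_r2: float = 0.1
    clump_window_kb: float = 250.0
    subtraction_gate: float = DEFAULT_RESIDUAL_GATE
    subtraction_targets: list | None = None
    rg_externals: list | None = None  # trait names to profile against

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for s in cfg.stages:
            if s not in STAGE_ORDER:
                raise ConfigurationError(f"unknown stage {s!r}")
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _truth_from_config(sim: dict) -> tuple[TruthModel, dict]:
    panel_cfg = dict(sim.get("panel", {"n_blocks": 500, "snps_per_block": 40, "rho": [0.0, 0.9]}))
    if isinstance(panel_cfg.get("rho"), list):
        panel_cfg["rho"] = tuple(panel_cfg["rho"])
    if isinstance(panel_cfg.get("maf_range"), list):
        panel_cfg["maf_range"] = tuple(panel_cfg["maf_range"])
    truth = TruthModel(
        trait_names=list(sim["trait_names"]),
        loadings=np.asarray(sim["loadings"], dtype=float),
        factor_corr=np.asarray(sim.get("factor_corr", np.eye(np.shape(sim["loadings"])[1]))),
        h2=np.asarray(sim["h2"], dtype=float),
        n=np.asarray(sim["n"], dtype=float),
        polygenicity=float(sim.get("polygenicity", 0.2)),
        overlap=np.asarray(sim["overlap"], dtype=float) if "overlap" in sim else None,
    )
    return truth, panel_cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns (and writes) the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    on = {s: config.stages.get(s, False) for s in STAGE_ORDER}
    manifest: dict = {
        "package": "gsemkit",
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGE_ORDER},
        "config": dataclasses.asdict(config),
        "stages": {},
    }

    def finish(status="complete"):
        manifest["status"] = status
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        return manifest

    try:
        # ---- inputs: simulate or read ------------------------------------
        if on["simulate"]:
            if config.simulate is None:
                raise ConfigurationError("simulate stage enabled but no 'simulate' block given")
            truth, panel_cfg = _truth_from_config(config.simulate)
            panel = build_ld_panel(seed=stage_seed(config.seed, "panel"), **panel_cfg)
            fx = simulate_truth_effects(truth, panel, seed=stage_seed(config.seed, "effects"))
            tables = simulate_sumstats(fx, panel, truth, seed=stage_seed(config.seed, "sumstats"))
            panel.save(outdir / "panel")
            truth_df = pd.DataFrame(fx.beta, columns=truth.trait_names)
            truth_df.insert(0, "SNP", fx.snp_ids)
            truth_df.to_csv(outdir / "true_effects.tsv", sep="\t", index=False)
            manifest["stages"]["simulate"] = {
                "n_snps": panel.n_snps,
                "n_traits": truth.k,
                "outputs": ["panel/", "true_effects.tsv"],
            }
        elif config.sumstats_files:
            if config.panel_dir is None:
                raise ConfigurationError("real-data input requires panel_dir")
            panel = LDPanel.load(config.panel_dir)
            tables = []
            digests = {}
            for spec_entry in config.sumstats_files:
                meta = None
                if "meta" in spec_entry:
                    meta = TraitMeta(trait_name=spec_entry["trait_name"], **spec_entry["meta"])
                tables.append(
                    read_sumstats(
                        spec_entry["path"],
                        column_map=spec_entry["column_map"],
                        trait_meta=meta,
                        odds_ratio=spec_entry.get("odds_ratio", False),
                    )
                )
                digests[spec_entry["trait_name"]] = _digest(Path(spec_entry["path"]))
            manifest["input_digests"] = digests
        else:
            raise ConfigurationError("no inputs: enable the simulate stage or give sumstats_files")

        # ---- munge -------------------------------------------------------
        if on["munge"]:
            munged = []
            counts = {}
            for t in tables:
                mt = munge(
                    t, panel,
                    maf_min=config.maf_min, info_min=config.info_min,
                    drop_ambiguous=config.drop_ambiguous,
                )
                counts[t.trait_name] = {"in": t.n_snps, "out": mt.n_snps}
                munged.append(mt)
            tables = munged
            sumdir = outdir / "munged"
            sumdir.mkdir(exist_ok=True)
            for t in tables:
                t.write(sumdir / f"{t.trait_name}.sumstats.tsv")
            manifest["stages"]["munge"] = {"snp_counts": counts}

        # ---- LDSC --------------------------------------------------------
        if not on["ldsc"]:
            if any(on[s] for s in ("efa", "cfa", "gwas", "subtraction")):
                raise ConfigurationError("downstream stages require the ldsc stage")
            return finish()
        gcov_all = multivariate_ldsc(tables, panel, n_blocks=config.n_blocks,
                                     fixed_intercepts=config.fixed_intercepts)
        np.savetxt(outdir / "S.tsv", gcov_all.S, delimiter="\t")
        np.savetxt(outdir / "I.tsv", gcov_all.I, delimiter="\t")
        np.savetxt(outdir / "V.tsv", gcov_all.V, delimiter="\t")
        manifest["stages"]["ldsc"] = {
            "M": gcov_all.M,
            "h2": dict(zip(gcov_all.trait_names, np.round(np.diag(gcov_all.S), 4).tolist())),
        }
        if config.split_chromosomes:
            gcov_efa = multivariate_ldsc(tables, panel, n_blocks=config.n_blocks, chrom_subset="odd",
                                         fixed_intercepts=config.fixed_intercepts)
            gcov_cfa = multivariate_ldsc(tables, panel, n_blocks=config.n_blocks, chrom_subset="even",
                                         fixed_intercepts=config.fixed_intercepts)
        else:
            gcov_efa = gcov_cfa = gcov_all

        # ---- EFA ---------------------------------------------------------
        factors_map = None
        if on["efa"]:
            n_fac = config.n_factors or suggest_n_factors(gcov_efa.S)
            efa_res = efa(gcov_efa, n_fac)
            efa_res.loadings.to_csv(outdir / "efa_loadings.tsv", sep="\t")
            manifest["stages"]["efa"] = {
                "n_factors": n_fac,
                "eigenvalues": np.round(efa_res.eigenvalues, 4).tolist(),
                "prop_var": np.round(efa_res.prop_var, 4).tolist(),
            }
            assign = efa_res.loadings.abs().idxmax(axis=1)
            factors_map = {
                f: [t for t in efa_res.loadings.index if assign[t] == f]
                for f in efa_res.loadings.columns
            }
            factors_map = {f: mems for f, mems in factors_map.items() if mems}
            if any(len(m) < 2 for m in factors_map.values()):
                raise ConfigurationError(
                    f"EFA assignment left a factor with < 2 indicators: {factors_map}; "
                    "supply an explicit cfa_model"
                )

        # ---- CFA ---------------------------------------------------------
        if not on["cfa"]:
            if any(on[s] for s in ("gwas", "subtraction")):
                raise ConfigurationError("factor GWAS and subtraction require the cfa stage")
            return finish()
        if config.cfa_model is not None:
            cfa_res = GsemModel(gcov_cfa, config.cfa_model).fit()
        elif factors_map is not None:
            cfa_res = GsemModel(gcov_cfa, common_factor_model(factors_map)).fit()
        else:
            raise ConfigurationError("cfa stage needs the efa stage or an explicit cfa_model")
        (outdir / "cfa_summary.txt").write_text(cfa_res.summary())
        manifest["stages"]["cfa"] = {
            "chi2": round(cfa_res.chi2, 4), "df": cfa_res.df,
            "aic": round(cfa_res.aic, 4), "cfi": round(cfa_res.cfi, 4),
            "srmr": round(cfa_res.srmr, 4), "converged": cfa_res.converged,
        }

        # ---- factor GWAS -------------------------------------------------
        gwas_tables = {}
        if on["gwas"]:
            rows = snp_factor_gwas(
                cfa_res, tables, panel, qsnp_threshold=config.qsnp_threshold
            )
            n_eff = {}
            for f in cfa_res.model.model.latents:
                write_factor_gwas(rows, f, outdir / f"gwas_{f}.tsv")
                sub = rows.rename(
                    columns={f"BETA_{f}": "BETA", f"SE_{f}": "SE", f"Z_{f}": "Z", f"P_{f}": "P"}
                )
                gwas_tables[f] = sub
                n_eff[f] = effective_n(sub)
            manifest["stages"]["gwas"] = {
                "n_snps": len(rows),
                "n_het_removed": int(rows["HET_REMOVED"].sum()),
                "n_nonconverged": int((~rows["CONVERGED"]).sum()),
                "effective_n": {f: round(v, 1) for f, v in n_eff.items()},
            }

        # ---- subtraction -------------------------------------------------
        subtraction_tables = {}
        if on["subtraction"]:
            targets = config.subtraction_targets or eligible_targets(
                cfa_res, gate=config.subtraction_gate
            )
            sub_info = {}
            for target in targets:
                model, sub_g = build_subtraction_model(cfa_res, target, gate=config.subtraction_gate)
                sub_rows = run_subtraction_gwas(model, sub_g, tables, panel, target=target)
                for stream, bcol in (("common", "COMMON"), ("indep", "INDEP")):
                    st = sub_rows.rename(
                        columns={
                            f"BETA_{bcol}": "BETA", f"SE_{bcol}": "SE",
                            f"Z_{bcol}": "Z", f"P_{bcol}": "P",
                        }
                    )
                    st.to_csv(outdir / f"{target}_{stream}.tsv", sep="\t", index=False)
                    subtraction_tables[f"{target}_{stream}"] = st
                sub_info[target] = {
                    k: round(v, 1) for k, v in subtraction_effective_n(sub_rows).items()
                }
            manifest["stages"]["subtraction"] = {"targets": targets, "effective_n": sub_info}

        # ---- clumping ----------------------------------------------------
        if on["clump"]:
            if not gwas_tables:
                raise ConfigurationError("clump stage requires the gwas stage")
            clump_info = {}
            for name, tbl in {**gwas_tables, **subtraction_tables}.items():
                cres = clump(
                    tbl, panel,
                    p1=config.clump_p1, r2=config.clump_r2, window_kb=config.clump_window_kb,
                )
                cres.leads.to_csv(outdir / f"clump_{name}.tsv", sep="\t", index=False)
                clump_info[name] = cres.n_leads
            manifest["stages"]["clump"] = {"n_leads": clump_info}

        # ---- genetic-correlation profile ---------------------------------
        if on["rg_profile"]:
            if not gwas_tables:
                raise ConfigurationError("rg_profile stage requires the gwas stage")
            externals = config.rg_externals or [t.trait_name for t in tables]
            ext_tables = [t for t in tables if t.trait_name in externals]
            profiles = []
            for f, tbl in gwas_tables.items():
                n_eff_f = effective_n(tbl)
                prof = rg_profile(tbl, n_eff_f, ext_tables, panel, n_blocks=config.n_blocks,
                                  stream_name=f)
                profiles.append(prof)
            prof_df = pd.concat(profiles, ignore_index=True)
            prof_df.to_csv(outdir / "rg_profile.tsv", sep="\t", index=False)
            manifest["stages"]["rg_profile"] = {"n_rows": len(prof_df)}

        return finish()
    except Exception:
        finish(status="error")
        raise


def rg_profile(
    factor_table: pd.DataFrame,
    n_eff: float,
    externals: list[SumstatsTable],
    panel: LDPanel,
    n_blocks: int = 200,
    stream_name: str = "factor",
) -> pd.DataFrame:
    """Bivariate LD score regression of a factor/stream GWAS against each
    external trait, with Benjamini-Hochberg FDR across the profile."""
    df = factor_table.copy()
    if "HET_REMOVED" in df.columns:
        df = df[~df["HET_REMOVED"].astype(bool)]
    if "CONVERGED" in df.columns:
        df = df[df["CONVERGED"].astype(bool)]
    df = df[np.isfinite(df["Z"].to_numpy(dtype=float))]
    df = df.assign(N=n_eff)
    stream = SumstatsTable(stream_name, df[["SNP", "CHR", "POS", "A1", "A2",
                                            "BETA", "SE", "Z", "P", "FRQ", "N"]])
    rows = []
    for ext in externals:
        fit = bivariate_ldsc(stream, ext, panel, n_blocks=n_blocks)
        rg, se = fit["r_g"], fit["se_r_g"]
        if np.isfinite(rg) and se > 0:
            p = float(2.0 * stats.norm.sf(abs(rg / se)))
        else:
            p = np.nan
        rows.append(
            {
                "stream": stream_name,
                "external": ext.trait_name,
                "rg": rg,
                "se": se,
                "p": p,
                "undefined": not np.isfinite(rg),
                "out_of_bounds": bool(np.isfinite(rg) and abs(rg) > 1.0),
            }
        )
    out = pd.DataFrame(rows)
    finite = np.isfinite(out["p"].to_numpy(dtype=float))
    q = np.full(len(out), np.nan)
    if finite.any():
        q[finite] = multipletests(out.loc[finite, "p"], method="fdr_bh")[1]
    out["q"] = q
    return out
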