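"""Reading, harmonization (munging), and MTAG combination of sumstats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsemkit import (
    GenomicCovariance,
    SumstatsTable,
    TraitMeta,
    build_ld_panel,
    mtag_combine,
    munge,
    read_sumstats,
)
from gsemkit.utils import ConfigurationError, InputError


@pytest.fixture(scope="module")
def munge_panel():
    return build_ld_panel(n_blocks=5, snps_per_block=10, rho=0.3, seed=7, maf_range=(0.05, 0.5))


def write_raw(tmp_path, df, name="raw.txt"):
    p = tmp_path / name
    df.to_csv(p, sep="\t", index=False)
    return p


CMAP = {"rsid": "snp_id", "ea": "a1", "oa": "a2", "eff": "beta", "stderr": "se"}


class TestReadSumstats:
    def test_odds_ratio_converted_to_log_scale(self, tmp_path):
        path = write_raw(
            tmp_path,
            pd.DataFrame({"rsid": ["rs1"], "ea": ["A"], "oa": ["C"], "eff": [1.10], "stderr": [0.02]}),
        )
        t = read_sumstats(path, CMAP, odds_ratio=True)
        assert t.df["BETA"].iloc[0] == pytest.approx(np.log(1.10), rel=1e-9)
        assert t.df["Z"].iloc[0] == pytest.approx(np.log(1.10) / 0.02, rel=1e-6)

    def test_null_effect_has_z_zero_p_one(self, tmp_path):
        path = write_raw(
            tmp_path,
            pd.DataFrame({"rsid": ["rs1"], "ea": ["A"], "oa": ["C"], "eff": [0.0], "stderr": [0.1]}),
        )
        t = read_sumstats(path, CMAP)
        assert t.df["Z"].iloc[0] == 0.0
        assert t.df["P"].iloc[0] == 1.0

    def test_z_n_frq_route_reconstructs_beta(self, tmp_path):
        path = write_raw(
            tmp_path,
            pd.DataFrame(
                {"rsid": ["rs1"], "ea": ["A"], "oa": ["C"], "zz": [2.0], "nn": [10000], "af": [0.5]}
            ),
        )
        t = read_sumstats(path, {"rsid": "snp_id", "ea": "a1", "oa": "a2", "zz": "z", "nn": "n", "af": "frq"})
        se_expected = 1.0 / np.sqrt(2 * 0.25 * 10000)
        assert t.df["SE"].iloc[0] == pytest.approx(se_expected)
        assert t.df["BETA"].iloc[0] == pytest.approx(2.0 * se_expected)

    def test_rows_with_nonfinite_fields_dropped(self, tmp_path):
        path = write_raw(
            tmp_path,
            pd.DataFrame(
                {
                    "rsid": ["rs1", "rs2", "rs3"],
                    "ea": ["A", "C", "G"],
                    "oa": ["C", "T", "T"],
                    "eff": [0.1, np.nan, 0.2],
                    "stderr": [0.02, 0.02, 0.02],
                }
            ),
        )
        t = read_sumstats(path, CMAP)
        assert t.n_snps == 2

    def test_unmapped_mandatory_column_is_configuration_error(self, tmp_path):
        path = write_raw(tmp_path, pd.DataFrame({"rsid": ["rs1"], "ea": ["A"], "oa": ["C"]}))
        with pytest.raises(ConfigurationError):
            read_sumstats(path, {"rsid": "snp_id", "ea": "a1", "oa": "a2"})

    def test_zero_parseable_rows_is_input_error(self, tmp_path):
        path = write_raw(
            tmp_path,
            pd.DataFrame({"rsid": ["rs1"], "ea": ["A"], "oa": ["C"], "eff": [np.nan], "stderr": [0.1]}),
        )
        with pytest.raises(InputError):
            read_sumstats(path, CMAP)


class TestTraitMeta:
    def test_sample_prevalence_from_case_control_counts(self):
        # the large alcohol-use-disorder meta-analysis: 113,325 cases of 753,248
        meta = TraitMeta("AUD", "case-control", n_cases=113_325, n_controls=639_923)
        assert meta.sample_prevalence == pytest.approx(113_325 / 753_248, abs=1e-5)
        assert meta.sample_prevalence == pytest.approx(0.15045, abs=1e-4)

    def test_effective_n_is_four_over_harmonic_sum(self):
        meta = TraitMeta("X", "case-control", n_cases=1000, n_controls=3000)
        assert meta.n_effective == pytest.approx(4.0 / (1 / 1000 + 1 / 3000))


def panel_table(panel, beta=0.05, flip_mask=None, ambiguate=None):
    """Canonical table aligned to the panel, optionally mangled for tests."""
    pf = panel.snp_frame()
    n = len(pf)
    df = pd.DataFrame(
        {
            "SNP": pf["SNP"], "CHR": pf["CHR"], "POS": pf["POS"],
            "A1": pf["A1"], "A2": pf["A2"],
            "BETA": np.full(n, beta), "SE": np.full(n, 0.01),
            "Z": np.full(n, beta / 0.01), "P": np.full(n, 0.5),
            "FRQ": pf["MAF"], "N": np.full(n, 10000.0),
        }
    )
    if flip_mask is not None:
        a1 = df.loc[flip_mask, "A1"].copy()
        df.loc[flip_mask, "A1"] = df.loc[flip_mask, "A2"]
        df.loc[flip_mask, "A2"] = a1
        df.loc[flip_mask, "BETA"] *= -1
        df.loc[flip_mask, "Z"] *= -1
    if ambiguate is not None:
        df.loc[ambiguate, "A1"] = "A"
        df.loc[ambiguate, "A2"] = "T"
    return SumstatsTable("trait", df)


class TestMunge:
    def test_swapped_alleles_flip_sign(self, munge_panel):
        mask = np.zeros(munge_panel.n_snps, dtype=bool)
        mask[:5] = True
        table = panel_table(munge_panel, beta=0.05, flip_mask=mask)
        out = munge(table, munge_panel, maf_min=0.0)
        # after orientation to the panel, all betas agree again
        assert np.allclose(out.df["BETA"], 0.05)

    def test_strand_ambiguous_removed_when_flagged(self, munge_panel):
        amb = np.zeros(munge_panel.n_snps, dtype=bool)
        amb[:3] = True
        table = panel_table(munge_panel, ambiguate=amb)
        out = munge(table, munge_panel, maf_min=0.0, drop_ambiguous=True)
        assert out.n_snps == munge_panel.n_snps - 3
        kept = munge(table, munge_panel, maf_min=0.0, drop_ambiguous=False)
        # ambiguous IDs are irreconcilable with the panel's A/C-style pairs anyway
        assert kept.n_snps >= out.n_snps

    def test_maf_filter_drops_expected_count(self):
        panel = build_ld_panel(n_blocks=1, snps_per_block=10, rho=0.0, seed=3, maf_range=(0.001, 0.5))
        maf = panel.blocks[0].maf
        maf[:] = np.concatenate([np.full(3, 0.005), np.full(7, 0.25)])
        table = panel_table(panel)
        out = munge(table, panel, maf_min=0.01)
        assert out.n_snps == 7

    def test_munge_is_idempotent(self, munge_panel):
        table = panel_table(munge_panel)
        once = munge(table, munge_panel)
        twice = munge(once, munge_panel)
        pd.testing.assert_frame_equal(once.df, twice.df)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_orientation_invariance(self, seed):
        """Flipping a1/a2 and negating beta yields an identical munged table."""
        panel = build_ld_panel(n_blocks=3, snps_per_block=8, rho=0.2, seed=11)
        rng = np.random.default_rng(seed)
        mask = rng.random(panel.n_snps) < 0.5
        base = panel_table(panel, beta=0.03)
        flipped = panel_table(panel, beta=0.03, flip_mask=mask)
        out_a = munge(base, panel, maf_min=0.0)
        out_b = munge(flipped, panel, maf_min=0.0)
        pd.testing.assert_frame_equal(out_a.df, out_b.df)

    def test_z_and_beta_consistent_after_munge(self, munge_panel):
        table = panel_table(munge_panel)
        out = munge(table, munge_panel)
        assert np.allclose(out.df["Z"] * out.df["SE"], out.df["BETA"], rtol=1e-6)


def _two_trait_gcov(rho_g, h2=0.5, m=1000):
    S = np.array([[h2, rho_g * h2], [rho_g * h2, h2]])
    return GenomicCovariance(["T1", "T2"], S, np.eye(2), np.eye(3) * 1e-4, M=m, n_blocks=50)


def _mtag_table(name, z, n=10000.0, n_snps=50, seed=0):
    rng = np.random.default_rng(seed)
    frq = rng.uniform(0.1, 0.5, n_snps)
    se = 1.0 / np.sqrt(2 * frq * (1 - frq) * n)
    zv = np.full(n_snps, z, dtype=float)
    df = pd.DataFrame(
        {
            "SNP": [f"rs{i}" for i in range(n_snps)],
            "CHR": 1, "POS": np.arange(n_snps) * 1000 + 1,
            "A1": "A", "A2": "C",
            "BETA": zv * se, "SE": se, "Z": zv,
            "P": 0.5, "FRQ": frq, "N": n,
        }
    )
    return SumstatsTable(name, df)


class TestMtag:
    def test_single_trait_is_identity(self):
        t = _mtag_table("T1", z=2.0)
        out = mtag_combine([t], None, "T1")
        pd.testing.assert_frame_equal(out.df, t.df)

    def test_exact_copies_scale_z_by_sqrt2(self):
        t1 = _mtag_table("T1", z=2.0)
        t2 = SumstatsTable("T2", t1.df.copy())
        gcov = _two_trait_gcov(rho_g=1.0)
        out = mtag_combine([t1, t2], gcov, "T1").df
        assert np.allclose(out["Z"], 2.0 * np.sqrt(2), rtol=1e-6)

    def test_diagonal_omega_leaves_target_unchanged(self):
        t1 = _mtag_table("T1", z=2.0, seed=1)
        t2 = _mtag_table("T2", z=-1.0, seed=1)
        gcov = _two_trait_gcov(rho_g=0.0)
        out = mtag_combine([t1, t2], gcov, "T1").df
        merged = t1.sorted().df
        assert np.allclose(out["Z"], merged["Z"], rtol=1e-9)
        assert np.allclose(out["BETA"], merged["BETA"], rtol=1e-6)

    def test_mtag_never_inflates_target_se(self):
        t1 = _mtag_table("T1", z=1.5, seed=2)
        t2 = _mtag_table("T2", z=1.0, seed=3)
        gcov = _two_trait_gcov(rho_g=0.6)
        out = mtag_combine([t1, t2], gcov, "T1").df
        base = t1.sorted().df
        frq = base["FRQ"].to_numpy()
        se_std_in = base["SE"].to_numpy() * np.sqrt(2 * frq * (1 - frq))
        frq_o = out["FRQ"].to_numpy()
        se_std_out = out["SE"].to_numpy() * np.sqrt(2 * frq_o * (1 - frq_o))
        assert (se_std_out <= se_std_in + 1e-12).all()
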