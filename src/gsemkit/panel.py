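"""LD reference panels with block-diagonal SNP correlation structure.

A panel plays the role that an external genotype reference (e.g. a 1000
Genomes phase 3 subset) plays for LD score regression and clumping: it fixes
the canonical allele orientation, allele frequencies, per-SNP LD scores, and
the local correlation structure.  Panels here are block diagonal — SNPs in
different blocks are exactly uncorrelated — which makes LD scores and
clumping oracles exact rather than approximate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .utils import ConfigurationError

_BASES = np.array(list("ACGT"))
# non-ambiguous partner choices for each effect allele
_PARTNERS = {"A": ["C", "G"], "T": ["C", "G"], "C": ["A", "T"], "G": ["A", "T"]}


@dataclass
class LDBlock:
    """One LD block: SNPs on a single chromosome with correlation matrix R."""

    chrom: int
    snp_ids: np.ndarray
    pos: np.ndarray
    maf: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    R: np.ndarray

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def ld_scores(self) -> np.ndarray:
        """Exact LD scores: sum of squared correlations within the block."""
        return (self.R**2).sum(axis=1)


@dataclass
class LDPanel:
    blocks: list[LDBlock]
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self._index is None:
            self._index = {}
            for b_idx, b in enumerate(self.blocks):
                for i, sid in enumerate(b.snp_ids):
                    self._index[sid] = (b_idx, i)

    @property
    def n_snps(self) -> int:
        return sum(b.n_snps for b in self.blocks)

    def locate(self, snp_id: str) -> tuple[int, int] | None:
        return self._index.get(snp_id)

    def ld_r2(self, snp_a: str, snp_b: str) -> float:
        """Squared LD correlation between two SNPs; 0 across blocks or if absent."""
        la, lb = self._index.get(snp_a), self._index.get(snp_b)
        if la is None or lb is None or la[0] != lb[0]:
            return 0.0
        return float(self.blocks[la[0]].R[la[1], lb[1]] ** 2)

    def snp_frame(self) -> pd.DataFrame:
        """Per-SNP reference table (SNP CHR POS A1 A2 MAF L2), sorted by position."""
        parts = []
        for b in self.blocks:
            parts.append(
                pd.DataFrame(
                    {
                        "SNP": b.snp_ids,
                        "CHR": b.chrom,
                        "POS": b.pos,
                        "A1": b.a1,
                        "A2": b.a2,
                        "MAF": b.maf,
                        "L2": b.ld_scores(),
                    }
                )
            )
        df = pd.concat(parts, ignore_index=True)
        return df.sort_values(["CHR", "POS"], kind="mergesort").reset_index(drop=True)

    # -- serialization (delimited text mirroring the .l2.ldscore layout) ------

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.snp_frame().to_csv(outdir / "panel.l2.ldscore.tsv", sep="\t", index=False)
        blockdir = outdir / "blocks"
        blockdir.mkdir(exist_ok=True)
        manifest = []
        for i, b in enumerate(self.blocks):
            name = f"block_{i:05d}"
            np.savetxt(blockdir / f"{name}.R.tsv", b.R, delimiter="\t")
            pd.DataFrame(
                {"SNP": b.snp_ids, "CHR": b.chrom, "POS": b.pos, "A1": b.a1, "A2": b.a2, "MAF": b.maf}
            ).to_csv(blockdir / f"{name}.snps.tsv", sep="\t", index=False)
            manifest.append(name)
        (outdir / "manifest.json").write_text(json.dumps({"blocks": manifest}))

    @classmethod
    def load(cls, indir: str | Path) -> "LDPanel":
        indir = Path(indir)
        manifest = json.loads((indir / "manifest.json").read_text())
        blocks = []
        for name in manifest["blocks"]:
            snps = pd.read_csv(indir / "blocks" / f"{name}.snps.tsv", sep="\t")
            R = np.loadtxt(indir / "blocks" / f"{name}.R.tsv", delimiter="\t", ndmin=2)
            blocks.append(
                LDBlock(
                    chrom=int(snps["CHR"].iloc[0]),
                    snp_ids=snps["SNP"].to_numpy(dtype=object),
                    pos=snps["POS"].to_numpy(dtype=np.int64),
                    maf=snps["MAF"].to_numpy(dtype=float),
                    a1=snps["A1"].to_numpy(dtype=object),
                    a2=snps["A2"].to_numpy(dtype=object),
                    R=R,
                )
            )
        return cls(blocks=blocks)


def build_ld_panel(
    n_blocks: int,
    snps_per_block: int,
    rho: float | tuple[float, float],
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    n_chrom: int = 22,
    intra_block_spacing: int = 1_000,
    inter_block_spacing: int = 10_000_000,
) -> LDPanel:
    """Build a synthetic block-diagonal LD panel with AR(1) within-block LD.

    Within a block ``R[i, j] = rho_b ** |i - j|``.  ``rho`` is either a single
    AR(1) parameter used for every block or a ``(lo, hi)`` range from which a
    per-block parameter is drawn uniformly; the latter is the realistic
    choice, since a panel with one shared rho has nearly constant LD scores
    and LD score regression needs spread in its regressor.  MAFs are uniform
    on ``maf_range``; positions are strictly increasing within chromosome;
    chromosomes are assigned round-robin over 1..n_chrom so odd/even
    chromosome splits are meaningful.
    """
    if np.isscalar(rho):
        rho_lo = rho_hi = float(rho)
    else:
        rho_lo, rho_hi = map(float, rho)
    if not (0.0 <= rho_lo <= rho_hi < 1.0):
        raise ConfigurationError(f"AR(1) parameter rho must be in [0, 1), got {rho}")
    if snps_per_block < 1 or n_blocks < 1:
        raise ConfigurationError("need at least one block of at least one SNP")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ConfigurationError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {maf_range}")

    rng = np.random.default_rng(seed)
    idx = np.arange(snps_per_block)
    dist = np.abs(idx[:, None] - idx[None, :]).astype(float)

    next_pos = {c: 1 for c in range(1, n_chrom + 1)}
    blocks = []
    snp_counter = 0
    for b in range(n_blocks):
        chrom = 1 + (b % n_chrom)
        start = next_pos[chrom]
        pos = start + idx * intra_block_spacing
        next_pos[chrom] = int(pos[-1]) + inter_block_spacing
        rho_b = rho_lo if rho_lo == rho_hi else rng.uniform(rho_lo, rho_hi)
        with np.errstate(divide="ignore"):
            R = rho_b**dist if rho_b > 0 else np.eye(snps_per_block)
        maf = rng.uniform(lo, hi, size=snps_per_block)
        a1 = rng.choice(_BASES, size=snps_per_block)
        a2 = np.array([rng.choice(_PARTNERS[a]) for a in a1], dtype=object)
        snp_ids = np.array([f"rs{snp_counter + i + 1}" for i in range(snps_per_block)], dtype=object)
        snp_counter += snps_per_block
        blocks.append(
            LDBlock(
                chrom=chrom,
                snp_ids=snp_ids,
                pos=pos.astype(np.int64),
                maf=maf,
                a1=a1.astype(object),
                a2=a2,
                R=R.copy(),
            )
        )
    return LDPanel(blocks=blocks)
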