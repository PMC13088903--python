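"""Shared small helpers: vech indexing, allele utilities, jackknife blocks, seeds."""

from __future__ import annotations

import hashlib

import numpy as np

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class ConfigurationError(ValueError):
    """Invalid configuration (bad column map, bad parameter, malformed model)."""


class InputError(ValueError):
    """Invalid or empty input data."""


def vech(m: np.ndarray) -> np.ndarray:
    """Half-vectorize a symmetric matrix, lower triangle in column-major order.

    Ordering is (0,0),(1,0),...,(k-1,0),(1,1),(2,1),...,(k-1,k-1).  This
    ordering is fixed package-wide; every index into a sampling covariance
    matrix V assumes it.
    """
    k = m.shape[0]
    return np.concatenate([m[j:, j] for j in range(k)])


def vech_indices(k: int) -> list[tuple[int, int]]:
    """(row, col) pairs in the package's fixed vech order."""
    return [(i, j) for j in range(k) for i in range(j, k)]


def vech_index(i: int, j: int, k: int) -> int:
    """Position of entry (i, j) (i >= j after swap) in vech of a k x k matrix."""
    if i < j:
        i, j = j, i
    return j * k - j * (j - 1) // 2 + (i - j)


def vech_rows_cols(k: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column index arrays realizing the package's vech order."""
    idx = vech_indices(k)
    return np.array([i for i, _ in idx]), np.array([j for _, j in idx])


def unvech(v: np.ndarray, k: int) -> np.ndarray:
    m = np.zeros((k, k))
    for pos, (i, j) in enumerate(vech_indices(k)):
        m[i, j] = v[pos]
        m[j, i] = v[pos]
    return m


def complement_allele(a: str) -> str:
    return COMPLEMENT[a]


def is_ambiguous(a1: str, a2: str) -> bool:
    """Strand-ambiguous pair (A/T or C/G): orientation cannot be resolved."""
    return (a1, a2) in AMBIGUOUS_PAIRS


def contiguous_blocks(n_snps: int, n_blocks: int) -> np.ndarray:
    """Assign sorted SNPs to ``n_blocks`` contiguous, near-equal jackknife blocks."""
    n_blocks = min(n_blocks, n_snps)
    return np.minimum((np.arange(n_snps) * n_blocks) // n_snps, n_blocks - 1)


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the master seed by stable hashing (< 2**31)."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def nearest_psd(m: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Clip eigenvalues below ``eps`` up to ``eps`` and reconstruct."""
    m = (m + m.T) / 2.0
    w, q = np.linalg.eigh(m)
    if w.min() >= eps:
        return m
    w = np.maximum(w, eps)
    return (q * w) @ q.T
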