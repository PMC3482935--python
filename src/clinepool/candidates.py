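"""Candidate SNP and gene identification.

Two-pronged design: (i) SNPs in the upper tail (default 0.5%) of the
pairwise F_ST distribution, conditioned on a two-sided Fisher exact test
of their allele counts surviving FDR control (default q < 0.01, BH); and
(ii) a gene-based alternative taking the upper 5% tail of mean gene F_ST.
Exact-test p-values are computed for *all* polymorphic SNPs (they also
feed the decay-of-significance profile) and q-values are taken over all of
them; candidacy requires outlier AND q below threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .genes import genes_for_positions
from .io_formats import GeneModel
from .site_filtering import SnpTable

#: relative tolerance when comparing hypergeometric probabilities for ties
_FET_RELTOL = 1e-7


@dataclass
class CandidateConfig:
    outlier_tail: float = 0.005
    q_max: float = 0.01
    gene_tail: float = 0.05
    flank: int = 1000

    def __post_init__(self) -> None:
        for name in ("outlier_tail", "gene_tail"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")


# ---------------------------------------------------------------------------
# Fisher's exact test (vectorised two-sided)
# ---------------------------------------------------------------------------

def fisher_exact_many(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray, chunk: int = 4096
) -> np.ndarray:
    """Two-sided Fisher exact p for many 2x2 tables ``[[a, b], [c, d]]``.

    The p-value sums hypergeometric probabilities (margins fixed) of all
    tables no more probable than the observed one, with a relative
    tolerance of 1e-7 for floating-point ties. Tables with an all-zero
    margin return p = 1.
    """
    a = np.asarray(a, dtype=np.int64).ravel()
    b = np.asarray(b, dtype=np.int64).ravel()
    c = np.asarray(c, dtype=np.int64).ravel()
    d = np.asarray(d, dtype=np.int64).ravel()
    if ((a < 0) | (b < 0) | (c < 0) | (d < 0)).any():
        raise ValueError("table entries must be non-negative")
    out = np.empty(a.shape, dtype=float)
    for lo in range(0, len(a), chunk):
        sl = slice(lo, lo + chunk)
        out[sl] = _fet_chunk(a[sl], b[sl], c[sl], d[sl])
    return out


def _fet_chunk(a, b, c, d) -> np.ndarray:
    m1 = a + b  # row margins
    m2 = c + d
    n1 = a + c  # first column margin
    N = m1 + m2
    kmin = np.maximum(0, n1 - m2)
    kmax = np.minimum(n1, m1)
    width = int((kmax - kmin).max()) + 1 if len(a) else 1
    k = kmin[:, None] + np.arange(width)[None, :]
    support = k <= kmax[:, None]
    kc = np.clip(k, kmin[:, None], kmax[:, None])
    # log hypergeometric pmf at k (margins m1, m2, n1)
    logpmf = (
        _logC(m1[:, None], kc)
        + _logC(m2[:, None], n1[:, None] - kc)
        - _logC(N[:, None], n1[:, None])
    )
    logpmf = np.where(support, logpmf, -np.inf)
    obs = (
        _logC(m1, a) + _logC(m2, c) - _logC(N, n1)
    )
    take = logpmf <= obs[:, None] + np.log1p(_FET_RELTOL)
    p = np.exp(logpmf, where=np.isfinite(logpmf), out=np.zeros_like(logpmf))
    pv = np.minimum((p * take).sum(axis=1), 1.0)
    # degenerate margins: single-table support
    return np.where(kmax == kmin, 1.0, pv)


def _logC(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for a single 2x2 table."""
    return float(fisher_exact_many([a], [b], [c], [d])[0])


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def fdr_qvalues(p: np.ndarray, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (pi0 = 1).

    ``method="storey"`` rescales by the Storey pi0 estimate at lambda=0.5
    (clipped to (0, 1]).
    """
    p = np.asarray(p, dtype=float)
    q = multipletests(p, method="fdr_bh")[1]
    if method == "storey":
        lam = 0.5
        pi0 = min(1.0, max(np.mean(p > lam) / (1 - lam), 1.0 / len(p)))
        q = np.minimum(q * pi0, 1.0)
    elif method != "bh":
        raise ValueError(f"unknown FDR method {method!r}")
    return q


# ---------------------------------------------------------------------------
# outlier + candidate selection
# ---------------------------------------------------------------------------

def select_outliers(
    fst: np.ndarray,
    tail: float,
    fet_p: np.ndarray | None = None,
    arms: np.ndarray | None = None,
    positions: np.ndarray | None = None,
) -> np.ndarray:
    """Flag the top ``floor(tail * N)`` SNPs by F_ST (rank-based).

    Ties at the cutoff are broken by smaller exact-test p, then by
    (arm, position) for determinism. NaN F_ST ranks last.
    """
    fst = np.asarray(fst, dtype=float)
    n = len(fst)
    if n == 0:
        raise ValueError("empty F_ST vector")
    k = int(np.floor(tail * n))
    flags = np.zeros(n, dtype=bool)
    if k == 0:
        return flags
    # np.lexsort: last key is primary; order is
    # fst desc, then fet_p asc, then (arm, position), then input index
    keys = [np.arange(n)]
    if positions is not None:
        keys.append(np.asarray(positions))
    if arms is not None:
        keys.append(np.unique(np.asarray(arms), return_inverse=True)[1])
    if fet_p is not None:
        keys.append(np.asarray(fet_p, dtype=float))
    keys.append(-np.where(np.isnan(fst), -np.inf, fst))
    order = np.lexsort(tuple(keys))
    flags[order[:k]] = True
    return flags


def call_candidates(
    snps: SnpTable,
    fst: np.ndarray,
    pool_i: int,
    pool_j: int,
    genes: list[GeneModel] | None = None,
    cfg: CandidateConfig = CandidateConfig(),
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Full per-pair candidate table for one pool pair.

    Columns: arm, position, fst, fet_p, q, outlier, candidate, gene_ids
    (comma-joined, empty = intergenic).
    """
    fet_p = fisher_exact_many(
        snps.major_counts[:, pool_i],
        snps.minor_counts[:, pool_i],
        snps.major_counts[:, pool_j],
        snps.minor_counts[:, pool_j],
    )
    q = fdr_qvalues(fet_p, method=fdr_method)
    outlier = select_outliers(
        fst, cfg.outlier_tail, fet_p=fet_p, arms=snps.arms, positions=snps.positions
    )
    candidate = outlier & (q < cfg.q_max)
    df = snps.frame[["arm", "position"]].copy()
    df["fst"] = np.asarray(fst, dtype=float)
    df["fet_p"] = fet_p
    df["q"] = q
    df["outlier"] = outlier
    df["candidate"] = candidate
    if genes is not None:
        df["gene_ids"] = [
            ",".join(g) for g in genes_for_positions(
                snps.arms, snps.positions, genes, flank=cfg.flank
            )
        ]
    else:
        df["gene_ids"] = ""
    return df


def gene_based_candidates(gene_fst: pd.DataFrame, tail: float = 0.05) -> set[str]:
    """Genes in the upper ``tail`` of the mean-gene-F_ST distribution
    (rank-based, floor(tail*N) genes; ties broken by gene id)."""
    n = len(gene_fst)
    k = int(np.floor(tail * n))
    if k == 0:
        return set()
    order = gene_fst.sort_values(
        ["mean_fst", "gene_id"], ascending=[False, True]
    )
    return set(order["gene_id"].head(k))


def overlap_fraction(snp_gene_set: set[str], gene_set: set[str]) -> float:
    """|A ∩ B| / |B| with B the gene-defined candidate set."""
    if not gene_set:
        raise ValueError("gene-defined candidate set is empty")
    return len(snp_gene_set & gene_set) / len(gene_set)


def compare_candidate_sets(
    set1: set[str],
    set2: set[str],
    universe: set[str],
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Observed overlap fraction of set1 with set2 (relative to set2) and a
    permutation p-value drawing |set1|-sized random sets from the universe."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not set1 <= universe or not set2 <= universe:
        raise ValueError("candidate sets must be subsets of the universe")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    uni = np.array(sorted(universe))
    in2 = np.isin(uni, np.array(sorted(set2)))
    observed = len(set1 & set2) / len(set2)
    k = len(set1)
    count = 0
    for _ in range(n_perm):
        draw = rng.choice(len(uni), size=k, replace=False)
        if in2[draw].sum() / len(set2) >= observed:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return observed, p
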