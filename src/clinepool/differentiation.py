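"""Pairwise F_ST between population pools, per SNP, per gene and per window.

The statistic is the classical heterozygosity-based form

    F_ST = (pi_total - pi_within) / pi_total

with every pi the pool-corrected per-site heterozygosity: pi_within is the
mean of the two pools' own estimates (each at its own pool size and
coverage); pi_total is estimated from the summed read counts at pool size
n_i + n_j and coverage M_i + M_j. Both use the two most frequent alleles of
the site. Negative values (pi_within above pi_total by sampling noise) are
retained; candidate calling uses only the upper tail.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .diversity import pi_site_biallelic, window_average, WindowGrid
from .genes import assign_positions_to_genes
from .io_formats import GeneModel
from .site_filtering import SnpTable


def fst_site(
    maj_i: np.ndarray, min_i: np.ndarray, n_i: int,
    maj_j: np.ndarray, min_j: np.ndarray, n_j: int,
) -> np.ndarray:
    """SNP-wise pairwise F_ST from biallelic major/minor read counts.

    Returns NaN where pi_total is zero (site monomorphic in the combined
    sample) or where either pool has fewer than two reads.
    """
    pi_i = pi_site_biallelic(maj_i, min_i, n_i)
    pi_j = pi_site_biallelic(maj_j, min_j, n_j)
    pi_within = 0.5 * (pi_i + pi_j)
    pi_total = pi_site_biallelic(
        np.asarray(maj_i) + np.asarray(maj_j),
        np.asarray(min_i) + np.asarray(min_j),
        n_i + n_j,
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = (pi_total - pi_within) / pi_total
    return np.where(pi_total > 0, fst, np.nan)


def pair_label(a: str, b: str) -> str:
    return f"{a}{b}"


def all_pair_fst(snps: SnpTable) -> pd.DataFrame:
    """SNP-wise F_ST for every pool pair.

    Returns a frame with arm, position and one ``fst_<pair>`` column per
    pair (e.g. ``fst_FM``), pairs ordered as itertools.combinations of the
    pool order.
    """
    out = snps.frame[["arm", "position"]].copy()
    for i, j in itertools.combinations(range(len(snps.pools)), 2):
        pi, pj = snps.pools[i], snps.pools[j]
        out[f"fst_{pair_label(pi.label, pj.label)}"] = fst_site(
            snps.major_counts[:, i], snps.minor_counts[:, i], pi.n_chromosomes,
            snps.major_counts[:, j], snps.minor_counts[:, j], pj.n_chromosomes,
        )
    return out


def fst_gene(
    snps: SnpTable,
    site_fst: np.ndarray,
    genes: list[GeneModel],
    flank: int = 1000,
) -> pd.DataFrame:
    """Mean SNP-wise F_ST per gene over the gene span +/- ``flank``.

    SNPs inside overlapping genes contribute to each of them; genes with no
    SNP (or only NaN F_ST) are omitted.
    """
    snp_idx, gene_ids = assign_positions_to_genes(
        snps.arms, snps.positions, genes, flank=flank
    )
    fst = np.asarray(site_fst, dtype=float)[snp_idx]
    df = pd.DataFrame({"gene_id": gene_ids, "fst": fst}).dropna()
    if df.empty:
        return pd.DataFrame(columns=["gene_id", "mean_fst", "n_snps"])
    g = df.groupby("gene_id", sort=True)["fst"]
    return g.agg(mean_fst="mean", n_snps="size").reset_index()


def fst_windows(
    snps: SnpTable, site_fst: np.ndarray, grid: WindowGrid | int = WindowGrid()
) -> pd.DataFrame:
    """Windowed mean F_ST (200-kb non-overlapping grid by default)."""
    return window_average(snps.arms, snps.positions, np.asarray(site_fst), grid)
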