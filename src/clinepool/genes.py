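"""Assignment of SNP positions to gene models (with flanks)."""

from __future__ import annotations

import numpy as np
from intervaltree import IntervalTree

from .io_formats import GeneModel


def build_gene_trees(
    genes: list[GeneModel], flank: int = 1000
) -> dict[str, IntervalTree]:
    """Per-arm interval trees of flanked gene spans (1-based inclusive)."""
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        lo, hi = g.flanked_span(flank)
        trees.setdefault(g.arm, IntervalTree()).addi(lo, hi + 1, g.gene_id)
    return trees


def assign_positions_to_genes(
    arms: np.ndarray,
    positions: np.ndarray,
    genes: list[GeneModel],
    flank: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """All (snp index, gene_id) assignments; a SNP hitting k genes yields
    k rows, a SNP hitting none yields none."""
    trees = build_gene_trees(genes, flank)
    idx: list[int] = []
    hits: list[str] = []
    for i, (arm, pos) in enumerate(zip(arms, positions)):
        tree = trees.get(arm)
        if tree is None:
            continue
        for iv in tree.at(int(pos)):
            idx.append(i)
            hits.append(iv.data)
    return np.array(idx, dtype=np.int64), np.array(hits, dtype=object)


def genes_for_positions(
    arms: np.ndarray,
    positions: np.ndarray,
    genes: list[GeneModel],
    flank: int = 1000,
) -> list[list[str]]:
    """Per-SNP sorted lists of overlapping gene ids (empty = intergenic)."""
    idx, hits = assign_positions_to_genes(arms, positions, genes, flank)
    out: list[list[str]] = [[] for _ in range(len(positions))]
    for i, g in zip(idx, hits):
        out[i].append(g)
    for lst in out:
        lst.sort()
    return out
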