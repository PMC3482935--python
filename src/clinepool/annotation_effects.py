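"""Genome-feature classification of SNPs and candidate over/under-
representation tests.

Each SNP gets exactly one feature by a fixed severity precedence:
nonsynonymous > synonymous > 5'UTR > 3'UTR > intron > upstream (1 kb) >
downstream (1 kb) > intergenic; unresolvable cases (e.g. inconsistent CDS
phase or missing coding sequence) map to "other". Synonymous versus
nonsynonymous is decided by translating the codon with each of the two
segregating alleles substituted at the SNP position (standard codon
table, strand-aware), across all isoforms of all covering genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .io_formats import GeneModel
from .site_filtering import SnpTable

#: classification precedence, most severe first ("other" marks genic but
#: unclassifiable positions, so it outranks intergenic)
FEATURES = (
    "nonsynonymous_coding",
    "synonymous_coding",
    "utr5",
    "utr3",
    "intron",
    "upstream_1kb",
    "downstream_1kb",
    "other",
    "intergenic",
)
_RANK = {f: i for i, f in enumerate(FEATURES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _cds_offset(pos: int, spans: list[tuple[int, int, int]], strand: str) -> int | None:
    """Offset of a genomic position within the spliced CDS (coding
    orientation), phase-adjusted; None when outside every span."""
    if strand == "+":
        ordered = sorted(spans)
        off = 0
        phase0 = ordered[0][2]
        for a, b, _ in ordered:
            if a <= pos <= b:
                return off + (pos - a) - phase0
            off += b - a + 1
    else:
        ordered = sorted(spans, reverse=True)
        off = 0
        phase0 = ordered[0][2]
        for a, b, _ in ordered:
            if a <= pos <= b:
                return off + (b - pos) - phase0
            off += b - a + 1
    return None


def _codon_class(
    pos: int, major: str, minor: str, gene: GeneModel, cds_seq: str | None
) -> str | None:
    """"synonymous_coding"/"nonsynonymous_coding"/"other" when the SNP is
    inside a CDS of any isoform, else None."""
    for spans in gene.cds_by_isoform.values():
        if not any(a <= pos <= b for a, b, _ in spans):
            continue
        if cds_seq is None:
            return "other"
        off = _cds_offset(pos, spans, gene.strand)
        if off is None or off < 0:
            return "other"
        ci, cp = divmod(off, 3)
        codon = cds_seq[ci * 3 : ci * 3 + 3].upper()
        if len(codon) < 3:
            return "other"
        a1, a2 = major, minor
        if gene.strand == "-":
            a1, a2 = a1.translate(_COMPLEMENT), a2.translate(_COMPLEMENT)
        c1 = codon[:cp] + a1 + codon[cp + 1 :]
        c2 = codon[:cp] + a2 + codon[cp + 1 :]
        aa1 = str(Seq(c1).translate())
        aa2 = str(Seq(c2).translate())
        return "synonymous_coding" if aa1 == aa2 else "nonsynonymous_coding"
    return None


def classify_snp(
    arm: str,
    pos: int,
    major: str,
    minor: str,
    genes: list[GeneModel],
    cds_seqs: dict[str, str] | None = None,
    flank: int = 1000,
) -> tuple[str, str]:
    """(feature, gene_id) for one SNP. gene_id is empty for intergenic."""
    cds_seqs = cds_seqs or {}
    best: tuple[int, str, str] = (_RANK["intergenic"], "intergenic", "")
    for gene in genes:
        if gene.arm != arm:
            continue
        lo, hi = gene.flanked_span(flank)
        if not lo <= pos <= hi:
            continue
        if gene.start <= pos <= gene.end:
            feat = _codon_class(pos, major, minor, gene, cds_seqs.get(gene.gene_id))
            if feat is None:
                if any(a <= pos <= b for a, b in gene.utr5):
                    feat = "utr5"
                elif any(a <= pos <= b for a, b in gene.utr3):
                    feat = "utr3"
                elif any(a <= pos <= b for a, b in gene.exons):
                    feat = "other"  # exonic but neither CDS nor UTR
                else:
                    feat = "intron"
        else:
            before = pos < gene.start
            upstream = before if gene.strand == "+" else not before
            feat = "upstream_1kb" if upstream else "downstream_1kb"
        if _RANK[feat] < best[0]:
            best = (_RANK[feat], feat, gene.gene_id)
    return best[1], best[2]


def annotate_snps(
    snps: SnpTable,
    genes: list[GeneModel],
    cds_seqs: dict[str, str] | None = None,
    flank: int = 1000,
) -> pd.DataFrame:
    """Feature classification for every SNP in the table."""
    feats, gids = [], []
    by_arm: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_arm.setdefault(g.arm, []).append(g)
    frame = snps.frame
    for arm, pos, major, minor in zip(
        frame["arm"], frame["position"], frame["major"], frame["minor"]
    ):
        f, gid = classify_snp(
            arm, int(pos), major, minor, by_arm.get(arm, []), cds_seqs, flank
        )
        feats.append(f)
        gids.append(gid)
    out = frame[["arm", "position"]].copy()
    out["feature"] = feats
    out["gene_id"] = gids
    return out


def feature_enrichment(
    candidate_features: pd.Series, background_features: pd.Series
) -> pd.DataFrame:
    """Per-feature 2x2 test of candidate versus background SNP counts.

    Chi-squared with 1 df (no continuity correction); when any expected
    cell is below 5 a Fisher exact test is used instead and flagged.
    ``background_features`` should exclude the candidates.
    """
    cand = pd.Series(candidate_features).value_counts()
    back = pd.Series(background_features).value_counts()
    n_cand, n_back = int(cand.sum()), int(back.sum())
    rows = []
    for feat in FEATURES:
        a = int(cand.get(feat, 0))
        c = int(back.get(feat, 0))
        if a == 0 and c == 0:
            continue
        table = np.array([[a, n_cand - a], [c, n_back - c]])
        expected = stats.contingency.expected_freq(table)
        exact = (expected < 5).any()
        if exact:
            p = stats.fisher_exact(table, alternative="two-sided")[1]
            statistic = np.nan
        else:
            statistic, p, _, _ = stats.chi2_contingency(table, correction=False)
        prop_cand = a / n_cand if n_cand else np.nan
        prop_back = c / n_back if n_back else np.nan
        rows.append(
            {
                "feature": feat,
                "candidate_count": a,
                "candidate_proportion": prop_cand,
                "background_count": c,
                "background_proportion": prop_back,
                "chi2": statistic,
                "p": p,
                "direction": "over" if prop_cand > prop_back else (
                    "under" if prop_cand < prop_back else "none"
                ),
                "exact_fallback": exact,
                "significant": p < 0.01,
            }
        )
    return pd.DataFrame(rows)
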