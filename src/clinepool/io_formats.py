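"""Readers and writers for the external formats shared across the pipeline.

The pipeline's on-disk lingua franca is the PoPoolation2 ``sync`` format
(one line per site: chromosome arm, 1-based position, reference base, then
one ``A:T:C:G:N:del`` count column per population pool), plus GFF3 gene
models, BED masks, GO association tables and headered TSV artifacts.

Coordinates are 1-based inclusive everywhere inside the package; BED input
(0-based, half-open) is converted on read.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

#: Column order of a sync count column.
SYNC_ALLELES = ("A", "T", "C", "G", "N", "del")
#: The four nucleotides, in sync column order.
NUCLEOTIDES = ("A", "T", "C", "G")


class SyncParseError(ValueError):
    """Raised for a malformed sync line; carries the 1-based line number."""


class PoolConfigError(ValueError):
    """Raised when a file does not match the configured pools."""


@dataclass(frozen=True)
class PoolProfile:
    """One sequenced population pool.

    Parameters
    ----------
    label:
        Short unique identifier (e.g. ``"F"``, ``"P"``, ``"M"``).
    latitude:
        Sampling latitude in decimal degrees north.
    n_chromosomes:
        Number of haploid genome copies in the pool. For a pool of diploid
        females this is twice the number of flies.
    n_flies:
        Optional provenance: number of individuals pooled.
    """

    label: str
    latitude: float
    n_chromosomes: int
    n_flies: int | None = None

    def __post_init__(self) -> None:
        if self.n_chromosomes < 2:
            raise ValueError(f"pool {self.label!r}: n_chromosomes must be >= 2")
        if not np.isfinite(self.latitude):
            raise ValueError(f"pool {self.label!r}: latitude must be finite")


def check_pools(pools: Sequence[PoolProfile]) -> None:
    labels = [p.label for p in pools]
    if len(set(labels)) != len(labels):
        raise PoolConfigError(f"duplicate pool labels: {labels}")


@dataclass
class SiteCounts:
    """Per-site nucleotide counts for every pool.

    ``counts`` has shape ``(n_pools, 6)`` in sync column order
    (A, T, C, G, N, deletion). Coverage is the sum of the four nucleotide
    columns only; N and deletion are carried but never enter statistics.
    """

    arm: str
    position: int
    ref: str
    counts: np.ndarray

    @property
    def coverage(self) -> np.ndarray:
        return self.counts[:, :4].sum(axis=1)


# ---------------------------------------------------------------------------
# sync
# ---------------------------------------------------------------------------

def read_sync(path: str | os.PathLike, pools: Sequence[PoolProfile]) -> Iterator[SiteCounts]:
    """Stream SiteCounts from a sync file, validating the pool count."""
    check_pools(pools)
    n_pools = len(pools)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3 + n_pools:
                if len(fields) < 3:
                    raise SyncParseError(f"line {lineno}: expected arm, position, ref")
                raise PoolConfigError(
                    f"line {lineno}: {len(fields) - 3} count columns for {n_pools} pools"
                )
            arm, pos_s, ref = fields[:3]
            try:
                pos = int(pos_s)
                counts = np.array(
                    [[int(x) for x in col.split(":")] for col in fields[3:]], dtype=np.int64
                )
            except ValueError as exc:
                raise SyncParseError(f"line {lineno}: {exc}") from exc
            if counts.shape != (n_pools, 6) or (counts < 0).any():
                raise SyncParseError(f"line {lineno}: malformed count column")
            if pos < 1:
                raise SyncParseError(f"line {lineno}: position must be >= 1")
            yield SiteCounts(arm=arm, position=pos, ref=ref, counts=counts)


def write_sync(records: Iterable[SiteCounts], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            cols = "\t".join(":".join(str(int(c)) for c in row) for row in rec.counts)
            fh.write(f"{rec.arm}\t{rec.position}\t{rec.ref}\t{cols}\n")


def read_sync_arrays(
    path: str | os.PathLike, pools: Sequence[PoolProfile]
) -> tuple[pd.DataFrame, np.ndarray]:
    """Bulk sync reader: a (arm, position, ref) frame plus an
    ``(n_sites, n_pools, 6)`` count array. Semantics match :func:`read_sync`."""
    check_pools(pools)
    n_pools = len(pools)
    sites = pd.read_csv(
        path, sep="\t", header=None, dtype={0: str, 2: str},
        names=["arm", "position", "ref"] + [f"_c{i}" for i in range(n_pools)],
    )
    if sites.shape[1] != 3 + n_pools or sites[f"_c{n_pools - 1}"].isna().any():
        raise PoolConfigError(f"sync file does not have {n_pools} count columns")
    counts = np.empty((len(sites), n_pools, 6), dtype=np.int64)
    for i in range(n_pools):
        col = sites.pop(f"_c{i}").str.split(":", expand=True)
        if col.shape[1] != 6:
            raise SyncParseError("malformed count column")
        counts[:, i, :] = col.to_numpy(dtype=np.int64)
    return sites, counts


def write_sync_arrays(
    sites: pd.DataFrame, counts: np.ndarray, path: str | os.PathLike
) -> None:
    """Inverse of :func:`read_sync_arrays`."""
    with open(path, "w") as fh:
        arms = sites["arm"].to_numpy()
        poss = sites["position"].to_numpy()
        refs = sites["ref"].to_numpy()
        for i in range(len(sites)):
            cols = "\t".join(":".join(map(str, row)) for row in counts[i])
            fh.write(f"{arms[i]}\t{poss[i]}\t{refs[i]}\t{cols}\n")


# ---------------------------------------------------------------------------
# pools
# ---------------------------------------------------------------------------

def read_pools(path: str | os.PathLike) -> list[PoolProfile]:
    """Read pool metadata from a headered TSV (label, latitude,
    n_chromosomes[, n_flies])."""
    df = pd.read_csv(path, sep="\t")
    pools = []
    for row in df.itertuples(index=False):
        n_flies = int(row.n_flies) if hasattr(row, "n_flies") and pd.notna(row.n_flies) else None
        pools.append(
            PoolProfile(
                label=str(row.label),
                latitude=float(row.latitude),
                n_chromosomes=int(row.n_chromosomes),
                n_flies=n_flies,
            )
        )
    check_pools(pools)
    return pools


def write_pools(pools: Sequence[PoolProfile], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "label": [p.label for p in pools],
            "latitude": [p.latitude for p in pools],
            "n_chromosomes": [p.n_chromosomes for p in pools],
            "n_flies": [p.n_flies if p.n_flies is not None else "" for p in pools],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene models (GFF3)
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A gene as the union span of its isoforms, 1-based inclusive.

    The gene span runs from the 5'-most to the 3'-most transcribed base
    (UTR to UTR); ``cds_by_isoform`` keeps one ordered list of
    ``(start, end, phase)`` spans per isoform for effect calling.
    """

    gene_id: str
    arm: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_by_isoform: dict[str, list[tuple[int, int, int]]] = field(default_factory=dict)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def flanked_span(self, flank: int = 1000) -> tuple[int, int]:
        return max(1, self.start - flank), self.end + flank


_UTR5_TYPES = {"five_prime_UTR", "5UTR", "five_prime_utr"}
_UTR3_TYPES = {"three_prime_UTR", "3UTR", "three_prime_utr"}


def read_gff(path: str | os.PathLike) -> list[GeneModel]:
    """Parse GFF3 gene models via gffutils.

    Multi-isoform genes are merged to the union span; per-isoform CDS spans
    (with phase) are retained. A CDS feature without a phase gets phase 0.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        model = GeneModel(
            gene_id=g.id, arm=g.seqid, strand=g.strand, start=g.start, end=g.end
        )
        exons: set[tuple[int, int]] = set()
        for mrna in db.children(g, featuretype=("mRNA", "transcript")):
            model.start = min(model.start, mrna.start)
            model.end = max(model.end, mrna.end)
            cds_spans: list[tuple[int, int, int]] = []
            for child in db.children(mrna, order_by="start"):
                span = (child.start, child.end)
                if child.featuretype == "exon":
                    exons.add(span)
                elif child.featuretype == "CDS":
                    try:
                        phase = int(child.frame)
                    except (TypeError, ValueError):
                        phase = 0
                    cds_spans.append((child.start, child.end, phase))
                elif child.featuretype in _UTR5_TYPES:
                    if span not in model.utr5:
                        model.utr5.append(span)
                elif child.featuretype in _UTR3_TYPES:
                    if span not in model.utr3:
                        model.utr3.append(span)
            if cds_spans:
                model.cds_by_isoform[mrna.id] = cds_spans
        # single-level genes: exons/CDS directly under the gene
        if not model.cds_by_isoform:
            direct = [
                (c.start, c.end, int(c.frame) if str(c.frame).isdigit() else 0)
                for c in db.children(g, featuretype="CDS", order_by="start")
            ]
            if direct:
                model.cds_by_isoform[g.id] = direct
        for c in db.children(g, featuretype="exon"):
            exons.add((c.start, c.end))
        model.exons = sorted(exons)
        if not model.exons:
            model.exons = [(model.start, model.end)]
        genes.append(model)
    return genes


# ---------------------------------------------------------------------------
# masks (BED)
# ---------------------------------------------------------------------------

@dataclass
class MaskSet:
    """Per-arm interval set, stored 1-based inclusive, sorted and merged."""

    intervals: dict[str, np.ndarray] = field(default_factory=dict)  # (k, 2) int arrays

    @classmethod
    def from_intervals(cls, spans: dict[str, Iterable[tuple[int, int]]]) -> "MaskSet":
        out = {}
        for arm, ivs in spans.items():
            arr = np.array(sorted((int(a), int(b)) for a, b in ivs), dtype=np.int64)
            out[arm] = _merge(arr) if len(arr) else arr.reshape(0, 2)
        return cls(out)

    def contains(self, arm: str, positions: np.ndarray) -> np.ndarray:
        """Vectorised membership test for 1-based positions."""
        positions = np.asarray(positions)
        ivs = self.intervals.get(arm)
        if ivs is None or len(ivs) == 0:
            return np.zeros(positions.shape, dtype=bool)
        idx = np.searchsorted(ivs[:, 0], positions, side="right") - 1
        ok = idx >= 0
        out = np.zeros(positions.shape, dtype=bool)
        out[ok] = positions[ok] <= ivs[idx[ok], 1]
        return out


def _merge(arr: np.ndarray) -> np.ndarray:
    merged = [list(arr[0])]
    for a, b in arr[1:]:
        if a <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return np.array(merged, dtype=np.int64)


def read_bed_mask(path: str | os.PathLike) -> MaskSet:
    """BED (0-based half-open) to a 1-based inclusive MaskSet."""
    spans: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            arm, start, end = line.split("\t")[:3]
            spans.setdefault(arm, []).append((int(start) + 1, int(end)))
    return MaskSet.from_intervals(spans)


def write_bed_mask(mask: MaskSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for arm in sorted(mask.intervals):
            for a, b in mask.intervals[arm]:
                fh.write(f"{arm}\t{a - 1}\t{b}\n")


# ---------------------------------------------------------------------------
# GO associations
# ---------------------------------------------------------------------------

def read_go_associations(path: str | os.PathLike, dialect: str = "tsv") -> dict[str, set[str]]:
    """Read a gene-to-GO table into ``{go_id: {gene ids}}``.

    ``dialect="tsv"`` expects two columns (gene_id, go_id, header optional);
    ``dialect="gaf"`` reads GO Annotation File lines (gene in column 3,
    GO id in column 5).
    """
    mapping: dict[str, set[str]] = {}
    if dialect == "tsv":
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[0] == "gene_id":
                    continue
                gene, go = parts[0], parts[1]
                mapping.setdefault(go, set()).add(gene)
    elif dialect == "gaf":
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("!"):
                    continue
                parts = line.rstrip("\n").split("\t")
                gene, go = parts[2], parts[4]
                mapping.setdefault(go, set()).add(gene)
    else:
        raise ValueError(f"unknown GO association dialect: {dialect!r}")
    return mapping


# ---------------------------------------------------------------------------
# generic TSV artifacts
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a pipeline artifact as headered TSV with stable float format."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
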