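"""Synthetic pool-seq study generator with complete ground truth.

Emulates a three-population latitudinal design: a southern, an
intermediate and a northern pool (defaults: latitudes 25.53, 39.88 and
44.02 degrees north; 78, 204 and 172 pooled chromosomes — twice the
number of pooled diploid females), sequenced to ~45-fold mean coverage.

Per-SNP population frequencies are drawn from one of four classes:

* ``neutral`` — ancestral frequency from a (truncated) Beta, per-pool
  frequencies from the Balding-Nichols model at a baseline F_ST;
* ``clinal`` — frequency linear in latitude with a configurable total
  change ``delta_p`` across the cline, truncated to [0.02, 0.98];
* ``inversion`` — SNPs inside a configured inversion span are pulled
  toward the inversion frequency: ``p = L*q_pool + (1 - L)*p_neutral``
  with linkage coefficient L (frequency-level linkage, no haplotypes);
* ``marker`` — diagnostic SNPs whose frequency equals the inversion
  frequency exactly (perfect linkage).

Read counts follow the two-stage pool-seq sampling scheme: pool allele
count k ~ Binomial(n_chromosomes, p); coverage M ~ Poisson(lambda)
truncated at >= 1; minor reads ~ Binomial(M, k / n_chromosomes); finally
each read is flipped to a uniformly chosen other nucleotide with
probability ``error_rate``.

Everything is deterministic given (config, seed): identical inputs give
byte-identical output files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    MaskSet,
    NUCLEOTIDES,
    PoolProfile,
    write_bed_mask,
    write_pools,
    write_sync_arrays,
)


def default_pools() -> list[PoolProfile]:
    """The three-population cline: Florida, Pennsylvania, Maine."""
    return [
        PoolProfile("F", 25.53, 78, n_flies=39),
        PoolProfile("P", 39.88, 204, n_flies=102),
        PoolProfile("M", 44.02, 172, n_flies=86),
    ]


@dataclass
class InversionSpec:
    name: str = "In(3R)P"
    arm: str = "3R"
    start: int = 0
    end: int = 0
    pool_frequencies: tuple[float, ...] = (0.5, 0.05, 0.05)
    linkage: float = 0.8
    n_markers: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.linkage <= 1:
            raise ValueError("linkage coefficient must be in [0, 1]")
        if any(not 0 <= q <= 1 for q in self.pool_frequencies):
            raise ValueError("inversion frequencies must be in [0, 1]")


@dataclass
class SimConfig:
    seed: int = 0
    pools: list[PoolProfile] = field(default_factory=default_pools)
    #: SNPs per arm
    arms: dict[str, int] = field(default_factory=lambda: {"2L": 20_000})
    mean_spacing: int = 100  # bp between adjacent SNPs (uniform 0.5x..1.5x)
    mean_coverage: float = 45.0
    error_rate: float = 0.001
    baseline_fst: float = 0.02
    ancestral_beta: tuple[float, float] = (0.5, 0.5)
    ancestral_range: tuple[float, float] = (0.05, 0.95)
    clinal_fraction: float = 0.0
    clinal_delta_p: float = 0.5
    clinal_base_freq: float = 0.1
    inversion: InversionSpec | None = None
    # gene/GO scaffold
    short_gene_length: int = 2_000
    long_gene_length: int = 20_000
    long_gene_fraction: float = 0.1
    gene_gap: int = 2_000
    n_go_categories: int = 20

    def __post_init__(self) -> None:
        if not 0 <= self.clinal_fraction <= 1:
            raise ValueError("clinal_fraction must be in [0, 1]")
        if self.inversion is not None:
            arm_len = self.arm_length(self.inversion.arm)
            if self.inversion.arm not in self.arms or self.inversion.end > arm_len:
                raise ValueError(
                    f"inversion span exceeds arm {self.inversion.arm!r} "
                    f"(length ~{arm_len})"
                )

    def arm_length(self, arm: str) -> int:
        if arm not in self.arms:
            return 0
        # upper bound on the largest possible SNP position
        return (self.arms[arm] * 3 * self.mean_spacing) // 2 + 2 * self.mean_spacing

    @property
    def latitudes(self) -> np.ndarray:
        return np.array([p.latitude for p in self.pools])


@dataclass
class SimTruth:
    """Ground truth: one row per SNP with true per-pool frequencies
    (columns ``p_<label>``), class label, inversion association ``d`` and
    true latitude slopes s1 (south->mid) and s2 (mid->north)."""

    frame: pd.DataFrame
    pools: list[PoolProfile]

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def freqs(self) -> np.ndarray:
        return self.frame[[f"p_{p.label}" for p in self.pools]].to_numpy()


def _rng(config_seed: int, stream: int, seed: int | None) -> np.random.Generator:
    base = config_seed if seed is None else seed
    return np.random.default_rng([base % (2**31), stream])


def simulate_frequencies(config: SimConfig, seed: int | None = None) -> SimTruth:
    """Draw SNP positions, classes and true per-pool frequencies."""
    rng = _rng(config.seed, 1, seed)
    lats = config.latitudes
    order = np.argsort(lats)
    lat_s, lat_n = lats[order[0]], lats[order[-1]]

    frames = []
    for arm in sorted(config.arms):
        n = config.arms[arm]
        gaps = rng.integers(
            max(1, config.mean_spacing // 2), config.mean_spacing * 3 // 2 + 1, size=n
        )
        pos = np.cumsum(gaps) + config.mean_spacing
        snp_class = np.full(n, "neutral", dtype=object)

        n_clinal = int(round(config.clinal_fraction * n))
        if n_clinal:
            clinal_idx = rng.choice(n, size=n_clinal, replace=False)
            snp_class[clinal_idx] = "clinal"

        inv = config.inversion
        d = np.zeros(n, dtype=np.int8)
        if inv is not None and inv.arm == arm:
            inside = (pos >= inv.start) & (pos <= inv.end)
            snp_class[inside & (snp_class == "neutral")] = "inversion"
            d[snp_class == "inversion"] = 1

        # neutral/inversion baseline: Balding-Nichols around a truncated Beta
        a, b = config.ancestral_beta
        lo, hi = config.ancestral_range
        anc = lo + (hi - lo) * rng.beta(a, b, size=n)
        F = config.baseline_fst
        if F > 0:
            shape = (1.0 - F) / F
            p_pools = rng.beta(
                anc[:, None] * shape, (1.0 - anc)[:, None] * shape,
                size=(n, len(config.pools)),
            )
        else:
            p_pools = np.repeat(anc[:, None], len(config.pools), axis=1)

        # clinal: linear in latitude
        is_clinal = snp_class == "clinal"
        if is_clinal.any():
            frac = (lats[None, :] - lat_s) / (lat_n - lat_s)
            p_clin = config.clinal_base_freq + config.clinal_delta_p * frac
            p_pools[is_clinal] = np.clip(p_clin, 0.02, 0.98)

        # inversion-linked: pulled toward the inversion frequency
        if inv is not None and inv.arm == arm:
            q = np.asarray(inv.pool_frequencies)
            is_inv = snp_class == "inversion"
            L = inv.linkage
            p_pools[is_inv] = L * q[None, :] + (1.0 - L) * p_pools[is_inv]

        df = pd.DataFrame({"arm": arm, "position": pos, "snp_class": snp_class, "d": d})
        for j, p in enumerate(config.pools):
            df[f"p_{p.label}"] = p_pools[:, j]
        frames.append(df)

        # diagnostic markers: extra SNPs at fixed frequency q
        if inv is not None and inv.arm == arm and inv.n_markers:
            mpos = np.linspace(inv.start, inv.end, inv.n_markers + 2)[1:-1].astype(int)
            mdf = pd.DataFrame(
                {"arm": arm, "position": mpos, "snp_class": "marker", "d": 1}
            )
            for j, p in enumerate(config.pools):
                mdf[f"p_{p.label}"] = inv.pool_frequencies[j]
            frames.append(mdf)

    truth = pd.concat(frames, ignore_index=True)
    # markers win position collisions (they are appended last per arm)
    truth = truth.drop_duplicates(["arm", "position"], keep="last").sort_values(
        ["arm", "position"], ignore_index=True
    )

    # reference/alternate nucleotides per SNP
    rng_alleles = _rng(config.seed, 2, seed)
    nuc = np.array(NUCLEOTIDES)
    major = rng_alleles.integers(0, 4, size=len(truth))
    minor = (major + rng_alleles.integers(1, 4, size=len(truth))) % 4
    truth["major"] = nuc[major]
    truth["minor"] = nuc[minor]

    # true slopes between latitude-adjacent pools (south->mid, mid->north)
    labels = [config.pools[i].label for i in order]
    pS, pM_, pN = (truth[f"p_{l}"].to_numpy() for l in labels)
    latS, latM, latN = lats[order]
    truth["s1_true"] = (pM_ - pS) / (latM - latS)
    truth["s2_true"] = (pN - pM_) / (latN - latM)
    return SimTruth(frame=truth, pools=list(config.pools))


def sample_pool_counts(
    truth: SimTruth, config: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Two-stage read-count sampling; returns a site frame (arm, position,
    ref) and an ``(n_sites, n_pools, 6)`` count array in sync order."""
    rng = _rng(config.seed, 3, seed)
    tf = truth.frame
    n = len(tf)
    n_pools = len(truth.pools)
    nuc_idx = {x: i for i, x in enumerate(NUCLEOTIDES)}
    major_idx = tf["major"].map(nuc_idx).to_numpy()
    minor_idx = tf["minor"].map(nuc_idx).to_numpy()

    counts = np.zeros((n, n_pools, 6), dtype=np.int64)
    for j, pool in enumerate(truth.pools):
        p = tf[f"p_{pool.label}"].to_numpy()
        k = rng.binomial(pool.n_chromosomes, p)
        M = rng.poisson(config.mean_coverage, size=n)
        while (M == 0).any():  # zero-truncated Poisson
            z = M == 0
            M[z] = rng.poisson(config.mean_coverage, size=int(z.sum()))
        minor_reads = rng.binomial(M, k / pool.n_chromosomes)
        major_reads = M - minor_reads
        base = np.zeros((n, 4), dtype=np.int64)
        np.put_along_axis(base, major_idx[:, None], major_reads[:, None], axis=1)
        np.add.at(base, (np.arange(n), minor_idx), minor_reads)
        if config.error_rate > 0:
            final = np.zeros((n, 4), dtype=np.int64)
            for src in range(4):
                c = base[:, src]
                errs = rng.binomial(c, config.error_rate)
                final[:, src] += c - errs
                others = [t for t in range(4) if t != src]
                spread = rng.multinomial(errs, [1 / 3] * 3)
                for t, tgt in enumerate(others):
                    final[:, tgt] += spread[:, t]
            base = final
        counts[:, j, :4] = base

    sites = pd.DataFrame(
        {"arm": tf["arm"], "position": tf["position"], "ref": tf["major"]}
    )
    return sites, counts


# ---------------------------------------------------------------------------
# gene / GO / CDS scaffolds
# ---------------------------------------------------------------------------

_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def build_gene_scaffold(
    config: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, dict[str, str], dict[str, set[str]]]:
    """Tile each arm with non-overlapping genes and invent GO annotations.

    Returns (gene frame, per-gene spliced CDS sequence, GO map). Gene
    lengths are two-class (short/long); the category ``GO:LONG`` collects
    long genes only, giving the length-biased fixture used to demonstrate
    why SNP-permutation GO testing is needed.
    """
    rng = _rng(config.seed, 4, seed)
    rows = []
    cds_seqs: dict[str, str] = {}
    gene_counter = 0
    for arm in sorted(config.arms):
        arm_len = config.arm_length(arm)
        pos = config.gene_gap
        while pos + config.short_gene_length < arm_len:
            is_long = rng.random() < config.long_gene_fraction
            length = config.long_gene_length if is_long else config.short_gene_length
            if pos + length >= arm_len:
                break
            gene_counter += 1
            gid = f"g{gene_counter:05d}"
            start, end = pos, pos + length - 1
            strand = "+" if rng.random() < 0.5 else "-"
            # layout: 5'UTR | CDS | 3'UTR on the forward strand, orientation
            # applied via the strand flag; single exon spanning the gene
            utr = max(50, length // 20)
            cds_len = ((length - 2 * utr) // 3) * 3
            cds_start = start + utr
            cds_end = cds_start + cds_len - 1
            n_codons = cds_len // 3
            seq = "ATG" + "".join(
                _CODONS[i] for i in rng.integers(0, len(_CODONS), size=n_codons - 1)
            )
            cds_seqs[gid] = seq
            rows.append(
                {
                    "gene_id": gid, "arm": arm, "strand": strand,
                    "start": start, "end": end, "is_long": is_long,
                    "cds_start": cds_start, "cds_end": cds_end,
                    "utr5": (start, cds_start - 1) if strand == "+" else (cds_end + 1, end),
                    "utr3": (cds_end + 1, end) if strand == "+" else (start, cds_start - 1),
                }
            )
            pos = end + 1 + config.gene_gap
    genes = pd.DataFrame(rows)

    go_map: dict[str, set[str]] = {}
    if len(genes):
        gids = genes["gene_id"].to_numpy()
        for g in gids:
            for cat in rng.choice(config.n_go_categories, size=2, replace=False):
                go_map.setdefault(f"GO:{cat + 1:07d}", set()).add(g)
        long_ids = set(genes.loc[genes["is_long"], "gene_id"])
        if long_ids:
            go_map["GO:LONG"] = long_ids
    return genes, cds_seqs, go_map


def write_gff(genes: pd.DataFrame, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in genes.itertuples(index=False):
            attrs_gene = f"ID={r.gene_id}"
            mrna = f"{r.gene_id}.t1"
            fh.write(
                f"{r.arm}\tsim\tgene\t{r.start}\t{r.end}\t.\t{r.strand}\t.\t{attrs_gene}\n"
                f"{r.arm}\tsim\tmRNA\t{r.start}\t{r.end}\t.\t{r.strand}\t.\tID={mrna};Parent={r.gene_id}\n"
                f"{r.arm}\tsim\texon\t{r.start}\t{r.end}\t.\t{r.strand}\t.\tID={mrna}.e1;Parent={mrna}\n"
            )
            u5a, u5b = r.utr5
            u3a, u3b = r.utr3
            if u5b >= u5a:
                fh.write(
                    f"{r.arm}\tsim\tfive_prime_UTR\t{u5a}\t{u5b}\t.\t{r.strand}\t.\tID={mrna}.u5;Parent={mrna}\n"
                )
            fh.write(
                f"{r.arm}\tsim\tCDS\t{r.cds_start}\t{r.cds_end}\t.\t{r.strand}\t0\tID={mrna}.c1;Parent={mrna}\n"
            )
            if u3b >= u3a:
                fh.write(
                    f"{r.arm}\tsim\tthree_prime_UTR\t{u3a}\t{u3b}\t.\t{r.strand}\t.\tID={mrna}.u3;Parent={mrna}\n"
                )


def write_simulation(
    truth: SimTruth,
    sites: pd.DataFrame,
    counts: np.ndarray,
    outdir: str | os.PathLike,
    config: SimConfig,
    seed: int | None = None,
) -> dict[str, str]:
    """Write sync, truth, pools, gene/GO/CDS scaffolds, masks and the
    inversion config; returns the path of every artifact."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {k: os.path.join(outdir, v) for k, v in {
        "sync": "counts.sync", "truth": "truth.tsv", "pools": "pools.tsv",
        "gff": "genes.gff3", "go": "go_associations.tsv", "cds": "cds.fasta",
        "include": "include.bed", "exclude": "exclude.bed",
        "inversion": "inversion.yaml",
    }.items()}

    write_sync_arrays(sites, counts, paths["sync"])
    truth.frame.to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
    write_pools(truth.pools, paths["pools"])

    genes, cds_seqs, go_map = build_gene_scaffold(config, seed)
    write_gff(genes, paths["gff"])
    with open(paths["go"], "w") as fh:
        fh.write("gene_id\tgo_id\n")
        for go in sorted(go_map):
            for g in sorted(go_map[go]):
                fh.write(f"{g}\t{go}\n")
    with open(paths["cds"], "w") as fh:
        for gid in sorted(cds_seqs):
            fh.write(f">{gid}\n{cds_seqs[gid]}\n")

    include = MaskSet.from_intervals(
        {arm: [(1, config.arm_length(arm))] for arm in sorted(config.arms)}
    )
    write_bed_mask(include, paths["include"])
    write_bed_mask(MaskSet.from_intervals({}), paths["exclude"])

    inv = config.inversion
    with open(paths["inversion"], "w") as fh:
        if inv is None:
            yaml.safe_dump({"inversions": []}, fh)
        else:
            mpos = np.linspace(inv.start, inv.end, inv.n_markers + 2)[1:-1].astype(int)
            tf = truth.frame
            markers = []
            for mp in mpos:
                row = tf[(tf["arm"] == inv.arm) & (tf["position"] == mp)]
                if len(row):
                    markers.append(
                        {"position": int(mp), "allele": str(row["minor"].iloc[0])}
                    )
            yaml.safe_dump(
                {
                    "inversions": [
                        {
                            "name": inv.name, "arm": inv.arm,
                            "start": int(inv.start), "end": int(inv.end),
                            "markers": markers,
                        }
                    ]
                },
                fh,
            )
    return paths


def simulate_study(
    config: SimConfig, outdir: str | os.PathLike | None = None, seed: int | None = None
) -> tuple[SimTruth, pd.DataFrame, np.ndarray, dict[str, str] | None]:
    """Convenience wrapper: frequencies + counts (+ files when ``outdir``)."""
    truth = simulate_frequencies(config, seed)
    sites, counts = sample_pool_counts(truth, config, seed)
    paths = None
    if outdir is not None:
        paths = write_simulation(truth, sites, counts, outdir, config, seed)
    return truth, sites, counts, paths
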