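"""Inversion-region analysis: candidate enrichment and F_ST elevation
inside breakpoint-delimited spans, and marker-based inversion frequency
estimates (In(3R)Payne-style diagnostic markers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.special import gammaln

from .candidates import fisher_exact_2x2
from .site_filtering import SnpTable


@dataclass
class InversionRegion:
    name: str
    arm: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.name}: start > end")


@dataclass
class MarkerSpec:
    marker_id: str
    arm: str
    position: int
    inversion_allele: str


def read_inversion_config(path: str) -> tuple[list[InversionRegion], list[MarkerSpec]]:
    """Read inversion spans + markers from the YAML emitted by the
    synthetic module (or hand-written with the same keys)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    regions, markers = [], []
    for inv in cfg.get("inversions", []):
        regions.append(
            InversionRegion(inv["name"], inv["arm"], int(inv["start"]), int(inv["end"]))
        )
        for i, m in enumerate(inv.get("markers", []), start=1):
            markers.append(
                MarkerSpec(
                    f"{inv['name']}_m{i}", inv["arm"], int(m["position"]), m["allele"]
                )
            )
    return regions, markers


def inversion_enrichment(
    candidate_flags: np.ndarray,
    arms: np.ndarray,
    positions: np.ndarray,
    region: InversionRegion,
) -> dict:
    """Two-sided FET on (candidate vs not) x (inside vs outside the
    inversion), restricted to the inversion's arm."""
    on_arm = np.asarray(arms) == region.arm
    pos = np.asarray(positions)[on_arm]
    cand = np.asarray(candidate_flags, dtype=bool)[on_arm]
    inside = (pos >= region.start) & (pos <= region.end)
    a = int((cand & inside).sum())
    b = int((~cand & inside).sum())
    c = int((cand & ~inside).sum())
    d = int((~cand & ~inside).sum())
    result = {
        "name": region.name,
        "n_inside": a + b,
        "n_outside": c + d,
        "candidates_inside": a,
        "candidates_outside": c,
    }
    if (a + b) == 0 or (c + d) == 0:
        result.update(p=np.nan, direction="undefined")
        return result
    prop_in = a / (a + b)
    prop_out = c / (c + d)
    # an all-zero candidate column is a valid (uninformative) table: p = 1
    result["p"] = fisher_exact_2x2(a, b, c, d)
    result["direction"] = (
        "enriched" if prop_in > prop_out else ("depleted" if prop_in < prop_out else "none")
    )
    return result


def inversion_fst_shift(
    site_fst: np.ndarray,
    arms: np.ndarray,
    positions: np.ndarray,
    region: InversionRegion,
    min_snps: int = 10,
) -> dict:
    """Two-sided Wilcoxon rank-sum test of SNP-wise F_ST inside versus
    outside the inversion (same arm); reports the stratum medians."""
    on_arm = np.asarray(arms) == region.arm
    pos = np.asarray(positions)[on_arm]
    fst = np.asarray(site_fst, dtype=float)[on_arm]
    ok = ~np.isnan(fst)
    pos, fst = pos[ok], fst[ok]
    inside = (pos >= region.start) & (pos <= region.end)
    x, y = fst[inside], fst[~inside]
    result = {
        "name": region.name,
        "n_inside": len(x),
        "n_outside": len(y),
        "median_inside": float(np.median(x)) if len(x) else np.nan,
        "median_outside": float(np.median(y)) if len(y) else np.nan,
    }
    if len(x) < min_snps or len(y) < min_snps:
        result.update(p=np.nan, flagged="stratum_too_small")
        return result
    if np.ptp(np.concatenate([x, y])) == 0:
        result.update(p=1.0, flagged="")
        return result
    result["p"] = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    result["flagged"] = ""
    return result


def _kx2_exact_homogeneity(
    inv_counts: np.ndarray, cov: np.ndarray, n_sim: int, rng: np.random.Generator
) -> float:
    """Monte-Carlo exact test of homogeneity for a K x 2 table with fixed
    margins (Fisher-style: sums the probability of tables no more probable
    than the observed one)."""
    inv_counts = np.asarray(inv_counts, dtype=np.int64)
    cov = np.asarray(cov, dtype=np.int64)
    total_inv = int(inv_counts.sum())

    def logprob(k: np.ndarray) -> np.ndarray:
        # product-hypergeometric probability of a table with row margins
        # cov, first-column margin total_inv
        lc = gammaln(cov + 1) - gammaln(k + 1) - gammaln(cov - k + 1)
        norm = (
            gammaln(cov.sum() + 1)
            - gammaln(total_inv + 1)
            - gammaln(cov.sum() - total_inv + 1)
        )
        return lc.sum(axis=-1) - norm

    obs = logprob(inv_counts)
    sims = np.stack(
        [rng.multivariate_hypergeometric(cov, total_inv) for _ in range(n_sim)]
    )
    lp = logprob(sims)
    return float((1 + np.sum(lp <= obs + 1e-9)) / (1 + n_sim))


def marker_frequencies_from_counts(
    sites,
    counts: np.ndarray,
    pools,
    markers: list[MarkerSpec],
    n_sim: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Marker frequencies straight from raw per-site nucleotide counts.

    Diagnostic markers are fixed, known positions: they need no SNP-calling
    step, and applying the coverage-cap filter would silently drop them.
    ``sites``/``counts`` are the raw sync arrays; otherwise identical in
    output to :func:`marker_frequencies`.
    """
    from .io_formats import NUCLEOTIDES

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = [p.label for p in pools]
    nuc_idx = {x: i for i, x in enumerate(NUCLEOTIDES)}
    key = pd.MultiIndex.from_arrays([sites["arm"], sites["position"]])
    rows = []
    tallies: dict[str, list[tuple[int, int]]] = {l: [] for l in labels}
    for m in markers:
        try:
            i = key.get_loc((m.arm, m.position))
        except KeyError:
            warnings.warn(f"marker {m.marker_id} absent from site table; omitted")
            continue
        row = {"marker_id": m.marker_id, "arm": m.arm, "position": m.position}
        a = nuc_idx[m.inversion_allele]
        for j, lab in enumerate(labels):
            inv_c = int(counts[i, j, a])
            cov = int(counts[i, j, :4].sum())
            row[f"freq_{lab}"] = inv_c / cov if cov else 0.0
            tallies[lab].append((inv_c, cov))
        rows.append(row)
    return _summarise_markers(pd.DataFrame(rows), labels, tallies, n_sim, rng)


def marker_frequencies(
    snps: SnpTable,
    markers: list[MarkerSpec],
    n_sim: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-pool inversion-allele frequencies at the diagnostic markers.

    Returns one row per marker plus a ``median`` summary row per pool
    block; the homogeneity row reports a seeded Monte-Carlo exact test of
    the K x 2 marker-count table per pool (NaN for a single marker).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = snps.labels
    frame = snps.frame
    key = pd.MultiIndex.from_arrays([frame["arm"], frame["position"]])
    rows = []
    counts: dict[str, list[tuple[int, int]]] = {l: [] for l in labels}
    for m in markers:
        try:
            i = key.get_loc((m.arm, m.position))
        except KeyError:
            warnings.warn(f"marker {m.marker_id} absent from SNP table; omitted")
            continue
        if isinstance(i, (slice, np.ndarray)):
            i = np.flatnonzero(np.asarray(key == (m.arm, m.position)))[0]
        row = {"marker_id": m.marker_id, "arm": m.arm, "position": m.position}
        is_minor = frame["minor"].iloc[i] == m.inversion_allele
        for j, lab in enumerate(labels):
            inv_c = int(
                snps.minor_counts[i, j] if is_minor else snps.major_counts[i, j]
            )
            cov = int(snps.major_counts[i, j] + snps.minor_counts[i, j])
            row[f"freq_{lab}"] = inv_c / cov if cov else 0.0
            counts[lab].append((inv_c, cov))
        rows.append(row)
    return _summarise_markers(pd.DataFrame(rows), labels, counts, n_sim, rng)


def _summarise_markers(out, labels, tallies, n_sim, rng) -> pd.DataFrame:
    """Append per-pool median and homogeneity-test rows to a marker table."""
    if out.empty:
        return out
    summary = {"marker_id": "median", "arm": "", "position": -1}
    homog = {"marker_id": "homogeneity_p", "arm": "", "position": -1}
    for lab in labels:
        summary[f"freq_{lab}"] = float(out[f"freq_{lab}"].median())
        cc = tallies[lab]
        if len(cc) < 2:
            homog[f"freq_{lab}"] = np.nan
        else:
            inv_c = np.array([c[0] for c in cc])
            cov = np.array([c[1] for c in cc])
            homog[f"freq_{lab}"] = _kx2_exact_homogeneity(inv_c, cov, n_sim, rng)
    return pd.concat([out, pd.DataFrame([summary, homog])], ignore_index=True)
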