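"""Pool-corrected nucleotide diversity, Watterson's theta and Tajima's D.

Pool-seq reads are a two-stage sample: n chromosomes are drawn from the
population into the pool, then M reads are drawn (with replacement) from
the pool. The estimators below correct for both stages:

* per-site heterozygosity
  ``pi = [n/(n-1)] * [M/(M-1)] * (1 - sum_a (c_a/M)^2)``,
  which is unbiased for the population heterozygosity 2p(1-p);
* Watterson's theta divides the segregating-site indicator by a
  detectability-corrected denominator
  ``a*(n, M, b) = sum_{i=1}^{n-1} (1/i) P(b <= K_i <= M-b)`` with
  ``K_i ~ Binomial(M, i/n)`` — the classical harmonic sum weighted by the
  probability that an allele at pool frequency i/n is actually seen at
  least ``b`` times among M reads;
* Tajima's D is computed after subsampling every site to a fixed target
  coverage (default 25) with minimum count 1, so that unequal coverage
  does not masquerade as a frequency-spectrum shift. D only supports
  relative comparisons between pools analysed identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats


def pi_site(counts: np.ndarray, coverage: np.ndarray, n_chromosomes: int) -> np.ndarray:
    """Pool-corrected per-site heterozygosity.

    ``counts`` holds per-allele read counts along the last axis; ``coverage``
    is their sum. Sites with coverage < 2 yield NaN.
    """
    counts = np.asarray(counts, dtype=float)
    M = np.asarray(coverage, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = 1.0 - np.sum((counts / M[..., None]) ** 2, axis=-1)
        pi = (n_chromosomes / (n_chromosomes - 1.0)) * (M / (M - 1.0)) * het
    return np.where(M >= 2, pi, np.nan)


def pi_site_biallelic(
    major: np.ndarray, minor: np.ndarray, n_chromosomes: int
) -> np.ndarray:
    """:func:`pi_site` on the two called alleles only (coverage = maj+min)."""
    major = np.asarray(major, dtype=float)
    minor = np.asarray(minor, dtype=float)
    return pi_site(np.stack([major, minor], axis=-1), major + minor, n_chromosomes)


@lru_cache(maxsize=None)
def watterson_denominator(n: int, M: int, b: int = 2) -> float:
    """Detectability-corrected Watterson denominator ``a*(n, M, b)``.

    ``b`` is the minimum allele count required to call a site segregating.
    Requires ``1 <= b <= M/2``.
    """
    if not 1 <= b <= M / 2:
        raise ValueError(f"minimum count b={b} must satisfy 1 <= b <= M/2 (M={M})")
    i = np.arange(1, n)
    detect = stats.binom.cdf(M - b, M, i / n) - stats.binom.cdf(b - 1, M, i / n)
    return float(np.sum(detect / i))


def theta_site(
    minor_counts: np.ndarray, coverage: np.ndarray, n_chromosomes: int, b: int = 2
) -> np.ndarray:
    """Per-site Watterson theta: S/a*(n, M, b) with S the indicator that the
    pool's minor count reaches ``b``. Sites with M < 2b yield NaN."""
    minor_counts = np.asarray(minor_counts)
    M = np.asarray(coverage)
    out = np.full(M.shape, np.nan)
    valid = M >= 2 * b
    seg = (minor_counts >= b) & valid
    uniq, inv = np.unique(M[valid], return_inverse=True)
    astar = np.array([watterson_denominator(n_chromosomes, int(m), b) for m in uniq])
    out[valid] = seg[valid] / astar[inv]
    return out


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _tajima_constants(n: int) -> tuple[float, float]:
    """(e1, e2) of Tajima's variance normalisation at sample size n."""
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return c1 / a1, c2 / (a1**2 + a2)


def subsample_counts(
    major: np.ndarray, minor: np.ndarray, target: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Subsample biallelic read counts to exactly ``target`` reads without
    replacement (hypergeometric). Sites with fewer reads are returned as-is;
    callers are expected to have dropped them."""
    sub_minor = rng.hypergeometric(minor, major, target)
    return target - sub_minor, sub_minor


def tajimas_d(
    major: np.ndarray,
    minor: np.ndarray,
    n_chromosomes: int,
    target_coverage: int = 25,
    b: int = 1,
    seed: int | np.random.Generator = 0,
) -> float:
    """Tajima's D for one pool over a set of sites.

    Sites with coverage below ``target_coverage`` are dropped; the rest are
    subsampled to exactly ``target_coverage`` reads. Tajima's constants are
    evaluated at the nominal sample size ``min(n_chromosomes, target)``.
    Returns NaN when no site segregates after subsampling.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    major = np.asarray(major)
    minor = np.asarray(minor)
    keep = major + minor >= target_coverage
    if not keep.any():
        return float("nan")
    maj, mnr = subsample_counts(major[keep], minor[keep], target_coverage, rng)
    seg = (mnr >= b) & (mnr <= target_coverage - b)
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    pi_sum = np.nansum(pi_site_biallelic(maj, mnr, n_chromosomes))
    astar = watterson_denominator(n_chromosomes, target_coverage, b)
    theta_sum = S / astar
    n_nom = min(n_chromosomes, target_coverage)
    e1, e2 = _tajima_constants(n_nom)
    var = e1 * S + e2 * S * (S - 1)
    return float((pi_sum - theta_sum) / np.sqrt(var))


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

@dataclass
class WindowGrid:
    size: int = 200_000
    min_valid_fraction: float = 0.6


def window_average(
    arms: np.ndarray,
    positions: np.ndarray,
    values: np.ndarray,
    grid: WindowGrid | int = WindowGrid(),
    valid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Average per-site values over non-overlapping genomic windows.

    ``valid`` marks sites fulfilling the coverage criteria; a window is
    flagged invalid when fewer than ``min_valid_fraction`` of its SNPs are
    valid (the broken-line rule for plots). NaN values count as invalid.
    Windows containing no SNP are not reported.
    """
    if isinstance(grid, int):
        grid = WindowGrid(size=grid)
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones(len(values), dtype=bool)
    valid = valid & ~np.isnan(values)

    win = (np.asarray(positions) - 1) // grid.size
    df = pd.DataFrame(
        {"arm": arms, "win": win, "value": np.where(valid, values, np.nan), "valid": valid}
    )
    g = df.groupby(["arm", "win"], sort=True)
    out = g.agg(
        mean_value=("value", "mean"),
        n_snps=("value", "size"),
        n_valid=("valid", "sum"),
    ).reset_index()
    out["start"] = out["win"] * grid.size + 1
    out["end"] = (out["win"] + 1) * grid.size
    out["valid"] = out["n_valid"] / out["n_snps"] >= grid.min_valid_fraction
    return out[["arm", "start", "end", "mean_value", "n_snps", "n_valid", "valid"]]
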