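"""SNP definition filters: coverage bounds, region masks and the pooled
minimum-allele-count rule.

A site is kept as a SNP iff

* every pool's coverage (sum of A,T,C,G counts) lies between
  ``min_coverage`` and that pool's empirical upper-quantile cap,
* the position falls inside the "include" regions (normally recombining
  spans) and outside the "exclude" mask (repeats/indels), and
* the counts summed over all pools carry at least two alleles, the
  second-most-frequent of which reaches ``min_total_minor_count``
  (default 6 — roughly two copies per population on average).

Major/minor alleles are chosen by total pooled counts with alphabetical
tie-breaking; at sites with more than two alleles the two most frequent
are kept and the ``multiallelic`` flag set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import MaskSet, NUCLEOTIDES, PoolProfile, check_pools

#: indices of A,T,C,G in sync column order
_NUC_IDX = np.arange(4)
#: alphabetical rank of A,T,C,G in sync column order (A,C,G,T sort order)
_ALPHA_RANK = np.array([0, 3, 1, 2])


@dataclass
class FilterConfig:
    min_coverage: int = 10
    max_coverage_quantile: float = 0.02  # upper tail mass, per pool
    min_total_minor_count: int = 6
    region_include: MaskSet | None = None
    region_exclude: MaskSet | None = None

    def __post_init__(self) -> None:
        if not (0 < self.max_coverage_quantile < 1):
            raise ValueError("max_coverage_quantile must be in (0, 1)")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")


@dataclass
class SnpTable:
    """Filtered SNP set in column-parallel arrays.

    ``frame`` holds arm, position, major, minor and the multiallelic flag;
    the per-pool matrices are shaped ``(n_snps, n_pools)`` in pool order.
    ``minor_freq`` is minor count over coverage.
    """

    pools: list[PoolProfile]
    frame: pd.DataFrame
    coverage: np.ndarray
    major_counts: np.ndarray
    minor_counts: np.ndarray

    def __post_init__(self) -> None:
        check_pools(self.pools)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.pools]

    @property
    def arms(self) -> np.ndarray:
        return self.frame["arm"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.frame["position"].to_numpy()

    @property
    def minor_freq(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.coverage > 0, self.minor_counts / self.coverage, np.nan)

    def pool_index(self, label: str) -> int:
        return self.labels.index(label)

    def subset(self, mask: np.ndarray) -> "SnpTable":
        return SnpTable(
            pools=self.pools,
            frame=self.frame.loc[mask].reset_index(drop=True),
            coverage=self.coverage[mask],
            major_counts=self.major_counts[mask],
            minor_counts=self.minor_counts[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        """Flat headered table (one cov/maj/min column triple per pool)."""
        df = self.frame.copy()
        for j, lab in enumerate(self.labels):
            df[f"cov_{lab}"] = self.coverage[:, j]
            df[f"maj_{lab}"] = self.major_counts[:, j]
            df[f"min_{lab}"] = self.minor_counts[:, j]
            df[f"freq_{lab}"] = self.minor_freq[:, j]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, pools: Sequence[PoolProfile]) -> "SnpTable":
        labels = [p.label for p in pools]
        return cls(
            pools=list(pools),
            frame=df[["arm", "position", "major", "minor", "multiallelic"]].reset_index(drop=True),
            coverage=df[[f"cov_{l}" for l in labels]].to_numpy(dtype=np.int64),
            major_counts=df[[f"maj_{l}" for l in labels]].to_numpy(dtype=np.int64),
            minor_counts=df[[f"min_{l}" for l in labels]].to_numpy(dtype=np.int64),
        )


def compute_coverage_caps(counts: np.ndarray, quantile: float = 0.02) -> np.ndarray:
    """Per-pool coverage caps: the empirical ``1 - quantile`` quantile
    (linear interpolation) of each pool's nucleotide coverage.

    ``counts`` is ``(n_sites, n_pools, 6)`` in sync order.
    """
    if counts.shape[0] == 0:
        raise ValueError("cannot compute coverage caps from an empty site set")
    coverage = counts[:, :, :4].sum(axis=2)
    return np.quantile(coverage, 1.0 - quantile, axis=0, method="linear")


def call_snps(
    sites: pd.DataFrame,
    counts: np.ndarray,
    pools: Sequence[PoolProfile],
    cfg: FilterConfig,
    caps: np.ndarray | None = None,
) -> SnpTable:
    """Apply the full SNP-definition filter to a site table.

    ``sites`` must have ``arm`` and ``position`` columns aligned with the
    first axis of ``counts``.
    """
    check_pools(pools)
    if caps is None:
        caps = compute_coverage_caps(counts, cfg.max_coverage_quantile)
    coverage = counts[:, :, :4].sum(axis=2)
    keep = ((coverage >= cfg.min_coverage) & (coverage <= caps[None, :])).all(axis=1)

    arms = sites["arm"].to_numpy()
    positions = sites["position"].to_numpy()
    if cfg.region_include is not None:
        inc = np.zeros(len(sites), dtype=bool)
        for arm in np.unique(arms):
            sel = arms == arm
            inc[sel] = cfg.region_include.contains(arm, positions[sel])
        keep &= inc
    if cfg.region_exclude is not None:
        exc = np.zeros(len(sites), dtype=bool)
        for arm in np.unique(arms):
            sel = arms == arm
            exc[sel] = cfg.region_exclude.contains(arm, positions[sel])
        keep &= ~exc

    pooled = counts[:, :, :4].sum(axis=1)  # (n_sites, 4) totals across pools
    # order alleles by (count desc, alphabetical asc): stable via lexsort keys
    order = np.lexsort((_ALPHA_RANK[None, :].repeat(len(pooled), 0), -pooled), axis=1)
    major_idx = order[:, 0]
    minor_idx = order[:, 1]
    rows = np.arange(len(pooled))
    second_count = pooled[rows, minor_idx]
    third_count = pooled[rows, order[:, 2]]
    keep &= second_count >= cfg.min_total_minor_count

    idx = np.flatnonzero(keep)
    nucs = np.array(NUCLEOTIDES)
    frame = pd.DataFrame(
        {
            "arm": arms[idx],
            "position": positions[idx],
            "major": nucs[major_idx[idx]],
            "minor": nucs[minor_idx[idx]],
            "multiallelic": third_count[idx] > 0,
        }
    )
    sel = counts[idx]
    maj = np.take_along_axis(sel, major_idx[idx][:, None, None], axis=2)[:, :, 0]
    mnr = np.take_along_axis(sel, minor_idx[idx][:, None, None], axis=2)[:, :, 0]
    return SnpTable(
        pools=list(pools),
        frame=frame,
        coverage=coverage[idx],
        major_counts=maj,
        minor_counts=mnr,
    )
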