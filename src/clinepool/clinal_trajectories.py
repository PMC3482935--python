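"""Clinal trajectory classification of candidate SNPs.

Each candidate SNP is oriented toward the allele that rises in frequency
from the southernmost to the northernmost pool; latitude slopes are then

    s1 = (p_mid - p_south) / (lat_mid - lat_south)
    s2 = (p_north - p_mid) / (lat_north - lat_mid)

and the trajectory class is the sign pair (++, +-, -+, or "tie" for a
zero slope or an orientation tie). SNPs that are ++ in at least one
pairwise candidate set form the core clinal set; within it, SNPs whose
exact 95% binomial (Clopper-Pearson) confidence intervals are pairwise
disjoint across all three pools show significant clinal change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .site_filtering import SnpTable


def binomial_ci(
    x: np.ndarray, n: np.ndarray, level: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Clopper-Pearson exact binomial interval (Beta-quantile form).

    lo = 0 when x = 0 and hi = 1 when x = n, as in the closed forms
    lo = Beta(alpha/2; x, n-x+1), hi = Beta(1-alpha/2; x+1, n-x).
    """
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("n must be >= 1")
    if np.any((x < 0) | (x > n)):
        raise ValueError("x must be in [0, n]")
    alpha = 1.0 - level
    with np.errstate(invalid="ignore"):
        lo = np.where(x > 0, stats.beta.ppf(alpha / 2, x, n - x + 1), 0.0)
        hi = np.where(x < n, stats.beta.ppf(1 - alpha / 2, x + 1, n - x), 1.0)
    return lo, hi


def classify_trajectory(s1: np.ndarray, s2: np.ndarray) -> np.ndarray:
    """Sign-pair class: "++", "+-", "-+", "--" or "tie" (any zero slope)."""
    s1 = np.atleast_1d(np.asarray(s1, dtype=float))
    s2 = np.atleast_1d(np.asarray(s2, dtype=float))
    out = np.full(s1.shape, "tie", dtype=object)
    out[(s1 > 0) & (s2 > 0)] = "++"
    out[(s1 > 0) & (s2 < 0)] = "+-"
    out[(s1 < 0) & (s2 > 0)] = "-+"
    out[(s1 < 0) & (s2 < 0)] = "--"
    return out


def orient_and_slopes(snps: SnpTable, level: float = 0.95) -> pd.DataFrame:
    """Oriented frequencies, slopes, classes and CIs for every SNP.

    Pools are ordered by latitude; the oriented allele is whichever of
    major/minor rises (weakly) from south to north, with an exact
    south-north tie oriented to the minor allele and classed "tie".
    CIs use n = read coverage (reads are the observed binomial trials).
    """
    if len(snps.pools) < 3:
        raise ValueError("clinal analysis needs three pools")
    lats = np.array([p.latitude for p in snps.pools])
    if len(np.unique(lats)) != len(lats):
        raise ValueError("pool latitudes must be distinct")
    order = np.argsort(lats)
    iS, iM, iN = order[0], order[len(order) // 2], order[-1]
    labels = snps.labels

    cov = snps.coverage.astype(float)
    eff_cov = (snps.major_counts + snps.minor_counts).astype(float)
    minor_freq = np.where(eff_cov > 0, snps.minor_counts / eff_cov, np.nan)

    # orient so the chosen allele's frequency is >= in the north
    rising_minor = minor_freq[:, iN] >= minor_freq[:, iS]
    tie = minor_freq[:, iN] == minor_freq[:, iS]
    use_minor = rising_minor  # ties keep the minor allele
    freqs = np.where(use_minor[:, None], minor_freq, 1.0 - minor_freq)
    counts = np.where(use_minor[:, None], snps.minor_counts, snps.major_counts)

    latS, latM, latN = lats[iS], lats[iM], lats[iN]
    s1 = (freqs[:, iM] - freqs[:, iS]) / (latM - latS)
    s2 = (freqs[:, iN] - freqs[:, iM]) / (latN - latM)
    klass = classify_trajectory(s1, s2)
    klass[tie] = "tie"

    out = snps.frame[["arm", "position"]].copy()
    out["allele"] = np.where(use_minor, snps.frame["minor"], snps.frame["major"])
    for j, lab in enumerate(labels):
        lo, hi = binomial_ci(counts[:, j], eff_cov[:, j], level)
        out[f"freq_{lab}"] = freqs[:, j]
        out[f"cov_{lab}"] = cov[:, j].astype(int)
        out[f"ci_lo_{lab}"] = lo
        out[f"ci_hi_{lab}"] = hi
    out["s1"] = s1
    out["s2"] = s2
    out["trajectory"] = klass

    # significance: class ++ and all three pairwise CIs disjoint
    pairs = [(iS, iM), (iM, iN), (iS, iN)]
    disjoint = np.ones(len(out), dtype=bool)
    for a, b in pairs:
        la, ha = out[f"ci_lo_{labels[a]}"], out[f"ci_hi_{labels[a]}"]
        lb, hb = out[f"ci_lo_{labels[b]}"], out[f"ci_hi_{labels[b]}"]
        disjoint &= (ha < lb) | (hb < la)
    out["significant"] = (klass == "++") & disjoint
    return out


def core_clinal_set(per_pair_records: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Union of ++ SNPs across the pairwise candidate sets, de-duplicated
    by (arm, position); records which pairs contributed each SNP."""
    frames = []
    for pair, df in per_pair_records.items():
        sel = df.loc[df["trajectory"] == "++"].copy()
        sel["pair"] = pair
        frames.append(sel)
    if not frames:
        return pd.DataFrame(columns=["arm", "position", "pairs"])
    allrows = pd.concat(frames, ignore_index=True)
    pairs = (
        allrows.groupby(["arm", "position"], sort=True)["pair"]
        .agg(lambda s: ",".join(sorted(set(s))))
        .rename("pairs")
    )
    dedup = allrows.drop_duplicates(["arm", "position"]).drop(columns=["pair"])
    return dedup.merge(pairs, on=["arm", "position"]).sort_values(
        ["arm", "position"], ignore_index=True
    )


def plot_trajectories(records: pd.DataFrame, pools, path: str) -> None:
    """Frequency-versus-latitude plot of the core clinal set; SNPs with
    significant (CI-disjoint) clines drawn in red over the rest in black."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lats = np.array([p.latitude for p in pools])
    order = np.argsort(lats)
    labels = [pools[i].label for i in order]
    fig, ax = plt.subplots(figsize=(5, 4))
    for _, row in records.iterrows():
        y = [row[f"freq_{l}"] for l in labels]
        if row.get("significant", False):
            ax.plot(lats[order], y, color="red", lw=1.0, zorder=3)
        else:
            ax.plot(lats[order], y, color="black", lw=0.4, alpha=0.4)
    ax.set_xlabel("latitude (°N)")
    ax.set_ylabel("oriented allele frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
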