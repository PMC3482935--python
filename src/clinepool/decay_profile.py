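"""Decay of exact-test significance around candidate SNPs.

For every focal SNP, all other SNPs within ``span`` bp are binned by the
signed distance ``d = flanking_position - focal_position`` into windows of
``window`` bp (bin index ``floor(d / window)``); -log10 of the exact-test
p-values are pooled across focal SNPs per bin and the median reported. The
focal SNP's own p-value (d = 0) is excluded. A matched background profile
repeats the analysis around randomly drawn non-candidate SNPs at least
``background_min_distance`` bp away from every candidate, per arm, with
the same per-arm focal counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class DecayConfig:
    window: int = 100
    span: int = 100_000
    background_min_distance: int = 500_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.span % self.window:
            raise ValueError("window must divide span")


def decay_profile(
    focal: pd.DataFrame,
    snps: pd.DataFrame,
    cfg: DecayConfig = DecayConfig(),
    label: str = "candidates",
) -> pd.DataFrame:
    """Median -log10(p) per distance bin around the focal SNPs.

    ``focal`` and ``snps`` need arm/position columns; ``snps`` also needs
    ``fet_p``. Bins with no SNP are reported with n = 0 and NaN median.
    """
    if len(focal) == 0:
        raise ValueError("focal SNP set is empty")
    n_bins = cfg.span // cfg.window
    offsets = np.arange(-n_bins, n_bins + 1)
    pooled: dict[int, list[np.ndarray]] = {o: [] for o in offsets}

    for arm, grp in snps.groupby("arm", sort=True):
        pos = grp["position"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        logp = -np.log10(np.clip(grp["fet_p"].to_numpy()[order], 1e-300, None))
        fpos = focal.loc[focal["arm"] == arm, "position"].to_numpy()
        for f in fpos:
            lo = np.searchsorted(pos, f - cfg.span, side="left")
            hi = np.searchsorted(pos, f + cfg.span, side="right")
            d = pos[lo:hi] - f
            vals = logp[lo:hi]
            keep = d != 0  # the focal SNP itself
            if not keep.all():
                d, vals = d[keep], vals[keep]
            bins = np.floor_divide(d, cfg.window)
            for o in np.unique(bins):
                pooled[int(o)].append(vals[bins == o])

    rows = []
    for o in offsets:
        vals = np.concatenate(pooled[o]) if pooled[o] else np.array([])
        rows.append(
            {
                "offset_bin": int(o),
                "offset_bp": int(o) * cfg.window,
                "median_neglog10_p": float(np.median(vals)) if len(vals) else np.nan,
                "n_snps": len(vals),
                "focal_set": label,
            }
        )
    return pd.DataFrame(rows)


def sample_background(
    candidates: pd.DataFrame,
    snps: pd.DataFrame,
    cfg: DecayConfig = DecayConfig(),
) -> pd.DataFrame:
    """Per arm, draw as many background focal SNPs as there are candidates,
    uniformly without replacement among non-candidate SNPs at least
    ``background_min_distance`` from every candidate on that arm."""
    rng = np.random.default_rng(cfg.seed)
    chosen = []
    cand_key = set(zip(candidates["arm"], candidates["position"]))
    for arm, grp in snps.groupby("arm", sort=True):
        k = int((candidates["arm"] == arm).sum())
        if k == 0:
            continue
        pos = np.sort(grp["position"].to_numpy())
        cpos = np.sort(candidates.loc[candidates["arm"] == arm, "position"].to_numpy())
        idx = np.clip(np.searchsorted(cpos, pos), 1, len(cpos) - 1)
        near = np.minimum(np.abs(pos - cpos[idx - 1]), np.abs(pos - cpos[idx]))
        eligible = pos[
            (near >= cfg.background_min_distance)
            & ~np.fromiter(((arm, p) in cand_key for p in pos), bool, len(pos))
        ]
        if len(eligible) < k:
            warnings.warn(
                f"arm {arm}: only {len(eligible)} background SNPs "
                f">= {cfg.background_min_distance} bp from candidates "
                f"(need {k}); sampling all of them"
            )
            take = eligible
        else:
            take = rng.choice(eligible, size=k, replace=False)
        chosen.append(pd.DataFrame({"arm": arm, "position": np.sort(take)}))
    if not chosen:
        return pd.DataFrame(columns=["arm", "position"])
    return pd.concat(chosen, ignore_index=True)


def background_profile(
    candidates: pd.DataFrame,
    snps: pd.DataFrame,
    cfg: DecayConfig = DecayConfig(),
) -> pd.DataFrame:
    """Decay profile of the matched random background set."""
    bg = sample_background(candidates, snps, cfg)
    if len(bg) == 0:
        warnings.warn("no eligible background SNPs; empty background profile")
        out = decay_profile(candidates.head(1), snps, cfg, label="background")
        out["median_neglog10_p"] = np.nan
        out["n_snps"] = 0
        return out
    return decay_profile(bg, snps, cfg, label="background")
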