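"""Config-driven end-to-end pipeline.

Stages communicate through headered TSV artifacts on disk so any stage
can be re-run or inspected in isolation: simulate (optional) -> filter ->
diversity -> F_ST -> candidates -> annotation -> GO -> inversions ->
clinal -> decay -> comparative stats -> report. Every stage logs records
in/out; the global seed propagates deterministically to the stages that
draw random numbers.
"""

from __future__ import annotations

import itertools
import logging
import os
import numpy as np
import pandas as pd
import yaml

from . import (
    annotation_effects,
    candidates as cand_mod,
    clinal_trajectories,
    comparative_stats,
    decay_profile as decay_mod,
    differentiation,
    diversity as div_mod,
    go_enrichment,
    inversion_analysis,
    io_formats,
    site_filtering,
    synthetic_data,
)

log = logging.getLogger("clinepool")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _cfg(config: dict, key: str, default: dict | None = None) -> dict:
    return dict(config.get(key) or (default or {}))


def load_config(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config: dict, outdir: str) -> dict:
    """Run all configured stages; returns a dict of artifact paths and the
    in-memory result frames. Raises StageError naming the failing stage."""
    os.makedirs(outdir, exist_ok=True)
    seed = int(config.get("seed", 0))
    results: dict = {"outdir": outdir}

    def art(name: str) -> str:
        return os.path.join(outdir, name)

    # ---- simulate or load -------------------------------------------------
    stage = "simulate" if "simulate" in config else "load"
    try:
        if "simulate" in config:
            sim = _cfg(config, "simulate")
            inv = sim.pop("inversion", None)
            if inv is not None:
                inv = synthetic_data.InversionSpec(**inv)
            pools_cfg = sim.pop("pools", None)
            kwargs = dict(sim)
            if pools_cfg is not None:
                kwargs["pools"] = [io_formats.PoolProfile(**p) for p in pools_cfg]
            simcfg = synthetic_data.SimConfig(seed=seed, inversion=inv, **kwargs)
            simdir = art("sim")
            truth, sites, counts, paths = synthetic_data.simulate_study(
                simcfg, outdir=simdir
            )
            pools = simcfg.pools
            inputs = paths
            results["truth"] = truth
        else:
            inputs = dict(config["inputs"])
            pools = io_formats.read_pools(inputs["pools"])
            sites, counts = io_formats.read_sync_arrays(inputs["sync"], pools)
        genes = io_formats.read_gff(inputs["gff"]) if inputs.get("gff") else []
        go_map = (
            io_formats.read_go_associations(inputs["go"]) if inputs.get("go") else {}
        )
        cds_seqs = _read_fasta(inputs["cds"]) if inputs.get("cds") else {}
        include = (
            io_formats.read_bed_mask(inputs["include"]) if inputs.get("include") else None
        )
        exclude = (
            io_formats.read_bed_mask(inputs["exclude"]) if inputs.get("exclude") else None
        )
        regions, markers = (
            inversion_analysis.read_inversion_config(inputs["inversion"])
            if inputs.get("inversion")
            else ([], [])
        )
        log.info("input: %d sites, %d pools", len(sites), len(pools))
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    # ---- filter -----------------------------------------------------------
    try:
        fcfg = site_filtering.FilterConfig(
            region_include=include, region_exclude=exclude, **_cfg(config, "filter")
        )
        snps = site_filtering.call_snps(sites, counts, pools, fcfg)
        io_formats.write_table(snps.to_frame(), art("snps.tsv"))
        log.info("filter: %d sites -> %d SNPs", len(sites), len(snps))
        results["snps"] = snps
    except Exception as exc:
        raise StageError("filter", exc) from exc

    # ---- diversity --------------------------------------------------------
    try:
        div_cfg = _cfg(config, "diversity", {"b": 2, "window": 200_000})
        b = int(div_cfg.get("b", 2))
        window = int(div_cfg.get("window", 200_000))
        frames = []
        for j, pool in enumerate(pools):
            pi = div_mod.pi_site_biallelic(
                snps.major_counts[:, j], snps.minor_counts[:, j], pool.n_chromosomes
            )
            theta = div_mod.theta_site(
                snps.minor_counts[:, j], snps.coverage[:, j], pool.n_chromosomes, b=b
            )
            for name, vals in (("pi", pi), ("theta_w", theta)):
                w = div_mod.window_average(snps.arms, snps.positions, vals, window)
                w.insert(0, "pool", pool.label)
                w.insert(1, "statistic", name)
                frames.append(w)
            d = div_mod.tajimas_d(
                snps.major_counts[:, j],
                snps.minor_counts[:, j],
                pool.n_chromosomes,
                target_coverage=int(div_cfg.get("target_coverage", 25)),
                b=int(div_cfg.get("tajima_b", 1)),
                seed=np.random.default_rng([seed, 10 + j]),
            )
            log.info("diversity %s: genome-wide D = %.3f", pool.label, d)
        diversity_windows = pd.concat(frames, ignore_index=True)
        io_formats.write_table(diversity_windows, art("diversity.tsv"))
        results["diversity_windows"] = diversity_windows
    except Exception as exc:
        raise StageError("diversity", exc) from exc

    # ---- F_ST -------------------------------------------------------------
    try:
        fst = differentiation.all_pair_fst(snps)
        io_formats.write_table(fst, art("fst.tsv"))
        pair_cols = [c for c in fst.columns if c.startswith("fst_")]
        results["fst"] = fst
        gene_fst = {}
        for col in pair_cols:
            gene_fst[col[4:]] = differentiation.fst_gene(
                snps, fst[col].to_numpy(), genes
            )
        results["gene_fst"] = gene_fst
    except Exception as exc:
        raise StageError("fst", exc) from exc

    # ---- candidates -------------------------------------------------------
    try:
        ccfg = cand_mod.CandidateConfig(**_cfg(config, "candidates"))
        cand_tables: dict[str, pd.DataFrame] = {}
        gene_candidates: dict[str, set] = {}
        for i, j in itertools.combinations(range(len(pools)), 2):
            pair = differentiation.pair_label(pools[i].label, pools[j].label)
            table = cand_mod.call_candidates(
                snps, fst[f"fst_{pair}"].to_numpy(), i, j, genes=genes, cfg=ccfg
            )
            cand_tables[pair] = table
            io_formats.write_table(table, art(f"candidates_{pair}.tsv"))
            gene_candidates[pair] = cand_mod.gene_based_candidates(
                gene_fst[pair], ccfg.gene_tail
            )
            log.info(
                "candidates %s: %d outliers, %d candidates",
                pair, int(table["outlier"].sum()), int(table["candidate"].sum()),
            )
        results["candidates"] = cand_tables
        results["gene_candidates"] = gene_candidates
    except Exception as exc:
        raise StageError("candidates", exc) from exc

    # ---- annotation -------------------------------------------------------
    try:
        if genes:
            effects = annotation_effects.annotate_snps(snps, genes, cds_seqs)
            io_formats.write_table(effects, art("effects.tsv"))
            results["effects"] = effects
    except Exception as exc:
        raise StageError("annotate", exc) from exc

    # ---- GO enrichment ----------------------------------------------------
    try:
        if go_map and genes:
            gcfg = _cfg(config, "go", {"n_perm": 10_000, "min_genes": 5})
            go_tables = {}
            for pair, table in cand_tables.items():
                mask = table["candidate"].to_numpy()
                if not mask.any():
                    continue
                go_tables[pair] = go_enrichment.go_permutation_test(
                    mask, snps.arms, snps.positions, genes, go_map,
                    n_perm=int(gcfg.get("n_perm", 10_000)),
                    min_genes=int(gcfg.get("min_genes", 5)),
                    seed=np.random.default_rng([seed, 20]),
                )
                io_formats.write_table(go_tables[pair], art(f"go_{pair}.tsv"))
            results["go"] = go_tables
    except Exception as exc:
        raise StageError("go", exc) from exc

    # ---- inversions -------------------------------------------------------
    try:
        if regions:
            rows = []
            for region in regions:
                for pair, table in cand_tables.items():
                    enr = inversion_analysis.inversion_enrichment(
                        table["candidate"].to_numpy(), snps.arms, snps.positions, region
                    )
                    shift = inversion_analysis.inversion_fst_shift(
                        fst[f"fst_{pair}"].to_numpy(), snps.arms, snps.positions, region
                    )
                    rows.append(
                        {"name": region.name, "pair": pair,
                         "enrichment_p": enr["p"], "direction": enr["direction"],
                         "fst_shift_p": shift["p"],
                         "median_fst_inside": shift["median_inside"],
                         "median_fst_outside": shift["median_outside"]}
                    )
            inv_table = pd.DataFrame(rows)
            io_formats.write_table(inv_table, art("inversions.tsv"))
            results["inversions"] = inv_table
            if markers:
                # markers are fixed positions: read them from the raw counts
                # so the coverage-cap filter cannot drop them
                mfreq = inversion_analysis.marker_frequencies_from_counts(
                    sites, counts, pools, markers,
                    seed=np.random.default_rng([seed, 30]),
                )
                io_formats.write_table(mfreq, art("inversion_markers.tsv"))
                results["marker_frequencies"] = mfreq
    except Exception as exc:
        raise StageError("inversions", exc) from exc

    # ---- clinal -----------------------------------------------------------
    try:
        clinal_all = clinal_trajectories.orient_and_slopes(snps)
        per_pair = {}
        for pair, table in cand_tables.items():
            sel = clinal_all.loc[table["candidate"].to_numpy()].copy()
            per_pair[pair] = sel
            io_formats.write_table(sel, art(f"clinal_{pair}.tsv"))
        core = clinal_trajectories.core_clinal_set(per_pair)
        io_formats.write_table(core, art("clinal_core.tsv"))
        log.info("clinal: core ++ set has %d SNPs (%d significant)",
                 len(core), int(core["significant"].sum()) if len(core) else 0)
        results["clinal"] = per_pair
        results["clinal_core"] = core
    except Exception as exc:
        raise StageError("clinal", exc) from exc

    # ---- decay ------------------------------------------------------------
    try:
        dcfg_d = _cfg(config, "decay")
        dcfg_d.setdefault("seed", seed)
        dcfg = decay_mod.DecayConfig(**dcfg_d)
        decay_tables = {}
        for pair, table in cand_tables.items():
            focal = table.loc[table["candidate"], ["arm", "position"]]
            if focal.empty:
                continue
            prof = decay_mod.decay_profile(focal, table, dcfg)
            back = decay_mod.background_profile(focal, table, dcfg)
            decay_tables[pair] = pd.concat([prof, back], ignore_index=True)
            io_formats.write_table(decay_tables[pair], art(f"decay_{pair}.tsv"))
        results["decay"] = decay_tables
    except Exception as exc:
        raise StageError("decay", exc) from exc

    # ---- comparative stats ------------------------------------------------
    try:
        dw = results["diversity_windows"]
        comps = []
        for statname in ("pi", "theta_w"):
            sub = dw[dw["statistic"] == statname]
            if sub["arm"].nunique() >= 2 and sub["pool"].nunique() >= 2:
                comps.append(
                    comparative_stats.rank_anova(
                        sub["mean_value"].to_numpy(), sub["arm"].to_numpy(),
                        sub["pool"].to_numpy(), statistic_name=statname,
                    )
                )
            groups = {
                lab: g["mean_value"].to_numpy() for lab, g in sub.groupby("pool")
            }
            if len(groups) >= 2 and all(len(v) >= 5 for v in groups.values()):
                comps.append(
                    comparative_stats.kruskal_windows(groups, statistic_name=statname)
                )
        comp_df = pd.DataFrame(
            [
                {"statistic": c.statistic_name, "test": c.test,
                 "value": c.statistic, "p": c.p}
                for c in comps
            ]
        )
        io_formats.write_table(comp_df, art("compare.tsv"))
        results["comparisons"] = comp_df
    except Exception as exc:
        raise StageError("compare", exc) from exc

    # ---- report -----------------------------------------------------------
    try:
        _write_report(results, pools, art("report.txt"))
    except Exception as exc:
        raise StageError("report", exc) from exc
    return results


def _read_fasta(path: str) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name:
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def _write_report(results: dict, pools, path: str) -> None:
    lines = ["clinepool run summary", "=" * 40, ""]
    snps = results.get("snps")
    lines.append(f"SNPs after filtering: {len(snps)}")
    lines.append("")
    lines.append("Candidate summary (per pair):")
    lines.append("pair\tn_snps\tn_outliers\tn_candidates\tmean_candidate_fst\tn_candidate_genes")
    for pair, table in results.get("candidates", {}).items():
        cand = table[table["candidate"]]
        genes = set()
        for g in cand["gene_ids"]:
            if isinstance(g, str) and g:
                genes.update(g.split(","))
        mean_fst = cand["fst"].mean() if len(cand) else float("nan")
        lines.append(
            f"{pair}\t{len(table)}\t{int(table['outlier'].sum())}"
            f"\t{len(cand)}\t{mean_fst:.4f}\t{len(genes)}"
        )
    effects = results.get("effects")
    if effects is not None:
        lines.append("")
        lines.append("Feature proportions (all SNPs):")
        props = effects["feature"].value_counts(normalize=True)
        for feat, frac in props.items():
            lines.append(f"  {feat}\t{frac:.4f}")
    core = results.get("clinal_core")
    if core is not None:
        lines.append("")
        lines.append(
            f"Core clinal (++) SNPs: {len(core)}"
            + (f", significant: {int(core['significant'].sum())}" if len(core) else "")
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
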