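"""End-to-end synthetic seascape-genomics pipeline.

Chains every stage on a generated dataset: QC (filters, secondary-SNP
collapse, clone removal), connectivity statistics (F_ST, H_T, A_R,
AMOVA, NJ tree, DAPC), environmental preparation (gap fill, depth mask,
collinearity pruning, extraction, standardisation), the outlier/GEA
scans, gradient-forest and GDM gene-environment models, and per-scenario
genetic-offset surfaces with reef-system comparisons.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import gdm as gdm_mod
from .env_stack import prune_correlated, standardize_env
from .gea import fst_outlier_scan, logistic_gea, select_adaptive_loci
from .genotypes import write_dart_csv, write_hierarchy
from .gradient_forest import GradientForest
from .offset import (OffsetConfig, buffer_membership, compare_systems,
                     future_env, gdm_offset, gf_offset, pca_rgb)
from .popgen import (allele_frequencies, allelic_richness, amova, dapc,
                     expected_heterozygosity, fst_linearized_distance,
                     nei_fst, nj_tree, pairwise_fst)
from .qc import QCConfig, apply_locus_filters, detect_clones, remove_clones
from .synthetic import paper_scale_dataset, simulate_future


def run_pipeline(seed: int = 0, out_dir=None,
                 nrows: int = 120, ncols: int = 120,
                 n_loci: int = 1200, n_per_site: int = 20,
                 scenarios=("RCP2.6-2040s", "RCP2.6-2090s",
                            "RCP8.5-2040s", "RCP8.5-2090s"),
                 n_trees: int = 300, n_boot: int = 200,
                 n_perm_outlier: int = 500, n_perm_amova: int = 199,
                 gf_max_loci: int = 60,
                 write_outputs: bool = True) -> dict:
    """Run the full pipeline on a synthetic dataset; returns all results.

    Heavy resampling counts are tunable so the same code path scales from
    smoke tests to the full preset.
    """
    rng = np.random.default_rng(seed)
    seeds = {k: int(v) for k, v in zip(
        ("qc", "popgen", "gea", "gf", "scen", "cmp"),
        rng.integers(0, 2 ** 31 - 1, 6))}
    out = {"seed": seed}
    data = paper_scale_dataset(seed=seed, nrows=nrows, ncols=ncols,
                               n_loci=n_loci, n_per_site=n_per_site)
    out["manifest"] = data["manifest"]

    # --- QC ---------------------------------------------------------------
    g_f, h_f, report = apply_locus_filters(data["genotypes"], data["hierarchy"],
                                           QCConfig())
    clone_sets, thr = detect_clones(g_f, h_f)
    g_qc, h_qc, removed = remove_clones(g_f, h_f, clone_sets)
    report.clones_removed = removed
    report.clone_threshold = thr
    report.record("clones", samples_removed=len(removed))
    out["qc_report"] = report
    out["genotypes_qc"] = g_qc
    out["hierarchy_qc"] = h_qc

    # --- neutral / outlier partition ---------------------------------------
    # centered statistic: excess differentiation over the genome-wide
    # background, not over panmixia (see docs/methods.md)
    outliers = fst_outlier_scan(g_qc, h_qc, n_perm=n_perm_outlier,
                                center=True, seed=seeds["gea"])
    neutral_idx = np.nonzero(~outliers["outlier"].to_numpy())[0]
    g_neutral = g_qc.subset(locus_idx=neutral_idx)
    out["fst_outliers"] = outliers

    # --- connectivity stats on the neutral panel ---------------------------
    freqs_site = allele_frequencies(g_neutral, h_qc, "site")
    freqs_sys = allele_frequencies(g_neutral, h_qc, "system")
    fst_sites, fst_p = pairwise_fst(freqs_site, n_boot=n_boot, seed=seeds["popgen"])
    popgen = {
        "overall_fst_sites": nei_fst(freqs_site, n_boot=n_boot, seed=seeds["popgen"]),
        "overall_fst_systems": nei_fst(freqs_sys, n_boot=n_boot, seed=seeds["popgen"]),
        "H_T": expected_heterozygosity(freqs_site),
        "A_R": allelic_richness(g_neutral, h_qc, "site"),
        "pairwise_fst": fst_sites,
        "pairwise_fst_p": fst_p,
    }
    popgen["amova"] = amova(g_neutral, h_qc, n_perm=n_perm_amova, seed=seeds["popgen"])
    popgen["nj_newick"] = nj_tree(fst_linearized_distance(fst_sites))
    popgen["dapc"] = dapc(g_neutral, k_max=8, seed=seeds["popgen"])
    out["popgen"] = popgen

    # --- environmental preparation -----------------------------------------
    site_env = data["site_env"]
    kept_vars = prune_correlated(site_env, r_max=0.80, never_drop=("SSTrange",))
    site_env_kept = site_env.subset(kept_vars)
    site_env_std = standardize_env(site_env_kept)
    out["env_variables"] = kept_vars

    # --- GEA scan ----------------------------------------------------------
    # univariate scan selects the adaptive panel; the population-corrected
    # mode is available but deliberately conservative when clines align
    # with the hierarchy. The scan sees signed (z-scored) site values:
    # the absolute-distance standardisation is sign-free by design and
    # would fold monotone clines at the reference (see docs/methods.md).
    env_vals = site_env_kept.values
    env_z = (env_vals - env_vals.mean()) / env_vals.std(ddof=0)
    gea = logistic_gea(g_qc, h_qc, env_z, mode="univariate")
    freqs_all = allele_frequencies(g_qc, h_qc, "site")
    gf_set, gdm_set = select_adaptive_loci(gea, freqs_all, fst_outliers=outliers)
    out["gea"] = gea

    # --- gradient forest ----------------------------------------------------
    if not gf_set:
        raise RuntimeError("no adaptive loci passed the polymorphism rule; "
                           "cannot fit the gradient forest")
    gf_loci = gf_set[:gf_max_loci]
    loc_idx = [list(g_qc.loci.index).index(l) for l in gf_loci]
    freq_gf = allele_frequencies(g_qc.subset(locus_idx=loc_idx), h_qc, "site")
    Y = freq_gf.freq.fillna(freq_gf.freq.mean())
    X = site_env_kept.values.loc[Y.index]
    gf = GradientForest(n_trees=n_trees, random_state=seeds["gf"]).fit(X, Y)
    out["gf"] = gf

    # --- GDM ----------------------------------------------------------------
    gdm_idx = [list(g_qc.loci.index).index(l) for l in gdm_set]
    freq_gdm = allele_frequencies(g_qc.subset(locus_idx=gdm_idx), h_qc, "site")
    D = gdm_mod.genetic_dissimilarity(freq_gdm)
    gdm = gdm_mod.GDM().fit(X.loc[D.index], D)
    out["gdm"] = gdm

    # --- offsets -------------------------------------------------------------
    stack = data["stack"]
    membership = buffer_membership(h_qc, stack, radius_km=50.0)
    out["membership"] = membership
    out["pca_rgb"] = pca_rgb(gf, stack, membership)
    surfaces_gf, surfaces_gdm = [], []
    scen_rng = np.random.default_rng(seeds["scen"])
    for scen in scenarios:
        cfg = OffsetConfig(scenario=scen)
        scen_layers = simulate_future(stack, scenario=scen,
                                      seed=int(scen_rng.integers(2 ** 31)))
        fut = future_env(stack, scen_layers, cfg)
        surfaces_gf.append(gf_offset(gf, stack, fut, membership, scenario=scen))
        surfaces_gdm.append(gdm_offset(gdm, stack, fut, membership, scenario=scen))
    out["offsets_gf"] = surfaces_gf
    out["offsets_gdm"] = surfaces_gdm
    out["tests_gf"] = compare_systems(surfaces_gf, method="kruskal_dunn",
                                      seed=seeds["cmp"])
    if len(scenarios) > 1:
        out["tests_gf_anova"] = compare_systems(surfaces_gf, method="anova_tukey",
                                                seed=seeds["cmp"])

    if write_outputs and out_dir is not None:
        _write_outputs(out, Path(out_dir))
    return out


def _write_outputs(out: dict, out_dir: Path):
    out_dir.mkdir(parents=True, exist_ok=True)
    out["qc_report"].to_json(out_dir / "qc_report.json")
    write_dart_csv(out["genotypes_qc"], out_dir / "genotypes_qc.csv")
    write_hierarchy(out["hierarchy_qc"], out_dir / "hierarchy_qc.csv")
    out["manifest"].to_json(out_dir / "manifest.json")
    pg = out["popgen"]
    pg["pairwise_fst"].to_csv(out_dir / "pairwise_fst.csv")
    pg["pairwise_fst_p"].to_csv(out_dir / "pairwise_fst_p.csv")
    pg["amova"].to_json(out_dir / "amova.json")
    with open(out_dir / "nj_tree.nwk", "w") as fh:
        fh.write(pg["nj_newick"] + "\n")
    with open(out_dir / "popgen_summary.json", "w") as fh:
        json.dump({
            "overall_fst_sites": pg["overall_fst_sites"]["fst"],
            "overall_fst_systems": pg["overall_fst_systems"]["fst"],
            "H_T": pg["H_T"], "A_R": pg["A_R"]["A_R"],
            "dapc_k": pg["dapc"].k_,
        }, fh, indent=2)
    out["gea"].associations.to_csv(out_dir / "gea_associations.csv", index=False)
    out["gea"].per_locus.to_csv(out_dir / "gea_per_locus.csv")
    with open(out_dir / "locus_sets.json", "w") as fh:
        json.dump({"gf_set": out["gea"].gf_set, "gdm_set": out["gea"].gdm_set}, fh)
    out["gf"].to_json(out_dir / "gf_model.json")
    out["gdm"].to_json(out_dir / "gdm_model.json")
    rows = []
    for surf in out["offsets_gf"] + out["offsets_gdm"]:
        summ = surf.per_system_summary().reset_index()
        summ["scenario"] = surf.scenario
        summ["model"] = surf.model_tag
        rows.append(summ)
    pd.concat(rows, ignore_index=True).to_csv(out_dir / "offset_summary.csv", index=False)
    with open(out_dir / "system_tests.json", "w") as fh:
        rep = dict(out["tests_gf"])
        rep["summary"] = rep["summary"].to_dict(orient="records")
        rep["posthoc"] = rep["posthoc"].to_dict(orient="records")
        json.dump(rep, fh, indent=2, default=float)
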