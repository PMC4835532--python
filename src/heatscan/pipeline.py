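"""End-to-end orchestration: simulate -> adjust -> heritability -> HSI ->
QTL -> candidate genes.

Stages are plain functions over the domain objects so they can be run
individually (the CLI wraps them); :func:`run_pipeline` chains everything
on a synthetic dataset and writes the result tables.

``aem_method`` selects between the REML entry-mean models ("reml", the
default analysis path) and plain genotype means of the adjusted
observations ("mean") — the latter is exact for balanced complete
layouts and is what the Monte-Carlo recovery loops use.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import hsi as hsi_mod
from . import io
from .config import RunConfig, HSI_TRAITS, ANALYSIS_TRAITS
from .core import GenotypeMatrix, map_summary
from .genes import colocate, project_genes
from .heritability import heritability_table
from .qtl import QTLScanner, QTLScanOutput, filter_markers_qc
from .simulate import (LOCATION_CONDITIONS, SimReport, TrialDesign,
                       default_architecture, default_cross_design,
                       simulate_cross_genotypes, simulate_genes, simulate_map,
                       simulate_trial, simulate_weather)
from .trial import (adjust_fieldbook, aem_location_table, compute_gdd,
                    condition_effect_test, derive_traits, location_means_fast)


def default_config(seed: int = 1) -> RunConfig:
    cfg = RunConfig(seed=seed, location_conditions=dict(LOCATION_CONDITIONS))
    cfg.validate()
    return cfg


@dataclass
class SimulatedDataset:
    gmap: pd.DataFrame
    geno: GenotypeMatrix
    fieldbook: pd.DataFrame
    weather: pd.DataFrame
    genes: pd.DataFrame
    truth: SimReport


def simulate_dataset(config: RunConfig, missing_rate: float = 0.0
                     ) -> SimulatedDataset:
    """One full synthetic study at the default study conditions."""
    gmap = simulate_map()
    design = default_cross_design()
    rng = config.rng(0)
    geno = simulate_cross_genotypes(gmap, design,
                                    het_target=config.heterozygosity, rng=rng)
    arch = default_architecture()
    fb, truth = simulate_trial(geno, arch, TrialDesign(), rng, gmap,
                               missing_rate=missing_rate, seed=config.seed)
    weather = simulate_weather(rng=rng)
    genes = simulate_genes(gmap, rng=rng)
    return SimulatedDataset(gmap=gmap, geno=geno, fieldbook=fb,
                            weather=weather, genes=genes, truth=truth)


def reference_location(config: RunConfig, weather: pd.DataFrame) -> str:
    """The configured reference, or the location with the lowest growing
    degree days (least heat stress)."""
    if config.reference_location:
        return config.reference_location
    return str(compute_gdd(weather).idxmin())


def estimate_hsi_tables(fb_adj: pd.DataFrame, traits, reference: str,
                        aem_method: str = "reml",
                        condition_tests: dict | None = None):
    """AEM tables, location means and the HSI matrix for ``traits``.

    Location means come from the combined condition model when its fits
    are supplied, otherwise from genotype-mean aggregation.
    """
    aem_by_trait, locmeans = {}, {}
    for t in traits:
        aem_by_trait[t] = aem_location_table(fb_adj, t, method=aem_method)
        if condition_tests and t in condition_tests:
            locmeans[t] = condition_tests[t].location_means
        else:
            locmeans[t] = location_means_fast(fb_adj, t, method="mean")
    hsi_matrix, details = hsi_mod.hsi_table(aem_by_trait, locmeans, reference)
    return hsi_matrix, details, aem_by_trait, locmeans


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None,
                 data: SimulatedDataset | None = None,
                 aem_method: str = "reml",
                 qtl_traits: tuple[str, ...] | None = None) -> dict:
    """The full analysis on a (by default freshly simulated) dataset.

    Returns a dict with every stage product; writes TSV tables and a
    manifest when ``out_dir`` is given.
    """
    if data is None:
        data = simulate_dataset(config)
    fb = derive_traits(data.fieldbook)
    gdd = compute_gdd(data.weather)
    reference = reference_location(config, data.weather)

    traits = [t for t in config.traits if t in fb.columns]
    fb_adj, phat = adjust_fieldbook(fb, traits)

    cond_tests = {t: condition_effect_test(fb_adj, t, alpha=config.alpha)
                  for t in traits}
    heat_dependent = [t for t in HSI_TRAITS
                      if t in cond_tests and cond_tests[t].heat_dependent]

    hsi_matrix, hsi_details, aem_by_trait, locmeans = estimate_hsi_tables(
        fb_adj, heat_dependent, reference, aem_method=aem_method,
        condition_tests=cond_tests)
    if {"DY", "FF"}.issubset(hsi_matrix.columns):
        hsi_matrix["DYA"] = hsi_mod.adjust_hsi(hsi_matrix["DY"],
                                               hsi_matrix["FF"])
    pca = hsi_mod.hsi_pca(hsi_matrix[[t for t in HSI_TRAITS
                                      if t in hsi_matrix.columns]])
    correlations = hsi_mod.hsi_correlations(
        hsi_matrix[[t for t in HSI_TRAITS if t in hsi_matrix.columns]])

    herit = heritability_table(fb_adj, traits)

    geno_kept, removed_markers = filter_markers_qc(data.geno)
    gmap_kept = data.gmap[data.gmap["marker"].isin(geno_kept.markers)] \
        .reset_index(drop=True)
    scanner = QTLScanner(geno_kept, gmap_kept, step=config.scan_step_cm)

    phenos: dict[str, pd.Series] = {}
    for t in hsi_matrix.columns:
        phenos[f"HSI_{t}"] = hsi_matrix[t]
    for pc in pca.scores.columns:
        phenos[pc] = pca.scores[pc]
    if qtl_traits is not None:
        phenos = {k: v for k, v in phenos.items() if k in qtl_traits}

    rng = config.rng(1)
    scans: dict[str, QTLScanOutput] = {}
    for name, ph in phenos.items():
        ph = ph.reindex(scanner.geno.individuals).dropna()
        if len(ph) < scanner.geno.n_individuals:
            keep = [i in ph.index for i in scanner.geno.individuals]
            if sum(keep) < 50:
                continue
        scans[name] = scanner.map_trait(
            ph, name, n_perm=config.n_permutations, alpha=config.alpha,
            min_spacing=config.cofactor_spacing_cm, lod_drop=config.lod_drop,
            rng=rng)

    all_qtl = [q for s in scans.values() for q in s.qtls]
    projected = project_genes(data.genes, gmap_kept)
    hits, hotspots = colocate(projected, all_qtl)

    results = {
        "config": config, "data": data, "gdd": gdd, "reference": reference,
        "fb_adj": fb_adj, "subexperiment_effects": phat,
        "condition_tests": cond_tests, "heat_dependent": heat_dependent,
        "aem": aem_by_trait, "location_means": locmeans,
        "hsi": hsi_matrix, "hsi_details": hsi_details,
        "pca": pca, "correlations": correlations,
        "heritability": herit, "map_summary": map_summary(data.gmap),
        "removed_markers": removed_markers, "scans": scans,
        "qtl": all_qtl, "gene_hits": hits, "hotspots": hotspots,
    }
    if out_dir is not None:
        write_pipeline_results(results, out_dir)
    return results


def qtl_table(qtls: list) -> pd.DataFrame:
    """Tidy per-locus effects table (one row per locus x effect level)."""
    rows = []
    for q in qtls:
        base = {"trait": q.trait, "qtl": q.name, "chromosome": q.chromosome,
                "position_cm": q.position_cm, "ci_lo": q.ci[0],
                "ci_hi": q.ci[1], "F": q.peak_f, "lod": q.peak_lod,
                "r2": q.r2_single}
        if q.additive is not None:
            for _, r in q.additive.iterrows():
                rows.append({**base, "effect_type": "additive",
                             "level": r["parent"], "effect": r["effect"],
                             "se": r["se"], "annotation": r["letters"]})
        if q.dominance is not None:
            for _, r in q.dominance.iterrows():
                rows.append({**base, "effect_type": "dominance",
                             "level": str(r["population"]),
                             "effect": r["effect"], "se": r["se"],
                             "annotation": r["stars"]})
        if q.additive is None and q.dominance is None:
            rows.append({**base, "effect_type": "", "level": "",
                         "effect": np.nan, "se": np.nan, "annotation": ""})
    return pd.DataFrame(rows)


def write_pipeline_results(results: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    cond = pd.DataFrame([
        {"trait": t, "F": ct.f_statistic, "p": ct.p_value,
         "heat_dependent": ct.heat_dependent}
        for t, ct in results["condition_tests"].items()])
    locmeans = pd.DataFrame(results["location_means"]).rename_axis("location") \
        .reset_index()
    herit = results["heritability"]
    tables = {
        "gdd": results["gdd"].rename_axis("location").reset_index(),
        "condition_effects": cond,
        "location_means": locmeans,
        "hsi": results["hsi"].rename_axis("genotype").reset_index(),
        "pca_scores": results["pca"].scores.rename_axis("genotype").reset_index(),
        "pca_loadings": results["pca"].loadings.rename_axis("trait").reset_index(),
        "hsi_correlations": results["correlations"],
        "heritability_location": herit["per_location"].rename_axis("trait").reset_index(),
        "qtl": qtl_table(results["qtl"]),
        "gene_hits": results["gene_hits"],
        "hotspots": results["hotspots"],
        "removed_markers": results["removed_markers"],
    }
    profiles = []
    for name, s in results["scans"].items():
        p = s.profile.copy()
        p.insert(0, "trait", name)
        p["threshold"] = s.threshold
        profiles.append(p)
    if profiles:
        tables["lod_profiles"] = pd.concat(profiles, ignore_index=True)
    io.write_results(tables, out, config=results["config"],
                     manifest_extra={
                         "reference_location": results["reference"],
                         "heat_dependent": results["heat_dependent"],
                         "map_summary": results["map_summary"],
                         "pca_explained": results["pca"].explained.to_dict(),
                     })
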