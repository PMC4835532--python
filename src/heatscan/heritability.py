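"""Broad-sense heritability at three granularities.

Per location (entry-mean basis over E replications):

    H2_j = sigma2_g / (sigma2_g + sigma2_e / E)

and per condition x population, with U locations per condition:

    H2_cp = sigma2_g / (sigma2_g + sigma2_gl / U + sigma2_e / (U * E))

Variance components come from REML fits of the entry-mean models with the
genotype term random; population-specific components are obtained by
fitting the model on that population's individuals alone, which is
equivalent to a heterogeneous-variance genotype-within-population term
here because each population occupies its own subexperiment (no
population shares blocks with another).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mixed import (dummy_matrix, fit_mixed, nested_sum_zero_encode,
                    sum_zero_encode)


def h2_entry_mean(sigma2_g: float, sigma2_e: float, n_reps: int) -> float:
    """Per-location broad-sense heritability on an entry-mean basis."""
    denom = sigma2_g + sigma2_e / n_reps
    if denom <= 0:
        return float("nan")
    return sigma2_g / denom


def h2_condition(sigma2_g: float, sigma2_gl: float, sigma2_e: float,
                 n_locations: int, n_reps: int) -> float:
    """Across-location heritability within a condition (U locations,
    E replications per location)."""
    denom = sigma2_g + sigma2_gl / n_locations + sigma2_e / (n_locations * n_reps)
    if denom <= 0:
        return float("nan")
    return sigma2_g / denom


def _location_components(d: pd.DataFrame, trait: str) -> tuple[float, float]:
    """REML sigma2_g and sigma2_e from the per-location entry-mean model
    (fixed replication, random block and genotype)."""
    y = d[trait].to_numpy(dtype=float)
    Xr, rlev = sum_zero_encode(d["replication"])
    X = np.hstack([np.ones((len(d), 1)), Xr])
    names = ["mu"] + [f"R[{r}]" for r in rlev[:-1]]
    blk = d["replication"].astype(str) + "/" + d["subexperiment"].astype(str) \
        + "/" + d["block"].astype(str)
    fit = fit_mixed(y, X, names, {
        "genotype": dummy_matrix(d["genotype"]),
        "block": dummy_matrix(blk),
    })
    return fit.varcomps["genotype"], fit.varcomps["residual"]


def h2_location(fb_adj: pd.DataFrame, location: str, trait: str,
                by_population: bool = False):
    """H2 of one trait at one location, across or within populations.

    With ``by_population`` the model is fit on each population's
    individuals separately (standards excluded), giving the
    population-specific genotypic and error components.  Returns a float,
    or a dict population -> float.
    """
    d = fb_adj[(fb_adj["location"] == location)].dropna(subset=[trait])
    if d.empty:
        return {} if by_population else float("nan")
    n_reps = d["replication"].nunique()
    if not by_population:
        s2g, s2e = _location_components(d, trait)
        return h2_entry_mean(s2g, s2e, n_reps)
    out: dict[int, float] = {}
    for pop, grp in d[~d["is_standard"]].groupby("population"):
        if grp["genotype"].nunique() < 3:
            out[int(pop)] = float("nan")
            continue
        s2g, s2e = _location_components(grp, trait)
        out[int(pop)] = h2_entry_mean(s2g, s2e, grp["replication"].nunique())
    return out


def h2_condition_population(fb_adj: pd.DataFrame, condition: str,
                            population: int, trait: str) -> float:
    """H2 of one trait for one population across the locations of a
    condition, from random genotype, genotype x location and residual
    components (fixed location and replication-within-location)."""
    d = fb_adj[(fb_adj["condition"] == condition)
               & (fb_adj["population"] == population)].dropna(subset=[trait])
    if d.empty or d["genotype"].nunique() < 3:
        return float("nan")
    U = d["location"].nunique()
    E = d.groupby("location")["replication"].nunique().max()
    y = d[trait].to_numpy(dtype=float)
    Xl, llev = sum_zero_encode(d["location"])
    Xr, rlev = nested_sum_zero_encode(d["location"], d["replication"])
    X = np.hstack([np.ones((len(d), 1)), Xl, Xr])
    names = (["mu"] + [f"L[{l}]" for l in llev[:-1]]
             + [f"R[{r}]" for r in rlev])
    blk = (d["location"].astype(str) + "/" + d["replication"].astype(str)
           + "/" + d["subexperiment"].astype(str) + "/" + d["block"].astype(str))
    gl = d["genotype"].astype(str) + "@" + d["location"].astype(str)
    fit = fit_mixed(y, X, names, {
        "genotype": dummy_matrix(d["genotype"]),
        "gxl": dummy_matrix(gl),
        "block": dummy_matrix(blk),
    })
    return h2_condition(fit.varcomps["genotype"], fit.varcomps["gxl"],
                        fit.varcomps["residual"], U, E)


def heritability_table(fb_adj: pd.DataFrame, traits) -> dict[str, pd.DataFrame]:
    """The three heritability summaries: trait x location (across
    populations), trait x (location, population), and trait x
    (condition, population)."""
    locations = list(fb_adj["location"].unique())
    conditions = list(fb_adj["condition"].unique())
    pops = sorted(int(p) for p in fb_adj["population"].dropna().unique())

    per_loc = pd.DataFrame(index=list(traits), columns=locations, dtype=float)
    per_loc_pop = {}
    per_cond_pop = pd.DataFrame(
        index=list(traits),
        columns=pd.MultiIndex.from_product([conditions, pops]), dtype=float)
    for t in traits:
        if t not in fb_adj.columns:
            continue
        for loc in locations:
            per_loc.loc[t, loc] = h2_location(fb_adj, loc, t)
            for pop, h2 in h2_location(fb_adj, loc, t, by_population=True).items():
                per_loc_pop[(t, loc, pop)] = h2
        for cond in conditions:
            for pop in pops:
                per_cond_pop.loc[t, (cond, pop)] = h2_condition_population(
                    fb_adj, cond, pop, t)
    lp = pd.Series(per_loc_pop).rename_axis(["trait", "location", "population"])
    return {
        "per_location": per_loc,
        "per_location_population": lp.unstack(["location", "population"]),
        "per_condition_population": per_cond_pop,
    }
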