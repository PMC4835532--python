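"""Design adjustment and entry-mean models for the multi-location trial.

The cascade: (1) estimate subexperiment effects from the standards
(parental inbreds, replicated once per subexperiment) and subtract them
from every plot; (2) adjusted entry means (AEM) per genotype at each
location; (3) AEM per genotype across the locations of a condition;
(4) a combined model over all locations giving per-location means and a
Wald test of the standard-vs-heat condition effect.  Traits with a
significant condition effect are flagged heat-dependent.

Mixed models are fit by REML (:mod:`heatscan.mixed`); fixed effects use
sum-to-zero constraints so that subtracting estimated subexperiment
effects is well defined and marginal means are intercept + effect.
``method="mean"`` variants replace the REML entry means with plain
genotype means of the adjusted observations — exact for the balanced
layouts the generator produces and fast enough for Monte-Carlo loops.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .mixed import (MixedFit, dummy_matrix, fit_mixed, nested_sum_zero_encode,
                    sum_zero_encode, wald_f_test)

# ---------------------------------------------------------------------------
# Thermal time and trait derivations


def compute_gdd(weather: pd.DataFrame, t_base: float = 10.0) -> pd.Series:
    """Growing degree days per location: sum of max(0, (Tmax+Tmin)/2 - Tbase).

    Requires a gap-free daily series per location; missing days are a hard
    error listing the gaps.
    """
    out = {}
    for loc, grp in weather.groupby("location"):
        dates = pd.DatetimeIndex(grp["date"]).sort_values()
        full = pd.date_range(dates[0], dates[-1], freq="D")
        gaps = full.difference(dates)
        if len(gaps):
            raise ValueError(
                f"weather series for {loc!r} has {len(gaps)} missing days: "
                f"{[str(d.date()) for d in gaps[:5]]}...")
        daily = (grp["tmax"] + grp["tmin"]) / 2.0 - t_base
        out[loc] = float(daily.clip(lower=0.0).sum())
    return pd.Series(out, name="gdd")


def derive_traits(fb: pd.DataFrame) -> pd.DataFrame:
    """Add derived traits: ASI = FF - MF and DY = FY * (1 - GM/100) / 0.85
    (dry yield at 15 % grain moisture).  Missing inputs give missing
    outputs; GM >= 100 % is a hard error."""
    fb = fb.copy()
    if "GM" in fb.columns:
        if (fb["GM"].dropna() >= 100).any():
            raise ValueError("grain moisture >= 100 %")
    if {"FF", "MF"}.issubset(fb.columns):
        fb["ASI"] = fb["FF"] - fb["MF"]
    if {"FY", "GM"}.issubset(fb.columns):
        fb["DY"] = fb["FY"] * (1.0 - fb["GM"] / 100.0) / 0.85
    return fb


# ---------------------------------------------------------------------------
# Step 1: subexperiment effects from the standards


@dataclass
class StandardsFit:
    """Estimated subexperiment effects P_hat[(replication, subexperiment)]
    at one location for one trait, under a sum-to-zero constraint within
    each replication."""

    location: str
    trait: str
    effects: dict[tuple[int, int], float]
    fit: MixedFit | None


def fit_standards_model(fb: pd.DataFrame, location: str, trait: str) -> StandardsFit:
    """Mixed model on the standards: random standard and block effects,
    fixed replication and subexperiment-within-replication effects."""
    d = fb[(fb["location"] == location) & fb["is_standard"]].dropna(subset=[trait])
    reps = sorted(d["replication"].unique())
    subs = sorted(fb.loc[fb["location"] == location, "subexperiment"].unique())
    if d["genotype"].nunique() < 2 or len(reps) < 2:
        raise ValueError(
            f"need >=2 standards and >=2 replications at {location!r} for {trait!r}")

    y = d[trait].to_numpy(dtype=float)
    Xr, rep_levels = sum_zero_encode(d["replication"])
    cols = [np.ones((len(d), 1)), Xr]
    names = ["mu"] + [f"rep[{r}]" for r in rep_levels[:-1]]
    # subexperiment within replication, sum-to-zero within each replication
    sub_cols: list[tuple[int, int]] = []
    for r in reps:
        in_rep = (d["replication"] == r).to_numpy()
        present = sorted(d.loc[in_rep, "subexperiment"].unique())
        absent = [s for s in subs if s not in present]
        if absent:
            warnings.warn(
                f"subexperiments {absent} have no standard observations at "
                f"{location!r} (rep {r}); their effects are set to 0")
        k = len(present)
        X = np.zeros((len(d), k - 1))
        codes = d["subexperiment"].to_numpy()
        for j, s in enumerate(present[:-1]):
            X[in_rep & (codes == s), j] = 1.0
        X[in_rep & (codes == present[-1]), :] = -1.0
        cols.append(X)
        names += [f"subexp[{r},{s}]" for s in present[:-1]]
        sub_cols.append((r, present))

    Zs, slev = dummy_matrix(d["genotype"])
    blk = d["replication"].astype(str) + "/" + d["subexperiment"].astype(str) \
        + "/" + d["block"].astype(str)
    Zb, blev = dummy_matrix(blk)
    fit = fit_mixed(y, np.hstack(cols), names,
                    {"standard": (Zs, slev), "block": (Zb, blev)})

    effects: dict[tuple[int, int], float] = {}
    for r, present in sub_cols:
        coefs = np.array([fit.beta[names.index(f"subexp[{r},{s}]")]
                          for s in present[:-1]])
        full = np.concatenate([coefs, [-coefs.sum()]])
        for s, e in zip(present, full):
            effects[(r, s)] = float(e)
        for s in subs:
            effects.setdefault((r, s), 0.0)
    return StandardsFit(location=location, trait=trait, effects=effects, fit=fit)


def adjust_observations(fb: pd.DataFrame,
                        phat: dict[str, dict[str, dict[tuple[int, int], float]]]
                        ) -> pd.DataFrame:
    """Subtract estimated subexperiment effects from every plot.

    ``phat[trait][location][(replication, subexperiment)]`` comes from
    :func:`fit_standards_model`; standards are adjusted like everything
    else.  Plots without an estimate (effect 0) pass through unchanged.
    """
    fb = fb.copy()
    for trait, per_loc in phat.items():
        if trait not in fb.columns:
            continue
        shift = np.zeros(len(fb))
        for loc, eff in per_loc.items():
            sel = (fb["location"] == loc).to_numpy()
            keys = list(zip(fb.loc[sel, "replication"], fb.loc[sel, "subexperiment"]))
            shift[sel] = [eff.get(k, 0.0) for k in keys]
        fb[trait] = fb[trait] - shift
    return fb


def adjust_fieldbook(fb: pd.DataFrame, traits: list[str] | tuple[str, ...]
                     ) -> tuple[pd.DataFrame, dict]:
    """Run the standards model for every (trait, location) and return the
    adjusted field book plus the estimated effects."""
    phat: dict[str, dict[str, dict]] = {}
    for trait in traits:
        if trait not in fb.columns:
            continue
        phat[trait] = {}
        for loc in fb["location"].unique():
            phat[trait][loc] = fit_standards_model(fb, loc, trait).effects
    return adjust_observations(fb, phat), phat


# ---------------------------------------------------------------------------
# Steps 2-3: adjusted entry means


def aem_per_location(fb_adj: pd.DataFrame, location: str, trait: str,
                     method: str = "reml") -> pd.Series:
    """AEM per genotype at one location: fixed genotype and replication,
    random incomplete-block effects.  Genotypes never observed at the
    location are absent from the result."""
    d = fb_adj[fb_adj["location"] == location].dropna(subset=[trait])
    if d.empty:
        return pd.Series(dtype=float, name=trait)
    if method == "mean":
        return d.groupby("genotype")[trait].mean().rename(trait)
    y = d[trait].to_numpy(dtype=float)
    Xg, glev = sum_zero_encode(d["genotype"])
    Xr, rlev = sum_zero_encode(d["replication"])
    X = np.hstack([np.ones((len(d), 1)), Xg, Xr])
    names = (["mu"] + [f"G[{g}]" for g in glev[:-1]]
             + [f"R[{r}]" for r in rlev[:-1]])
    blk = d["replication"].astype(str) + "/" + d["subexperiment"].astype(str) \
        + "/" + d["block"].astype(str)
    Zb, blev = dummy_matrix(blk)
    fit = fit_mixed(y, X, names, {"block": (Zb, blev)})
    mu = fit.beta[0]
    g_eff = np.concatenate([fit.beta[1:len(glev)], [-fit.beta[1:len(glev)].sum()]])
    return pd.Series(mu + g_eff, index=glev, name=trait)


def aem_per_condition(fb_adj: pd.DataFrame, condition: str, trait: str,
                      method: str = "reml") -> pd.Series:
    """AEM per genotype across the locations sharing a condition: fixed
    genotype, location and replication-within-location, random blocks."""
    d = fb_adj[fb_adj["condition"] == condition].dropna(subset=[trait])
    if d.empty:
        return pd.Series(dtype=float, name=trait)
    if method == "mean":
        return d.groupby("genotype")[trait].mean().rename(trait)
    y = d[trait].to_numpy(dtype=float)
    Xg, glev = sum_zero_encode(d["genotype"])
    Xl, llev = sum_zero_encode(d["location"])
    Xr, rlev = nested_sum_zero_encode(d["location"], d["replication"])
    X = np.hstack([np.ones((len(d), 1)), Xg, Xl, Xr])
    names = (["mu"] + [f"G[{g}]" for g in glev[:-1]]
             + [f"L[{l}]" for l in llev[:-1]]
             + [f"R[{r}]" for r in rlev])
    blk = (d["location"].astype(str) + "/" + d["replication"].astype(str)
           + "/" + d["subexperiment"].astype(str) + "/" + d["block"].astype(str))
    Zb, blev = dummy_matrix(blk)
    fit = fit_mixed(y, X, names, {"block": (Zb, blev)})
    mu = fit.beta[0]
    g_eff = np.concatenate([fit.beta[1:len(glev)], [-fit.beta[1:len(glev)].sum()]])
    return pd.Series(mu + g_eff, index=glev, name=trait)


def aem_location_table(fb_adj: pd.DataFrame, trait: str,
                       method: str = "reml") -> pd.DataFrame:
    """Genotype x location AEM matrix for one trait."""
    cols = {}
    for loc in fb_adj["location"].unique():
        cols[loc] = aem_per_location(fb_adj, loc, trait, method=method)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Step 4: condition effect across all locations


@dataclass
class ConditionTest:
    trait: str
    location_means: pd.Series  # AEM of each location (L_cj)
    f_statistic: float
    p_value: float
    heat_dependent: bool
    fit: MixedFit | None


def condition_effect_test(fb_adj: pd.DataFrame, trait: str,
                          alpha: float = 0.05) -> ConditionTest:
    """Combined model over all locations with a fixed condition effect.

    Fixed: condition, location within condition.  Random: replication
    within location, block, genotype, genotype x location, condition x
    genotype.  The condition effect is Wald-F tested with a
    containment-style denominator df, (#conditions-1) x (#genotypes-1).
    """
    d = fb_adj.dropna(subset=[trait])
    conds = sorted(d["condition"].unique())
    if len(conds) < 2:
        raise ValueError("both conditions must be present")
    y = d[trait].to_numpy(dtype=float)
    Xc, clev = sum_zero_encode(d["condition"])
    cols = [np.ones((len(d), 1)), Xc]
    names = ["mu"] + [f"C[{c}]" for c in clev[:-1]]
    # locations nested in condition, sum-to-zero within condition
    loc_of = d.groupby("location")["condition"].first()
    loc_cols: dict[str, np.ndarray] = {}
    for c in conds:
        locs = sorted(loc_of[loc_of == c].index)
        X = np.zeros((len(d), len(locs) - 1))
        lvals = d["location"].to_numpy()
        for j, l in enumerate(locs[:-1]):
            X[lvals == l, j] = 1.0
        X[lvals == locs[-1], :] = -1.0
        cols.append(X)
        names += [f"L[{l}]" for l in locs[:-1]]
        loc_cols[c] = locs
    X = np.hstack(cols)

    rep = d["location"].astype(str) + "/r" + d["replication"].astype(str)
    blk = (d["location"].astype(str) + "/" + d["replication"].astype(str)
           + "/" + d["subexperiment"].astype(str) + "/" + d["block"].astype(str))
    gl = d["genotype"].astype(str) + "@" + d["location"].astype(str)
    cg = d["condition"].astype(str) + "@" + d["genotype"].astype(str)
    terms = {
        "rep": dummy_matrix(rep),
        "block": dummy_matrix(blk),
        "genotype": dummy_matrix(d["genotype"]),
        "gxl": dummy_matrix(gl),
        "cxg": dummy_matrix(cg),
    }
    try:
        fit = fit_mixed(y, X, names, terms, compute_cov=True)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"condition-effect model for {trait!r} is singular ({err}); "
            "check that each condition has >=2 locations with data"
        ) from err

    cond_cols = np.array([names.index(f"C[{c}]") for c in clev[:-1]])
    n_geno = d["genotype"].nunique()
    ddf = (len(conds) - 1) * (n_geno - 1)
    F, p = wald_f_test(fit, cond_cols, ddf)

    # marginal mean of each location: mu + C_c + L_cj
    c_full = np.concatenate([fit.beta[cond_cols], [-fit.beta[cond_cols].sum()]])
    c_eff = dict(zip(clev, c_full))
    loc_means = {}
    for c in conds:
        locs = loc_cols[c]
        coefs = np.array([fit.beta[names.index(f"L[{l}]")] for l in locs[:-1]])
        full = np.concatenate([coefs, [-coefs.sum()]])
        for l, e in zip(locs, full):
            loc_means[l] = float(fit.beta[0] + c_eff[c] + e)
    return ConditionTest(trait=trait, location_means=pd.Series(loc_means),
                         f_statistic=F, p_value=p,
                         heat_dependent=bool(p < alpha), fit=fit)


def location_means_fast(fb_adj: pd.DataFrame, trait: str,
                        method: str = "mean") -> pd.Series:
    """Per-location means of the genotype AEMs — the light-weight stand-in
    for the combined-model location means in Monte-Carlo loops."""
    aem = aem_location_table(fb_adj, trait, method=method)
    return aem.mean(axis=0)
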