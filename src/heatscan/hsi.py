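"""Heat-susceptibility index (HSI) from multi-location ratios and
Finlay-Wilkinson stability regression.

For each heat-dependent trait, a genotype's entry means are first divided
by its entry mean at the reference location (the one with least heat
stress), removing its growth potential; the all-genotype location means
are scaled the same way.  The slope of the per-genotype ratios regressed
on the location-mean ratios is the HSI: 1 means average susceptibility,
>1 more susceptible than average.  A flowering-adjusted yield index
(HSI_DYA) is the residual of HSI_DY regressed on HSI_FF; the first two
principal components of the five standardized HSI columns serve as
multi-trait measures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MIN_LOCATIONS = 3  # a 2-point slope is noise; genotypes below get no HSI


def location_ratios(location_means: pd.Series, reference: str) -> pd.Series:
    """Location means scaled by the reference location (r_j); the
    reference itself maps to exactly 1."""
    if reference not in location_means.index:
        raise KeyError(f"reference location {reference!r} has no mean")
    ref = location_means[reference]
    if ref == 0:
        raise ZeroDivisionError(f"mean at reference location {reference!r} is 0")
    return location_means / ref


def genotype_ratios(aem: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Per-genotype entry means scaled by the genotype's own value at the
    reference location (r_ij); missing wherever either term is missing,
    all-missing where the reference value is 0 or absent."""
    if reference not in aem.columns:
        raise KeyError(f"reference location {reference!r} not in AEM table")
    ref = aem[reference].copy()
    ref[ref == 0] = np.nan
    return aem.div(ref, axis=0)


@dataclass
class HSIResult:
    trait: str
    table: pd.DataFrame  # genotype x [hsi, intercept, n_locations, reason]
    r_j: pd.Series

    @property
    def hsi(self) -> pd.Series:
        return self.table["hsi"]


def compute_hsi(r_ij: pd.DataFrame, r_j: pd.Series, trait: str = "") -> HSIResult:
    """Per-genotype OLS of the trait ratios on the location ratios.

    Genotypes with fewer than three usable locations, or facing ratio
    vectors without variance, get a missing HSI with a reason code.
    """
    r_j = r_j.reindex(r_ij.columns)
    X = r_ij.to_numpy(dtype=float)
    xv = r_j.to_numpy(dtype=float)
    n_g = X.shape[0]
    slope = np.full(n_g, np.nan)
    intercept = np.full(n_g, np.nan)
    n_used = np.zeros(n_g, dtype=int)
    reason = np.array([""] * n_g, dtype=object)
    for i in range(n_g):
        ok = np.isfinite(X[i]) & np.isfinite(xv)
        n_used[i] = int(ok.sum())
        if n_used[i] < MIN_LOCATIONS:
            reason[i] = "fewer than 3 locations"
            continue
        x = xv[ok]
        if np.ptp(x) == 0:
            reason[i] = "no variance in location ratios"
            continue
        xc = x - x.mean()
        yc = X[i, ok] - X[i, ok].mean()
        b = float(xc @ yc / (xc @ xc))
        slope[i] = b
        intercept[i] = float(X[i, ok].mean() - b * x.mean())
    table = pd.DataFrame({"hsi": slope, "intercept": intercept,
                          "n_locations": n_used, "reason": reason},
                         index=r_ij.index)
    return HSIResult(trait=trait, table=table, r_j=r_j)


def adjust_hsi(hsi_dy: pd.Series, hsi_ff: pd.Series) -> pd.Series:
    """Flowering-adjusted yield susceptibility: residuals of HSI_DY
    regressed (with intercept) on HSI_FF over the common genotypes."""
    common = hsi_dy.dropna().index.intersection(hsi_ff.dropna().index)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} genotypes share both indices")
    x = hsi_ff[common].to_numpy(dtype=float)
    y = hsi_dy[common].to_numpy(dtype=float)
    xc = x - x.mean()
    b = float(xc @ (y - y.mean()) / (xc @ xc))
    resid = y - (y.mean() + b * xc)
    return pd.Series(resid, index=common, name="HSI_DYA")


@dataclass
class PCAResult:
    scores: pd.DataFrame      # genotype x [PC1, PC2]
    loadings: pd.DataFrame    # trait x [PC1, PC2]
    explained: pd.Series      # fraction of total variance per PC


def hsi_pca(hsi_matrix: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """PCA of the standardized HSI matrix (complete cases).

    Columns are centered and scaled to unit variance (the indices of
    different traits are incommensurate).  Sign convention: within each
    component, the largest-|loading| trait gets a positive loading.
    """
    complete = hsi_matrix.dropna()
    if len(complete) < max(5, hsi_matrix.shape[1]):
        raise ValueError(
            f"only {len(complete)} complete genotypes for PCA; need >=5")
    Z = (complete - complete.mean()) / complete.std(ddof=1)
    U, s, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    var = s**2 / (len(complete) - 1)
    explained = var / hsi_matrix.shape[1]
    signs = np.sign(Vt[np.arange(len(s)), np.abs(Vt).argmax(axis=1)])
    signs[signs == 0] = 1.0
    Vt = Vt * signs[:, None]
    scores = (Z.to_numpy() @ Vt.T)[:, :n_components]
    return PCAResult(
        scores=pd.DataFrame(scores, index=complete.index,
                            columns=[f"PC{k+1}" for k in range(n_components)]),
        loadings=pd.DataFrame(Vt[:n_components].T, index=hsi_matrix.columns,
                              columns=[f"PC{k+1}" for k in range(n_components)]),
        explained=pd.Series(explained[:n_components],
                            index=[f"PC{k+1}" for k in range(n_components)]),
    )


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def hsi_correlations(hsi_matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations between the indices, with two-sided
    p-values and star codes; pairs with <3 complete cases or a constant
    column are undefined."""
    cols = list(hsi_matrix.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            pair = hsi_matrix[[a, b]].dropna()
            if len(pair) < 3 or pair[a].nunique() == 1 or pair[b].nunique() == 1:
                rows.append({"trait_a": a, "trait_b": b, "r": np.nan,
                             "p": np.nan, "n": len(pair), "stars": ""})
                continue
            r, p = stats.pearsonr(pair[a], pair[b])
            rows.append({"trait_a": a, "trait_b": b, "r": float(r),
                         "p": float(p), "n": len(pair),
                         "stars": significance_stars(p)})
    return pd.DataFrame(rows)


def hsi_table(aem_by_trait: dict[str, pd.DataFrame],
              location_means_by_trait: dict[str, pd.Series],
              reference: str) -> tuple[pd.DataFrame, dict[str, HSIResult]]:
    """HSI for every supplied trait; returns the genotype x trait slope
    matrix and the per-trait detail tables."""
    details: dict[str, HSIResult] = {}
    cols = {}
    for trait, aem in aem_by_trait.items():
        r_j = location_ratios(location_means_by_trait[trait], reference)
        r_ij = genotype_ratios(aem, reference)
        res = compute_hsi(r_ij, r_j, trait=trait)
        details[trait] = res
        cols[trait] = res.hsi
    return pd.DataFrame(cols), details
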