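"""Connected multi-population composite interval mapping.

The scan regresses a susceptibility index (or PC score) on expected
parental-allele doses at each grid position: eight additive parental
effects shared across the six populations ("connected" through the
common parents), one dominance coefficient per biparental population
(active where ancestry is heterozygous), plus population intercepts and
marker cofactors.  The position test is a model-comparison F (full vs
cofactors-only); LOD = (n/2) log10(RSS_reduced/RSS_full).

Genome-wide F thresholds come from within-population phenotype
permutations; cofactors are chosen by forward selection at 90 % of the
threshold with a minimum spacing; detection iterates scan / peak /
cofactor refresh until stable; support intervals are 1.5-LOD drops;
effects, their Tukey letter groups (additive) and normal-test stars
(dominance) come from a simultaneous fit over all detected loci.

Identifiability: the crossing scheme splits the eight parents into
connected components (two pairwise-disjoint sets of four here); additive
effects are encoded sum-to-zero within each component, which makes the
reported effects unique in the presence of population intercepts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import CrossDesign, GenotypeMatrix
from .genoprob import AncestryProbabilities, ancestry_probabilities
from .hsi import significance_stars

# ---------------------------------------------------------------------------
# Marker quality control


def filter_markers_qc(geno: GenotypeMatrix, alpha: float = 0.001
                      ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove markers whose within-population allele frequencies deviate
    from the expected 1:1 (chi-square goodness of fit, P < alpha in any
    population), and markers monomorphic in every population."""
    removed = []
    keep = []
    for j, marker in enumerate(geno.markers):
        col = geno.codes[:, j]
        worst = None
        poly_anywhere = False
        for pop in geno.cross_design.populations:
            c = col[(geno.population == pop)]
            c = c[c >= 0]
            if len(c) == 0:
                continue
            n_b = int(c.sum())
            n_a = int(2 * len(c) - n_b)
            if n_a and n_b:
                poly_anywhere = True
            total = n_a + n_b
            chi2 = (n_a - n_b) ** 2 / total
            p = float(stats.chi2.sf(chi2, df=1))
            if p < alpha and (worst is None or p < worst[2]):
                worst = (pop, chi2, p)
        if not poly_anywhere:
            removed.append({"marker": marker, "population": pd.NA,
                            "chi2": np.nan, "p": np.nan,
                            "reason": "monomorphic in all populations"})
        elif worst is not None:
            removed.append({"marker": marker, "population": worst[0],
                            "chi2": worst[1], "p": worst[2],
                            "reason": "segregation distortion"})
        else:
            keep.append(marker)
    removed_df = pd.DataFrame(removed, columns=["marker", "population",
                                                "chi2", "p", "reason"])
    return geno.subset_markers(keep), removed_df


# ---------------------------------------------------------------------------
# Design construction


def crossing_components(design: CrossDesign) -> list[list[str]]:
    """Connected components of the parent graph (parents joined when they
    share a population)."""
    adj: dict[str, set[str]] = {p: set() for p in design.all_parents}
    for a, b in design.parents.values():
        adj[a].add(b)
        adj[b].add(a)
    seen: set[str] = set()
    comps = []
    for p in design.all_parents:
        if p in seen:
            continue
        stack, comp = [p], []
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            comp.append(u)
            stack.extend(adj[u] - seen)
        comps.append(sorted(comp))
    return comps


@dataclass
class ScanDesign:
    """Phenotype-independent design blocks at every scan position.

    ``blocks[i]`` is (n_individuals, n_effect_columns): additive
    contrasts (sum-to-zero within each crossing component) followed by
    one dominance column per population.
    """

    positions: pd.DataFrame
    blocks: list[np.ndarray]
    pop_dummies: np.ndarray
    parents: list[str]
    components: list[list[str]]
    populations: list[int]
    expand: np.ndarray  # (n_parents, n_additive_cols) contrast -> effects
    column_names: list[str]

    @property
    def n_additive(self) -> int:
        return self.expand.shape[1]


def build_scan_design(ap: AncestryProbabilities, design: CrossDesign) -> ScanDesign:
    parents = design.all_parents
    comps = crossing_components(design)
    pops = design.populations
    n, P = ap.probs.shape[0], ap.n_positions
    dose_b, het = ap.dose_design()

    # per-parent expected allele dose at every position
    D = np.zeros((len(parents), n, P))
    pidx = {p: k for k, p in enumerate(parents)}
    for pop in pops:
        a, b = design.parents_of(pop)
        sel = ap.population == pop
        D[pidx[a], sel, :] += 2.0 - dose_b[sel, :]
        D[pidx[b], sel, :] += dose_b[sel, :]

    # sum-to-zero-within-component contrasts
    contrast_pairs: list[tuple[str, str]] = []
    for comp in comps:
        ref = comp[-1]
        contrast_pairs += [(p, ref) for p in comp[:-1]]
    expand = np.zeros((len(parents), len(contrast_pairs)))
    for j, (p, ref) in enumerate(contrast_pairs):
        expand[pidx[p], j] = 1.0
        expand[pidx[ref], j] = -1.0

    blocks = []
    for i in range(P):
        add = np.stack([D[pidx[p], :, i] - D[pidx[ref], :, i]
                        for p, ref in contrast_pairs], axis=1)
        dom = np.zeros((n, len(pops)))
        for k, pop in enumerate(pops):
            sel = ap.population == pop
            dom[sel, k] = het[sel, i]
        blocks.append(np.hstack([add, dom]))

    pop_dummies = np.zeros((n, len(pops)))
    for k, pop in enumerate(pops):
        pop_dummies[ap.population == pop, k] = 1.0

    names = [f"add[{p}-{ref}]" for p, ref in contrast_pairs] \
        + [f"dom[{pop}]" for pop in pops]
    return ScanDesign(positions=ap.positions.copy(), blocks=blocks,
                      pop_dummies=pop_dummies, parents=parents,
                      components=comps, populations=list(pops),
                      expand=expand, column_names=names)


# ---------------------------------------------------------------------------
# Scanning


@dataclass
class Cofactor:
    chromosome: int
    cm: float
    block: np.ndarray

    def excludes(self, chrom: int, cm: float, spacing: float) -> bool:
        return self.chromosome == chrom and abs(self.cm - cm) < spacing


def _fit_rss(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if res.size:
        return float(res[0]), int(rank)
    r = y - X @ beta
    return float(r @ r), int(rank)


def scan(y: np.ndarray, sd: ScanDesign,
         cofactors: list[Cofactor] | None = None,
         min_spacing: float = 10.0,
         chromosomes: list[int] | None = None) -> pd.DataFrame:
    """F and LOD profile over the grid, excluding any cofactor within
    ``min_spacing`` cM of the tested position."""
    cofactors = cofactors or []
    pos = sd.positions
    rows = []
    n = len(y)
    rss_cache: dict[frozenset, tuple[float, int]] = {}
    for i in range(len(pos)):
        chrom, cm = int(pos.iloc[i]["chromosome"]), float(pos.iloc[i]["cm"])
        if chromosomes is not None and chrom not in chromosomes:
            continue
        sel = frozenset(k for k, c in enumerate(cofactors)
                        if not c.excludes(chrom, cm, min_spacing))
        if sel not in rss_cache:
            X0 = np.hstack([sd.pop_dummies] + [cofactors[k].block for k in sorted(sel)]) \
                if sel else sd.pop_dummies
            rss0, rank0 = _fit_rss(y, X0)
            rss_cache[sel] = (rss0, rank0, X0)
        rss0, rank0, X0 = rss_cache[sel]
        X1 = np.hstack([X0, sd.blocks[i]])
        rss1, rank1 = _fit_rss(y, X1)
        q = max(rank1 - rank0, 1)
        if rss1 <= 0:
            F, lod = np.inf, np.inf
        else:
            F = ((rss0 - rss1) / q) / (rss1 / (n - rank1))
            lod = 0.5 * n * np.log10(rss0 / rss1)
        rows.append({"chromosome": chrom, "cm": cm, "F": F, "lod": lod, "df": q})
    return pd.DataFrame(rows)


def _demean_within(y: np.ndarray, pop: np.ndarray) -> np.ndarray:
    out = np.asarray(y, dtype=float).copy()
    for p in np.unique(pop):
        sel = pop == p
        out[sel] -= out[sel].mean()
    return out


def permutation_threshold(y: np.ndarray, sd: ScanDesign, pop: np.ndarray,
                          n_perm: int = 1000, alpha: float = 0.05,
                          rng: np.random.Generator | None = None
                          ) -> dict:
    """Genome-wide F threshold from within-population permutations.

    The phenotype is permuted inside each population (population mean
    differences are structure, not QTL signal); each permutation records
    the genome-wide maximum F of a cofactor-free scan, and the threshold
    is the empirical (1 - alpha) quantile of those maxima.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; thresholds will be noisy")
    y = np.asarray(y, dtype=float)
    n = len(y)
    y0 = _demean_within(y, pop)

    # orthonormal bases of the within-population-centered position blocks
    Ws, qs = [], []
    for B in sd.blocks:
        Bc = np.column_stack([_demean_within(B[:, j], pop)
                              for j in range(B.shape[1])])
        U, s, _ = np.linalg.svd(Bc, full_matrices=False)
        r = int((s > s[0] * 1e-9).sum()) if s.size and s[0] > 0 else 0
        Ws.append(U[:, :r])
        qs.append(r)
    Wall = np.hstack(Ws) if Ws else np.zeros((n, 0))
    qarr = np.array(qs)
    starts = np.concatenate([[0], np.cumsum(qarr)])

    Y = np.empty((n, n_perm))
    for t in range(n_perm):
        yp = y0.copy()
        for p in np.unique(pop):
            sel = np.flatnonzero(pop == p)
            yp[sel] = y0[sel[rng.permutation(len(sel))]]
        Y[:, t] = yp

    rss_r = (y0 ** 2).sum()
    n_pops = len(np.unique(pop))

    def genome_max_f(Y: np.ndarray) -> np.ndarray:
        proj2 = (Wall.T @ Y) ** 2
        Fmat = np.zeros((len(sd.blocks), Y.shape[1]))
        for i in range(len(sd.blocks)):
            if qarr[i] == 0:
                continue
            expl = proj2[starts[i]:starts[i + 1]].sum(axis=0)
            dfe = n - n_pops - qarr[i]
            Fmat[i] = (expl / qarr[i]) / np.maximum(rss_r - expl, 1e-300) * dfe
        return Fmat.max(axis=0)

    max_f = genome_max_f(Y)
    threshold = float(np.quantile(max_f, 1.0 - alpha))
    observed = float(genome_max_f(y0[:, None])[0])
    return {"threshold": threshold, "max_f": max_f, "alpha": alpha,
            "n_perm": n_perm, "observed_max_f": observed}


# ---------------------------------------------------------------------------
# Cofactor selection and the iterative detection loop


def select_cofactors(y: np.ndarray, sd_markers: ScanDesign, threshold: float,
                     min_spacing: float = 10.0) -> list[Cofactor]:
    """Greedy forward selection of marker cofactors.

    Repeatedly adds the marker with the highest partial F above
    ``threshold`` (90 % of the detection threshold upstream), skipping
    markers within ``min_spacing`` cM of one already selected; ties break
    to the lowest chromosome, then position.
    """
    selected: list[Cofactor] = []
    while True:
        prof = scan(y, sd_markers, cofactors=selected, min_spacing=0.0)
        pos = sd_markers.positions
        blocked = np.zeros(len(prof), dtype=bool)
        for c in selected:
            blocked |= ((prof["chromosome"] == c.chromosome)
                        & ((prof["cm"] - c.cm).abs() < min_spacing)).to_numpy()
        cand = prof[~blocked & (prof["F"] > threshold)]
        if cand.empty:
            return selected
        cand = cand.sort_values(["F", "chromosome", "cm"],
                                ascending=[False, True, True])
        best = cand.iloc[0]
        i = int(prof.index[(prof["chromosome"] == best["chromosome"])
                           & (prof["cm"] == best["cm"])][0])
        selected.append(Cofactor(int(best["chromosome"]), float(best["cm"]),
                                 sd_markers.blocks[i]))


def _find_peaks(profile: pd.DataFrame, threshold: float,
                min_spacing: float) -> list[tuple[int, float]]:
    """Local maxima of the F profile above the threshold, greedily thinned
    so no two declared peaks lie within ``min_spacing`` of each other
    (the higher one wins)."""
    peaks: list[tuple[int, float, float]] = []
    for chrom, grp in profile.groupby("chromosome"):
        grp = grp.sort_values("cm").reset_index(drop=True)
        f = grp["F"].to_numpy(dtype=float)
        for i in range(len(grp)):
            if f[i] < threshold:
                continue
            if (i > 0 and f[i - 1] > f[i]) or (i < len(f) - 1 and f[i + 1] > f[i]):
                continue
            peaks.append((int(chrom), float(grp.loc[i, "cm"]), f[i]))
    peaks.sort(key=lambda t: -t[2])
    final: list[tuple[int, float, float]] = []
    for c, cm, fv in peaks:
        if all(c != c0 or abs(cm - cm0) > min_spacing for c0, cm0, _ in final):
            final.append((c, cm, fv))
    return sorted((c, cm) for c, cm, _ in final)


def _same_peaks(a: list[tuple[int, float]], b: list[tuple[int, float]],
                tol: float) -> bool:
    """Peak sets count as equal when they pair off on the same
    chromosomes within ``tol`` cM (peaks drifting inside their own
    spacing window are the same locus)."""
    if len(a) != len(b):
        return False
    return all(ca == cb and abs(pa - pb) <= tol
               for (ca, pa), (cb, pb) in zip(sorted(a), sorted(b)))


def lod_drop_ci(profile: pd.DataFrame, peak_cm: float,
                drop: float = 1.5) -> tuple[float, float]:
    """Support interval: outermost positions around the peak where LOD
    stays within ``drop`` units of the peak LOD, linearly interpolated
    between grid points and clipped at the chromosome ends."""
    prof = profile.sort_values("cm").reset_index(drop=True)
    cms = prof["cm"].to_numpy(dtype=float)
    lods = prof["lod"].to_numpy(dtype=float)
    i_peak = int(np.argmin(np.abs(cms - peak_cm)))
    cut = lods[i_peak] - drop

    lo = cms[0]
    for i in range(i_peak, 0, -1):
        if lods[i - 1] < cut:
            frac = (lods[i] - cut) / (lods[i] - lods[i - 1])
            lo = cms[i] - frac * (cms[i] - cms[i - 1])
            break
    hi = cms[-1]
    for i in range(i_peak, len(cms) - 1):
        if lods[i + 1] < cut:
            frac = (lods[i] - cut) / (lods[i] - lods[i + 1])
            hi = cms[i] + frac * (cms[i + 1] - cms[i])
            break
    return float(lo), float(hi)


@dataclass
class QTLRecord:
    trait: str
    name: str
    chromosome: int
    position_cm: float
    peak_f: float
    peak_lod: float
    ci: tuple[float, float]
    r2_single: float = np.nan
    additive: pd.DataFrame | None = None   # parent, effect, se, letters
    dominance: pd.DataFrame | None = None  # population, effect, se, p, stars


@dataclass
class QTLScanOutput:
    trait: str
    qtls: list[QTLRecord]
    profile: pd.DataFrame
    threshold: float
    r2_simultaneous: float = np.nan
    n_iterations: int = 0
    converged: bool = True
    cofactors: list[Cofactor] = field(default_factory=list)


def iqtlm(y: np.ndarray, sd_grid: ScanDesign, sd_markers: ScanDesign,
          threshold: float, trait: str = "", min_spacing: float = 10.0,
          lod_drop: float = 1.5, max_iter: int = 10,
          alpha: float = 0.05) -> QTLScanOutput:
    """Iterative composite interval mapping across connected populations.

    Iterates cofactor selection, windowed scanning and peak declaration
    until the declared peak set stabilizes; then re-derives each locus'
    support interval from a scan conditioned on the *other* loci only,
    and fits all loci simultaneously for effects and explained variance.
    """
    y = np.asarray(y, dtype=float)
    cof = select_cofactors(y, sd_markers, 0.9 * threshold, min_spacing)
    history: list[list[tuple[int, float]]] = []
    profile = scan(y, sd_grid, cofactors=cof, min_spacing=min_spacing)
    peaks = _find_peaks(profile, threshold, min_spacing)
    n_iter, converged = 1, True
    while True:
        history.append(peaks)
        if not peaks:
            break
        if n_iter >= max_iter:
            warnings.warn(f"{trait}: peak set not stable after {max_iter} "
                          "iterations; keeping last")
            converged = False
            break
        cof = [_cofactor_at(sd_grid, c, cm) for c, cm in peaks]
        profile = scan(y, sd_grid, cofactors=cof, min_spacing=min_spacing)
        new_peaks = _find_peaks(profile, threshold, min_spacing)
        n_iter += 1
        if _same_peaks(new_peaks, peaks, min_spacing):
            peaks = new_peaks
            break
        if any(_same_peaks(new_peaks, h, min_spacing) for h in history[:-1]):
            warnings.warn(f"{trait}: peak set oscillates; keeping last iteration")
            peaks = new_peaks
            converged = False
            break
        peaks = new_peaks

    records = []
    for chrom, cm in peaks:
        others = [_cofactor_at(sd_grid, c2, cm2) for c2, cm2 in peaks
                  if (c2, cm2) != (chrom, cm)]
        prof_c = scan(y, sd_grid, cofactors=others, min_spacing=min_spacing,
                      chromosomes=[chrom])
        row = prof_c.iloc[(prof_c["cm"] - cm).abs().argmin()]
        ci = lod_drop_ci(prof_c, cm, drop=lod_drop)
        records.append(QTLRecord(
            trait=trait, name=f"Q_{trait}_{len(records) + 1}",
            chromosome=chrom, position_cm=cm,
            peak_f=float(row["F"]), peak_lod=float(row["lod"]), ci=ci))

    out = QTLScanOutput(trait=trait, qtls=records, profile=profile,
                        threshold=threshold, n_iterations=n_iter,
                        converged=converged, cofactors=cof)
    if records:
        fit = simultaneous_fit(y, sd_grid, [(q.chromosome, q.position_cm)
                                            for q in records])
        out.r2_simultaneous = fit["r2_total"]
        for q, r2, add, dom in zip(records, fit["r2_single"],
                                   fit["additive"], fit["dominance"]):
            q.r2_single = r2
            q.additive, q.dominance = posthoc_tests(add, dom, fit["ddf"],
                                                    alpha=alpha)
    return out


def _cofactor_at(sd: ScanDesign, chrom: int, cm: float) -> Cofactor:
    pos = sd.positions
    i = int(((pos["chromosome"] - chrom).abs() * 1e6
             + (pos["cm"] - cm).abs()).idxmin())
    return Cofactor(chrom, float(pos.iloc[i]["cm"]), sd.blocks[i])


# ---------------------------------------------------------------------------
# Simultaneous fit and post-hoc effect tests


def simultaneous_fit(y: np.ndarray, sd: ScanDesign,
                     qtl_positions: list[tuple[int, float]]) -> dict:
    """Joint linear model with all detected loci.

    Returns total and per-locus explained variance (sequential drop,
    relative to the population-intercept baseline) plus per-locus effect
    frames with estimates, standard errors and covariance blocks.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    idxs = []
    pos = sd.positions
    for chrom, cm in qtl_positions:
        i = int(((pos["chromosome"] - chrom).abs() * 1e6
                 + (pos["cm"] - cm).abs()).idxmin())
        idxs.append(i)
    blocks = [sd.blocks[i] for i in idxs]
    nb = blocks[0].shape[1] if blocks else 0
    X = np.hstack([sd.pop_dummies] + blocks)
    beta, rss, rank = _fit_with_pinv(y, X)
    rss_base, _ = _fit_rss(y, sd.pop_dummies)
    r2_total = (rss_base - rss) / rss_base if rss_base > 0 else np.nan

    r2_single = []
    for k in range(len(blocks)):
        Xk = np.hstack([sd.pop_dummies] + [b for j, b in enumerate(blocks) if j != k])
        rss_k, _ = _fit_rss(y, Xk)
        r2_single.append((rss_k - rss) / rss_base if rss_base > 0 else np.nan)

    ddf = max(n - rank, 1)
    sigma2 = rss / ddf
    cov = sigma2 * np.linalg.pinv(X.T @ X)

    p0 = sd.pop_dummies.shape[1]
    n_add = sd.n_additive
    additive, dominance = [], []
    for k in range(len(blocks)):
        a0 = p0 + k * nb
        ca = slice(a0, a0 + n_add)
        cd = slice(a0 + n_add, a0 + nb)
        a_con = beta[ca]
        cov_con = cov[ca, :][:, ca]
        eff = sd.expand @ a_con
        cov_eff = sd.expand @ cov_con @ sd.expand.T
        additive.append({"parents": sd.parents, "effect": eff,
                         "cov": cov_eff})
        d = beta[cd]
        cov_d = cov[cd, :][:, cd]
        dominance.append({"populations": sd.populations, "effect": d,
                          "se": np.sqrt(np.maximum(np.diag(cov_d), 0.0))})
    return {"r2_total": float(r2_total), "r2_single": r2_single,
            "additive": additive, "dominance": dominance,
            "ddf": ddf, "rss": rss, "beta": beta}


def _fit_with_pinv(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, int]:
    beta, res, rank, sv = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return beta, float(r @ r), int(rank)


def posthoc_tests(additive: dict, dominance: dict, ddf: int,
                  alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A-posteriori effect tests for one locus.

    Dominance: two-sided normal test of each population's coefficient.
    Additive: all pairwise parent comparisons against the studentized
    range (Tukey), summarized as a compact letter display — parents
    sharing a letter are not significantly different.
    """
    eff = np.asarray(additive["effect"], dtype=float)
    cov = np.asarray(additive["cov"], dtype=float)
    parents = list(additive["parents"])
    k = len(parents)
    sig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            var_d = cov[i, i] + cov[j, j] - 2 * cov[i, j]
            if var_d <= 0:
                continue
            q = abs(eff[i] - eff[j]) / np.sqrt(var_d / 2.0)
            p = float(stats.studentized_range.sf(q, k, ddf))
            sig[i, j] = sig[j, i] = p < alpha
    letters = compact_letter_display(parents, sig)
    add_df = pd.DataFrame({
        "parent": parents, "effect": eff,
        "se": np.sqrt(np.maximum(np.diag(cov), 0.0)),
        "letters": [letters[p] for p in parents],
    })

    d = np.asarray(dominance["effect"], dtype=float)
    se = np.asarray(dominance["se"], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, d / se, np.nan)
    p = 2.0 * stats.norm.sf(np.abs(z))
    dom_df = pd.DataFrame({
        "population": dominance["populations"], "effect": d, "se": se,
        "z": z, "p": p,
        "stars": [significance_stars(v) if np.isfinite(v) else "" for v in p],
    })
    return add_df, dom_df


def compact_letter_display(names: list, significant: np.ndarray) -> dict:
    """Insert-and-absorb letter assignment: every non-significant pair
    shares at least one letter, no significant pair shares any."""
    sets: list[set[int]] = [set(range(len(names)))]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if not significant[i, j]:
                continue
            for s in [s for s in sets if i in s and j in s]:
                sets.remove(s)
                for cand in (s - {i}, s - {j}):
                    if cand and not any(cand <= t for t in sets):
                        sets.append(cand)
            sets = [s for s in sets if not any(s < t for t in sets)]
    sets.sort(key=lambda s: min(s))
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    out = {nm: "" for nm in names}
    for letter, s in zip(alphabet, sets):
        for i in sorted(s):
            out[names[i]] += letter
    return out


def combined_effect(effects: pd.DataFrame, picks: list[tuple[str, str]],
                    column: str = "effect") -> float:
    """Sum of chosen (locus, level) effect entries — the stacked-effect
    prediction used to read combined allele contributions off a results
    table."""
    total = 0.0
    for locus, level in picks:
        sel = effects[(effects["qtl"] == locus) & (effects["level"] == level)]
        if len(sel) != 1:
            raise KeyError(f"no unique entry for ({locus!r}, {level!r})")
        total += float(sel.iloc[0][column])
    return total


# ---------------------------------------------------------------------------
# Convenience wrapper


class QTLScanner:
    """Bundles the genotype-side structures for repeated scans.

    Builds grid and marker scan designs once; phenotypes are then mapped
    with :meth:`map_trait`.
    """

    def __init__(self, geno: GenotypeMatrix, gmap: pd.DataFrame,
                 step: float = 5.0, n_self: int = 2):
        self.geno = geno
        self.gmap = gmap.reset_index(drop=True)
        ap_grid = ancestry_probabilities(geno, gmap, step=step, n_self=n_self)
        marker_grid = self.gmap[["chromosome", "cm"]].copy()
        ap_mark = ancestry_probabilities(geno, gmap, n_self=n_self,
                                         grid=marker_grid)
        self.sd_grid = build_scan_design(ap_grid, geno.cross_design)
        self.sd_markers = build_scan_design(ap_mark, geno.cross_design)
        self.population = geno.population

    def align(self, phenotype: pd.Series) -> np.ndarray:
        y = phenotype.reindex(self.geno.individuals)
        if y.isna().any():
            raise ValueError(
                f"{int(y.isna().sum())} individuals lack a phenotype; "
                "impute or subset before scanning")
        return y.to_numpy(dtype=float)

    def threshold(self, phenotype: pd.Series, n_perm: int, alpha: float,
                  rng: np.random.Generator) -> dict:
        return permutation_threshold(self.align(phenotype), self.sd_grid,
                                     self.population, n_perm=n_perm,
                                     alpha=alpha, rng=rng)

    def map_trait(self, phenotype: pd.Series, trait: str,
                  n_perm: int = 1000, alpha: float = 0.05,
                  min_spacing: float = 10.0, lod_drop: float = 1.5,
                  rng: np.random.Generator | None = None,
                  threshold: float | None = None) -> QTLScanOutput:
        y = self.align(phenotype)
        if threshold is None:
            threshold = permutation_threshold(
                y, self.sd_grid, self.population, n_perm=n_perm,
                alpha=alpha, rng=rng)["threshold"]
        return iqtlm(y, self.sd_grid, self.sd_markers, threshold,
                     trait=trait, min_spacing=min_spacing,
                     lod_drop=lod_drop, alpha=alpha)
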