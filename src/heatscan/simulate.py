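"""Synthetic crossing scheme, genotypes, QTL architecture, weather and
plot-level phenotypes with known ground truth.

The generator emulates the study system: four Dent and four Flint maize
inbreds crossed pairwise into six F3 populations (~608 individuals
total), genotyped at ~161 SNP markers on 10 chromosomes, and phenotyped
at four locations (two standard, two heat) in alpha-lattice trials with
two replications of six subexperiments, one population per
subexperiment, the eight parents included once per subexperiment as
standards.

Ground truth (marker map, QTL effects, per-genotype analytic
heat-susceptibility indices, noiseless adjusted entry means) is returned
in a :class:`SimReport` so every downstream stage can be tested by
parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CrossDesign, GenotypeMatrix

DENT = ("S058", "S067", "S070", "P040")
FLINT = ("L043", "L017", "L023", "L012")
PARENTS = DENT + FLINT

#: Chromosome marker counts of the consensus map being emulated.
_MARKERS_PER_CHROM = (21, 19, 18, 19, 18, 13, 15, 14, 12, 12)
_TOTAL_MAP_CM = 1823.5
#: Physical chromosome sizes (Mb), maize-like, descending.
_CHROM_MB = (301, 244, 235, 247, 223, 174, 182, 181, 160, 151)

LOCATIONS = ("Einbeck", "Greven", "Monselice", "Zsombo")
LOCATION_CONDITIONS = {"Einbeck": "standard", "Greven": "standard",
                       "Monselice": "heat", "Zsombo": "heat"}
#: Growing-degree-day totals each synthetic weather series is calibrated to.
GDD_TARGETS = {"Einbeck": 899.0, "Greven": 1136.0,
               "Monselice": 1588.0, "Zsombo": 1390.0}

REFERENCE_LOCATION = "Einbeck"  # least heat stress (lowest GDD)


def default_cross_design() -> CrossDesign:
    """Two Dent x Dent, two Flint x Flint and two Dent x Flint crosses."""
    return CrossDesign({
        1: ("P040", "S067"),
        2: ("S070", "S058"),
        3: ("L012", "L017"),
        4: ("L043", "L023"),
        5: ("S067", "L012"),
        6: ("S070", "L023"),
    })


DEFAULT_POP_SIZES = (107, 100, 103, 98, 100, 100)  # totals 608


def haldane_r(d_cm: float | np.ndarray) -> np.ndarray:
    """Recombination fraction for a Haldane map distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


# ---------------------------------------------------------------------------
# Genetic map

def simulate_map(n_per_chrom=_MARKERS_PER_CHROM, total_cm=_TOTAL_MAP_CM,
                 chrom_mb=_CHROM_MB) -> pd.DataFrame:
    """Deterministic marker map with centromeric condensation.

    Chromosome spans are proportional to their marker counts and sum to
    ``total_cm``; markers condense toward chromosome centers on the cM
    axis (mimicking suppressed centromeric recombination) while physical
    positions spread evenly, so the bp<->cM relation is non-linear but
    monotone.
    """
    n_total = sum(n_per_chrom)
    rows = []
    for c, (n, mb) in enumerate(zip(n_per_chrom, chrom_mb), start=1):
        span = total_cm * n / n_total
        u = np.linspace(0.0, 1.0, n)
        # condense cM gaps near the middle of the chromosome
        cm = span * (u + 0.55 * np.sin(2 * np.pi * u) / (2 * np.pi))
        cm = np.sort(cm)
        cm -= cm[0]
        v = cm / cm[-1]
        # physical positions stretch through the centromere
        bp_frac = v - 0.55 * np.sin(2 * np.pi * v) / (2 * np.pi)
        bp = np.maximum(1, np.round(bp_frac * mb * 1e6)).astype(int)
        for j in range(n):
            rows.append({"marker": f"M{c:02d}_{j + 1:02d}", "chromosome": c,
                         "cm": round(float(cm[j]), 3), "bp": int(bp[j])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Genotypes: F1 gametes with Haldane recombination, then selfing to F3

def _gametes(hapA: np.ndarray, hapB: np.ndarray, r: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """One gamete per individual from parental haplotype pairs.

    ``hapA``/``hapB`` are (n, m) allele arrays; ``r`` the (m-1,)
    recombination fractions between adjacent markers.  Crossovers are
    independent across intervals (Haldane model, no interference).
    """
    n, m = hapA.shape
    start = rng.integers(0, 2, size=n)
    switch = rng.random((n, m - 1)) < r
    chain = np.empty((n, m), dtype=np.int8)
    chain[:, 0] = start
    chain[:, 1:] = switch
    current = np.cumsum(chain, axis=1) % 2  # which homolog at each marker
    return np.where(current == 0, hapA, hapB).astype(np.int8)


def simulate_cross_genotypes(
    gmap: pd.DataFrame,
    cross_design: CrossDesign,
    pop_sizes=DEFAULT_POP_SIZES,
    het_target: float = 0.25,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Simulate marker genotypes for every population.

    Each individual derives from two F1 gametes followed by
    ``log2(1/het_target)`` generations of selfing tracked at the marker
    loci (two generations, i.e. F3, for the default 25 % target).
    """
    if rng is None:
        rng = np.random.default_rng()
    pops = cross_design.populations
    if len(pop_sizes) != len(pops):
        raise ValueError("pop_sizes length must match number of populations")
    if not 0.0 < het_target <= 0.5:
        raise ValueError("het_target must be in (0, 0.5]")
    n_self = max(1, round(math.log2(1.0 / het_target)))

    markers = gmap["marker"].tolist()
    chrom_slices = []
    pos = 0
    for _, grp in gmap.groupby("chromosome", sort=True):
        d = np.diff(grp["cm"].to_numpy())
        chrom_slices.append((slice(pos, pos + len(grp)), haldane_r(d)))
        pos += len(grp)

    all_codes, all_pops, all_ids = [], [], []
    for pop, size in zip(pops, pop_sizes):
        codes = np.empty((size, len(markers)), dtype=np.int8)
        for sl, r in chrom_slices:
            m = sl.stop - sl.start
            # F1 is fully heterozygous in coupling: hapA all parent-A (0),
            # hapB all parent-B (1); both F1 gametes per F2 individual.
            hapA = np.zeros((size, m), dtype=np.int8)
            hapB = np.ones((size, m), dtype=np.int8)
            h1 = _gametes(hapA, hapB, r, rng)
            h2 = _gametes(hapA, hapB, r, rng)
            for _ in range(n_self - 1):
                h1, h2 = _gametes(h1, h2, r, rng), _gametes(h1, h2, r, rng)
            codes[:, sl] = h1 + h2
        all_codes.append(codes)
        all_pops.append(np.full(size, pop))
        all_ids.extend(f"P{pop}_{k + 1:03d}" for k in range(size))

    return GenotypeMatrix(
        individuals=all_ids, markers=markers,
        codes=np.vstack(all_codes), population=np.concatenate(all_pops),
        cross_design=cross_design,
    )


# ---------------------------------------------------------------------------
# Trait architecture

@dataclass
class TraitModel:
    """Generating model of one trait.

    A genotype's expected value at location ``j`` is

        (mu + P_i) * (1 + b_i * (m_j - 1))

    where ``P_i`` is its growth potential (SD ``sigma_g``), ``m_j`` the
    location's stress multiplier (1 at the reference) and ``b_i`` its
    susceptibility coefficient: 1 + QTL susceptibility effects + a
    polygenic deviation (SD ``sigma_susc``), so the population mean
    tracks ``mu * m_j`` and the genotype's stability slope is ``b_i``.
    ``escape_rho`` correlates the polygenic susceptibility with a latent
    per-genotype heat-escape factor shared across traits (early
    flowering trading off against yield loss).  ``sigma_gl`` (genotype x
    location deviations, biology) and ``sigma_e`` (plot residual) may
    differ between conditions; heat trials are noisier.
    """

    mu: float
    stress: dict[str, float]
    sigma_g: float
    sigma_gl: dict[str, float]
    sigma_e: dict[str, float]
    sigma_susc: float = 0.1
    escape_rho: float = 0.0
    sigma_rep: float = 0.3
    sigma_subexp: float = 1.0
    sigma_block: float = 0.5
    ordinal: bool = False  # discretize to a 1-9 score in the field book


@dataclass
class QTL:
    """A planted locus: per-trait additive effects of the parental alleles
    (per allele, on the susceptibility-coefficient scale, sum-to-zero
    across the eight parents) and per-population dominance."""

    name: str
    chromosome: int
    position_cm: float
    additive: dict[str, dict[str, float]]  # trait -> parent -> effect
    dominance: dict[str, dict[int, float]] = field(default_factory=dict)

    def validate(self, parents=PARENTS) -> None:
        for trait, eff in self.additive.items():
            total = sum(eff.get(p, 0.0) for p in parents)
            if abs(total) > 1e-9:
                raise ValueError(
                    f"QTL {self.name}: additive effects for {trait} sum to "
                    f"{total}, must sum to zero")


@dataclass
class TrueArchitecture:
    traits: dict[str, TraitModel]
    qtls: list[QTL]

    def validate(self, reference: str = REFERENCE_LOCATION) -> None:
        for q in self.qtls:
            q.validate()
        for name, tm in self.traits.items():
            if abs(tm.stress.get(reference, 1.0) - 1.0) > 1e-12:
                raise ValueError(
                    f"trait {name}: stress multiplier at the reference "
                    f"location must be 1")


def default_architecture() -> TrueArchitecture:
    """Study-condition defaults.

    Stress multipliers follow the observed heat/standard ratios of the
    location means (yield roughly halved, flowering ~30 % faster, grain
    moisture halved, leaf scorching strongly increased under heat); the
    male and female flowering multipliers are tied so that their
    difference (the anthesis-silking interval) carries no condition
    effect.  Susceptibility QTL effects are on the stability-slope scale
    (homozygous contrasts ~0.2-0.4, matching the size of effects such
    loci show on ratio-based indices); the yield/flowering locus pair
    carries opposite-signed effects and the latent escape factor
    correlates polygenic flowering and yield susceptibility negatively —
    genotypes that keep flowering late under heat lose more yield.
    """
    mf_mult = {"Einbeck": 1.0, "Greven": 0.99, "Monselice": 0.70, "Zsombo": 0.72}
    # FF multiplier solves m_FF*mu_FF = m_MF*mu_MF + 2 at every location,
    # keeping ASI = FF - MF free of a condition effect.
    mu_mf, mu_ff = 70.0, 72.0
    ff_mult = {loc: (m * mu_mf + 2.0) / mu_ff for loc, m in mf_mult.items()}

    traits = {
        "MF": TraitModel(mu=mu_mf, stress=mf_mult, sigma_g=2.2,
                         sigma_susc=0.08, escape_rho=0.5,
                         sigma_gl={"standard": 0.5, "heat": 1.2},
                         sigma_e={"standard": 1.2, "heat": 1.7},
                         sigma_rep=0.3, sigma_subexp=0.8, sigma_block=0.4),
        "FF": TraitModel(mu=mu_ff, stress=ff_mult, sigma_g=2.2,
                         sigma_susc=0.08, escape_rho=0.5,
                         sigma_gl={"standard": 0.5, "heat": 1.2},
                         sigma_e={"standard": 1.2, "heat": 1.7},
                         sigma_rep=0.3, sigma_subexp=0.8, sigma_block=0.4),
        "LS": TraitModel(mu=2.0,
                         stress={"Einbeck": 1.0, "Greven": 1.02,
                                 "Monselice": 2.45, "Zsombo": 2.30},
                         sigma_g=0.3, sigma_susc=0.25, escape_rho=0.0,
                         sigma_gl={"standard": 0.2, "heat": 0.5},
                         sigma_e={"standard": 0.7, "heat": 0.8},
                         sigma_rep=0.1, sigma_subexp=0.3, sigma_block=0.2,
                         ordinal=True),
        "DY": TraitModel(mu=80.0,
                         stress={"Einbeck": 1.0, "Greven": 0.97,
                                 "Monselice": 0.46, "Zsombo": 0.50},
                         sigma_g=6.5, sigma_susc=0.10, escape_rho=-0.5,
                         sigma_gl={"standard": 1.5, "heat": 5.0},
                         sigma_e={"standard": 2.5, "heat": 3.5},
                         sigma_rep=0.6, sigma_subexp=2.0, sigma_block=1.2),
        "GM": TraitModel(mu=32.0,
                         stress={"Einbeck": 1.0, "Greven": 0.98,
                                 "Monselice": 0.45, "Zsombo": 0.47},
                         sigma_g=2.2, sigma_susc=0.08, escape_rho=0.0,
                         sigma_gl={"standard": 0.5, "heat": 1.5},
                         sigma_e={"standard": 1.2, "heat": 1.6},
                         sigma_rep=0.3, sigma_subexp=0.8, sigma_block=0.4),
    }

    def bal(d: dict[str, float]) -> dict[str, float]:
        s = sum(d.values())
        assert abs(s) < 1e-9
        return d

    qtls = [
        QTL("q_dy_a", 2, 45.0,
            additive={"DY": bal({"S067": -0.10, "P040": 0.10}),
                      "FF": bal({"S067": 0.05, "P040": -0.05}),
                      "MF": bal({"S067": 0.05, "P040": -0.05})},
            dominance={"DY": {1: -0.10}}),
        QTL("q_dy_b", 3, 120.0,
            additive={"DY": bal({"P040": -0.10, "S067": 0.10}),
                      "FF": bal({"P040": 0.05, "S067": -0.05}),
                      "MF": bal({"P040": 0.05, "S067": -0.05})},
            dominance={"DY": {1: 0.10}}),
        QTL("q_fl", 8, 60.0,
            additive={"FF": bal({"S070": 0.06, "L043": -0.06}),
                      "MF": bal({"S070": 0.06, "L043": -0.06})}),
        QTL("q_ls", 9, 65.0,
            additive={"LS": bal({"L012": 0.18, "P040": -0.18})},
            dominance={"LS": {5: 0.12}}),
        QTL("q_gm", 5, 140.0,
            additive={"GM": bal({"L043": 0.08, "L023": -0.08})}),
    ]
    arch = TrueArchitecture(traits=traits, qtls=qtls)
    arch.validate()
    return arch


# ---------------------------------------------------------------------------
# Weather

def simulate_weather(locations=LOCATIONS, gdd_targets=GDD_TARGETS,
                     n_days: int = 160, t_base: float = 10.0,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Daily min/max temperature series calibrated to target GDD totals.

    A seasonal sinusoid plus weather noise per location, with the level
    shifted so the clamped degree-day sum over the season matches the
    location's target exactly.
    """
    if rng is None:
        rng = np.random.default_rng()
    day = np.arange(n_days)
    season = np.sin(np.pi * (day + 15) / (n_days + 30))
    frames = []
    for loc in locations:
        noise = rng.normal(0, 2.0, n_days)
        noise = np.convolve(noise, np.ones(5) / 5, mode="same")  # weather persistence
        mid0 = 8.0 + 12.0 * season + noise
        spread = 5.0 + 2.0 * season

        def gdd_total(offset: float) -> float:
            return float(np.maximum(mid0 + offset - t_base, 0.0).sum())

        target = gdd_targets[loc]
        lo, hi = -20.0, 40.0
        for _ in range(80):  # bisection: gdd_total is monotone in offset
            mid = (lo + hi) / 2
            if gdd_total(mid) < target:
                lo = mid
            else:
                hi = mid
        offset = (lo + hi) / 2
        tmid = mid0 + offset
        frames.append(pd.DataFrame({
            "location": loc,
            "date": pd.date_range("2012-05-01", periods=n_days, freq="D"),
            "tmin": np.round(tmid - spread, 2),
            "tmax": np.round(tmid + spread, 2),
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Genetic values and the field trial

def _snap_qtl_to_markers(arch: TrueArchitecture, gmap: pd.DataFrame) -> dict[str, tuple[int, float]]:
    """QTL are realized at their nearest mapped marker; returns
    name -> (marker column index, realized cM)."""
    out = {}
    markers = gmap.reset_index(drop=True)
    for q in arch.qtls:
        chrom = markers[markers["chromosome"] == q.chromosome]
        if chrom.empty:
            raise ValueError(f"QTL {q.name}: chromosome {q.chromosome} not on map")
        i = (chrom["cm"] - q.position_cm).abs().idxmin()
        out[q.name] = (int(i), float(markers.loc[i, "cm"]))
    return out


def genetic_values(geno: GenotypeMatrix, gmap: pd.DataFrame,
                   arch: TrueArchitecture) -> tuple[pd.DataFrame, dict[str, float]]:
    """QTL genetic value per individual and parent for every trait.

    The value is the sum over loci of the two parental-allele additive
    effects plus the population's dominance effect when heterozygous;
    parents are homozygous carriers of their own allele throughout.
    """
    snapped = _snap_qtl_to_markers(arch, gmap)
    ids = list(geno.individuals) + list(PARENTS)
    vals = pd.DataFrame(0.0, index=ids, columns=list(arch.traits))
    for q in arch.qtls:
        col, _ = snapped[q.name]
        codes = geno.codes[:, col]
        for trait, eff in q.additive.items():
            if trait not in vals.columns:
                continue
            add = np.zeros(geno.n_individuals)
            for pop in geno.cross_design.populations:
                a, b = geno.cross_design.parents_of(pop)
                sel = geno.population == pop
                dose_b = codes[sel].astype(float)
                add[sel] = (2.0 - dose_b) * eff.get(a, 0.0) + dose_b * eff.get(b, 0.0)
            dom = q.dominance.get(trait, {})
            if dom:
                het = (codes == 1)
                for pop, d in dom.items():
                    add[(geno.population == pop) & het] += d
            vals.loc[geno.individuals, trait] += add
            for p in PARENTS:
                vals.loc[p, trait] += 2.0 * eff.get(p, 0.0)
    realized = {name: cm for name, (_, cm) in snapped.items()}
    return vals, realized


@dataclass
class TrialDesign:
    """Field layout: locations with conditions, replications, one
    subexperiment per population, incomplete blocks of ``block_size``."""

    locations: tuple[tuple[str, str], ...] = tuple(LOCATION_CONDITIONS.items())
    n_reps: int = 2
    n_subexperiments: int = 6
    block_size: int = 12


@dataclass
class SimReport:
    """Ground truth of one simulated trial."""

    true_hsi: pd.DataFrame  # genotype x trait slopes (design-noise free)
    true_aem: dict[str, pd.DataFrame]  # trait -> genotype x location
    true_location_means: dict[str, pd.Series]
    genetic_value: pd.DataFrame  # QTL susceptibility value per trait
    susceptibility: pd.DataFrame  # genotype x trait b coefficients
    qtl_positions: dict[str, float]
    architecture: TrueArchitecture
    seed: int | None = None


def _true_hsi(aem: pd.DataFrame, reference: str) -> pd.Series:
    """Finlay-Wilkinson slope of each genotype's AEM ratios on the
    location-mean ratios, from noiseless AEMs."""
    loc_means = aem.mean(axis=0)
    r_j = (loc_means / loc_means[reference]).to_numpy()
    r_ij = aem.div(aem[reference], axis=0).to_numpy()
    x = r_j - r_j.mean()
    sxx = float(x @ x)
    if sxx == 0.0:  # no stress gradient: susceptibility is undefined
        return pd.Series(np.nan, index=aem.index)
    slopes = (r_ij - r_ij.mean(axis=1, keepdims=True)) @ x / sxx
    return pd.Series(slopes, index=aem.index)


def simulate_trial(
    geno: GenotypeMatrix,
    arch: TrueArchitecture,
    design: TrialDesign,
    rng: np.random.Generator,
    gmap: pd.DataFrame,
    reference: str = REFERENCE_LOCATION,
    missing_rate: float = 0.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, SimReport]:
    """Generate a plot-level field book plus its ground truth.

    Plot value = (mu + growth potential) * (1 + b_i * (stress_j - 1))
    + genotype x location deviation + replication + subexperiment +
    block + residual, where the susceptibility coefficient b_i sums the
    locus effects (additive per allele plus the population's dominance
    when heterozygous) and a polygenic deviation partially driven by a
    latent heat-escape factor shared across traits.  Every parent
    appears once per subexperiment as a standard, and each population
    occupies exactly one subexperiment per replication.
    """
    pops = geno.cross_design.populations
    if len(pops) != design.n_subexperiments:
        raise ValueError(
            f"{len(pops)} populations but {design.n_subexperiments} "
            "subexperiments; the layout assigns one population per subexperiment")

    qvals, qtl_pos = genetic_values(geno, gmap, arch)
    ids = list(qvals.index)
    traits = list(arch.traits)

    # genotype-level random deviations, shared across locations
    polygenic = pd.DataFrame(
        {t: rng.normal(0.0, arch.traits[t].sigma_g, len(ids)) for t in traits},
        index=ids)
    escape = rng.normal(0.0, 1.0, len(ids))
    susceptibility = {}
    for t in traits:
        tm = arch.traits[t]
        rho = tm.escape_rho
        poly_b = tm.sigma_susc * (rho * escape
                                  + np.sqrt(max(1 - rho ** 2, 0.0))
                                  * rng.normal(0.0, 1.0, len(ids)))
        susceptibility[t] = 1.0 + qvals[t].to_numpy() + poly_b
    b_frame = pd.DataFrame(susceptibility, index=ids)

    gl_dev = {
        t: pd.DataFrame(
            {loc: rng.normal(0.0, arch.traits[t].sigma_gl[cond], len(ids))
             for loc, cond in design.locations},
            index=ids)
        for t in traits
    }

    true_aem, true_locmeans, true_hsi = {}, {}, {}
    for t in traits:
        tm = arch.traits[t]
        aem = pd.DataFrame(index=ids, columns=[l for l, _ in design.locations],
                           dtype=float)
        for loc, cond in design.locations:
            aem[loc] = ((tm.mu + polygenic[t])
                        * (1.0 + b_frame[t] * (tm.stress[loc] - 1.0))
                        + gl_dev[t][loc])
        true_aem[t] = aem
        true_locmeans[t] = aem.mean(axis=0)
        true_hsi[t] = _true_hsi(aem, reference)
    hsi_frame = pd.DataFrame(true_hsi)

    rows = []
    pop_members = {p: [ids[k] for k in np.flatnonzero(geno.population == p)]
                   for p in pops}
    for loc, cond in design.locations:
        for rep in range(1, design.n_reps + 1):
            rep_eff = {t: rng.normal(0.0, arch.traits[t].sigma_rep) for t in traits}
            for sub_idx, pop in enumerate(pops, start=1):
                sub_eff = {t: rng.normal(0.0, arch.traits[t].sigma_subexp)
                           for t in traits}
                entries = pop_members[pop] + list(PARENTS)
                order = rng.permutation(len(entries))
                n_blocks = max(1, math.ceil(len(entries) / design.block_size))
                block_eff = {t: rng.normal(0.0, arch.traits[t].sigma_block, n_blocks)
                             for t in traits}
                for slot, k in enumerate(order):
                    gid = entries[k]
                    is_std = gid in PARENTS
                    blk = slot % n_blocks + 1
                    row = {
                        "genotype": gid, "is_standard": is_std,
                        "population": (pd.NA if is_std else pop),
                        "location": loc, "condition": cond,
                        "replication": rep, "subexperiment": sub_idx,
                        "block": blk,
                    }
                    for t in traits:
                        tm = arch.traits[t]
                        val = (true_aem[t].at[gid, loc]
                               + rep_eff[t] + sub_eff[t] + block_eff[t][blk - 1]
                               + rng.normal(0.0, tm.sigma_e[cond]))
                        row[t] = val
                    rows.append(row)
    fb = pd.DataFrame(rows)

    # observed scales: LS is an ordinal 1-9 score; FY/GM are what the
    # combine measures, dry yield is re-derived downstream
    if "LS" in fb.columns:
        fb["LS"] = fb["LS"].round().clip(1, 9)
    if "GM" in fb.columns:
        fb["GM"] = fb["GM"].clip(5.0, 60.0)
    if "DY" in fb.columns and "GM" in fb.columns:
        fb["FY"] = fb["DY"] * 0.85 / (1.0 - fb["GM"] / 100.0)
        fb = fb.drop(columns=["DY"])

    if missing_rate > 0:
        trait_cols = [c for c in fb.columns if c in ("MF", "FF", "LS", "FY", "GM")]
        mask = rng.random((len(fb), len(trait_cols))) < missing_rate
        for j, c in enumerate(trait_cols):
            fb.loc[mask[:, j], c] = np.nan

    report = SimReport(
        true_hsi=hsi_frame, true_aem=true_aem,
        true_location_means=true_locmeans, genetic_value=qvals,
        susceptibility=b_frame, qtl_positions=qtl_pos,
        architecture=arch, seed=seed,
    )
    return fb, report


# ---------------------------------------------------------------------------
# Candidate-gene list

def simulate_genes(gmap: pd.DataFrame, n_genes: int = 120,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Synthetic heat-responsive / heat-tolerance gene list with physical
    positions spread over the mapped bp range of each chromosome."""
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    chroms = gmap.groupby("chromosome")["bp"].agg(["min", "max"])
    for k in range(n_genes):
        c = int(rng.integers(1, len(chroms) + 1))
        lo, hi = chroms.loc[c, "min"], chroms.loc[c, "max"]
        start = int(rng.integers(lo, hi))
        rows.append({
            "gene_id": f"GENE{k + 1:04d}", "chromosome": c,
            "bp_start": start, "bp_end": start + int(rng.integers(1000, 6000)),
            "class": "heat-tolerance" if rng.random() < 0.06 else "heat-responsive",
        })
    return pd.DataFrame(rows).sort_values(["chromosome", "bp_start"]).reset_index(drop=True)
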