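"""Parental-origin probabilities on the scan grid.

F3 individuals derive from two F1 gametes plus one further selfing
generation, so genotypes at linked loci follow a two-locus distribution
that is computed exactly by recursion over unordered haplotype pairs
(gametes recombine with Haldane fractions, no interference).  Grid-point
probabilities condition on the nearest informative flanking markers via
the resulting genotype-to-genotype transition kernel, treating the
process as Markov along the chromosome (exact at the markers, standard
approximation between them).

Genotype classes are doses of the population's second parent allele:
0 = AA, 1 = AB, 2 = BB; the unconditional F3 class frequencies are
(3/8, 1/4, 3/8).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .core import GenotypeMatrix
from .simulate import haldane_r

# unordered pairs of two-locus haplotypes; haplotype = (allele@1, allele@2)
_HAPS = [(0, 0), (0, 1), (1, 0), (1, 1)]
_STATES = [(i, j) for i in range(4) for j in range(i, 4)]  # 10 states


def _gamete_distribution(state: tuple[int, int], r: float) -> np.ndarray:
    h1, h2 = _HAPS[state[0]], _HAPS[state[1]]
    dist = np.zeros(4)
    dist[_HAPS.index(h1)] += (1 - r) / 2
    dist[_HAPS.index(h2)] += (1 - r) / 2
    dist[_HAPS.index((h1[0], h2[1]))] += r / 2
    dist[_HAPS.index((h2[0], h1[1]))] += r / 2
    return dist


def _selfing_matrix(r: float) -> np.ndarray:
    """10x10 transition of unordered haplotype-pair states under one
    generation of selfing."""
    M = np.zeros((len(_STATES), len(_STATES)))
    for si, state in enumerate(_STATES):
        g = _gamete_distribution(state, r)
        joint = np.outer(g, g)
        for a in range(4):
            for b in range(4):
                key = (a, b) if a <= b else (b, a)
                M[si, _STATES.index(key)] += joint[a, b]
    return M


def _genotype_pair(state: tuple[int, int]) -> tuple[int, int]:
    h1, h2 = _HAPS[state[0]], _HAPS[state[1]]
    return h1[0] + h2[0], h1[1] + h2[1]


@lru_cache(maxsize=4096)
def two_locus_joint(d_cm: float, n_self: int = 2) -> tuple:
    """Exact joint distribution of genotype classes at two loci ``d_cm``
    apart in a selfed F(1 + n_self) population (F3 for n_self=2)."""
    r = float(haldane_r(d_cm))
    state = np.zeros(len(_STATES))
    state[_STATES.index((_HAPS.index((0, 0)), _HAPS.index((1, 1))))] = 1.0
    M = _selfing_matrix(r)
    for _ in range(n_self):
        state = state @ M
    joint = np.zeros((3, 3))
    for si, s in enumerate(_STATES):
        g1, g2 = _genotype_pair(s)
        joint[g1, g2] += state[si]
    return tuple(map(tuple, joint))


def transition_kernel(d_cm: float, n_self: int = 2) -> np.ndarray:
    """P(genotype at a locus | genotype at a locus d_cm to its left)."""
    joint = np.array(two_locus_joint(round(float(d_cm), 6), n_self))
    rows = joint.sum(axis=1, keepdims=True)
    return joint / rows


def genotype_prior(n_self: int = 2) -> np.ndarray:
    """Unconditional class frequencies after n_self selfing generations."""
    het = 0.5 ** n_self
    return np.array([(1 - het) / 2, het, (1 - het) / 2])


@dataclass
class AncestryProbabilities:
    """Per individual x grid position probabilities over the classes
    (AA, AB, BB) of the population's parental alleles."""

    positions: pd.DataFrame  # columns chromosome, cm
    probs: np.ndarray        # (n_individuals, n_positions, 3)
    individuals: list[str]
    population: np.ndarray

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def dose_design(self) -> tuple[np.ndarray, np.ndarray]:
        """Expected dose of the second parent allele and the
        heterozygosity probability, (n_ind, n_pos) each."""
        dose_b = self.probs[:, :, 1] + 2.0 * self.probs[:, :, 2]
        het = self.probs[:, :, 1]
        return dose_b, het


def scan_grid(gmap: pd.DataFrame, step: float = 5.0) -> pd.DataFrame:
    """Grid positions every ``step`` cM per chromosome, always including
    the terminal marker position."""
    rows = []
    for chrom, grp in gmap.groupby("chromosome", sort=True):
        lo, hi = float(grp["cm"].min()), float(grp["cm"].max())
        pts = list(np.arange(lo, hi, step))
        if not pts or hi - pts[-1] > 1e-9:
            pts.append(hi)
        rows += [{"chromosome": chrom, "cm": float(p)} for p in pts]
    return pd.DataFrame(rows)


def ancestry_probabilities(geno: GenotypeMatrix, gmap: pd.DataFrame,
                           step: float = 5.0, n_self: int = 2,
                           grid: pd.DataFrame | None = None
                           ) -> AncestryProbabilities:
    """Hidden-genotype probabilities at every grid point, conditioning on
    the nearest informative (non-missing) flanking markers.

    ``grid`` overrides the regular every-``step`` grid (e.g. with the
    marker positions themselves for cofactor selection).  Chromosomes
    with a single marker fall back to that marker plus the selfing
    prior; individuals with no informative marker on a chromosome get
    the prior itself.
    """
    gmap = gmap.reset_index(drop=True)
    marker_col = {m: j for j, m in enumerate(geno.markers)}
    if grid is None:
        grid = scan_grid(gmap, step=step)
    grid = grid.reset_index(drop=True)
    n_ind = geno.n_individuals
    probs = np.empty((n_ind, len(grid), 3))
    prior = genotype_prior(n_self)

    pos_idx = 0
    for chrom, cgrp in gmap.groupby("chromosome", sort=True):
        cms = cgrp["cm"].to_numpy(dtype=float)
        cols = np.array([marker_col[m] for m in cgrp["marker"]])
        codes = geno.codes[:, cols]  # (n_ind, n_markers_on_chrom)
        gpts = grid.loc[grid["chromosome"] == chrom, "cm"].to_numpy()
        for x in gpts:
            probs[:, pos_idx, :] = _point_probs(codes, cms, float(x), prior, n_self)
            pos_idx += 1
    return AncestryProbabilities(positions=grid, probs=probs,
                                 individuals=list(geno.individuals),
                                 population=geno.population.copy())


def _point_probs(codes: np.ndarray, cms: np.ndarray, x: float,
                 prior: np.ndarray, n_self: int) -> np.ndarray:
    """Probabilities at one grid point for all individuals of a
    chromosome block."""
    n_ind, n_mark = codes.shape
    out = np.empty((n_ind, 3))
    left_candidates = np.flatnonzero(cms <= x + 1e-9)
    right_candidates = np.flatnonzero(cms >= x - 1e-9)

    # default flanks: nearest markers; individuals missing there use the
    # next informative marker outward (slow path, rare)
    def flank_for(ind_codes: np.ndarray, cand: np.ndarray, reverse: bool):
        order = cand[::-1] if reverse else cand
        for j in order:
            if ind_codes[j] >= 0:
                return j
        return None

    # fast path: group individuals by (left marker, right marker) pair
    lmat = np.full(n_ind, -1)
    rmat = np.full(n_ind, -1)
    for i in range(n_ind):
        lj = flank_for(codes[i], left_candidates, reverse=True)
        rj = flank_for(codes[i], right_candidates, reverse=False)
        lmat[i] = -1 if lj is None else lj
        rmat[i] = -1 if rj is None else rj

    cache: dict[tuple[int, int], np.ndarray] = {}
    for (lj, rj) in {(int(a), int(b)) for a, b in zip(lmat, rmat)}:
        if (lj, rj) not in cache:
            cache[(lj, rj)] = _combo_table(cms, x, lj, rj, prior, n_self)
    for i in range(n_ind):
        lj, rj = int(lmat[i]), int(rmat[i])
        table = cache[(lj, rj)]
        gl = codes[i, lj] if lj >= 0 else 0
        gr = codes[i, rj] if rj >= 0 else 0
        out[i] = table[gl, gr]
    return out


def _combo_table(cms: np.ndarray, x: float, lj: int, rj: int,
                 prior: np.ndarray, n_self: int) -> np.ndarray:
    """(3, 3, 3) table: P(class at x | left class, right class)."""
    table = np.empty((3, 3, 3))
    if lj < 0 and rj < 0:
        table[:, :, :] = prior
        return table
    if lj >= 0 and rj >= 0 and lj == rj:
        # grid point sits on an informative marker
        eye = np.eye(3)
        for gl in range(3):
            table[gl, :, :] = eye[gl]
        return table
    TL = transition_kernel(x - cms[lj], n_self) if lj >= 0 else None
    TR = transition_kernel(cms[rj] - x, n_self) if rj >= 0 else None
    for gl in range(3):
        for gr in range(3):
            if TL is not None and TR is not None:
                w = TL[gl, :] * TR[:, gr]
            elif TL is not None:
                w = TL[gl, :].copy()
            else:
                # only a right flank: Bayes-invert the kernel
                w = prior * TR[:, gr]
            total = w.sum()
            table[gl, gr] = w / total if total > 0 else prior
    return table
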