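"""In-memory containers shared across modules.

Tabular objects (field book, genetic map, weather, gene lists, result
tables) are plain :class:`pandas.DataFrame` with documented columns and
validators in :mod:`heatscan.io`.  The marker genotype matrix gets its own
class because cells are pairs of parental alleles tied to a crossing
design, which a flat frame does not express well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Genotype codes: dose of the population's *second* parent allele.
#: 0 = homozygous parent A, 1 = heterozygous, 2 = homozygous parent B,
#: -1 = missing.
CODE_MISSING = -1

# Design-key columns of a field book; one row = one plot observation set.
FIELDBOOK_KEYS = ["location", "replication", "subexperiment", "block", "genotype"]
FIELDBOOK_META = ["genotype", "is_standard", "population", "location", "condition",
                  "replication", "subexperiment", "block"]


@dataclass
class CrossDesign:
    """Mapping population number -> (parentA, parentB) inbred names."""

    parents: dict[int, tuple[str, str]]

    @property
    def populations(self) -> list[int]:
        return sorted(self.parents)

    @property
    def all_parents(self) -> list[str]:
        seen: list[str] = []
        for a, b in self.parents.values():
            for p in (a, b):
                if p not in seen:
                    seen.append(p)
        return seen

    def parents_of(self, population: int) -> tuple[str, str]:
        return self.parents[population]


@dataclass
class GenotypeMatrix:
    """Marker genotypes of population individuals, coded by parental origin.

    ``codes[i, m]`` is the dose (0/1/2) of the second parent's allele for
    individual ``i`` at marker ``m``, or -1 when missing.  Which inbreds
    are "first" and "second" parent is defined by ``cross_design``.
    """

    individuals: list[str]
    markers: list[str]
    codes: np.ndarray  # (n_ind, n_markers) int8
    population: np.ndarray  # (n_ind,) int
    cross_design: CrossDesign

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.population = np.asarray(self.population, dtype=int)
        n, m = self.codes.shape
        if n != len(self.individuals) or m != len(self.markers):
            raise ValueError("codes shape does not match individuals x markers")
        if not np.isin(self.codes, [-1, 0, 1, 2]).all():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_index(self, name: str) -> int:
        try:
            return self.markers.index(name)
        except ValueError:
            raise KeyError(f"unknown marker {name!r}") from None

    def heterozygosity(self, population: int | None = None) -> float:
        """Realized mean fraction of heterozygous, non-missing calls."""
        codes = self.codes if population is None else self.codes[self.population == population]
        obs = codes >= 0
        if not obs.any():
            return float("nan")
        return float((codes == 1).sum() / obs.sum())

    def subset_markers(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self.marker_index(m) for m in keep]
        return GenotypeMatrix(
            individuals=list(self.individuals),
            markers=list(keep),
            codes=self.codes[:, idx].copy(),
            population=self.population.copy(),
            cross_design=self.cross_design,
        )

    def to_frame(self) -> pd.DataFrame:
        """Cells as 'parentX/parentY' strings (the on-disk representation)."""
        cells = np.empty(self.codes.shape, dtype=object)
        for k, pop in enumerate(self.population):
            a, b = self.cross_design.parents_of(int(pop))
            row = self.codes[k]
            cells[k] = np.select(
                [row == 0, row == 1, row == 2],
                [f"{a}/{a}", f"{a}/{b}", f"{b}/{b}"],
                default="",
            )
        df = pd.DataFrame(cells, columns=self.markers)
        df.insert(0, "individual", self.individuals)
        df.insert(1, "population", self.population)
        return df


def validate_map(gmap: pd.DataFrame) -> pd.DataFrame:
    """Check genetic-map invariants; returns the frame sorted by (chrom, cM)."""
    required = {"marker", "chromosome", "cm"}
    missing = required - set(gmap.columns)
    if missing:
        raise ValueError(f"genetic map missing columns: {sorted(missing)}")
    if gmap["marker"].duplicated().any():
        dup = gmap.loc[gmap["marker"].duplicated(), "marker"].tolist()
        raise ValueError(f"duplicate marker names in map: {dup}")
    if (gmap["cm"] < 0).any():
        raise ValueError("cM positions must be >= 0")
    out = gmap.sort_values(["chromosome", "cm"], kind="stable").reset_index(drop=True)
    return out


def map_summary(gmap: pd.DataFrame) -> dict:
    """Total length, marker count and average inter-marker distance.

    The average distance is the total map length divided by the number of
    markers, the convention used when summarizing consensus maps of this
    kind.
    """
    gmap = validate_map(gmap)
    lengths = gmap.groupby("chromosome")["cm"].agg(lambda s: s.max() - s.min())
    total = float(lengths.sum())
    n = int(len(gmap))
    gaps = gmap.groupby("chromosome")["cm"].diff().dropna()
    return {
        "total_length_cm": total,
        "n_markers": n,
        "n_chromosomes": int(gmap["chromosome"].nunique()),
        "mean_spacing_cm": total / n,
        "max_gap_cm": float(gaps.max()) if len(gaps) else float("nan"),
    }
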