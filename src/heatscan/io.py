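"""Readers and writers for all file formats.

All coordinate and coding conventions are enforced here: cM positions are
floats on per-chromosome axes starting at 0, physical positions are
1-based bp, genotype cells are ``parentA/parentB`` name pairs, missing
phenotypes stay missing (never 0).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, MEASURED_TRAITS, DERIVED_TRAITS
from .core import CrossDesign, GenotypeMatrix, FIELDBOOK_KEYS, FIELDBOOK_META, validate_map

KNOWN_TRAITS = set(MEASURED_TRAITS) | set(DERIVED_TRAITS)


def read_fieldbook(path: str | Path, config: RunConfig,
                   extra_traits: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read a plot-level field book CSV into a typed frame.

    Raises on duplicated design keys and on locations without a declared
    condition.  Unknown trait columns are rejected unless listed in
    ``extra_traits``.
    """
    fb = pd.read_csv(path)
    missing = [c for c in FIELDBOOK_META if c not in fb.columns and c != "condition"]
    if missing:
        raise ValueError(f"field book missing columns: {missing}")
    trait_cols = [c for c in fb.columns if c not in FIELDBOOK_META]
    unknown = [c for c in trait_cols if c not in KNOWN_TRAITS and c not in extra_traits]
    if unknown:
        raise ValueError(f"unknown trait columns: {unknown} (pass extra_traits to allow)")
    fb = _finalize_fieldbook(fb, config)
    return fb


def _finalize_fieldbook(fb: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    fb = fb.copy()
    fb["is_standard"] = fb["is_standard"].astype(bool)
    fb["population"] = fb["population"].astype("Int64")
    for col in ("replication", "subexperiment", "block"):
        fb[col] = fb[col].astype(int)
    # condition is declared per location, never inferred from the data
    fb["condition"] = fb["location"].map(lambda l: config.condition_of(l))
    dup = fb.duplicated(subset=FIELDBOOK_KEYS)
    if dup.any():
        rows = fb.loc[dup, FIELDBOOK_KEYS].head(5).to_dict("records")
        raise ValueError(f"duplicate design keys in field book, e.g. {rows}")
    if "LS" in fb.columns:
        ls = fb["LS"].dropna()
        if len(ls) and ((ls < 1) | (ls > 9)).any():
            raise ValueError("LS scores must lie in [1, 9]")
    meta = [c for c in FIELDBOOK_META if c in fb.columns]
    traits = [c for c in fb.columns if c not in FIELDBOOK_META]
    return fb[meta + traits]


def read_map(path: str | Path) -> pd.DataFrame:
    """Genetic map CSV: marker, chromosome, cm [, bp]."""
    gmap = pd.read_csv(path)
    gmap = validate_map(gmap)
    if "bp" in gmap.columns:
        gmap["bp"] = gmap["bp"].astype("Int64")
    return gmap


def read_cross_design(path: str | Path) -> CrossDesign:
    """Crossing design CSV: population, parentA, parentB."""
    df = pd.read_csv(path)
    return CrossDesign({int(r.population): (str(r.parentA), str(r.parentB))
                        for r in df.itertuples()})


def write_cross_design(design: CrossDesign, path: str | Path) -> None:
    rows = [{"population": p, "parentA": a, "parentB": b}
            for p, (a, b) in sorted(design.parents.items())]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_genotypes(path: str | Path, design: CrossDesign) -> GenotypeMatrix:
    """Genotype CSV with 'parentX/parentY' cells into coded doses."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    individuals = df["individual"].tolist()
    population = df["population"].astype(int).to_numpy()
    markers = [c for c in df.columns if c not in ("individual", "population")]
    codes = np.full((len(df), len(markers)), -1, dtype=np.int8)
    for k, pop in enumerate(population):
        a, b = design.parents_of(int(pop))
        legal = {f"{a}/{a}": 0, f"{a}/{b}": 1, f"{b}/{a}": 1, f"{b}/{b}": 2, "": -1}
        for j, m in enumerate(markers):
            cell = df.iloc[k][m]
            try:
                codes[k, j] = legal[cell]
            except KeyError:
                raise ValueError(
                    f"individual {individuals[k]!r} (population {pop}) carries "
                    f"allele pair {cell!r} at {m}, not derivable from parents "
                    f"({a}, {b})"
                ) from None
    return GenotypeMatrix(individuals, markers, codes, population, design)


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    geno.to_frame().to_csv(path, index=False)


def read_genes(path: str | Path) -> pd.DataFrame:
    """Candidate gene CSV: gene_id, chromosome, bp_start, bp_end [, class]."""
    genes = pd.read_csv(path)
    required = {"gene_id", "chromosome", "bp_start", "bp_end"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"gene list missing columns: {sorted(missing)}")
    if (genes["bp_end"] < genes["bp_start"]).any():
        raise ValueError("gene bp_end < bp_start")
    return genes


def read_weather(path: str | Path) -> pd.DataFrame:
    """Daily weather CSV: location, date, tmin, tmax."""
    wx = pd.read_csv(path, parse_dates=["date"])
    if (wx["tmax"] < wx["tmin"]).any():
        bad = wx[wx["tmax"] < wx["tmin"]].head()
        raise ValueError(f"tmax < tmin in weather series:\n{bad}")
    return wx


# ---------------------------------------------------------------------------
# Result bundles: one TSV per table plus a JSON run manifest.

def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                  config: RunConfig | None = None,
                  manifest_extra: dict | None = None) -> list[Path]:
    """Write each table as TSV plus a ``manifest.json`` describing the run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        p = out / f"{name}.tsv"
        table.to_csv(p, sep="\t", index=False, float_format="%.12g")
        written.append(p)
    manifest: dict = {"tables": sorted(tables)}
    if config is not None:
        manifest["config"] = {"seed": config.seed, "alpha": config.alpha,
                              "n_permutations": config.n_permutations,
                              "scan_step_cm": config.scan_step_cm,
                              "reference_location": config.reference_location}
    if manifest_extra:
        manifest.update(manifest_extra)
    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, default=str))
    written.append(mp)
    return written


def read_results(out_dir: str | Path) -> dict[str, pd.DataFrame]:
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    return {name: pd.read_csv(out / f"{name}.tsv", sep="\t")
            for name in manifest["tables"]}
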