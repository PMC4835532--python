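"""Shared fixtures: small synthetic datasets built once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from heatscan.config import RunConfig
from heatscan.core import CrossDesign
from heatscan.simulate import (TrialDesign, default_architecture,
                               default_cross_design, simulate_cross_genotypes,
                               simulate_map, simulate_trial)
from heatscan.pipeline import default_config


def small_map(n_chrom: int = 3, n_markers: int = 9, length: float = 100.0,
              mb: float = 150.0) -> pd.DataFrame:
    rows = []
    for c in range(1, n_chrom + 1):
        cms = np.linspace(0.0, length, n_markers)
        bps = np.linspace(1, mb * 1e6, n_markers).astype(int)
        for j, (cm, bp) in enumerate(zip(cms, bps)):
            rows.append({"marker": f"m{c}_{j + 1}", "chromosome": c,
                         "cm": float(cm), "bp": int(bp)})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def tiny_map() -> pd.DataFrame:
    return small_map()


@pytest.fixture(scope="session")
def cross_design() -> CrossDesign:
    return default_cross_design()


@pytest.fixture(scope="session")
def study_genotypes(cross_design):
    """Study-scale genotypes on the default 161-marker map."""
    gmap = simulate_map()
    rng = np.random.default_rng(20_001)
    geno = simulate_cross_genotypes(gmap, cross_design, rng=rng)
    return gmap, geno


@pytest.fixture(scope="session")
def small_trial(cross_design):
    """A compact trial (6 populations x 15 individuals, 4 locations) with
    its ground truth; used wherever paper scale is unnecessary."""
    gmap = small_map()
    rng = np.random.default_rng(20_002)
    geno = simulate_cross_genotypes(gmap, cross_design,
                                    pop_sizes=[15] * 6, rng=rng)
    arch = default_architecture()
    # move the planted loci onto the small map's chromosomes
    for q in arch.qtls:
        q.chromosome = (q.chromosome - 1) % 3 + 1
        q.position_cm = min(q.position_cm, 100.0)
    fb, truth = simulate_trial(geno, arch, TrialDesign(), rng, gmap)
    return {"gmap": gmap, "geno": geno, "fieldbook": fb, "truth": truth,
            "architecture": arch}


@pytest.fixture(scope="session")
def config() -> RunConfig:
    return default_config(seed=11)
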