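"""Candidate-gene projection onto the genetic map and QTL colocation.

Genes carry physical (bp) positions; the linkage map anchors markers in
both bp and cM, so a gene's genetic position is interpolated linearly
between the two markers flanking it in bp (extrapolated from the
terminal pair, flagged, when outside the mapped range).  A gene
colocates with a QTL when its projected position falls inside the
closed support interval on the same chromosome; overlapping intervals
across traits merge into hot-spot regions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .qtl import QTLRecord


def project_to_genetic(gene_bp: float, chromosome: int,
                       gmap: pd.DataFrame) -> tuple[float, bool]:
    """Genetic position (cM) of a physical position; returns
    (cM, extrapolated flag).

    Uses the two markers nearest in bp.  Marker pairs whose cM order
    disagrees with their bp order (possible in consensus maps) still
    interpolate between their cM values, clamped to the pair's range.
    """
    chrom = gmap[(gmap["chromosome"] == chromosome) & gmap["bp"].notna()]
    if len(chrom) < 2:
        raise ValueError(
            f"chromosome {chromosome} has {len(chrom)} marker(s) with bp; "
            "need >=2 for projection")
    chrom = chrom.sort_values("bp")
    bp = chrom["bp"].to_numpy(dtype=float)
    cm = chrom["cm"].to_numpy(dtype=float)

    exact = np.flatnonzero(bp == gene_bp)
    if exact.size:
        return float(cm[exact[0]]), False

    extrapolated = gene_bp < bp[0] or gene_bp > bp[-1]
    if gene_bp <= bp[0]:
        i, j = 0, 1
    elif gene_bp >= bp[-1]:
        i, j = len(bp) - 2, len(bp) - 1
    else:
        j = int(np.searchsorted(bp, gene_bp))
        i = j - 1
    frac = (gene_bp - bp[i]) / (bp[j] - bp[i])
    pos = cm[i] + frac * (cm[j] - cm[i])
    if cm[j] < cm[i]:
        warnings.warn(
            f"markers at bp {bp[i]:.0f}/{bp[j]:.0f} on chromosome "
            f"{chromosome} have inverted cM order; clamping")
    if not extrapolated:
        lo, hi = min(cm[i], cm[j]), max(cm[i], cm[j])
        pos = float(np.clip(pos, lo, hi))
    return float(pos), bool(extrapolated)


def project_genes(genes: pd.DataFrame, gmap: pd.DataFrame) -> pd.DataFrame:
    """Project every gene (interval midpoint) onto the genetic map."""
    out = genes.copy()
    if out.empty:
        out["cm"] = pd.Series(dtype=float)
        out["extrapolated"] = pd.Series(dtype=bool)
        return out
    mids = (out["bp_start"] + out["bp_end"]) / 2.0
    cms, flags = [], []
    for bp, chrom in zip(mids, out["chromosome"]):
        cm, ex = project_to_genetic(float(bp), int(chrom), gmap)
        cms.append(cm)
        flags.append(ex)
    out["cm"] = cms
    out["extrapolated"] = flags
    return out


def colocate(projected_genes: pd.DataFrame,
             qtls: list[QTLRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x QTL hits (closed-interval rule) and hot-spot regions.

    Hot spots are maximal unions of overlapping support intervals on a
    chromosome, listing every contributing locus.
    """
    hits = []
    for _, g in projected_genes.iterrows():
        for q in qtls:
            if int(g["chromosome"]) != q.chromosome:
                continue
            lo, hi = q.ci
            if lo <= g["cm"] <= hi:
                hits.append({"gene_id": g["gene_id"],
                             "chromosome": q.chromosome,
                             "gene_cm": float(g["cm"]),
                             "qtl": q.name, "trait": q.trait,
                             "ci_lo": lo, "ci_hi": hi,
                             "class": g.get("class", "")})
    hits_df = pd.DataFrame(hits, columns=["gene_id", "chromosome", "gene_cm",
                                          "qtl", "trait", "ci_lo", "ci_hi",
                                          "class"])

    hotspots = []
    by_chrom: dict[int, list[QTLRecord]] = {}
    for q in qtls:
        by_chrom.setdefault(q.chromosome, []).append(q)
    for chrom, qs in sorted(by_chrom.items()):
        qs = sorted(qs, key=lambda q: q.ci[0])
        cur_lo, cur_hi = qs[0].ci
        members = [qs[0].name]
        for q in qs[1:]:
            lo, hi = q.ci
            if lo <= cur_hi:  # closed-interval overlap
                cur_hi = max(cur_hi, hi)
                members.append(q.name)
            else:
                hotspots.append({"chromosome": chrom, "cm_start": cur_lo,
                                 "cm_end": cur_hi, "n_qtl": len(members),
                                 "members": ",".join(members)})
                cur_lo, cur_hi, members = lo, hi, [q.name]
        hotspots.append({"chromosome": chrom, "cm_start": cur_lo,
                         "cm_end": cur_hi, "n_qtl": len(members),
                         "members": ",".join(members)})
    hotspots_df = pd.DataFrame(hotspots, columns=["chromosome", "cm_start",
                                                  "cm_end", "n_qtl", "members"])
    return hits_df, hotspots_df
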