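"""Gene-set enrichment in candidate introgression regions.

A 2x2 chi-square test of independence between membership in a focal gene
set (e.g. hibernation-associated genes) and overlap with candidate
regions.  Overlap uses half-open semantics: at least one shared bp counts,
touching does not.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .io_core import IntroscanError, Region, RegionSet


@dataclass(frozen=True)
class GeneInterval:
    gene_id: str
    region: Region
    in_set: bool


def read_gene_bed(path, gene_set) -> list:
    """BED of gene intervals; names in ``gene_set`` are flagged in-set."""
    gene_set = set(gene_set)
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 else f"{parts[0]}:{parts[1]}"
            genes.append(GeneInterval(
                gene_id=name,
                region=Region(parts[0], int(parts[1]), int(parts[2])),
                in_set=name in gene_set,
            ))
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise IntroscanError("duplicate gene ids in BED")
    return genes


def genes_in_regions(genes, regions: RegionSet) -> pd.DataFrame:
    """Flag each gene that shares at least one bp with any region."""
    rows = [
        (g.gene_id, g.in_set, regions.overlaps_region(g.region)) for g in genes
    ]
    return pd.DataFrame(rows, columns=["gene_id", "in_set", "overlaps"])


def build_contingency(flagged: pd.DataFrame) -> np.ndarray:
    """2x2 counts: rows in-set / not-in-set, columns overlapping / not."""
    if len(flagged) == 0:
        raise IntroscanError("no genes supplied")
    a = int((flagged["in_set"] & flagged["overlaps"]).sum())
    b = int((flagged["in_set"] & ~flagged["overlaps"]).sum())
    c = int((~flagged["in_set"] & flagged["overlaps"]).sum())
    d = int((~flagged["in_set"] & ~flagged["overlaps"]).sum())
    return np.array([[a, b], [c, d]], dtype=np.int64)


def chi_square_tail(chi2, df=1) -> float:
    """Upper-tail probability of the chi-square distribution."""
    if chi2 < 0 or df < 1:
        raise IntroscanError("need chi2 >= 0 and df >= 1")
    return float(chi2_dist.sf(chi2, df=df))


def chi_square_2x2(table, continuity_correction=False):
    """Chi-square test of independence on a 2x2 table, df = 1.

    Returns ``(chi2, p)``.  No continuity correction by default; with
    Yates' correction |ad - bc| is reduced by N/2 before squaring.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise IntroscanError("need a 2x2 table of non-negative counts")
    a, b = t[0]
    c, d = t[1]
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if n <= 0 or any(m == 0 for m in margins):
        raise IntroscanError("chi-square test undefined: zero margin")
    delta = abs(a * d - b * c)
    if continuity_correction:
        delta = max(delta - n / 2.0, 0.0)
    chi2 = n * delta ** 2 / np.prod(margins)
    p = float(chi2_dist.sf(chi2, df=1))
    return float(chi2), p


def enrichment_test(genes, regions: RegionSet, continuity_correction=False) -> dict:
    """Full pipeline: overlap flags -> contingency -> chi-square, with the
    direction of the deviation (excess or deficit of in-set overlaps)."""
    flagged = genes_in_regions(genes, regions)
    table = build_contingency(flagged)
    chi2, p = chi_square_2x2(table, continuity_correction)
    a, b = table[0]
    c, d = table[1]
    expected_a = (a + b) * (a + c) / table.sum()
    direction = "excess" if a > expected_a else ("deficit" if a < expected_a else "none")
    return {
        "table": table,
        "chi2": chi2,
        "p": p,
        "df": 1,
        "direction": direction,
        "n_in_set_overlapping": int(a),
    }
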