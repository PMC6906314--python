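"""Genome-wide Patterson's D from derived-allele frequencies.

D = (sum ABBA - sum BABA) / (sum ABBA + sum BABA) with frequency-weighted
site patterns, and a delete-one block jackknife over contiguous genomic
blocks for the standard error and Z score.  The frequency form is exact
for single diploids and deterministic, unlike single-read sampling.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import IntroscanError, PolarizedSiteTable


@dataclass
class PatternCounts:
    sum_abba: float
    sum_baba: float
    n_sites: int


@dataclass
class DStatResult:
    D: float
    SE: float
    Z: float
    n_blocks: int
    pop_labels: tuple
    counts: PatternCounts
    se_zero: bool = False


def site_pattern_weights(p1, p2, p3, p4):
    """Frequency-weighted ABBA and BABA contributions of one site."""
    for p in (p1, p2, p3, p4):
        if not 0.0 <= p <= 1.0:
            raise IntroscanError(f"allele frequency {p} outside [0, 1]")
    abba = (1.0 - p1) * p2 * p3 * (1.0 - p4)
    baba = p1 * (1.0 - p2) * p3 * (1.0 - p4)
    return abba, baba


def _weights(freqs):
    """Vectorized ABBA/BABA weights for an (n, 4) frequency array."""
    p1, p2, p3, p4 = freqs.T
    abba = (1.0 - p1) * p2 * p3 * (1.0 - p4)
    baba = p1 * (1.0 - p2) * p3 * (1.0 - p4)
    return abba, baba


def _freq_columns(table: PolarizedSiteTable, order):
    cols = []
    for name in order:
        if name == table.outgroup:
            cols.append(np.zeros(table.n_sites))
        else:
            cols.append(table.freq[:, table.pop_index(name)])
    return np.column_stack(cols) if table.n_sites else np.empty((0, 4))


def patterson_d(table: PolarizedSiteTable, order):
    """Genome-wide D for population order (P1, P2, P3, O).

    Returns ``(PatternCounts, D)``; D is NaN when no site carries pattern
    weight.  Sites where P3 carries no derived allele contribute zero
    weight and are not counted.
    """
    if table.n_sites == 0:
        raise IntroscanError("empty polarized table")
    if len(order) != 4:
        raise IntroscanError("order must name exactly (P1, P2, P3, O)")
    freqs = _freq_columns(table, order)
    abba, baba = _weights(freqs)
    informative = freqs[:, 2] > 0
    counts = PatternCounts(
        sum_abba=float(abba.sum()),
        sum_baba=float(baba.sum()),
        n_sites=int(informative.sum()),
    )
    denom = counts.sum_abba + counts.sum_baba
    d = (counts.sum_abba - counts.sum_baba) / denom if denom > 0 else float("nan")
    return counts, d


def jackknife_z(table: PolarizedSiteTable, order, block_span_bp=1_000_000,
                min_blocks=20) -> DStatResult:
    """Block-jackknife standard error and Z for genome-wide D.

    The genome is cut into contiguous blocks of ``block_span_bp`` per
    scaffold; SE is the delete-one jackknife estimate
    ``sqrt((m-1)/m * sum((D_-i - mean)^2))`` over the ``m`` non-empty
    blocks.  A block is non-empty when it contains at least one site with
    a derived allele in P3.
    """
    counts, d = patterson_d(table, order)
    freqs = _freq_columns(table, order)
    abba, baba = _weights(freqs)
    informative = freqs[:, 2] > 0

    block_key = table.scaffold_idx.astype(np.int64) * (1 << 33) + table.pos // block_span_bp
    uniq, inv = np.unique(block_key[informative], return_inverse=True)
    m = len(uniq)
    if m < min_blocks:
        raise IntroscanError(
            f"only {m} non-empty jackknife blocks (< {min_blocks}); "
            "supply more sequence or a smaller block span"
        )
    a_blk = np.bincount(inv, weights=abba[informative], minlength=m)
    b_blk = np.bincount(inv, weights=baba[informative], minlength=m)
    A, B = a_blk.sum(), b_blk.sum()
    num = (A - B) - (a_blk - b_blk)
    den = (A + B) - (a_blk + b_blk)
    with np.errstate(invalid="ignore", divide="ignore"):
        d_del = np.where(den > 0, num / den, 0.0)
    se = float(np.sqrt((m - 1) / m * np.sum((d_del - d_del.mean()) ** 2)))
    if se == 0.0:
        z = math_inf_signed(d)
        return DStatResult(d, se, z, m, tuple(order), counts, se_zero=True)
    return DStatResult(d, se, d / se, m, tuple(order), counts)


def math_inf_signed(d):
    if d > 0:
        return float("inf")
    if d < 0:
        return float("-inf")
    return 0.0
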