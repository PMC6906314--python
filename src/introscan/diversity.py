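"""Sliding-window heterozygosity per individual.

Heterozygosity in a window is the count of heterozygous genotype calls
divided by the callable window span (window size minus missing genotype
calls); invariant positions absent from the VCF are assumed genotyped
homozygous-reference.  Windows are non-overlapping by default so that the
genome mean does not double-count sequence; a smaller step yields
overlapping (sliding) windows.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .io_core import ConfigError, GenotypeTable, IntroscanError


def window_heterozygosity(table: GenotypeTable, sample, win=100_000, step=None,
                          joint_missing=False) -> pd.DataFrame:
    """Per-window heterozygosity for one sample.

    ``joint_missing=True`` counts a site as missing when any sample lacks a
    call (the cross-species rule); the default counts only the focal
    sample's missing calls.  Windows with no callable span are flagged
    undefined (het = NaN).
    """
    if win <= 0:
        raise ConfigError("window span must be > 0")
    step = step or win
    if step <= 0:
        raise ConfigError("step must be > 0")
    j = table.sample_index(sample)
    het_site = (table.gt[:, j] == 1).astype(float)
    if joint_missing:
        miss_site = np.any(table.gt == -1, axis=1).astype(float)
    else:
        miss_site = (table.gt[:, j] == -1).astype(float)
    het_site[miss_site > 0] = 0.0

    rows = []
    for si, scaf in enumerate(table.scaffolds):
        L = table.scaffold_lengths[scaf]
        sel = table.scaffold_idx == si
        pos = table.pos[sel]
        h = np.concatenate([[0.0], np.cumsum(het_site[sel])])
        m = np.concatenate([[0.0], np.cumsum(miss_site[sel])])
        starts = np.arange(0, L, step, dtype=np.int64)
        ends = np.minimum(starts + win, L)
        lo = np.searchsorted(pos, starts)
        hi = np.searchsorted(pos, ends)
        n_het = h[hi] - h[lo]
        n_missing = m[hi] - m[lo]
        span = ends - starts
        callable_ = span - n_missing
        with np.errstate(invalid="ignore", divide="ignore"):
            het = np.where(callable_ > 0, n_het / np.maximum(callable_, 1), np.nan)
        rows.append(pd.DataFrame({
            "scaffold": scaf,
            "start": starts,
            "end": ends,
            "n_het": n_het.astype(np.int64),
            "n_missing": n_missing.astype(np.int64),
            "het": het,
            "defined": callable_ > 0,
        }))
    return pd.concat(rows, ignore_index=True)


def genome_mean_het(windows: pd.DataFrame):
    """Mean of defined windows' het, and the pooled genome-wide estimate.

    The pooled value is sum(n_het) / sum(span - n_missing) over defined
    windows and is invariant to window size.
    """
    ok = windows.loc[windows["defined"]]
    if len(ok) == 0:
        raise IntroscanError("no window with callable sequence")
    span = (ok["end"] - ok["start"]).to_numpy(float)
    pooled = ok["n_het"].sum() / (span.sum() - ok["n_missing"].sum())
    return float(ok["het"].mean()), float(pooled)
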