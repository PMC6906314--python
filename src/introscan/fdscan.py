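"""Windowed f_d admixture-proportion scan and candidate-region calling.

f_d (Martin et al.'s dynamic-donor estimator) normalizes the per-window
ABBA-BABA excess by its value under complete introgression, using
pD = max(p2, p3) site-wise as the donor frequency.  Candidate regions are
the windows in the upper tail of the genome-wide f_d distribution, merged
and clipped to scaffold ends.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import (
    ConfigError,
    IntroscanError,
    PolarizedSiteTable,
    Region,
    RegionSet,
    SiteMask,
    clip_to_scaffold,
    merge_regions,
)
from .dstat import _freq_columns


@dataclass
class CandidateSet:
    """Top-quantile f_d windows and the merged candidate regions."""

    cutoff_value: float
    regions: RegionSet
    windows: pd.DataFrame


def fd_site_terms(p1, p2, p3, p4):
    """Per-site numerator and denominator contributions to f_d."""
    for p in (p1, p2, p3, p4):
        if not 0.0 <= p <= 1.0:
            raise IntroscanError(f"allele frequency {p} outside [0, 1]")
    pd_ = max(p2, p3)
    num = (1 - p1) * p2 * p3 * (1 - p4) - p1 * (1 - p2) * p3 * (1 - p4)
    den = (1 - p1) * pd_ * pd_ * (1 - p4) - p1 * (1 - pd_) * pd_ * (1 - p4)
    return num, den


def _site_terms_arrays(freqs):
    p1, p2, p3, p4 = freqs.T
    pd_ = np.maximum(p2, p3)
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    num = abba - baba
    den = (1 - p1) * pd_ * pd_ * (1 - p4) - p1 * (1 - pd_) * pd_ * (1 - p4)
    return num, den, abba, baba


def window_fd(table: PolarizedSiteTable, order, win=40_000, step=10_000,
              scaffold_lengths=None) -> pd.DataFrame:
    """Sliding-window f_d over each scaffold.

    Windows of ``win`` bp advance by ``step`` bp; each row carries the SNP
    count, the window's own D, and f_d = sum(num)/sum(den) over the same
    sites.  Windows with non-positive window D or zero denominator get
    f_d = 0 with ``fd_defined = False``; windows with no SNPs are omitted.
    """
    if win <= 0 or step <= 0 or win < step:
        raise ConfigError(f"need win >= step > 0 (got win={win}, step={step})")
    lengths = scaffold_lengths or table.scaffold_lengths
    freqs = _freq_columns(table, order)
    num, den, abba, baba = _site_terms_arrays(freqs)

    rows = []
    for si, scaf in enumerate(table.scaffolds):
        if scaf not in lengths:
            continue
        L = lengths[scaf]
        sel = table.scaffold_idx == si
        if not sel.any():
            continue
        pos = table.pos[sel]
        cs = {
            k: np.concatenate([[0.0], np.cumsum(v[sel])])
            for k, v in (("num", num), ("den", den), ("abba", abba), ("baba", baba))
        }
        starts = np.arange(0, L, step, dtype=np.int64)
        ends = np.minimum(starts + win, L)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        n_snps = hi - lo
        keep = n_snps > 0
        if not keep.any():
            continue
        w_num = cs["num"][hi] - cs["num"][lo]
        w_den = cs["den"][hi] - cs["den"][lo]
        w_abba = cs["abba"][hi] - cs["abba"][lo]
        w_baba = cs["baba"][hi] - cs["baba"][lo]
        d_denom = w_abba + w_baba
        with np.errstate(invalid="ignore", divide="ignore"):
            w_d = np.where(d_denom > 0, (w_abba - w_baba) / d_denom, 0.0)
        defined = (w_d > 0) & (w_den > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            fd = np.where(defined, w_num / np.where(w_den > 0, w_den, 1.0), 0.0)
        rows.append(pd.DataFrame({
            "scaffold": scaf,
            "start": starts[keep],
            "end": ends[keep],
            "n_snps": n_snps[keep],
            "sum_num": w_num[keep],
            "sum_den": w_den[keep],
            "window_D": w_d[keep],
            "fd": fd[keep],
            "fd_defined": defined[keep],
            "masked": False,
        }))
    if not rows:
        return pd.DataFrame(columns=[
            "scaffold", "start", "end", "n_snps", "sum_num", "sum_den",
            "window_D", "fd", "fd_defined", "masked",
        ])
    return pd.concat(rows, ignore_index=True)


def apply_window_mask(windows: pd.DataFrame, mask: SiteMask,
                      max_fail_frac=0.30) -> pd.DataFrame:
    """Mask windows where more than ``max_fail_frac`` of assayed sites fail.

    The fraction is taken over the coverage-assayed sites falling in the
    window; exactly the threshold fraction is kept ("more than").  Windows
    with no assayed sites are left unmasked.
    """
    windows = windows.copy()
    frac = np.zeros(len(windows))
    scaf_to_idx = {s: i for i, s in enumerate(mask.scaffolds)}
    for scaf, grp in windows.groupby("scaffold", sort=False):
        si = scaf_to_idx.get(scaf)
        if si is None:
            continue
        sel = mask.scaffold_idx == si
        pos = mask.pos[sel]
        fail = np.concatenate([[0.0], np.cumsum(mask.fail[sel].astype(float))])
        lo = np.searchsorted(pos, grp["start"].to_numpy())
        hi = np.searchsorted(pos, grp["end"].to_numpy())
        n = hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n > 0, (fail[hi] - fail[lo]) / np.maximum(n, 1), 0.0)
        frac[grp.index] = f
    windows["fail_frac"] = frac
    windows["masked"] = frac > max_fail_frac
    return windows


def call_candidates(windows: pd.DataFrame, quantile=0.9995,
                    scaffold_lengths=None) -> CandidateSet:
    """Call candidate introgression regions from the f_d upper tail.

    The cutoff is the ``quantile``-quantile of unmasked windows' f_d over
    the whole genome jointly; all windows at or above the cutoff (ties
    kept) are merged and clipped to scaffold ends.
    """
    unmasked = windows.loc[~windows["masked"]]
    if len(unmasked) == 0:
        raise IntroscanError("all windows are masked; cannot call candidates")
    if len(unmasked) < 2000:
        warnings.warn(
            f"only {len(unmasked)} unmasked windows; the {quantile:.4%} quantile "
            "cutoff is poorly determined"
        )
    cutoff = float(np.quantile(unmasked["fd"].to_numpy(), quantile))
    selected = unmasked.loc[unmasked["fd"] >= cutoff]
    regions = []
    for _, row in selected.iterrows():
        reg = Region(row["scaffold"], int(row["start"]), int(row["end"]))
        if scaffold_lengths and reg.scaffold in scaffold_lengths:
            reg = clip_to_scaffold(reg, scaffold_lengths[reg.scaffold])
            if reg is None:
                continue
        regions.append(reg)
    return CandidateSet(
        cutoff_value=cutoff,
        regions=merge_regions(regions),
        windows=selected.reset_index(drop=True),
    )
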