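"""Triplet-based detection, filtering and molecular-clock dating of
introgressed blocks.

Three aligned consensus sequences are scanned in windows of a fixed number
of segregating sites; runs of consecutive windows in which the same
non-background pair is the most similar are fused into candidate blocks.
Blocks are then refined, assigned a binomial p-value for unusually low
pair divergence against the genome-wide background, filtered (minimum SNP
count, maximum p, sister pairs removed), and dated with a strict
divergence clock: age_years = divergence / (2 * mu_year).

Sequences are diploid consensi; an IUPAC-ambiguous position counts as half
a difference against a base contained in its allele set, a full difference
against a disjoint set, and zero against the identical code.  ``N`` (or
any non-IUPAC byte) masks the position entirely.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.stats import binom

from .io_core import IntroscanError, Region, RegionSet, merge_regions, intersect_regions

_IUPAC_SETS = {
    b"A": {0}, b"C": {1}, b"G": {2}, b"T": {3},
    b"M": {0, 1}, b"R": {0, 2}, b"W": {0, 3},
    b"S": {1, 2}, b"Y": {1, 3}, b"K": {2, 3},
}


def _diff_table():
    """256x256 lookup of per-site difference (NaN = masked)."""
    tab = np.full((256, 256), np.nan, dtype=np.float32)
    for a, sa in _IUPAC_SETS.items():
        for b, sb in _IUPAC_SETS.items():
            if sa == sb:
                v = 0.0
            elif sa & sb:
                v = 0.5
            else:
                v = 1.0
            tab[a[0], b[0]] = v
    return tab


_DIFF = _diff_table()


def pair_differences(seq_a: np.ndarray, seq_b: np.ndarray) -> np.ndarray:
    """Per-position difference between two byte sequences (NaN where masked)."""
    if len(seq_a) != len(seq_b):
        raise IntroscanError("sequences must be the same length")
    a = seq_a.view(np.uint8)
    b = seq_b.view(np.uint8)
    return _DIFF[a, b]


@dataclass
class TripletScanParams:
    """Tunables of the triplet block scan."""

    snp_window: int = 100     # segregating sites per scan window
    step_snps: int = 50
    min_snps: int = 10
    max_p: float = 1e-6
    mu_year: float = 0.2e-8
    refine: bool = True       # trim block edges to the maximum-scoring subsegment

    def __post_init__(self):
        if self.min_snps < 1:
            raise IntroscanError("min_snps must be >= 1")
        if not 0 < self.max_p < 1:
            raise IntroscanError("max_p must be in (0, 1)")


@dataclass
class Block:
    """A candidate introgressed tract between one sequence pair of a triplet."""

    triplet: tuple
    pair: tuple
    region: Region
    n_snps_in_block: int
    pair_diffs: float
    block_len: int
    divergence: float
    p_value: float
    age_years: float


def block_p_value(pair_diffs, block_len, background_divergence) -> float:
    """P(X <= pair_diffs) for X ~ Binomial(block_len, background_divergence)."""
    if not 0 <= pair_diffs <= block_len:
        raise IntroscanError("pair_diffs must lie in [0, block_len]")
    if not 0 < background_divergence < 1:
        raise IntroscanError("degenerate background divergence")
    return float(binom.cdf(int(np.floor(pair_diffs)), block_len, background_divergence))


def date_block(pair_diffs, block_len, mu_year=0.2e-8) -> float:
    """Divergence-clock age in years: (diffs / len) / (2 * mu_year)."""
    if block_len <= 0:
        raise IntroscanError("block_len must be > 0")
    return (pair_diffs / block_len) / (2.0 * mu_year)


def _kadane_bounds(score: np.ndarray):
    """Start/end (half-open) of the maximum-sum contiguous subarray."""
    best, best_lo, best_hi = -np.inf, 0, 1
    cur, cur_lo = 0.0, 0
    for i, x in enumerate(score):
        if cur <= 0:
            cur, cur_lo = x, i
        else:
            cur += x
        if cur > best:
            best, best_lo, best_hi = cur, cur_lo, i + 1
    return best_lo, best_hi


def scan_triplet(sequences: dict, params: TripletScanParams = None,
                 scaffold: str = "scaffold_1", background_pair=None) -> list:
    """Candidate blocks for one triplet of aligned equal-length sequences.

    ``sequences`` maps three labels to equal-length byte arrays (dtype S1
    or uint8).  Windows of ``snp_window`` segregating sites advance by
    ``step_snps`` sites; in each window the most similar pair is found, and
    maximal runs of the same winning non-background pair become candidate
    blocks.  The background pair — never eligible for blocks — is the
    triplet's sister pair when given explicitly (``background_pair``), else
    the genome-wide most similar pair.  Block statistics (diffs, length, p, age) are measured over callable
    positions only, against the per-pair background divergence computed
    outside all candidate blocks.
    """
    params = params or TripletScanParams()
    labels = list(sequences)
    if len(labels) != 3:
        raise IntroscanError("scan_triplet needs exactly three sequences")
    arrs = [np.asarray(sequences[l]).view(np.uint8) for l in labels]
    if len({len(a) for a in arrs}) != 1:
        raise IntroscanError("sequences must be the same length")

    pairs = [(0, 1), (0, 2), (1, 2)]
    diffs = [_DIFF[arrs[i], arrs[j]] for i, j in pairs]
    callable_ = ~np.isnan(diffs[0]) & ~np.isnan(diffs[1]) & ~np.isnan(diffs[2])
    seg_mask = callable_ & (
        (np.nan_to_num(diffs[0]) > 0)
        | (np.nan_to_num(diffs[1]) > 0)
        | (np.nan_to_num(diffs[2]) > 0)
    )
    seg_pos = np.flatnonzero(seg_mask)
    n_seg = len(seg_pos)
    if n_seg < params.snp_window:
        return []

    seg_diffs = np.vstack([d[seg_pos] for d in diffs])  # (3, n_seg)
    if background_pair is not None:
        want = frozenset(background_pair)
        matches = [k for k, (i, j) in enumerate(pairs)
                   if frozenset((labels[i], labels[j])) == want]
        if not matches:
            raise IntroscanError(f"background pair {background_pair} not in triplet")
        background_pair_idx = matches[0]
    else:
        total = seg_diffs.sum(axis=1)
        background_pair_idx = int(np.argmin(total))

    w, s = params.snp_window, params.step_snps
    starts = np.arange(0, n_seg - w + 1, s)
    cs = np.concatenate([np.zeros((3, 1)), np.cumsum(seg_diffs, axis=1)], axis=1)
    win_sums = cs[:, starts + w] - cs[:, starts]  # (3, n_windows)
    order = np.argsort(win_sums, axis=0)
    winner = order[0]
    strict = win_sums[order[0], np.arange(len(starts))] < win_sums[
        order[1], np.arange(len(starts))
    ]
    winner = np.where(strict, winner, -1)

    # fuse runs of the same winning non-background pair
    raw = []
    run_pair, run_lo = None, None
    for wi in range(len(starts)):
        p = winner[wi]
        if p == run_pair and p not in (-1, background_pair_idx):
            run_hi = wi
            continue
        if run_pair not in (None, -1, background_pair_idx):
            raw.append((run_pair, run_lo, run_hi))
        run_pair, run_lo, run_hi = p, wi, wi
    if run_pair not in (None, -1, background_pair_idx):
        raw.append((run_pair, run_lo, run_hi))

    # provisional spans in sequence coordinates
    spans = []
    for pidx, lo_w, hi_w in raw:
        lo = int(seg_pos[starts[lo_w]])
        hi = int(seg_pos[min(starts[hi_w] + w - 1, n_seg - 1)]) + 1
        spans.append((pidx, lo, hi))

    # background divergence per pair, excluding provisional spans
    excl = np.zeros(len(callable_), dtype=bool)
    for _, lo, hi in spans:
        excl[lo:hi] = True
    bg_sel = callable_ & ~excl
    bg_div = []
    for k in range(3):
        n_call = int(bg_sel.sum())
        bg_div.append(float(np.nansum(diffs[k][bg_sel]) / n_call) if n_call else np.nan)

    seg_cum = np.concatenate([[0], np.cumsum(seg_mask.astype(np.int64))])
    call_cum = np.concatenate([[0], np.cumsum(callable_.astype(np.int64))])
    diff_cums = [
        np.concatenate([[0.0], np.cumsum(np.where(callable_, np.nan_to_num(d), 0.0))])
        for d in diffs
    ]

    blocks = []
    for pidx, lo, hi in spans:
        bg = bg_div[pidx]
        if not (bg and 0 < bg < 1):
            continue
        if params.refine:
            # maximum-likelihood boundary refinement under a two-rate model:
            # per-site log-likelihood ratio of block divergence vs background,
            # maximised over contiguous subsegments (Kadane)
            idx = np.flatnonzero(callable_[lo:hi]) + lo
            if len(idx) == 0:
                continue
            x = np.nan_to_num(diffs[pidx][idx])
            p_t = min(max(x.mean(), 1e-9), bg * 0.999)
            score = x * np.log(p_t / bg) + (1.0 - x) * np.log((1 - p_t) / (1 - bg))
            klo, khi = _kadane_bounds(score)
            lo, hi = int(idx[klo]), int(idx[khi - 1]) + 1
        block_len = int(call_cum[hi] - call_cum[lo])
        if block_len == 0:
            continue
        pair_diffs = float(diff_cums[pidx][hi] - diff_cums[pidx][lo])
        n_snps = int(seg_cum[hi] - seg_cum[lo])
        divergence = pair_diffs / block_len
        i, j = pairs[pidx]
        blocks.append(Block(
            triplet=tuple(labels),
            pair=(labels[i], labels[j]),
            region=Region(scaffold, lo, hi),
            n_snps_in_block=n_snps,
            pair_diffs=pair_diffs,
            block_len=block_len,
            divergence=divergence,
            p_value=block_p_value(pair_diffs, block_len, bg),
            age_years=date_block(pair_diffs, block_len, params.mu_year),
        ))
    return blocks


def filter_blocks(blocks, params: TripletScanParams, species_tree) -> list:
    """Apply the retention filters: SNP count, p-value, and sister-pair removal."""
    out = []
    for b in blocks:
        sister = frozenset(species_tree.sister_pair(b.triplet))
        if frozenset(b.pair) == sister:
            continue
        if b.n_snps_in_block < params.min_snps:
            continue
        if not b.p_value < params.max_p:
            continue
        out.append(b)
    return out


def summarize_blocks(blocks, fd_candidates: RegionSet = None) -> dict:
    """Per-pair counts, mean lengths and ages, plus overlap accounting
    against f_d candidate regions (regions hit and discrete sections)."""
    per_pair = {}
    for b in blocks:
        key = tuple(sorted(b.pair))
        per_pair.setdefault(key, []).append(b)
    summary = {
        "n_blocks": len(blocks),
        "pairs": {
            "/".join(k): {
                "n_blocks": len(v),
                "mean_length_bp": float(np.mean([b.region.length for b in v])),
                "mean_age_years": float(np.mean([b.age_years for b in v])),
            }
            for k, v in per_pair.items()
        },
    }
    if fd_candidates is not None:
        block_regions = merge_regions(b.region for b in blocks)
        _, n_hit, n_sections = intersect_regions(fd_candidates, block_regions)
        summary["n_fd_regions_hit"] = n_hit
        summary["n_sections"] = n_sections
    return summary


def read_fasta_sequences(path) -> dict:
    """Load a FASTA of scaffolds into byte arrays (uppercased)."""
    from Bio import SeqIO

    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = np.frombuffer(str(rec.seq).upper().encode(), dtype="S1").copy()
    return out
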