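"""Windowed quartet-topology segmentation.

A transparent surrogate for HMM-based local-phylogeny segmentation: each
genomic window is classified by the neighbour-joining quartet topology of
an allele-sharing p-distance matrix over four individuals, runs of the
same label are fused into segments, and genome fractions per label are
reported.  For four taxa the NJ split is simply the pairing {i,j},{k,l}
minimizing d(i,j) + d(k,l) (the four-point condition); ties or windows
with too few SNPs are unresolved ("U").

Labels: T1 is the split concordant with the species tree; T2 and T3 are
the two discordant splits, ordered by the partner of the first-listed
taxon.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .io_core import GenotypeTable, IntroscanError

_SPLITS = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]


def window_distance_matrix(freqs: np.ndarray, min_snps=50):
    """Allele-sharing p-distance matrix from an (n_sites, 4) frequency array.

    d_ij is the mean over sites of |f_i - f_j| with f in {0, 0.5, 1}.
    Returns ``None`` when fewer than ``min_snps`` sites are available.
    """
    if freqs.shape[0] < min_snps:
        return None
    d = np.zeros((4, 4))
    for i in range(4):
        for j in range(i + 1, 4):
            d[i, j] = d[j, i] = float(np.mean(np.abs(freqs[:, i] - freqs[:, j])))
    return d


def nj_quartet(distances, tol=1e-12):
    """Index of the winning split (0, 1 or 2 into the three pairings), or
    ``None`` on a tie — four-taxon neighbour joining."""
    sums = []
    for (i, j), (k, l) in _SPLITS:
        sums.append(distances[i, j] + distances[k, l])
    order = np.argsort(sums)
    if sums[order[1]] - sums[order[0]] <= tol:
        return None
    return int(order[0])


def _split_labels(taxa, species_tree):
    """Map split index -> T1/T2/T3 with T1 the species-tree-concordant split."""
    times = {}
    for si, ((i, j), (k, l)) in enumerate(_SPLITS):
        times[si] = min(
            species_tree.divergence_time(taxa[i], taxa[j]),
            species_tree.divergence_time(taxa[k], taxa[l]),
        )
    concordant = min(times, key=times.get)
    others = sorted(s for s in range(3) if s != concordant)
    labels = {concordant: "T1", others[0]: "T2", others[1]: "T3"}
    return labels


def classify_windows(table: GenotypeTable, taxa, species_tree, win=100_000,
                     min_snps=50) -> pd.DataFrame:
    """Label non-overlapping windows by their NJ quartet topology."""
    if len(taxa) != 4:
        raise IntroscanError("need exactly four taxa")
    cols = [table.sample_index(t) for t in taxa]
    gt = table.gt[:, cols]
    ok = np.all(gt != -1, axis=1)
    labels = _split_labels(taxa, species_tree)

    rows = []
    for si, scaf in enumerate(table.scaffolds):
        L = table.scaffold_lengths[scaf]
        sel = (table.scaffold_idx == si) & ok
        pos = table.pos[sel]
        freqs = gt[sel].astype(float) / 2.0
        starts = np.arange(0, L, win, dtype=np.int64)
        ends = np.minimum(starts + win, L)
        lo = np.searchsorted(pos, starts)
        hi = np.searchsorted(pos, ends)
        for a, b, st, en in zip(lo, hi, starts, ends):
            d = window_distance_matrix(freqs[a:b], min_snps=min_snps)
            if d is None:
                lab = "U"
            else:
                split = nj_quartet(d)
                lab = "U" if split is None else labels[split]
            rows.append((scaf, int(st), int(en), int(b - a), lab))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "n_snps", "label"])


def segment_topologies(window_labels: pd.DataFrame):
    """Fuse runs of same-label windows into segments; report genome fractions.

    Fractions (over {T1, T2, T3, U}) are window-count based and sum to 1.
    """
    segs = []
    for scaf, grp in window_labels.groupby("scaffold", sort=False):
        grp = grp.sort_values("start")
        cur = None
        for _, row in grp.iterrows():
            if cur is not None and row["label"] == cur["label"] and row["start"] == cur["end"]:
                cur["end"] = row["end"]
                cur["n_windows"] += 1
            else:
                if cur is not None:
                    segs.append(cur)
                cur = {
                    "scaffold": scaf, "start": row["start"], "end": row["end"],
                    "label": row["label"], "n_windows": 1,
                }
        if cur is not None:
            segs.append(cur)
    segments = pd.DataFrame(segs, columns=["scaffold", "start", "end", "label", "n_windows"])
    n = len(window_labels)
    fractions = {
        lab: float((window_labels["label"] == lab).sum() / n) if n else 0.0
        for lab in ("T1", "T2", "T3", "U")
    }
    return segments, fractions
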