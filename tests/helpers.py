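"""Shared builders and brute-force oracles for the test suite."""
import numpy as np

from introscan.io_core import GenotypeTable, PolarizedSiteTable, Region


def make_polarized(sites, populations=("P1", "P2", "P3"), outgroup="O",
                   scaffolds=("s1",), scaffold_length=10_000_000):
    """Polarized table from [(scaffold_idx, pos, (f1, f2, ...)), ...]."""
    sites = sorted(sites, key=lambda x: (x[0], x[1]))
    return PolarizedSiteTable(
        populations=list(populations),
        outgroup=outgroup,
        scaffolds=list(scaffolds),
        scaffold_lengths={s: scaffold_length for s in scaffolds},
        scaffold_idx=np.array([s[0] for s in sites], dtype=np.int32),
        pos=np.array([s[1] for s in sites], dtype=np.int64),
        freq=(np.array([s[2] for s in sites], dtype=float)
              if sites else np.empty((0, len(populations)))),
    )


def make_genotypes(sites, samples, scaffolds=("s1",), scaffold_length=1_000_000):
    """Genotype table from [(scaffold_idx, pos, (gt per sample)), ...]."""
    sites = sorted(sites, key=lambda x: (x[0], x[1]))
    n = len(sites)
    return GenotypeTable(
        samples=list(samples),
        scaffolds=list(scaffolds),
        scaffold_lengths={s: scaffold_length for s in scaffolds},
        scaffold_idx=np.array([s[0] for s in sites], dtype=np.int32),
        pos=np.array([s[1] for s in sites], dtype=np.int64),
        ref=np.full(n, "A", dtype="U1"),
        alt=np.full(n, "T", dtype="U1"),
        gt=np.array([s[2] for s in sites], dtype=np.int8).reshape(n, -1),
    )


def brute_union(regions, length):
    """Per-base boolean union of intervals on a single scaffold."""
    cov = np.zeros(length, dtype=bool)
    for r in regions:
        cov[r.start:min(r.end, length)] = True
    return cov


def bool_to_regions(cov, scaffold="s1"):
    """Back-convert a per-base boolean track to half-open intervals."""
    out = []
    padded = np.concatenate([[False], cov, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    for a, b in zip(starts, ends):
        out.append(Region(scaffold, int(a), int(b)))
    return out


def random_regions(rng, n, length, scaffold="s1"):
    out = []
    for _ in range(n):
        a = int(rng.integers(0, length - 1))
        b = int(rng.integers(a + 1, min(a + 1 + length // 5, length) + 1))
        out.append(Region(scaffold, a, min(b, length)))
    return out
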