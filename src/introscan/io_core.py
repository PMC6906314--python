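"""Format readers, allele polarization, coverage masks and interval arithmetic.

All genomic coordinates are 0-based half-open internally.  VCF positions
(1-based) are converted at the boundary; BED coordinates pass through
natively.  The interval primitives here (:func:`merge_regions`,
:func:`intersect_regions`, :func:`clip_to_scaffold`) are the single source
of coordinate arithmetic for every downstream module.
"""
from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


class IntroscanError(Exception):
    """Base class for errors raised by introscan."""


class ConfigError(IntroscanError):
    """Invalid parameter or configuration value."""


# ---------------------------------------------------------------------------
# Intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Region:
    """Half-open genomic interval ``[start, end)`` on a named scaffold."""

    scaffold: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ConfigError(
                f"invalid region {self.scaffold}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start < other.end
            and other.start < self.end
        )


class RegionSet:
    """Sorted set of non-overlapping, non-touching regions.

    Construction merges the input (overlapping-or-touching intervals are
    unioned), so a ``RegionSet`` is always in canonical form and the merge
    operation is idempotent.
    """

    def __init__(self, regions=()):
        self.regions = _merge(list(regions))

    def __len__(self):
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __eq__(self, other):
        return isinstance(other, RegionSet) and self.regions == other.regions

    def __repr__(self):
        return f"RegionSet({len(self.regions)} regions, {self.total_span} bp)"

    @property
    def total_span(self) -> int:
        return sum(r.length for r in self.regions)

    def overlaps_region(self, region: Region) -> bool:
        """True if ``region`` shares at least one bp with the set."""
        same = [r for r in self.regions if r.scaffold == region.scaffold]
        starts = [r.start for r in same]
        i = bisect_right(starts, region.start)
        for r in same[max(i - 1, 0):i + 1]:
            if r.overlaps(region):
                return True
        # regions beginning inside [start, end)
        j = bisect_right(starts, region.end - 1)
        return any(region.overlaps(r) for r in same[max(i - 1, 0):j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.scaffold, r.start, r.end) for r in self.regions],
            columns=["scaffold", "start", "end"],
        )

    def to_bed(self, path, name_prefix="region"):
        with open(path, "w") as fh:
            for i, r in enumerate(self.regions):
                fh.write(f"{r.scaffold}\t{r.start}\t{r.end}\t{name_prefix}_{i + 1}\n")

    @classmethod
    def from_bed(cls, path) -> "RegionSet":
        regions = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                regions.append(Region(parts[0], int(parts[1]), int(parts[2])))
        return cls(regions)


def _merge(regions):
    out = []
    for reg in sorted(regions):
        if out and reg.scaffold == out[-1].scaffold and reg.start <= out[-1].end:
            if reg.end > out[-1].end:
                out[-1] = Region(reg.scaffold, out[-1].start, reg.end)
        else:
            out.append(reg)
    return out


def merge_regions(regions) -> RegionSet:
    """Union of intervals; touching intervals merge ([0,10)+[10,20) -> [0,20))."""
    return RegionSet(regions)


def intersect_regions(a: RegionSet, b: RegionSet):
    """Pairwise intersections of two merged sets.

    Returns ``(sections, n_a_hit, n_sections)`` where *sections* is the
    merged set of all overlap pieces, *n_a_hit* counts regions of ``a``
    overlapping at least one bp of ``b`` and *n_sections* the number of
    discrete overlap sections.
    """
    sections = []
    n_a_hit = 0
    b_by_scaf: dict[str, list[Region]] = {}
    for r in b:
        b_by_scaf.setdefault(r.scaffold, []).append(r)
    for ra in a:
        hit = False
        for rb in b_by_scaf.get(ra.scaffold, ()):
            lo = max(ra.start, rb.start)
            hi = min(ra.end, rb.end)
            if lo < hi:
                sections.append(Region(ra.scaffold, lo, hi))
                hit = True
        if hit:
            n_a_hit += 1
    out = RegionSet(sections)
    return out, n_a_hit, len(out)


def clip_to_scaffold(region: Region, scaffold_length: int):
    """Trim a window that overran the scaffold end; ``None`` if fully outside."""
    if region.start >= scaffold_length:
        warnings.warn(
            f"region {region.scaffold}:{region.start}-{region.end} starts beyond "
            f"scaffold end ({scaffold_length} bp); dropped"
        )
        return None
    if region.end <= scaffold_length:
        return region
    return Region(region.scaffold, region.start, scaffold_length)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeTable:
    """Biallelic SNP genotypes: per site, alt-allele copy counts per sample.

    ``gt`` holds 0/1/2 alt copies with -1 for missing calls.  Positions are
    0-based and strictly increasing within each scaffold.
    """

    samples: list
    scaffolds: list
    scaffold_lengths: dict
    scaffold_idx: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    gt: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def sample_index(self, name) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise IntroscanError(f"sample {name!r} not in table {self.samples}") from None

    def validate(self):
        for si in range(len(self.scaffolds)):
            p = self.pos[self.scaffold_idx == si]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise IntroscanError(
                    f"positions not strictly increasing on {self.scaffolds[si]}"
                )


def read_vcf_biallelic(path, samples=None, min_scaffold_len=100_000) -> GenotypeTable:
    """Read biallelic SNPs on scaffolds strictly longer than ``min_scaffold_len``.

    Indels and multiallelic records are dropped; genotypes are decoded to
    alt-allele counts with missing preserved as -1.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    if not len(vcf.seqlens):
        raise IntroscanError(f"{path}: VCF header carries no contig lengths")
    lengths = dict(zip(vcf.seqnames, vcf.seqlens))
    if samples is not None:
        missing = [s for s in samples if s not in vcf.samples]
        if missing:
            raise IntroscanError(f"samples absent from VCF header: {missing}")
        vcf.set_samples(list(samples))
    used = list(vcf.samples)

    keep_scaf = {s for s, L in lengths.items() if L > min_scaffold_len}
    scaffolds = [s for s in lengths if s in keep_scaf]
    scaf_to_idx = {s: i for i, s in enumerate(scaffolds)}

    sidx, pos, ref, alt, gts = [], [], [], [], []
    for var in vcf:
        if var.CHROM not in keep_scaf:
            continue
        if not var.is_snp or len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            continue
        sidx.append(scaf_to_idx[var.CHROM])
        pos.append(var.POS - 1)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        # gt_types may view into a reused buffer; copy before the next record
        gts.append(np.array(var.gt_types, dtype=np.int8))
    vcf.close()

    gt = (np.vstack(gts) if gts
          else np.empty((0, len(used)), dtype=np.int8))
    gt[gt == 3] = -1  # gts012: 3 encodes unknown
    if samples is not None and used != list(samples):
        order = [used.index(s) for s in samples]
        gt = gt[:, order]
        used = list(samples)
    table = GenotypeTable(
        samples=used,
        scaffolds=scaffolds,
        scaffold_lengths={s: lengths[s] for s in scaffolds},
        scaffold_idx=np.array(sidx, dtype=np.int32),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype="U1"),
        alt=np.array(alt, dtype="U1"),
        gt=gt,
    )
    table.validate()
    return table


# ---------------------------------------------------------------------------
# Polarization
# ---------------------------------------------------------------------------

@dataclass
class PolarizedSiteTable:
    """Per-site derived-allele frequencies for the ingroup populations.

    The ancestral state is the outgroup's homozygous allele, so single
    diploids yield frequencies in {0, 0.5, 1}.  Sites where the outgroup is
    heterozygous or missing, or where any ingroup genotype is missing, are
    excluded on construction.
    """

    populations: list
    outgroup: str
    scaffolds: list
    scaffold_lengths: dict
    scaffold_idx: np.ndarray
    pos: np.ndarray
    freq: np.ndarray  # (n_sites, n_populations)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def pop_index(self, name) -> int:
        try:
            return self.populations.index(name)
        except ValueError:
            raise IntroscanError(
                f"population {name!r} not in {self.populations}"
            ) from None


def polarize(table: GenotypeTable, outgroup: str) -> PolarizedSiteTable:
    """Polarize alleles by the outgroup's homozygous state."""
    oi = table.sample_index(outgroup)
    in_cols = [i for i in range(len(table.samples)) if i != oi]
    og = table.gt[:, oi]
    ing = table.gt[:, in_cols]
    keep = ((og == 0) | (og == 2)) & np.all(ing != -1, axis=1)
    freq = ing[keep].astype(np.float64) / 2.0
    flip = og[keep] == 2  # reference allele is the derived one
    freq[flip] = 1.0 - freq[flip]
    return PolarizedSiteTable(
        populations=[table.samples[i] for i in in_cols],
        outgroup=outgroup,
        scaffolds=table.scaffolds,
        scaffold_lengths=table.scaffold_lengths,
        scaffold_idx=table.scaffold_idx[keep],
        pos=table.pos[keep],
        freq=freq,
    )


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

@dataclass
class CoverageTable:
    """Per-site, per-sample sequencing depth at assayed positions."""

    samples: list
    scaffolds: list
    scaffold_idx: np.ndarray
    pos: np.ndarray
    depth: np.ndarray  # (n_sites, n_samples)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def write_tsv(self, path):
        recs = []
        for j, s in enumerate(self.samples):
            recs.append(pd.DataFrame({
                "scaffold": np.asarray(self.scaffolds, dtype=object)[self.scaffold_idx],
                "pos0": self.pos,
                "sample": s,
                "depth": self.depth[:, j],
            }))
        pd.concat(recs).sort_values(["scaffold", "pos0", "sample"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def read_tsv(cls, path) -> "CoverageTable":
        df = pd.read_csv(path, sep="\t")
        wide = df.pivot_table(
            index=["scaffold", "pos0"], columns="sample", values="depth"
        ).reset_index()
        samples = [c for c in wide.columns if c not in ("scaffold", "pos0")]
        scaffolds = sorted(wide["scaffold"].unique())
        scaf_to_idx = {s: i for i, s in enumerate(scaffolds)}
        wide = wide.sort_values(["scaffold", "pos0"])
        return cls(
            samples=list(samples),
            scaffolds=scaffolds,
            scaffold_idx=wide["scaffold"].map(scaf_to_idx).to_numpy(np.int32),
            pos=wide["pos0"].to_numpy(np.int64),
            depth=wide[samples].to_numpy(np.int32),
        )


@dataclass
class SiteMask:
    """Per-site coverage-failure flags plus the per-scaffold mean depth."""

    scaffolds: list
    scaffold_idx: np.ndarray
    pos: np.ndarray
    fail: np.ndarray
    scaffold_mean: dict


def coverage_mask(cov: CoverageTable, low_factor=0.5, high_factor=2.0) -> SiteMask:
    """Flag sites whose cross-sample mean depth is extreme for the scaffold.

    The per-site depth is first averaged across samples; a site fails when
    that value is strictly above ``high_factor`` times, or strictly below
    ``low_factor`` times, the mean of those per-site values on its scaffold.
    Exactly twice (or half) the mean passes.
    """
    if cov.n_sites == 0:
        raise IntroscanError("empty coverage table")
    site_mean = cov.depth.mean(axis=1)
    fail = np.zeros(cov.n_sites, dtype=bool)
    scaffold_mean = {}
    for si, name in enumerate(cov.scaffolds):
        sel = cov.scaffold_idx == si
        if not sel.any():
            continue
        m = site_mean[sel].mean()
        scaffold_mean[name] = float(m)
        fail[sel] = (site_mean[sel] > high_factor * m) | (site_mean[sel] < low_factor * m)
    return SiteMask(
        scaffolds=cov.scaffolds,
        scaffold_idx=cov.scaffold_idx,
        pos=cov.pos,
        fail=fail,
        scaffold_mean=scaffold_mean,
    )
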