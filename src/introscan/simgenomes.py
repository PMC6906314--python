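"""Synthetic diploid genomes on a known species tree with planted introgression.

The generator draws an independent coalescent genealogy for every short
non-recombining locus (default 2 kb), evolves sequences by dropping
mutations on the genealogy (Jukes-Cantor alphabet, at most one mutation per
site), and emits the downstream input formats (VCF, per-sample IUPAC
consensus FASTA, coverage table, truth BED/JSON) plus machine-readable
ground truth for every planted tract.

Model
-----
One diploid individual per species.  Within each species the two haplotype
lineages coalesce at an exponentially distributed time with rate
``1/(2*Ne)`` per generation; lineages that fail to coalesce before the
parent divergence enter the ancestral population, where the standard
multi-lineage coalescent continues (this is what produces incomplete
lineage sorting).  Inside a planted tract the recipient haplotype's lineage
is held apart from its own species and coalesces with a donor lineage at
exactly ``admix_time_gens``, which gives every tract a true age recoverable
by a divergence clock.  Tract zygosity is configurable: ``"het"`` places
the tract on one of the recipient's haplotypes, ``"hom"`` on both.

The default demography emulates a four-species dwarf-lemur clade plus an
outgroup: topology (((major, crossleyi), medius), sibreei) with divergences
at 6 / 10 / 18 My, the outgroup joining at 30 My, Ne = 100,000 on every
branch, a per-generation mutation rate of 0.8e-8 and a 4-year generation
time.
"""
from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io_core import ConfigError, CoverageTable, GenotypeTable, IntroscanError, Region

_BASES = np.frombuffer(b"ACGT", dtype="S1")
# IUPAC code for an unordered base pair, indexed [min(a,b), max(a,b)] over ACGT
_IUPAC = {
    (0, 0): b"A", (1, 1): b"C", (2, 2): b"G", (3, 3): b"T",
    (0, 1): b"M", (0, 2): b"R", (0, 3): b"W",
    (1, 2): b"S", (1, 3): b"Y", (2, 3): b"K",
}


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------

class SpeciesTree:
    """Rooted binary species tree with node times in generations.

    Built from a nested-tuple description in which a leaf is a name string
    and an internal node is ``(left, right, time_gens)``.  Node times must
    strictly increase root-ward.
    """

    def __init__(self, nested):
        self.parent: dict[str, str] = {}
        self.children: dict[str, tuple] = {}
        self.time: dict[str, float] = {}
        self.leaves: list[str] = []
        self.root = self._build(nested)
        for node, (a, b) in self.children.items():
            for c in (a, b):
                if c in self.children and self.time[c] >= self.time[node]:
                    raise ConfigError(
                        f"node times must increase root-ward ({c} at {self.time[c]} "
                        f"under {node} at {self.time[node]})"
                    )

    def _build(self, node):
        if isinstance(node, str):
            if node in self.time:
                raise ConfigError(f"duplicate leaf name {node!r}")
            self.time[node] = 0.0
            self.leaves.append(node)
            return node
        try:
            left, right, t = node
        except (TypeError, ValueError):
            raise ConfigError(f"malformed tree node {node!r}") from None
        a = self._build(left)
        b = self._build(right)
        name = f"({a},{b})"
        self.children[name] = (a, b)
        self.time[name] = float(t)
        self.parent[a] = name
        self.parent[b] = name
        return name

    @property
    def nodes(self):
        return list(self.time)

    @property
    def internal_nodes(self):
        return sorted(self.children, key=lambda n: self.time[n])

    @property
    def outgroup(self):
        """The leaf attached directly at the root, if any."""
        for c in self.children[self.root]:
            if c in self.leaves:
                return c
        return None

    @property
    def ingroups(self):
        og = self.outgroup
        return [l for l in self.leaves if l != og]

    def leaves_under(self, node):
        if node in self.leaves:
            return [node]
        a, b = self.children[node]
        return self.leaves_under(a) + self.leaves_under(b)

    def _ancestors(self, node):
        out = [node]
        while node in self.parent:
            node = self.parent[node]
            out.append(node)
        return out

    def mrca(self, a, b):
        for n in (a, b):
            if n not in self.time:
                raise IntroscanError(f"{n!r} is not a node of the species tree")
        anc_a = set(self._ancestors(a))
        for n in self._ancestors(b):
            if n in anc_a:
                return n
        raise IntroscanError(f"no common ancestor of {a!r} and {b!r}")  # pragma: no cover

    def divergence_time(self, a, b) -> float:
        return self.time[self.mrca(a, b)]

    def sister_pair(self, triplet):
        """The two members of a leaf triplet with the most recent common ancestor."""
        a, b, c = triplet
        pairs = [(a, b), (a, c), (b, c)]
        times = [self.divergence_time(*p) for p in pairs]
        order = sorted(range(3), key=times.__getitem__)
        if times[order[0]] == times[order[1]]:
            raise IntroscanError(f"triplet {triplet} not resolvable against the tree")
        return pairs[order[0]]


def default_species_tree() -> SpeciesTree:
    """Four dwarf-lemur species plus an outgroup (times in generations)."""
    return SpeciesTree(
        (
            (
                (("major", "crossleyi", 1_500_000), "medius", 2_500_000),
                "sibreei",
                4_500_000,
            ),
            "outgroup",
            7_500_000,
        )
    )


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TractSpec:
    """A planted introgression tract: donor -> recipient over a half-open interval."""

    donor: str
    recipient: str
    scaffold: str
    start: int
    end: int
    admix_time_gens: float
    zygosity: str = "het"  # "het": one recipient haplotype; "hom": both


@dataclass
class TractTruth:
    """Ground truth for planted tracts, for scoring downstream recovery."""

    records: list = field(default_factory=list)

    def regions(self, recipient=None):
        from .io_core import RegionSet

        return RegionSet(
            Region(r["scaffold"], r["start"], r["end"])
            for r in self.records
            if recipient is None or r["recipient"] == recipient
        )

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.records, fh, indent=1)

    def to_bed(self, path):
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(
                    f"{r['scaffold']}\t{r['start']}\t{r['end']}\t"
                    f"{r['donor']}>{r['recipient']}@{r['admix_time_gens']:g}\n"
                )


@dataclass
class SimConfig:
    """Full description of one synthetic dataset."""

    scaffold_lengths: list
    species_tree: SpeciesTree = field(default_factory=default_species_tree)
    # scalar, or dict keyed by node name with optional "leaf"/"ancestral"
    # class defaults (diploid Ne per branch)
    branch_ne: object = field(
        default_factory=lambda: {"leaf": 100_000.0, "ancestral": 500_000.0}
    )
    mu_gen: float = 0.8e-8
    gen_time_years: float = 4.0
    tracts: tuple = ()
    coverage_mean: float = 30.0
    missing_rate: float = 0.01
    seed: int = 0
    locus_length: int = 2_000

    def scaffold_names(self):
        return [f"scaffold_{i + 1}" for i in range(len(self.scaffold_lengths))]

    def ne_of(self, node) -> float:
        if isinstance(self.branch_ne, dict):
            if node in self.branch_ne:
                return float(self.branch_ne[node])
            cls = "leaf" if node in self.species_tree.leaves else "ancestral"
            try:
                return float(self.branch_ne[cls])
            except KeyError:
                raise ConfigError(f"no Ne given for branch {node!r}") from None
        return float(self.branch_ne)

    def validate(self):
        tree = self.species_tree
        if not self.scaffold_lengths or any(L <= 0 for L in self.scaffold_lengths):
            raise ConfigError("scaffold lengths must all be > 0")
        if self.mu_gen <= 0:
            raise ConfigError("mu_gen must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.locus_length <= 0:
            raise ConfigError("locus_length must be > 0")
        for node in tree.nodes:
            if self.ne_of(node) <= 0:
                raise ConfigError(f"Ne must be > 0 (branch {node!r})")
        names = set(self.scaffold_names())
        lengths = dict(zip(self.scaffold_names(), self.scaffold_lengths))
        og = tree.outgroup
        seen = []
        for t in self.tracts:
            if t.scaffold not in names:
                raise ConfigError(f"tract on unknown scaffold {t.scaffold!r}")
            if not (0 <= t.start < t.end <= lengths[t.scaffold]):
                raise ConfigError(
                    f"tract {t.scaffold}:{t.start}-{t.end} outside scaffold bounds"
                )
            for sp in (t.donor, t.recipient):
                if sp not in tree.leaves:
                    raise ConfigError(f"tract species {sp!r} not in tree")
            if t.donor == t.recipient:
                raise ConfigError("tract donor and recipient must differ")
            if og in (t.donor, t.recipient):
                raise ConfigError("the outgroup never participates in admixture")
            div = tree.divergence_time(t.donor, t.recipient)
            if not 0 < t.admix_time_gens < div:
                raise ConfigError(
                    f"admix time {t.admix_time_gens} must lie in (0, divergence "
                    f"{div}) for {t.donor}->{t.recipient}"
                )
            if t.zygosity not in ("het", "hom"):
                raise ConfigError(f"unknown tract zygosity {t.zygosity!r}")
            for u in seen:
                if u.scaffold == t.scaffold and t.start < u.end and u.start < t.end:
                    raise ConfigError("planted tracts must not overlap")
            seen.append(t)


# ---------------------------------------------------------------------------
# Simulated dataset container
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """In-memory result of :func:`simulate_dataset`.

    ``haps`` holds the derived-allele indicator for each haplotype (two per
    sample, sample order = species-tree leaf order).  Genotypes, consensus
    sequences and the coverage table are derived views.
    """

    config: SimConfig
    samples: list
    scaffolds: list
    scaffold_lengths: dict
    scaffold_idx: np.ndarray
    pos: np.ndarray
    haps: np.ndarray       # (n_sites, 2*n_samples) uint8
    anc_code: np.ndarray   # 0..3 ancestral/reference base
    der_code: np.ndarray   # 0..3 derived base
    missing: np.ndarray    # (n_sites, n_samples) bool
    coverage: np.ndarray   # (n_sites, n_samples) int32
    ref_seqs: list         # per scaffold uint8 base-code array
    truth: TractTruth

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def genotype_table(self) -> GenotypeTable:
        gt = (self.haps[:, 0::2] + self.haps[:, 1::2]).astype(np.int8)
        gt[self.missing] = -1
        return GenotypeTable(
            samples=list(self.samples),
            scaffolds=list(self.scaffolds),
            scaffold_lengths=dict(self.scaffold_lengths),
            scaffold_idx=self.scaffold_idx,
            pos=self.pos,
            ref=_BASES[self.anc_code].astype("U1"),
            alt=_BASES[self.der_code].astype("U1"),
            gt=gt,
        )

    def coverage_table(self) -> CoverageTable:
        return CoverageTable(
            samples=list(self.samples),
            scaffolds=list(self.scaffolds),
            scaffold_idx=self.scaffold_idx,
            pos=self.pos,
            depth=self.coverage,
        )

    def consensus_sequences(self) -> dict:
        """Per-sample full-length consensus with IUPAC codes at heterozygous sites.

        Missing genotypes become ``N``; invariant positions carry the
        reference (ancestral) base.
        """
        out = {}
        for j, sample in enumerate(self.samples):
            chunks = {}
            for si, name in enumerate(self.scaffolds):
                seq = _BASES[self.ref_seqs[si]].copy()
                sel = self.scaffold_idx == si
                p = self.pos[sel]
                a = self.haps[sel, 2 * j] * (self.der_code[sel] - self.anc_code[sel]) + self.anc_code[sel]
                b = self.haps[sel, 2 * j + 1] * (self.der_code[sel] - self.anc_code[sel]) + self.anc_code[sel]
                lo = np.minimum(a, b)
                hi = np.maximum(a, b)
                codes = np.array(
                    [_IUPAC[(int(x), int(y))] for x, y in zip(lo, hi)], dtype="S1"
                ) if len(p) else np.empty(0, dtype="S1")
                seq[p] = codes
                miss = self.missing[sel, j]
                seq[p[miss]] = b"N"
                chunks[name] = seq
            out[sample] = chunks
        return out

    def segregating_site_count(self) -> int:
        return self.n_sites


# ---------------------------------------------------------------------------
# Coalescent machinery
# ---------------------------------------------------------------------------

def _sim_genealogy(events, init_pops, isolated, ne2, rng):
    """One genealogy for a locus; returns branches as ``(carrier_mask, length)``.

    ``events`` is a time-sorted list of ``("merge", t, parent, children)``
    and ``("admix", t, donor_pop, n_migrants)`` entries, ending with a
    sentinel at +inf.  ``isolated`` holds lineages barred from coalescing
    until their admixture event fires (planted-tract haplotypes).
    """
    pops = {pid: [[m, 0.0] for m in masks] for pid, masks in init_pops.items()}
    iso = [[m, 0.0] for m in isolated]
    branches = []
    t = 0.0

    def coalesce(lins, idx_pair, when):
        i, j = idx_pair
        mi, bi = lins[i]
        mj, bj = lins[j]
        branches.append((mi, when - bi))
        branches.append((mj, when - bj))
        keep = [lins[k] for k in range(len(lins)) if k not in (i, j)]
        keep.append([mi | mj, when])
        return keep

    def run_until(te):
        nonlocal t
        while True:
            best_pid, best_t = None, te
            for pid, lins in pops.items():
                k = len(lins)
                if k < 2:
                    continue
                dt = rng.expovariate(k * (k - 1) / 2.0 / ne2[pid])
                if t + dt < best_t:
                    best_pid, best_t = pid, t + dt
            if best_pid is None:
                t = te
                return
            lins = pops[best_pid]
            i = rng.randrange(len(lins))
            j = rng.randrange(len(lins) - 1)
            if j >= i:
                j += 1
            pops[best_pid] = coalesce(lins, (i, j), best_t)
            t = best_t

    for ev in events:
        run_until(ev[1])
        if ev[0] == "merge":
            _, _, parent, children = ev
            merged = []
            for c in children:
                merged.extend(pops.pop(c, ()))
            pops[parent] = merged
        elif ev[0] == "admix":
            _, ta, donor, n_migrants = ev
            target_lins = pops[donor]
            tgt = target_lins[rng.randrange(len(target_lins))]
            mask, birth = tgt
            branches.append((mask, ta - birth))
            for _ in range(n_migrants):
                m, b = iso.pop(0)
                branches.append((m, ta - b))
                mask |= m
            target_lins.remove(tgt)
            target_lins.append([mask, ta])
        else:  # "end"
            run_until(math.inf)
    return branches


def _locus_plan(tree, tract, samples):
    """Initial populations / isolated lineages / events for one locus class."""
    hap_of = {s: (1 << (2 * i), 1 << (2 * i + 1)) for i, s in enumerate(samples)}
    init = {s: list(hap_of[s]) for s in samples}
    isolated = []
    events = []
    if tract is not None:
        h0, h1 = hap_of[tract.recipient]
        if tract.zygosity == "het":
            init[tract.recipient] = [h0]
            isolated = [h1]
        else:
            init[tract.recipient] = []
            isolated = [h0, h1]
        events.append(("admix", tract.admix_time_gens, tract.donor, len(isolated)))
    for node in tree.internal_nodes:
        events.append(("merge", tree.time[node], node, tree.children[node]))
    events.sort(key=lambda e: e[1])
    events.append(("end", math.inf))
    return init, isolated, events


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Simulate a full dataset; byte-identical for identical configs and seeds."""
    config.validate()
    tree = config.species_tree
    samples = list(tree.leaves)
    n_samples = len(samples)
    nhap = 2 * n_samples
    full_mask = (1 << nhap) - 1

    rng = np.random.default_rng(config.seed)
    pyrng = random.Random(int(rng.integers(2 ** 63)))
    ne2 = {node: 2.0 * config.ne_of(node) for node in tree.nodes}
    names = config.scaffold_names()

    plans = {None: _locus_plan(tree, None, samples)}
    for tr in config.tracts:
        plans[tr] = _locus_plan(tree, tr, samples)

    all_sidx, all_pos, all_mask = [], [], []
    ref_seqs = []
    for si, L in enumerate(config.scaffold_lengths):
        name = names[si]
        ref_seqs.append(rng.integers(0, 4, size=L).astype(np.uint8))
        tracts_here = sorted(
            (t for t in config.tracts if t.scaffold == name), key=lambda t: t.start
        )
        cuts = {0, L}
        cuts.update(range(config.locus_length, L, config.locus_length))
        for t in tracts_here:
            cuts.update((t.start, t.end))
        edges = sorted(cuts)
        loci = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            owner = None
            for t in tracts_here:
                if t.start <= lo and hi <= t.end:
                    owner = t
                    break
            loci.append((lo, hi, owner))

        b_mask, b_len, b_locus = [], [], []
        for li, (lo, hi, owner) in enumerate(loci):
            init, isolated, events = plans[owner]
            branches = _sim_genealogy(events, init, isolated, ne2, pyrng)
            for m, ln in branches:
                if ln > 0.0 and m != full_mask:
                    b_mask.append(m)
                    b_len.append(ln)
                    b_locus.append(li)

        if not b_mask:
            continue
        b_mask = np.array(b_mask, dtype=np.int64)
        b_len = np.array(b_len)
        b_locus = np.array(b_locus, dtype=np.int64)
        starts = np.array([lo for lo, _, _ in loci], dtype=np.int64)
        spans = np.array([hi - lo for lo, hi, _ in loci], dtype=np.int64)
        counts = rng.poisson(config.mu_gen * spans[b_locus] * b_len)
        rep = np.repeat(np.arange(len(b_mask)), counts)
        if rep.size == 0:
            continue
        loc = b_locus[rep]
        pos = starts[loc] + (rng.random(rep.size) * spans[loc]).astype(np.int64)
        # infinite sites: co-located mutations are redrawn, not discarded,
        # so mutation counts keep their branch-Poisson expectation
        for _ in range(64):
            order = np.argsort(pos, kind="stable")
            ps = pos[order]
            dup = order[1:][ps[1:] == ps[:-1]]
            if dup.size == 0:
                break
            pos[dup] = starts[loc[dup]] + (
                rng.random(dup.size) * spans[loc[dup]]
            ).astype(np.int64)
        else:  # pathological density: drop remaining collisions
            order = np.argsort(pos, kind="stable")
            ps = pos[order]
            keep = np.concatenate([[True], ps[1:] != ps[:-1]])
            sel = order[keep]
            pos, rep = pos[sel], rep[sel]
        order = np.argsort(pos, kind="stable")
        all_pos.append(pos[order])
        all_mask.append(b_mask[rep[order]])
        all_sidx.append(np.full(order.size, si, dtype=np.int32))

    if all_pos:
        pos = np.concatenate(all_pos)
        mask = np.concatenate(all_mask)
        sidx = np.concatenate(all_sidx)
    else:
        pos = np.empty(0, dtype=np.int64)
        mask = np.empty(0, dtype=np.int64)
        sidx = np.empty(0, dtype=np.int32)

    haps = ((mask[:, None] >> np.arange(nhap)) & 1).astype(np.uint8)
    n = len(pos)
    anc = np.empty(n, dtype=np.uint8)
    for si in range(len(names)):
        s = sidx == si
        anc[s] = ref_seqs[si][pos[s]]
    der = ((anc + rng.integers(1, 4, size=n)) % 4).astype(np.uint8)
    coverage = rng.poisson(config.coverage_mean, size=(n, n_samples)).astype(np.int32)
    missing = rng.random((n, n_samples)) < config.missing_rate

    truth = TractTruth(
        records=[
            {
                "donor": t.donor,
                "recipient": t.recipient,
                "scaffold": t.scaffold,
                "start": t.start,
                "end": t.end,
                "admix_time_gens": t.admix_time_gens,
                "age_years": t.admix_time_gens * config.gen_time_years,
                "zygosity": t.zygosity,
            }
            for t in config.tracts
        ]
    )
    return SimulatedDataset(
        config=config,
        samples=samples,
        scaffolds=names,
        scaffold_lengths=dict(zip(names, config.scaffold_lengths)),
        scaffold_idx=sidx,
        pos=pos,
        haps=haps,
        anc_code=anc,
        der_code=der,
        missing=missing,
        coverage=coverage,
        ref_seqs=ref_seqs,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_outputs(dataset: SimulatedDataset, out_dir) -> dict:
    """Write VCF, per-sample FASTA, truth BED/JSON and the coverage TSV.

    VCF positions are 1-based; BED intervals 0-based half-open.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    vcf_path = out / "variants.vcf"
    gt_tab = dataset.genotype_table()
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=introscan-simgenomes\n")
        for name in dataset.scaffolds:
            fh.write(f"##contig=<ID={name},length={dataset.scaffold_lengths[name]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dataset.samples)
            + "\n"
        )
        for i in range(dataset.n_sites):
            gts = "\t".join(_GT_STR[int(g)] for g in gt_tab.gt[i])
            fh.write(
                f"{dataset.scaffolds[dataset.scaffold_idx[i]]}\t{dataset.pos[i] + 1}"
                f"\t.\t{gt_tab.ref[i]}\t{gt_tab.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )
    paths["vcf"] = vcf_path

    consensus = dataset.consensus_sequences()
    for sample, chunks in consensus.items():
        p = out / f"{sample}.fasta"
        with open(p, "w") as fh:
            for scaf, seq in chunks.items():
                fh.write(f">{scaf}\n")
                s = seq.tobytes().decode()
                for k in range(0, len(s), 80):
                    fh.write(s[k:k + 80] + "\n")
        paths[f"fasta:{sample}"] = p

    bed = out / "tracts_truth.bed"
    dataset.truth.to_bed(bed)
    paths["truth_bed"] = bed
    tj = out / "truth.json"
    dataset.truth.to_json(tj)
    paths["truth_json"] = tj

    cov = out / "coverage.tsv"
    dataset.coverage_table().write_tsv(cov)
    paths["coverage"] = cov
    return paths


# ---------------------------------------------------------------------------
# Synthetic demographic output (inverse of the biological-unit conversion)
# ---------------------------------------------------------------------------

def make_msmc_output(trajectory, mu_gen=0.8e-8, gen_time_years=4.0, n_segments=32,
                     path=None) -> str:
    """Emit coalescence-rate segments in MSMC2 output format.

    ``trajectory`` is a piecewise-constant Ne history given as
    ``[(left_time_years, Ne), ...]`` with strictly increasing times starting
    at 0.  Scaled time boundaries are ``t_years / gen_time * mu_gen`` and
    the scaled coalescence rate is ``lambda = 1 / (2 * mu_gen * Ne)``, so
    parsing the result and converting back to biological units recovers the
    input exactly.
    """
    times = [t for t, _ in trajectory]
    nes = [ne for _, ne in trajectory]
    if times[0] != 0:
        raise ConfigError("trajectory must start at time 0")
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ConfigError("trajectory times must strictly increase")
    if any(ne <= 0 for ne in nes):
        raise ConfigError("Ne must be positive")
    if n_segments < len(trajectory):
        raise ConfigError("n_segments must be >= number of trajectory pieces")

    horizon = (times[-1] * 2) if times[-1] > 0 else 40 * gen_time_years * max(nes)
    bounds = set(times)
    # log-spaced filler boundaries so every trajectory piece may span
    # several segments, as real output does
    lo = max(horizon * 1e-3, 1e-9)
    k = 1
    while len(bounds) < n_segments:
        frac = k / (n_segments + 1)
        cand = lo * (horizon / lo) ** frac
        bounds.add(float(cand))
        k += 1
        if k > 10 * n_segments:  # pragma: no cover - defensive
            break
    edges = sorted(bounds)[:n_segments]

    def ne_at(t_years):
        idx = 0
        for i, left in enumerate(times):
            if t_years >= left:
                idx = i
        return nes[idx]

    lines = ["time_index\tleft_time_boundary\tright_time_boundary\tlambda"]
    scale = mu_gen / gen_time_years
    for i, left in enumerate(edges):
        right = edges[i + 1] if i + 1 < len(edges) else math.inf
        lam = 1.0 / (2.0 * mu_gen * ne_at(left))
        right_s = "inf" if math.isinf(right) else repr(right * scale)
        lines.append(f"{i}\t{left * scale!r}\t{right_s}\t{lam!r}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
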