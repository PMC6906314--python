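"""The coalescent simulator: determinism, closed-form expectations, tracts."""
import numpy as np
import pytest

from introscan import (
    ConfigError,
    SimConfig,
    SpeciesTree,
    TractSpec,
    simulate_dataset,
)
from introscan.simgenomes import default_species_tree


class TestSpeciesTree:
    def test_default_structure(self):
        t = default_species_tree()
        assert t.outgroup == "outgroup"
        assert set(t.ingroups) == {"major", "crossleyi", "medius", "sibreei"}
        assert t.divergence_time("major", "crossleyi") == 1_500_000
        assert t.divergence_time("medius", "sibreei") == 4_500_000

    def test_sister_pair(self):
        t = default_species_tree()
        assert set(t.sister_pair(("major", "crossleyi", "medius"))) == {
            "major", "crossleyi",
        }
        assert set(t.sister_pair(("medius", "crossleyi", "sibreei"))) == {
            "medius", "crossleyi",
        }

    def test_times_must_increase_rootward(self):
        with pytest.raises(ConfigError):
            SpeciesTree((("a", "b", 2e6), "c", 1e6))


class TestConfigValidation:
    def _tract(self, **kw):
        base = dict(donor="sibreei", recipient="medius", scaffold="scaffold_1",
                    start=0, end=10_000, admix_time_gens=50_000.0)
        base.update(kw)
        return TractSpec(**base)

    def test_tract_outside_scaffold(self):
        cfg = SimConfig([50_000], tracts=(self._tract(end=60_000),))
        with pytest.raises(ConfigError, match="bounds"):
            cfg.validate()

    def test_admix_time_must_predate_divergence(self):
        cfg = SimConfig([50_000], tracts=(self._tract(end=10_000,
                                                      admix_time_gens=5e6),))
        with pytest.raises(ConfigError, match="divergence"):
            cfg.validate()

    def test_outgroup_never_admixed(self):
        cfg = SimConfig([50_000], tracts=(self._tract(donor="outgroup"),))
        with pytest.raises(ConfigError, match="outgroup"):
            cfg.validate()

    def test_overlapping_tracts_rejected(self):
        cfg = SimConfig([50_000], tracts=(
            self._tract(), self._tract(start=5_000, end=15_000),
        ))
        with pytest.raises(ConfigError, match="overlap"):
            cfg.validate()


class TestSimulation:
    def test_no_tracts_empty_truth(self, small_dataset):
        assert small_dataset.truth.records == []

    def test_determinism(self):
        a = simulate_dataset(SimConfig([150_000], seed=33))
        b = simulate_dataset(SimConfig([150_000], seed=33))
        assert np.array_equal(a.pos, b.pos)
        assert np.array_equal(a.haps, b.haps)
        assert np.array_equal(a.coverage, b.coverage)
        assert np.array_equal(a.missing, b.missing)
        c = simulate_dataset(SimConfig([150_000], seed=34))
        assert not np.array_equal(a.pos, c.pos)

    def test_genotypes_consistent_with_haplotypes(self, small_dataset):
        gt = small_dataset.genotype_table()
        expect = small_dataset.haps[:, 0::2] + small_dataset.haps[:, 1::2]
        visible = gt.gt != -1
        assert np.array_equal(gt.gt[visible], expect.astype(np.int8)[visible])
        gt.validate()

    def test_coverage_nonnegative(self, small_dataset):
        assert (small_dataset.coverage >= 0).all()

    def test_two_species_closed_form_divergence(self):
        # split 1e6 generations, ancestral Ne 1e5, mu 1e-8, L 1 Mb:
        # E[pairwise diffs] = L*(2*T*mu + 4*Ne*mu) = 24,000
        tree = SpeciesTree(("A", "B", 1_000_000))
        totals = []
        for rep in range(20):
            cfg = SimConfig([1_000_000], species_tree=tree, branch_ne=100_000.0,
                            mu_gen=1e-8, missing_rate=0.0, seed=500 + rep)
            ds = simulate_dataset(cfg)
            diffs = np.abs(ds.haps[:, 0].astype(int) - ds.haps[:, 2].astype(int)).sum()
            totals.append(diffs)
        sd = np.sqrt(24_000 * (1 - 0.024))
        assert abs(np.mean(totals) - 24_000) < 3 * sd

    def test_tract_lowers_donor_recipient_divergence(self):
        ok = 0
        for rep in range(5):
            tracts = (TractSpec("sibreei", "medius", "scaffold_1",
                                200_000, 260_000, 100_000, "hom"),)
            cfg = SimConfig([500_000], tracts=tracts, seed=60 + rep,
                            branch_ne=100_000.0)
            ds = simulate_dataset(cfg)
            med = ds.haps[:, 2 * ds.samples.index("medius")]
            sib = ds.haps[:, 2 * ds.samples.index("sibreei")]
            diff = np.abs(med.astype(int) - sib.astype(int))
            in_tract = (ds.pos >= 200_000) & (ds.pos < 260_000)
            div_in = diff[in_tract].sum() / 60_000
            div_out = diff[~in_tract].sum() / 440_000
            if div_in < div_out:
                ok += 1
        assert ok == 5

    def test_het_tract_affects_single_haplotype(self):
        tracts = (TractSpec("sibreei", "medius", "scaffold_1",
                            100_000, 200_000, 100_000, "het"),)
        cfg = SimConfig([300_000], tracts=tracts, seed=77, branch_ne=100_000.0)
        ds = simulate_dataset(cfg)
        mi = ds.samples.index("medius")
        sib = ds.haps[:, 2 * ds.samples.index("sibreei")].astype(int)
        in_tract = (ds.pos >= 100_000) & (ds.pos < 200_000)
        d0 = np.abs(ds.haps[in_tract, 2 * mi].astype(int) - sib[in_tract]).mean()
        d1 = np.abs(ds.haps[in_tract, 2 * mi + 1].astype(int) - sib[in_tract]).mean()
        # the tract haplotype (index 1) is sibreei-like, its partner is not
        assert d1 < 0.5 * d0

    def test_truth_age_in_years(self):
        tracts = (TractSpec("sibreei", "medius", "scaffold_1",
                            0, 10_000, 250_000, "hom"),)
        cfg = SimConfig([50_000], tracts=tracts, seed=1)
        ds = simulate_dataset(cfg)
        assert ds.truth.records[0]["age_years"] == pytest.approx(1_000_000)

    def test_genomewide_het_matches_coalescent_expectation(self):
        from introscan import diversity, polarize

        cfg = SimConfig([2_000_000], branch_ne=100_000.0, missing_rate=0.0, seed=88)
        ds = simulate_dataset(cfg)
        w = diversity.window_heterozygosity(ds.genotype_table(), "crossleyi")
        _, pooled = diversity.genome_mean_het(w)
        assert pooled == pytest.approx(4 * 100_000 * 0.8e-8, rel=0.10)


class TestWrittenOutputs:
    def test_vcf_and_bed_conventions(self, small_outputs, tmp_path):
        dataset, paths = small_outputs
        head = paths["vcf"].read_text().splitlines()
        assert head[0] == "##fileformat=VCFv4.2"
        first = next(l for l in head if not l.startswith("#")).split("\t")
        assert int(first[1]) == dataset.pos[0] + 1  # VCF is 1-based

        tracts = (TractSpec("sibreei", "medius", "scaffold_1",
                            10_000, 50_000, 50_000),)
        cfg = SimConfig([100_000], tracts=tracts, seed=5)
        ds = simulate_dataset(cfg)
        bed = tmp_path / "t.bed"
        ds.truth.to_bed(bed)
        assert bed.read_text().startswith("scaffold_1\t10000\t50000\t")

    def test_zero_sites_vcf_has_header_only(self, tmp_path):
        from introscan import write_outputs

        cfg = SimConfig([5_000], mu_gen=1e-12, seed=2)
        ds = simulate_dataset(cfg)
        assert ds.n_sites == 0
        paths = write_outputs(ds, tmp_path / "empty")
        lines = paths["vcf"].read_text().splitlines()
        assert all(l.startswith("#") for l in lines)

    def test_fasta_consensus_matches_haplotypes(self, small_outputs):
        from introscan.blockscan import read_fasta_sequences

        dataset, paths = small_outputs
        seqs = read_fasta_sequences(paths["fasta:medius"])
        scaf = dataset.scaffolds[0]
        sel = dataset.scaffold_idx == 0
        j = dataset.samples.index("medius")
        hom_derived = sel & (dataset.haps[:, 2 * j] == 1) & (dataset.haps[:, 2 * j + 1] == 1)
        hom_derived &= ~dataset.missing[:, j]
        pos = dataset.pos[hom_derived & sel]
        from introscan.simgenomes import _BASES
        expect = _BASES[dataset.der_code[hom_derived & sel]]
        assert np.array_equal(seqs[scaf][pos], expect)
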