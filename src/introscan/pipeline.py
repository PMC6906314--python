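"""End-to-end orchestration of the genome scan from one configuration.

Stages run in dependency order: simulate (or load inputs) -> polarize ->
genome-wide D -> windowed f_d -> candidate regions -> triplet blocks ->
overlap accounting -> heterozygosity -> topology windows -> demography
summary -> gene-set enrichment.  Every stage's outputs are written in
re-loadable text formats and the machine-readable report carries per-stage
summaries, a file manifest with checksums, and the seed.
"""
from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .io_core import (
    CoverageTable,
    IntroscanError,
    RegionSet,
    coverage_mask,
    polarize,
    read_vcf_biallelic,
)
from .simgenomes import (
    SimConfig,
    SimulatedDataset,
    SpeciesTree,
    TractSpec,
    default_species_tree,
    make_msmc_output,
    simulate_dataset,
    write_outputs,
)
from . import blockscan, demography, diversity, dstat, enrich, fdscan, topowin


class StageError(IntroscanError):
    """Failure inside a named pipeline stage."""

    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def sim_config_from_dict(d: dict, seed=None) -> SimConfig:
    tree = (
        SpeciesTree(_as_nested(d["species_tree"])) if "species_tree" in d
        else default_species_tree()
    )
    tracts = tuple(
        TractSpec(
            donor=t["donor"],
            recipient=t["recipient"],
            scaffold=t["scaffold"],
            start=int(t["start"]),
            end=int(t["end"]),
            admix_time_gens=float(t["admix_time_gens"]),
            zygosity=t.get("zygosity", "het"),
        )
        for t in d.get("tracts", ())
    )
    kwargs = {}
    for key, cast in (("branch_ne", None), ("mu_gen", float),
                      ("gen_time_years", float), ("coverage_mean", float),
                      ("missing_rate", float), ("locus_length", int)):
        if key in d:
            kwargs[key] = cast(d[key]) if cast else d[key]
    return SimConfig(
        scaffold_lengths=[int(x) for x in d["scaffold_lengths"]],
        species_tree=tree,
        tracts=tracts,
        seed=int(d.get("seed", seed or 0)),
        **kwargs,
    )


def _as_nested(node):
    # YAML represents nested tuples as nested lists
    if isinstance(node, str):
        return node
    a, b, t = node
    return (_as_nested(a), _as_nested(b), float(t))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the configured stages; returns the report dict (also written
    to ``report.json`` in ``out_dir``)."""
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    report = {"seed": seed, "version": __version__, "stages": {}}
    files = {}

    # ---- inputs --------------------------------------------------------
    dataset = None
    stage = "inputs"
    try:
        if "simulate" in config:
            cfg = sim_config_from_dict(dict(config["simulate"]), seed=seed)
            dataset = simulate_dataset(cfg)
            paths = write_outputs(dataset, out / "sim")
            files.update({f"sim/{k}": v for k, v in paths.items()})
            gt = dataset.genotype_table()
            cov = dataset.coverage_table()
            report["stages"]["simulate"] = {
                "n_sites": int(dataset.n_sites),
                "n_tracts": len(dataset.truth.records),
                "samples": dataset.samples,
            }
        else:
            inputs = config["inputs"]
            gt = read_vcf_biallelic(
                inputs["vcf"],
                samples=inputs.get("samples"),
                min_scaffold_len=int(inputs.get("min_scaffold_len", 100_000)),
            )
            cov = (
                CoverageTable.read_tsv(inputs["coverage_tsv"])
                if "coverage_tsv" in inputs
                else None
            )
            report["stages"]["inputs"] = {"n_sites": gt.n_sites, "samples": gt.samples}
    except IntroscanError as e:
        raise StageError(stage, e) from e

    # ---- polarize ------------------------------------------------------
    stage = "polarize"
    outgroup = config.get("outgroup", "outgroup")
    try:
        poltab = polarize(gt, outgroup)
    except IntroscanError as e:
        raise StageError(stage, e) from e
    report["stages"]["polarize"] = {
        "outgroup": outgroup,
        "n_sites": poltab.n_sites,
        "populations": poltab.populations,
    }

    # ---- genome-wide D -------------------------------------------------
    stage = "dstat"
    dcfg = config.get("dstat", {})
    dres = []
    try:
        for test in dcfg.get("tests", ()):
            order = (test["p1"], test["p2"], test["p3"], test.get("outgroup", outgroup))
            tab = poltab if order[3] == outgroup else polarize(gt, order[3])
            res = dstat.jackknife_z(
                tab, order,
                block_span_bp=int(dcfg.get("block_span_bp", 1_000_000)),
                min_blocks=int(dcfg.get("min_blocks", 20)),
            )
            dres.append({
                "order": list(order), "D": res.D, "SE": res.SE, "Z": res.Z,
                "n_blocks": res.n_blocks, "n_sites": res.counts.n_sites,
            })
    except IntroscanError as e:
        raise StageError(stage, e) from e
    report["stages"]["dstat"] = dres

    # ---- f_d scan ------------------------------------------------------
    candidates = None
    if "fdscan" in config:
        stage = "fdscan"
        fcfg = config["fdscan"]
        try:
            order = tuple(fcfg["order"])
            tab = poltab if order[3] == outgroup else polarize(gt, order[3])
            windows = fdscan.window_fd(
                tab, order,
                win=int(fcfg.get("win", 40_000)),
                step=int(fcfg.get("step", 10_000)),
            )
            if cov is not None:
                mask = coverage_mask(cov)
                windows = fdscan.apply_window_mask(
                    windows, mask, max_fail_frac=float(fcfg.get("max_fail_frac", 0.30))
                )
            candidates = fdscan.call_candidates(
                windows,
                quantile=float(fcfg.get("quantile", 0.9995)),
                scaffold_lengths=gt.scaffold_lengths,
            )
        except IntroscanError as e:
            raise StageError(stage, e) from e
        wpath = out / "fd_windows.tsv"
        windows.to_csv(wpath, sep="\t", index=False)
        bpath = out / "fd_candidates.bed"
        candidates.regions.to_bed(bpath, name_prefix="fd")
        files["fd_windows"] = wpath
        files["fd_candidates"] = bpath
        report["stages"]["fdscan"] = {
            "order": list(order),
            "n_windows": int(len(windows)),
            "n_masked": int(windows["masked"].sum()),
            "cutoff": candidates.cutoff_value,
            "n_candidate_regions": len(candidates.regions),
            "candidate_span_bp": candidates.regions.total_span,
            "mean_fd": float(windows.loc[~windows["masked"], "fd"].mean()),
        }

    # ---- triplet blocks ------------------------------------------------
    if "blocks" in config:
        stage = "blocks"
        bcfg = config["blocks"]
        try:
            if dataset is None:
                seqs = {
                    s: blockscan.read_fasta_sequences(Path(config["inputs"]["fasta_dir"]) / f"{s}.fasta")
                    for s in gt.samples
                }
            else:
                seqs = dataset.consensus_sequences()
            params = blockscan.TripletScanParams(
                snp_window=int(bcfg.get("snp_window", 100)),
                step_snps=int(bcfg.get("step_snps", 50)),
                min_snps=int(bcfg.get("min_snps", 10)),
                max_p=float(bcfg.get("max_p", 1e-6)),
                mu_year=float(bcfg.get("mu_year", 0.2e-8)),
            )
            tree = (
                dataset.config.species_tree if dataset is not None
                else SpeciesTree(_as_nested(config["species_tree"]))
            )
            retained = []
            for triplet in bcfg.get("triplets", ()):
                sister = tree.sister_pair(tuple(triplet))
                for scaf in gt.scaffolds:
                    tri = {t: seqs[t][scaf] for t in triplet}
                    found = blockscan.scan_triplet(
                        tri, params, scaffold=scaf, background_pair=sister
                    )
                    retained.extend(blockscan.filter_blocks(found, params, tree))
            summary = blockscan.summarize_blocks(
                retained, candidates.regions if candidates else None
            )
        except IntroscanError as e:
            raise StageError(stage, e) from e
        bpath = out / "blocks.tsv"
        with open(bpath, "w") as fh:
            fh.write("triplet\tpair\tscaffold\tstart\tend\tn_snps\tdiffs\t"
                     "divergence\tp\tage_years\n")
            for b in retained:
                fh.write(
                    f"{','.join(b.triplet)}\t{','.join(b.pair)}\t{b.region.scaffold}"
                    f"\t{b.region.start}\t{b.region.end}\t{b.n_snps_in_block}"
                    f"\t{b.pair_diffs}\t{b.divergence:.6g}\t{b.p_value:.3g}"
                    f"\t{b.age_years:.1f}\n"
                )
        files["blocks"] = bpath
        report["stages"]["blocks"] = summary

    # ---- heterozygosity ------------------------------------------------
    if "heterozygosity" in config:
        stage = "heterozygosity"
        hcfg = config["heterozygosity"]
        het_summary = {}
        try:
            for s in gt.samples:
                if s == outgroup and not hcfg.get("include_outgroup", False):
                    continue
                w = diversity.window_heterozygosity(
                    gt, s, win=int(hcfg.get("win", 100_000)),
                    joint_missing=bool(hcfg.get("joint_missing", False)),
                )
                mean_w, pooled = diversity.genome_mean_het(w)
                het_summary[s] = {"windowed_mean": mean_w, "pooled": pooled}
        except IntroscanError as e:
            raise StageError(stage, e) from e
        report["stages"]["heterozygosity"] = het_summary

    # ---- topology windows ----------------------------------------------
    if "topology" in config:
        stage = "topology"
        tcfg = config["topology"]
        try:
            taxa = tuple(tcfg["taxa"])
            tree = (
                dataset.config.species_tree if dataset is not None
                else SpeciesTree(_as_nested(config["species_tree"]))
            )
            labels = topowin.classify_windows(
                gt, taxa, tree,
                win=int(tcfg.get("win", 100_000)),
                min_snps=int(tcfg.get("min_snps", 50)),
            )
            segments, fractions = topowin.segment_topologies(labels)
        except IntroscanError as e:
            raise StageError(stage, e) from e
        tpath = out / "topology_windows.tsv"
        labels.to_csv(tpath, sep="\t", index=False)
        files["topology_windows"] = tpath
        report["stages"]["topology"] = {
            "fractions": fractions, "n_segments": int(len(segments)),
        }

    # ---- demography ----------------------------------------------------
    if "demography" in config:
        stage = "demography"
        gcfg = config["demography"]
        demo = {}
        try:
            msmc_paths = dict(gcfg.get("msmc_paths", {}))
            if not msmc_paths and dataset is not None:
                # emit a constant-Ne trajectory per species from the
                # simulation's own parameters, exercising the full
                # write -> parse -> convert -> summarize path
                for s in dataset.samples:
                    if s == outgroup:
                        continue
                    p = out / f"msmc_{s}.final.txt"
                    make_msmc_output(
                        [(0.0, dataset.config.ne_of(s))],
                        mu_gen=dataset.config.mu_gen,
                        gen_time_years=dataset.config.gen_time_years,
                        n_segments=int(gcfg.get("n_segments", 32)),
                        path=p,
                    )
                    msmc_paths[s] = p
                    files[f"msmc:{s}"] = p
            for s, p in msmc_paths.items():
                segs = demography.parse_msmc(p)
                traj = demography.convert_units(
                    segs,
                    mu_gen=float(gcfg.get("mu_gen", 0.8e-8)),
                    gen_time_years=float(gcfg.get("gen_time_years", 4.0)),
                )
                demo[s] = {
                    "n_segments": len(traj),
                    "harmonic_mean_ne": demography.harmonic_mean_ne(
                        traj,
                        drop_first=int(gcfg.get("drop_first", 5)),
                        drop_last=int(gcfg.get("drop_last", 5)),
                    ),
                }
        except IntroscanError as e:
            raise StageError(stage, e) from e
        report["stages"]["demography"] = demo

    # ---- enrichment ----------------------------------------------------
    if "enrichment" in config and candidates is not None:
        stage = "enrichment"
        ecfg = config["enrichment"]
        try:
            if "gene_bed" in ecfg:
                gene_set = set(
                    Path(ecfg["gene_set"]).read_text().split()
                ) if "gene_set" in ecfg else set()
                genes = enrich.read_gene_bed(ecfg["gene_bed"], gene_set)
            else:
                genes = _synthetic_genes(gt, ecfg.get("synthetic_genes", {}), seed)
            res = enrich.enrichment_test(
                genes, candidates.regions,
                continuity_correction=bool(ecfg.get("continuity_correction", False)),
            )
        except IntroscanError as e:
            raise StageError(stage, e) from e
        report["stages"]["enrichment"] = {
            "table": res["table"].tolist(),
            "chi2": res["chi2"],
            "p": res["p"],
            "direction": res["direction"],
        }

    # ---- report --------------------------------------------------------
    report["files"] = {
        str(k): {"path": str(Path(v).relative_to(out)), "sha256": _sha256(v)}
        for k, v in files.items()
    }
    report["wall_clock_s"] = round(time.time() - t0, 3)
    stable = {k: v for k, v in report.items() if k != "wall_clock_s"}
    report["report_checksum"] = hashlib.sha256(
        json.dumps(stable, sort_keys=True).encode()
    ).hexdigest()
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report


def _synthetic_genes(gt, cfg, seed):
    """Random gene annotation over the genotyped scaffolds, a stand-in used
    when no real annotation is supplied (synthetic by construction)."""
    rng = np.random.default_rng(seed + 77_003)
    n_genes = int(cfg.get("n_genes", 200))
    length = int(cfg.get("gene_length", 2_000))
    set_fraction = float(cfg.get("set_fraction", 0.1))
    from .io_core import Region
    from .enrich import GeneInterval

    genes = []
    scafs = list(gt.scaffold_lengths.items())
    for i in range(n_genes):
        scaf, L = scafs[int(rng.integers(len(scafs)))]
        start = int(rng.integers(0, max(L - length, 1)))
        genes.append(GeneInterval(
            gene_id=f"gene_{i + 1}",
            region=Region(scaf, start, min(start + length, L)),
            in_set=bool(rng.random() < set_fraction),
        ))
    return genes
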