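"""End-to-end orchestration of the comparative-mitogenomics workflow.

Stages run in a fixed order — genome I/O, supermatrix construction,
saturation assessment, tree inference and bootstrap, the per-gene influence
audit, exact Bremer/PBS support (when the taxon count permits exhaustive
enumeration), the SNP-hotspot scan, and the ND3 frameshift survey — and
each stage communicates with the next only through files in the run
directory.  Reports are deterministic for a fixed config and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .genomes import base_composition, extract_gene, gene_table, read_genbank
from .infer import bootstrap_support, gene_audit
from .nd3 import calls_to_tsv, classify_nd3, survey, survey_to_tsv
from .parsimony import MAX_ENUM_TAXA, bremer_and_pbs
from .saturation import pairwise_profiles, profiles_to_tsv, saturation_test
from .supermatrix import (GeneAlignment, concatenate, remove_incomplete_columns,
                          strip_stop_codon, write_partitions_json,
                          write_partitions_raxml)
from .trees import bipartitions, classify_arborophila, write_newick
from .variation import bin_profile, hotspot_association_test, variable_sites
from .simulate import GENE_LENGTHS, INGROUP, make_arborophila_benchmark

log = logging.getLogger("mitoaudit")


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    genbank: str | None = None          # real-data mode: GenBank flat file
    synthetic: bool = True              # default: generate the benchmark
    candidates: dict | None = None      # 1-based supermatrix pos -> tier
    order_table: dict | None = None     # taxon -> taxonomic order
    nd3_reference_taxon: str | None = None
    consensus_newick: str | None = None  # externally computed consensus tree
    ingroup: tuple = INGROUP
    bin_width: int = 60
    n_permutations: int = 9999
    bootstrap_replicates: int = 100
    saturation_replicates: int = 300
    distance_model: str = "K80"
    stages: tuple = ("io", "supermatrix", "saturation", "trees", "audit",
                     "support", "scan", "nd3")

    def __post_init__(self):
        if self.synthetic == (self.genbank is not None):
            raise ValueError("exactly one input mode: synthetic or genbank")


def _prepare_gene_alignments(genomes, reference_taxon, out):
    """Extract the 13 PCGs, call ND3 frameshifts, normalize WEC sequences
    (delete the called insertion) and strip stop codons."""
    taxa = [g.taxon for g in genomes]
    if reference_taxon is not None:
        ref_genome = next(g for g in genomes if g.taxon == reference_taxon)
        nd3_reference = extract_gene(ref_genome, "ND3")
    else:
        # auto-pick a frameshift-free reference: in-frame length and clean ORF
        from .nd3 import _first_internal_stop

        nd3_reference = None
        for g in genomes:
            seq = extract_gene(g, "ND3")
            if len(seq) % 3 == 0 and _first_internal_stop(seq, 2) is None:
                nd3_reference = seq
                break
        if nd3_reference is None:
            raise ValueError(
                "no frameshift-free ND3 found to serve as WOC reference; "
                "supply nd3_reference_taxon explicitly"
            )
    calls = []
    per_gene: dict[str, dict[str, str]] = {g: {} for g in GENE_LENGTHS}
    for genome in genomes:
        for gene in GENE_LENGTHS:
            seq = extract_gene(genome, gene)
            if gene == "ND3":
                call = classify_nd3(seq, nd3_reference, accession=genome.accession,
                                    taxon=genome.taxon,
                                    order_name=genome.order_name)
                calls.append(call)
                if call.state == "WEC":
                    p = call.insertion_position - 1
                    seq = seq[:p] + seq[p + 1:]
            seq, _flags = strip_stop_codon(seq)
            per_gene[gene][genome.taxon] = seq
    alns = []
    for gene, seqs in per_gene.items():
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise ValueError(
                f"{gene}: unequal post-normalization lengths {sorted(lengths)}; "
                "an external alignment step is required for these inputs"
            )
        alns.append(GeneAlignment(gene, taxa, [seqs[t] for t in taxa]))
    return alns, calls


def run(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest = {
        "version": __version__, "seed": config.seed,
        "mode": "synthetic" if config.synthetic else "genbank",
        "parameters": {
            "bin_width": config.bin_width,
            "n_permutations": config.n_permutations,
            "bootstrap_replicates": config.bootstrap_replicates,
            "saturation_replicates": config.saturation_replicates,
            "distance_model": config.distance_model,
            "stages": list(config.stages),
        },
        "inputs": {"genbank": config.genbank},
        "stages_completed": [],
    }
    state: dict = {}

    def done(stage):
        manifest["stages_completed"].append(stage)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        log.info("stage %-12s done at +%.1fs", stage, time.time() - t0)

    try:
        if "io" in config.stages:
            if config.synthetic:
                bench = make_arborophila_benchmark(config.seed, out_dir=out / "input")
                genomes = bench.genomes
                state["ledger"] = bench.ledger
            else:
                genomes = read_genbank(config.genbank)
            state["genomes"] = genomes
            gene_table(genomes).to_csv(out / "gene_table.tsv", sep="\t", index=False)
            with open(out / "genome_stats.tsv", "w") as fh:
                fh.write("accession\ttaxon\tlength\tpct_A\tpct_C\tpct_G\tpct_T\n")
                for g in genomes:
                    c = base_composition(g.sequence)
                    fh.write(f"{g.accession}\t{g.taxon}\t{len(g)}\t{c.pct_A:.2f}\t"
                             f"{c.pct_C:.2f}\t{c.pct_G:.2f}\t{c.pct_T:.2f}\n")
            done("io")

        if "supermatrix" in config.stages:
            alns, nd3_calls = _prepare_gene_alignments(
                state["genomes"], config.nd3_reference_taxon, out)
            state["nd3_calls"] = nd3_calls
            sm = concatenate(alns, [g for g in GENE_LENGTHS if any(
                a.gene_name == g for a in alns)])
            pre_width = sm.width
            sm = remove_incomplete_columns(sm)
            state["sm"] = sm
            from .genomes import write_fasta
            write_fasta(dict(zip(sm.taxa, sm.rows)), out / "supermatrix.fasta")
            write_partitions_raxml(sm, out / "partitions.txt")
            write_partitions_json(sm, out / "partitions.json")
            with open(out / "supermatrix_report.json", "w") as fh:
                json.dump({"taxa": sm.taxa, "width_before_filter": pre_width,
                           "width_after_filter": sm.width}, fh, indent=1)
            done("supermatrix")

        if "saturation" in config.stages:
            sm = state["sm"]
            profiles_to_tsv(pairwise_profiles(sm, "all"), out / "pair_profiles.tsv")
            res = saturation_test(sm, replicates=config.saturation_replicates,
                                  seed=config.seed)
            with open(out / "saturation.json", "w") as fh:
                json.dump({"iss": res.iss, "iss_c": res.iss_c,
                           "p_value": res.p_value,
                           "n_otus_subsampled": res.n_otus_subsampled,
                           "replicate_count": res.replicate_count,
                           "decision": res.decision, "rule": res.rule}, fh, indent=1)
            done("saturation")

        if "trees" in config.stages:
            sm = state["sm"]
            if config.consensus_newick:
                from .trees import parse_newick
                consensus = parse_newick(config.consensus_newick)
            else:
                consensus = bootstrap_support(
                    sm, model=config.distance_model,
                    replicates=config.bootstrap_replicates, seed=config.seed)
            state["consensus"] = consensus
            (out / "consensus.nwk").write_text(write_newick(consensus) + "\n")
            try:
                topo = classify_arborophila(consensus)
            except ValueError:
                topo = "n/a"
            (out / "consensus_type.txt").write_text(topo + "\n")
            done("trees")

        if "audit" in config.stages:
            report = gene_audit(state["sm"], state["consensus"],
                                model=config.distance_model)
            state["audit"] = report
            report.to_tsv(out / "gene_audit.tsv")
            done("audit")

        if "support" in config.stages:
            sm = state["sm"]
            if sm.n_taxa <= MAX_ENUM_TAXA:
                clades = sorted(bipartitions(state["consensus"]),
                                key=lambda c: (len(c), sorted(c)))
                genes = sm.gene_order()
                with open(out / "support.tsv", "w") as fh:
                    fh.write("clade\tbremer\t" + "\t".join(genes) + "\n")
                    for clade in clades:
                        rep = bremer_and_pbs(sm, clade)
                        fh.write("\t".join(
                            [",".join(sorted(clade)), str(rep.bremer)]
                            + [str(rep.pbs[g]) for g in genes]) + "\n")
                state["support_clades"] = clades
            else:
                (out / "support.tsv").write_text(
                    "# skipped: taxon count exceeds exhaustive-enumeration cap\n")
            done("support")

        if "scan" in config.stages:
            sm = state["sm"]
            scan_taxa = [t for t in sm.taxa if t in set(config.ingroup)]
            if len(scan_taxa) < 2:
                scan_taxa = list(sm.taxa)
            rows = [sm.row(t) for t in scan_taxa]
            vs = variable_sites(rows)
            candidates = config.candidates
            if candidates is None and "ledger" in state:
                candidates = state["ledger"].candidate_sites
            profile = bin_profile(vs.positions, vs.length,
                                  bin_width=config.bin_width,
                                  candidates=candidates or {},
                                  excluded_columns=vs.gap_columns)
            profile.to_tsv(out / "bin_profile.tsv")
            result = {"n_variable_sites": len(vs.positions),
                      "n_gap_columns_excluded": len(vs.gap_columns),
                      "scan_taxa": scan_taxa}
            if candidates:
                perm = hotspot_association_test(
                    profile, n_permutations=config.n_permutations,
                    seed=config.seed)
                result["permutation_test"] = perm.as_dict()
            with open(out / "variation_scan.json", "w") as fh:
                json.dump(result, fh, indent=1)
            state["scan"] = result
            done("scan")

        if "nd3" in config.stages:
            calls = state.get("nd3_calls", [])
            if config.order_table:
                for c in calls:
                    c.order_name = config.order_table.get(c.taxon, c.order_name)
            calls_to_tsv(calls, out / "nd3_calls.tsv")
            survey_to_tsv(survey(calls), out / "nd3_orders.tsv")
            done("nd3")
    except Exception as exc:
        stage = (set(config.stages) - set(manifest["stages_completed"]))
        log.error("pipeline halted (completed: %s): %s",
                  manifest["stages_completed"], exc)
        raise RuntimeError(
            f"stage failure after {manifest['stages_completed']}: {exc}"
        ) from exc
    return out
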