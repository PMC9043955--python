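"""End-to-end orchestration: simulate -> filter -> assemble -> call ->
features -> network, as one reproducible, seeded run.

Every stage writes plain-text artifacts into the output directory and the
run report records per-stage counts plus a SHA-256 manifest, so two runs
with the same configuration and seed produce byte-identical output trees.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import cdsfilter, hapnet, igsfeat, ribotypes, simarray, unitasm

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    seed: int = 1
    output_dir: str = "ribomine_run"
    simulation: simarray.SimulationConfig = field(
        default_factory=lambda: simarray.SimulationConfig(
            proportions=[0.6, 0.3, 0.1], pseudogene_fraction=0.1))
    assembly: unitasm.AssemblyConfig = field(
        default_factory=lambda: unitasm.AssemblyConfig(min_kmer_coverage=5))
    integrity: ribotypes.IntegrityConfig = field(
        default_factory=ribotypes.IntegrityConfig)
    classification: ribotypes.ClassificationConfig = field(
        default_factory=ribotypes.ClassificationConfig)
    similarity: igsfeat.SimilarityOptions = field(
        default_factory=igsfeat.SimilarityOptions)
    probe_length: int = 20
    map_max_mismatches: int = 2
    cluster_max_edge: int = 3
    epsilon: int = 0
    run_network: bool = True

    def __post_init__(self) -> None:
        self.simulation.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        kwargs = {}
        mapping = {
            "simulation": simarray.SimulationConfig,
            "assembly": unitasm.AssemblyConfig,
            "integrity": ribotypes.IntegrityConfig,
            "classification": ribotypes.ClassificationConfig,
            "similarity": igsfeat.SimilarityOptions,
        }
        for key, val in data.items():
            if key in mapping:
                if key == "simulation" and val.get("duplication_spec"):
                    val["duplication_spec"] = simarray.DuplicationSpec(
                        **val["duplication_spec"])
                kwargs[key] = mapping[key](**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)


@dataclass
class RunReport:
    seed: int
    stages: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> RunReport:
    """Run all stages in order; any failure leaves a ``failed/`` marker.

    With a degenerate input (e.g. pure background reads) the run completes
    with an empty catalog and an explicit warning rather than failing.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)
    stage = "setup"
    try:
        stage = "simulate"
        sim = config.simulation
        _, ribos, truth = simarray.generate_ribotype_set(sim)
        array = simarray.build_tandem_array(ribos, truth, sim)
        library = simarray.simulate_reads(array, sim)
        simarray.write_array_fasta(array, out / "array.fasta")
        simarray.write_truth(truth, out / "truth.tsv")
        simarray.write_fastq(library, out / "reads.fastq")
        simarray.write_config(sim, out / "sim_config.yaml")
        report.stages[stage] = {
            "array_length": len(array),
            "n_reads": len(library),
            "n_ribotypes_true": len(ribos),
        }

        stage = "filter"
        probes = cdsfilter.make_probes(truth.cds, config.probe_length)
        fstats = cdsfilter.FilterStats()
        filtered = cdsfilter.filter_reads(library, probes, stats=fstats)
        simarray.write_fastq(filtered, out / "filtered.fastq")
        report.stages[stage] = {
            "kept": fstats.kept, "discarded": fstats.discarded,
            "too_short": fstats.too_short,
        }

        stage = "assemble"
        graph = unitasm.build_graph(filtered, config.assembly)
        contigs = unitasm.prune_and_assemble(graph, config.assembly)
        unitasm.write_contigs_fasta(contigs, out / "contigs.fasta")
        units = unitasm.assemble_units(filtered, truth.cds, config.assembly,
                                       config.probe_length)
        unitasm.write_units_fasta(units, out / "units.fasta")
        report.stages[stage] = {
            "n_kmers": len(graph), "n_contigs": len(contigs),
            "n_units": len(units),
        }

        stage = "call"
        catalog = ribotypes.dedup_ribotypes(units, config.integrity)
        if catalog.ribotypes:
            table = ribotypes.estimate_abundance(
                catalog, library, config.map_max_mismatches)
            table = ribotypes.classify(table, config.classification, catalog)
            class_counts = table.class_counts
            cum = table.cumulative_major_minor
            table.rows.to_csv(out / "abundance.tsv", sep="\t", index=False)
        else:
            log.warning("pipeline: empty ribotype catalog")
            class_counts, cum = {"major": 0, "minor": 0, "rare": 0}, 0.0
            (out / "abundance.tsv").write_text(
                "ribotype_id\tassigned_weight\trelative_content"
                "\tabundance_class\n")
        with open(out / "catalog.fasta", "w") as fh:
            for rt in catalog.ribotypes:
                fh.write(f">{rt.id} class={rt.abundance_class} "
                         f"content={rt.relative_content:.4f}\n{rt.igs_seq}\n")
        with open(out / "pseudogenes.tsv", "w") as fh:
            fh.write("source_contig\tn_mutations\tmutations\n")
            for u, muts in catalog.pseudogenes:
                desc = ";".join(f"{m.kind}@{m.position}:{m.ref}>{m.alt}"
                                for m in muts)
                fh.write(f"{u.source_contig}\t{len(muts)}\t{desc}\n")
        report.stages[stage] = {
            "n_ribotypes": len(catalog.ribotypes),
            "n_pseudogenes": len(catalog.pseudogenes),
            "class_counts": class_counts,
            "cumulative_major_minor": round(cum, 6),
        }

        stage = "features"
        rows = []
        for rt in catalog.ribotypes:
            dup = igsfeat.find_tandem_duplication(
                rt.representative_unit.unit_seq,
                cds_length=len(rt.representative_unit.cds_seq))
            rows.append({
                "ribotype_id": rt.id,
                "igs_length": len(rt.igs_seq),
                "gc_percent": round(igsfeat.gc_content(rt.igs_seq), 1),
                "class": rt.abundance_class,
                "content": round(rt.relative_content, 4),
                "duplication": dup.unit_length if dup else 0,
            })
        sim_range = igsfeat.similarity_range(
            [rt.igs_seq for rt in catalog.ribotypes], config.similarity)
        with open(out / "features.tsv", "w") as fh:
            fh.write("ribotype_id\tigs_length\tgc_percent\tclass\tcontent"
                     "\tduplication_unit\n")
            for r in rows:
                fh.write(f"{r['ribotype_id']}\t{r['igs_length']}"
                         f"\t{r['gc_percent']}\t{r['class']}\t{r['content']}"
                         f"\t{r['duplication']}\n")
        with open(out / "motifs.tsv", "w") as fh:
            fh.write("ribotype_id\tmotif\tfound\toffset\tmismatches\n")
            for rt in catalog.ribotypes:
                for hit in igsfeat.scan_promoter_motifs(
                        rt.representative_unit):
                    fh.write(f"{rt.id}\t{hit.name}\t{int(hit.found)}"
                             f"\t{hit.offset}\t{hit.mismatches}\n")
        report.stages[stage] = {
            "n_rows": len(rows),
            "similarity_range": list(sim_range) if sim_range else None,
        }

        stage = "network"
        if config.run_network and len(catalog.ribotypes) >= 2:
            aln = hapnet.align_small(
                {rt.id: rt.igs_seq for rt in catalog.ribotypes},
                config.similarity)
            net = hapnet.mj_network(aln, config.epsilon)
            assignment, sizes = hapnet.cluster_by_threshold(
                net, config.cluster_max_edge)
            hapnet.write_graphml(net, out / "network.graphml")
            with open(out / "clusters.tsv", "w") as fh:
                fh.write("node\tcluster\tkind\tmultiplicity\n")
                for node in sorted(assignment):
                    data = net.graph.nodes[node]
                    fh.write(f"{node}\t{assignment[node]}\t{data['kind']}"
                             f"\t{data['multiplicity']}\n")
            report.stages[stage] = {
                "n_nodes": net.graph.number_of_nodes(),
                "n_medians": len(net.medians),
                "n_clusters": len(sizes),
            }
        else:
            report.stages[stage] = {"skipped": True}

        stage = "manifest"
        for p in sorted(out.glob("*")):
            if p.is_file() and p.name != "report.json":
                report.manifest[p.name] = _sha256(p)
        (out / "report.json").write_text(report.to_json())
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        marker = out / "failed"
        marker.mkdir(exist_ok=True)
        (marker / f"{stage}.txt").write_text(f"{type(exc).__name__}: {exc}\n")
        raise PipelineError(stage, exc) from exc
    return report
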