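"""End-to-end orchestration: detect -> context -> extract -> matrices ->
consensus -> scan -> compare, with provenance manifest and run log.

Every numeric cell in the emitted reports is re-derivable by calling the
owning module's operation directly; the pipeline adds no math of its own.
Reruns with identical inputs are bit-identical (no timestamps enter any
output file); each run goes to a fresh numbered run directory so prior
outputs are never mutated.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .consensus import ConservedSequence, build_star_msa, derive_conserved_sequence
from .genomic_context import assign_context, extract_region
from .io_formats import (
    NucleotideSequence,
    UsageError,
    read_fasta,
    read_gene_models,
    read_mirna_db,
    read_repeatmasker_out,
    write_fasta,
)
from .mirna_scan import hits_to_bed6, scan_mirnas, summarize_hits
from .pairwise_alignment import ScoringScheme, align_global, identity_matrix
from .species_compare import compare_hit_sets, family_rollup, species_prefix_counts
from .trinomial_detection import (
    DEFAULT_IGNORE_CLASSES,
    clusters_to_bed6,
    detect_trinomial_clusters,
    name_clusters,
)

log = logging.getLogger("trirec")

__all__ = ["SpeciesInputs", "PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class SpeciesInputs:
    label: str
    genome: str
    repeats: str
    genes: str
    gene_dialect: str = "gff3"


@dataclass
class PipelineConfig:
    species_a: SpeciesInputs
    species_b: SpeciesInputs
    mirna_db: str
    outdir: str
    seed: int = 0
    # detection
    line_family: str = "RTE-BovB"
    ltr_family: str = "BTLTR1"
    max_gap: int = 100
    detection_mode: str = "adjacency"
    require_same_strand: bool = True
    ignore_classes: tuple[str, ...] = tuple(sorted(DEFAULT_IGNORE_CLASSES))
    # alignment scoring
    match: int = 5
    mismatch: int = -4
    gap_open: int = 12
    gap_extend: int = 2
    # consensus thresholds
    min_source_identity: float = 95.0
    min_occupancy: float = 0.9
    # miRNA scan thresholds
    seed_k: int = 7
    scan_min_identity: float = 85.0
    scan_min_coverage: float = 0.9
    both_strands: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("species_a", "species_b"):
            raw[key] = SpeciesInputs(**raw[key])
        if "ignore_classes" in raw:
            raw["ignore_classes"] = tuple(raw["ignore_classes"])
        return cls(**raw)

    def scoring(self) -> ScoringScheme:
        return ScoringScheme(self.match, self.mismatch, self.gap_open,
                             self.gap_extend)

    def validate(self) -> None:
        for sp in (self.species_a, self.species_b):
            for p in (sp.genome, sp.repeats, sp.genes):
                if not Path(p).exists():
                    raise UsageError(f"input path does not exist: {p}")
        if not Path(self.mirna_db).exists():
            raise UsageError(f"input path does not exist: {self.mirna_db}")
        if self.species_a.label == self.species_b.label:
            raise UsageError("species labels must differ")


@dataclass
class SpeciesResult:
    label: str
    clusters: list
    context: list
    regions: list[NucleotideSequence]
    matrix: Optional[object]
    conserved: ConservedSequence
    hits: list


@dataclass
class PipelineResult:
    run_dir: Path
    species_a: SpeciesResult
    species_b: SpeciesResult
    cross_identity: dict[str, float]
    comparison: object
    rollup: dict
    manifest: dict


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _next_run_dir(outdir: Path) -> Path:
    outdir.mkdir(parents=True, exist_ok=True)
    i = 1
    while (outdir / f"run-{i:04d}").exists():
        i += 1
    run_dir = outdir / f"run-{i:04d}"
    run_dir.mkdir()
    return run_dir


def _process_species(cfg: PipelineConfig, sp: SpeciesInputs, run_dir: Path,
                     logfh) -> SpeciesResult:
    genome = read_fasta(sp.genome)
    features = read_repeatmasker_out(sp.repeats)
    genes = read_gene_models(sp.genes, sp.gene_dialect)
    clusters = detect_trinomial_clusters(
        features, cfg.line_family, cfg.ltr_family, cfg.max_gap,
        frozenset(cfg.ignore_classes), cfg.detection_mode,
        cfg.require_same_strand,
    )
    name_clusters(clusters)
    context = assign_context(clusters, genes)
    print(f"stage=detect species={sp.label} features={len(features)} "
          f"clusters={len(clusters)}", file=logfh)
    regions = []
    for c in clusters:
        r = extract_region(genome, c.chrom, c.span_start, c.span_end,
                           c.orientation)
        r.id = f"{sp.label}:{c.name}"
        regions.append(r)
    scoring = cfg.scoring()
    matrix = None
    if len(regions) >= 2:
        matrix = identity_matrix(regions, "global", scoring)
        matrix.write_tsv(run_dir / f"identity_matrix_{sp.label}.tsv")
        with open(run_dir / f"identity_matrix_{sp.label}.json", "w") as fh:
            json.dump(matrix.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    if len(regions) >= 2:
        center = None
        if matrix is not None:
            # medoid of the identity matrix doubles as the star center
            totals = matrix.values.sum(axis=1)
            order = sorted(range(len(regions)),
                           key=lambda i: (-totals[i], matrix.labels[i]))
            center = matrix.labels[order[0]]
        msa = build_star_msa(regions, scoring, center_label=center)
        msa.write_fasta(run_dir / f"msa_{sp.label}.fasta")
        conserved = derive_conserved_sequence(
            msa, cfg.min_source_identity, cfg.min_occupancy)
    elif len(regions) == 1:
        conserved = ConservedSequence(
            residues=regions[0].residues, msa_window=(1, len(regions[0])),
            per_source_identity={regions[0].id: 100.0}, min_identity=100.0,
            diagnostic="single source region; consensus equals the region",
        )
    else:
        conserved = ConservedSequence(
            residues="", msa_window=None, per_source_identity={},
            min_identity=0.0, diagnostic="no cluster regions detected",
        )
    print(f"stage=consensus species={sp.label} window_bp={len(conserved)} "
          f"min_identity={conserved.min_identity:.2f}", file=logfh)

    clusters_to_bed6(clusters, run_dir / f"clusters_{sp.label}.bed")
    with open(run_dir / f"clusters_{sp.label}.tsv", "w") as fh:
        fh.write("name\tchrom\tspan_start\tspan_end\torientation\t"
                 "gap_left\tgap_right\tdetection_mode\n")
        for c in clusters:
            fh.write(f"{c.name}\t{c.chrom}\t{c.span_start}\t{c.span_end}\t"
                     f"{c.orientation}\t{c.gap_left}\t{c.gap_right}\t"
                     f"{c.detection_mode}\n")
    with open(run_dir / f"context_{sp.label}.tsv", "w") as fh:
        fh.write("cluster\thost_gene\tcontext\n")
        for call in context:
            fh.write(f"{call.cluster_name}\t{call.host_gene or 'NA'}\t"
                     f"{call.context}\n")
    if regions:
        write_fasta(regions, run_dir / f"regions_{sp.label}.fasta")

    hits = []
    if conserved.residues:
        db = read_mirna_db(cfg.mirna_db)
        query = NucleotideSequence(f"{sp.label}_conserved", conserved.residues)
        hits = scan_mirnas(query, db, cfg.seed_k, cfg.scan_min_identity,
                           cfg.scan_min_coverage, cfg.both_strands)
        write_fasta([query], run_dir / f"conserved_{sp.label}.fasta")
        with open(run_dir / f"conserved_{sp.label}_identity.tsv", "w") as fh:
            fh.write("source\tpct_identity\n")
            for label in sorted(conserved.per_source_identity):
                fh.write(f"{label}\t{conserved.per_source_identity[label]:.2f}\n")
        with open(run_dir / f"hits_{sp.label}.tsv", "w") as fh:
            fh.write("mirna\tquery\tq_start\tq_end\tstrand\taligned_length\t"
                     "mismatches\tgaps\tidentity\tcoverage\n")
            for h in hits:
                fh.write(f"{h.mirna_name}\t{h.query_id}\t{h.q_start}\t{h.q_end}"
                         f"\t{h.strand}\t{h.aligned_length}\t{h.mismatches}\t"
                         f"{h.gaps}\t{h.identity:.2f}\t{h.coverage:.3f}\n")
        hits_to_bed6(hits, run_dir / f"hits_{sp.label}.bed")
    print(f"stage=scan species={sp.label} hits={len(hits)} "
          f"distinct={len({h.mirna_name for h in hits})}", file=logfh)
    return SpeciesResult(sp.label, clusters, context, regions, matrix,
                         conserved, hits)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage on two species and write the report bundle."""
    cfg.validate()
    run_dir = _next_run_dir(Path(cfg.outdir))
    with open(run_dir / "run.log", "w") as logfh:
        res_a = _process_species(cfg, cfg.species_a, run_dir, logfh)
        res_b = _process_species(cfg, cfg.species_b, run_dir, logfh)

        # per-cluster cross-species identity (homologs paired by name)
        scoring = cfg.scoring()
        by_name_a = {c.name: r for c, r in zip(res_a.clusters, res_a.regions)}
        by_name_b = {c.name: r for c, r in zip(res_b.clusters, res_b.regions)}
        cross = {}
        for name in sorted(set(by_name_a) & set(by_name_b)):
            aln = align_global(by_name_a[name], by_name_b[name], scoring)
            cross[name] = round(aln.pct_identity, 2)
        with open(run_dir / "cross_species_identity.tsv", "w") as fh:
            fh.write(f"cluster\tpct_identity_"
                     f"{cfg.species_a.label}_vs_{cfg.species_b.label}\n")
            for name, pid in cross.items():
                fh.write(f"{name}\t{pid:.2f}\n")
        ratio = (len(res_a.clusters) / len(res_b.clusters)
                 if res_b.clusters else None)
        print(f"stage=cross clusters_a={len(res_a.clusters)} "
              f"clusters_b={len(res_b.clusters)} "
              f"ratio={'NA' if ratio is None else f'{ratio:.3f}'} "
              f"paired={len(cross)}", file=logfh)

        comparison = compare_hit_sets(res_a.hits, res_b.hits,
                                      cfg.species_a.label, cfg.species_b.label)
        comparison.write_json(run_dir / "comparison.json")
        rollup = family_rollup(comparison)
        with open(run_dir / "family_table.tsv", "w") as fh:
            fh.write("family\tcommon\tonly_a\tonly_b\n")
            for fam, counts in rollup["families"].items():
                fh.write(f"{fam}\t{counts['common']}\t{counts['only_a']}\t"
                         f"{counts['only_b']}\n")
        summary = {
            "species_a": summarize_hits(res_a.hits),
            "species_b": summarize_hits(res_b.hits),
            "n_common": len(comparison.common),
            "n_only_a": len(comparison.only_a),
            "n_only_b": len(comparison.only_b),
            "species_prefixes_a": species_prefix_counts(comparison.set_a),
            "species_prefixes_b": species_prefix_counts(comparison.set_b),
            "cluster_count_a": len(res_a.clusters),
            "cluster_count_b": len(res_b.clusters),
            "cluster_count_ratio_a_over_b": ratio,
            "dominant_family_only_a": rollup["dominant_family_only_a"],
            "dominant_share_only_a": rollup["dominant_share_only_a"],
        }
        with open(run_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        print(f"stage=compare common={summary['n_common']} "
              f"only_a={summary['n_only_a']} only_b={summary['n_only_b']}",
              file=logfh)

    cfg_dict = asdict(cfg)
    # the run location must not make otherwise-identical reruns differ
    cfg_dict["outdir"] = ""
    manifest = {
        "trirec_version": __version__,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
        "input_sha256": {
            "genome_a": _sha256(cfg.species_a.genome),
            "repeats_a": _sha256(cfg.species_a.repeats),
            "genes_a": _sha256(cfg.species_a.genes),
            "genome_b": _sha256(cfg.species_b.genome),
            "repeats_b": _sha256(cfg.species_b.repeats),
            "genes_b": _sha256(cfg.species_b.genes),
            "mirna_db": _sha256(cfg.mirna_db),
        },
    }
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return PipelineResult(run_dir, res_a, res_b, cross, comparison, rollup,
                          manifest)
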