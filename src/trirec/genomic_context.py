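"""Gene/intron/intergenic context of clusters, region extraction, synteny.

Overlap semantics are closed-interval (two intervals overlap when they share
at least one base).  A cluster straddling a gene boundary is called
``mixed`` rather than forced into the gene; ``exonic`` and ``intronic`` are
reserved for clusters lying fully inside the host gene span.  When a cluster
lies inside two overlapping genes the host is the gene with the larger
overlap, ties going to the lexicographically smaller gene id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .io_formats import (
    CoordinateError,
    GeneModel,
    NucleotideSequence,
    reverse_complement,
)
from .trinomial_detection import TrinomialCluster

log = logging.getLogger("trirec")

__all__ = ["GenomicContextCall", "SyntenyReport", "assign_context",
           "extract_region", "check_synteny"]


@dataclass
class GenomicContextCall:
    """Placement of one cluster relative to the gene annotation."""

    cluster_name: str
    host_gene: Optional[str]
    context: str  # intronic | exonic | intergenic | mixed


def _overlap(s1: int, e1: int, s2: int, e2: int) -> int:
    return max(0, min(e1, e2) - max(s1, s2) + 1)


def assign_context(clusters: Sequence[TrinomialCluster],
                   genes: Sequence[GeneModel]) -> list[GenomicContextCall]:
    """Classify each cluster as intronic / exonic / intergenic / mixed.

    Cluster names gain their host-gene suffix here (``+1-NA`` becomes e.g.
    ``+1-gart``); intergenic clusters keep ``NA``.  Clusters on chromosomes
    absent from the gene set are intergenic with a logged warning.
    """
    trees: dict[str, IntervalTree] = {}
    by_id: dict[str, GeneModel] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g.gene_id)
        by_id[g.gene_id] = g
    known_chroms = set(trees)

    calls = []
    for c in clusters:
        if c.chrom not in known_chroms:
            log.warning("cluster %s on chrom %s absent from gene annotation",
                        c.name, c.chrom)
            calls.append(GenomicContextCall(c.name, None, "intergenic"))
            continue
        hits = trees[c.chrom].overlap(c.span_start, c.span_end + 1)
        if not hits:
            calls.append(GenomicContextCall(c.name, None, "intergenic"))
            continue
        # host = largest overlap, ties to the lexicographically smaller id
        host = min(
            (iv.data for iv in hits),
            key=lambda gid: (
                -_overlap(c.span_start, c.span_end, by_id[gid].start, by_id[gid].end),
                gid,
            ),
        )
        g = by_id[host]
        if not (g.start <= c.span_start and c.span_end <= g.end):
            context = "mixed"
        elif any(_overlap(c.span_start, c.span_end, es, ee) for es, ee in g.exons):
            context = "exonic"
        else:
            context = "intronic"
        if c.name.endswith("-NA"):
            c.name = c.name[:-2] + host
        calls.append(GenomicContextCall(c.name, host, context))
    return calls


def extract_region(genome: Sequence[NucleotideSequence], chrom: str,
                   start: int, end: int, strand: str = "+") -> NucleotideSequence:
    """Extract a strand-aware region (1-based inclusive coordinates).

    Strand ``C`` returns the reverse complement; the record id encodes
    ``chrom:start-end(strand)``.
    """
    by_id = {s.id: s for s in genome}
    if chrom not in by_id:
        raise CoordinateError(f"chromosome {chrom!r} not in genome")
    seq = by_id[chrom].residues
    if not (1 <= start <= end <= len(seq)):
        raise CoordinateError(
            f"{chrom}:{start}-{end} outside 1..{len(seq)}"
        )
    sub = seq[start - 1:end]
    if strand == "C":
        sub = reverse_complement(sub)
    return NucleotideSequence(f"{chrom}:{start}-{end}({strand})", sub)


@dataclass
class SyntenyReport:
    """Presence, order and orientation of a gene block in two species."""

    species_a_order: list[str]
    species_b_order: list[str]
    shared: list[str]
    order_preserved: bool
    orientation_flips: list[str]
    missing_a: list[str]
    missing_b: list[str]

    def to_dict(self) -> dict:
        return {
            "species_a_order": self.species_a_order,
            "species_b_order": self.species_b_order,
            "shared": self.shared,
            "order_preserved": self.order_preserved,
            "orientation_flips": self.orientation_flips,
            "missing_a": self.missing_a,
            "missing_b": self.missing_b,
        }


def check_synteny(genes_a: Sequence[GeneModel], genes_b: Sequence[GeneModel],
                  block: Sequence[str]) -> SyntenyReport:
    """Check co-localisation of a gene block across two species.

    Each species' genes are ordered by (chrom, start); for scaffold-split
    assemblies the scaffold order therefore follows the scaffold naming, and
    the report is only meaningful per scaffold run.  Genes absent from a
    species are listed as missing rather than failing the check.  Order is
    compared after projecting both species onto the shared gene set;
    ``orientation_flips`` lists shared genes whose strands disagree.
    """
    if not block:
        raise ValueError("gene block must be non-empty")
    block_set = set(block)

    def ordered(genes: Sequence[GeneModel]) -> list[GeneModel]:
        present = [g for g in genes if g.gene_id in block_set]
        return sorted(present, key=lambda g: (g.chrom, g.start))

    ga, gb = ordered(genes_a), ordered(genes_b)
    order_a = [g.gene_id for g in ga]
    order_b = [g.gene_id for g in gb]
    shared_set = set(order_a) & set(order_b)
    proj_a = [g for g in order_a if g in shared_set]
    proj_b = [g for g in order_b if g in shared_set]
    strand_a = {g.gene_id: g.strand for g in ga}
    strand_b = {g.gene_id: g.strand for g in gb}
    flips = [g for g in proj_a if strand_a[g] != strand_b[g]]
    return SyntenyReport(
        species_a_order=order_a,
        species_b_order=order_b,
        shared=proj_a,
        order_preserved=proj_a == proj_b,
        orientation_flips=flips,
        missing_a=[g for g in block if g not in set(order_a)],
        missing_b=[g for g in block if g not in set(order_b)],
    )
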