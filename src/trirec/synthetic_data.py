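"""Paired-species synthetic scenarios with full ground truth.

The generator emulates the study design the pipeline targets: two closely
related genomes (a domesticated-like species A and a wild-like species B)
sharing a syntenic block of 12 genes, with trinomial LINE/LTR/LINE clusters
planted only inside introns.  All cluster copies descend from one ancestral
element by substitution-only mutation, so every realized identity is
computable directly from the planted substitutions:

* each copy's flanks diverge at ``cluster_divergence`` per site, while a
  fixed interior window of ``core_length`` bp (the conserved core, default
  266 bp) stays within ``core_identity_floor`` percent identity of the
  ancestor - one designated copy sits exactly at the floor so the realized
  minimum matches the configured floor;
* species B is species A mutated at ``species_divergence`` per site outside
  the cores; inside each core, a small set of species-level substitutions
  (``core_species_subs``, shared by every B copy) plus bounded per-copy
  noise keeps B cores within the floor of their A counterparts and gives
  the two species distinct core references;
* the mature-miRNA database mixes planted homologs of the core (with
  controlled mismatch counts and strands, mismatches kept out of a protected
  seed window) and random decoys at 1:``decoy_ratio``.

The ground truth records planted coordinates, realized identities and - for
every database record, decoys included - the expected hit flag per species,
computed by an exhaustive ungapped slide against each species' core
reference (independent of the pipeline's seed-and-extend scan).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io_formats import (
    GeneModel,
    MiRNARecord,
    NucleotideSequence,
    RepeatFeature,
    UsageError,
    reverse_complement,
    write_fasta,
    write_gff3,
    write_repeatmasker_out,
)

__all__ = ["ScenarioConfig", "Scenario", "simulate", "generate_scenario",
           "GENE_BLOCK"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# the 12-gene syntenic block with gene strands and the canonical allocation
# of 30 clusters (n_forward, n_complement per gene); the forward/complement
# numbering this induces is +1-gart .. +20-jam2 / c1-kcne2 .. c10-jam2
GENE_BLOCK = [
    ("kcne2", "C", 0, 1), ("gart", "+", 1, 0), ("tmem50b", "+", 1, 0),
    ("il10rb", "C", 2, 0), ("ifnar2", "C", 1, 0), ("urb1", "+", 1, 0),
    ("grik1", "+", 6, 3), ("usp16", "C", 0, 1), ("ltn1", "+", 1, 0),
    ("cyyr1", "+", 0, 1), ("app", "+", 6, 3), ("jam2", "C", 1, 1),
]

_PREFIX_POOL = ["hsa", "mmu", "mtr", "eca", "gga", "oar", "chi", "ssc",
                "bta", "aly", "osa", "cfa"]
_A_ONLY_NAMES = [("bta", "miR-30a", "5p"), ("bta", "miR-30e", "5p"),
                 ("hsa", "miR-30c", "5p"), ("mmu", "miR-30d", "3p"),
                 ("eca", "miR-30b", "5p")]
_B_ONLY_NAMES = [("cli", "miR-1416", "3p"), ("bbi", "miR-526b", "none"),
                 ("gga", "miR-1272", "none")]


@dataclass
class ScenarioConfig:
    """Study-condition parameters of a synthetic scenario."""

    seed: int = 0
    genome_length: int = 240_000
    n_genes: int = 12
    exon_length_range: tuple[int, int] = (120, 300)
    intron_pad_range: tuple[int, int] = (350, 700)
    intergenic_range: tuple[int, int] = (1400, 2600)
    n_clusters: int = 30
    line_length_range: tuple[int, int] = (220, 320)
    ltr_length_range: tuple[int, int] = (150, 220)
    gap_range: tuple[int, int] = (25, 80)
    cluster_divergence: float = 0.08
    species_divergence: float = 0.03
    core_length: int = 266
    core_identity_floor: float = 95.0
    core_species_subs: int = 4
    n_mirnas: int = 16
    n_mirnas_a_only: int = 3
    n_mirnas_b_only: int = 1
    decoy_ratio: int = 4
    mirna_length_range: tuple[int, int] = (18, 24)
    planted_mirna_mismatches: tuple[int, ...] = (0, 1, 2, 3, 0, 1, 2, 5, 0, 2, 4, 6)
    scan_seed_k: int = 7
    scan_min_identity: float = 85.0
    scan_min_coverage: float = 0.9
    line_name: str = "RTE-BovB"
    line_class: str = "LINE/RTE-BovB"
    ltr_name: str = "BTLTR1"
    ltr_class: str = "LTR/ERVL"
    label_a: str = "cattle_like"
    label_b: str = "bison_like"
    chrom: str = "chr1"

    @property
    def core_sub_cap(self) -> int:
        """Maximum substitutions a core copy may carry and keep the floor."""
        return int((1.0 - self.core_identity_floor / 100.0) * self.core_length)

    def validate(self) -> None:
        for name in ("exon_length_range", "intron_pad_range", "intergenic_range",
                     "line_length_range", "ltr_length_range", "gap_range",
                     "mirna_length_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise UsageError(f"{name} is degenerate: {(lo, hi)}")
        for name in ("cluster_divergence", "species_divergence"):
            if not 0.0 <= getattr(self, name) <= 0.3:
                raise UsageError(f"{name} must be in [0, 0.3]")
        if not 0.0 <= self.core_identity_floor <= 100.0:
            raise UsageError("core_identity_floor must be in [0, 100]")
        min_span = (2 * self.line_length_range[0] + self.ltr_length_range[0]
                    + 2 * self.gap_range[0])
        if min_span < self.core_length + 24:
            raise UsageError(
                "cluster span too small to carry the conserved core: "
                f"min span {min_span} < core {self.core_length} + 24"
            )
        if self.core_sub_cap < self.core_species_subs:
            raise UsageError(
                "core_identity_floor leaves no room for core_species_subs"
            )
        n_specific = self.n_mirnas_a_only + self.n_mirnas_b_only
        if n_specific > self.n_mirnas:
            raise UsageError("species-specific miRNAs exceed n_mirnas")
        if n_specific > 0 and self.core_species_subs < 3:
            raise UsageError(
                "species-specific miRNAs need core_species_subs >= 3"
            )
        if self.n_clusters < 1 or self.n_genes < 1:
            raise UsageError("need at least one gene and one cluster")


@dataclass
class Scenario:
    """An in-memory synthetic scenario plus its ground truth."""

    config: ScenarioConfig
    genome_a: list[NucleotideSequence]
    genome_b: list[NucleotideSequence]
    repeats_a: list[RepeatFeature]
    repeats_b: list[RepeatFeature]
    genes_a: list[GeneModel]
    genes_b: list[GeneModel]
    mirna_db: list[MiRNARecord]
    truth: dict


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode("ascii")


def _mutate_positions(rng: np.random.Generator, arr: np.ndarray,
                      positions: np.ndarray) -> None:
    """Substitute each position with a different base, in place."""
    if positions.size == 0:
        return
    shift = rng.integers(1, 4, positions.size).astype(np.uint8)
    code = np.zeros(256, np.uint8)
    for i, b in enumerate(b"ACGT"):
        code[b] = i
    old = code[arr[positions]]
    arr[positions] = _BASES[(old + shift) % 4]


def _hamming(x: str, y: str) -> int:
    return sum(1 for a, b in zip(x, y) if a != b)


def _allocation(cfg: ScenarioConfig) -> list[tuple[str, str, int, int]]:
    if cfg.n_genes == 12 and cfg.n_clusters == 30:
        return list(GENE_BLOCK)
    names = [g for g, *_ in GENE_BLOCK][:cfg.n_genes]
    names += [f"gene{i + 1}" for i in range(len(names), cfg.n_genes)]
    strands = {g: s for g, s, *_ in GENE_BLOCK}
    counts = {g: [0, 0] for g in names}
    for i in range(cfg.n_clusters):
        g = names[i % cfg.n_genes]
        counts[g][1 if i % 3 == 2 else 0] += 1
    return [(g, strands.get(g, "+"), counts[g][0], counts[g][1]) for g in names]


def _best_semiglobal(mature: str, ref: str) -> tuple[int, int, int, int]:
    """Best full-width semiglobal alignment of a mature against a reference.

    The full mature aligns against any stretch of the reference (free
    reference end-gaps), maximising the scan's published placement score
    2*matches - 3*mismatches - 5*gap_columns.  Unlike the pipeline's search
    this is a complete dynamic programme over the whole reference - no
    seeding, no band.  Returns (score, matches, mismatches, gap_columns).
    """
    L, R = len(mature), len(ref)
    NEG = -(10 ** 9)
    score = [[0] * (R + 1) for _ in range(L + 1)]
    bt = [[0] * (R + 1) for _ in range(L + 1)]  # 1 diag, 2 up, 3 left
    for i in range(1, L + 1):
        score[i][0] = score[i - 1][0] - 5
        bt[i][0] = 2
    for i in range(1, L + 1):
        row, prev = score[i], score[i - 1]
        btrow = bt[i]
        mc = mature[i - 1]
        for j in range(1, R + 1):
            s = 2 if mc == ref[j - 1] else -3
            cand = prev[j - 1] + s
            ptr = 1
            if prev[j] - 5 > cand:
                cand = prev[j] - 5
                ptr = 2
            if row[j - 1] - 5 > cand:
                cand = row[j - 1] - 5
                ptr = 3
            row[j] = cand
            btrow[j] = ptr
    end_j = max(range(R + 1), key=lambda j: (score[L][j], -j))
    i, j = L, end_j
    matches = mm = gaps = 0
    while i > 0:
        p = bt[i][j]
        if p == 1:
            if mature[i - 1] == ref[j - 1]:
                matches += 1
            else:
                mm += 1
            i -= 1
            j -= 1
        elif p == 2:
            gaps += 1
            i -= 1
        else:
            gaps += 1
            j -= 1
    return score[L][end_j], matches, mm, gaps


def _expected_hit(mature: str, ref: str, min_identity: float,
                  min_coverage: float) -> tuple[bool, Optional[int]]:
    """Does the mature match the reference under the scan's criteria?

    This is the generator's own truth oracle: an exhaustive ungapped slide
    over every offset (covering end-clipped placements) plus a complete
    gapped semiglobal dynamic programme (covering indel-rescued placements),
    both strands, sharing no code with the pipeline's seed-and-extend
    search.  Returns (hit, edit count of the best passing placement, gaps
    counted with mismatches).
    """
    L = len(mature)
    best_edits: Optional[int] = None
    for seq in (mature, reverse_complement(mature)):
        for d in range(-(L - 1), len(ref)):
            ms = max(0, -d)
            me = min(L, len(ref) - d)
            cols = me - ms
            if cols < 1 or cols / L < min_coverage:
                continue
            mm = _hamming(seq[ms:me], ref[d + ms:d + me])
            if 100.0 * (cols - mm) / cols < min_identity:
                continue
            if best_edits is None or mm < best_edits:
                best_edits = mm
        _, matches, mm, gaps = _best_semiglobal(seq, ref)
        cols = matches + mm + gaps
        if cols and 100.0 * matches / cols >= min_identity and 1.0 >= min_coverage:
            if best_edits is None or mm + gaps < best_edits:
                best_edits = mm + gaps
    return best_edits is not None, best_edits


def simulate(cfg: ScenarioConfig) -> Scenario:
    """Build a scenario in memory (deterministic in ``cfg.seed``)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    cap = cfg.core_sub_cap

    # --- ancestral trinomial element -------------------------------------
    ll1 = int(rng.integers(cfg.line_length_range[0], cfg.line_length_range[1] + 1))
    ll2 = int(rng.integers(cfg.line_length_range[0], cfg.line_length_range[1] + 1))
    lt = int(rng.integers(cfg.ltr_length_range[0], cfg.ltr_length_range[1] + 1))
    gl = int(rng.integers(cfg.gap_range[0], cfg.gap_range[1] + 1))
    gr = int(rng.integers(cfg.gap_range[0], cfg.gap_range[1] + 1))
    anc = _rand_dna(rng, ll1 + gl + lt + gr + ll2)
    span = len(anc)
    core_off = (span - cfg.core_length) // 2
    core_a_ref = anc[core_off:core_off + cfg.core_length]

    # species-level core substitutions: a short consecutive block plus
    # isolated positions, all interior so window-boundary jitter cannot
    # clip planted miRNA loci
    s = cfg.core_species_subs
    sp_positions: list[int] = []
    if s > 0:
        block_len = min(3, s)
        p3 = int(rng.integers(60, 120))
        sp_positions.extend(range(p3, p3 + block_len))
        extra = s - block_len
        if extra > 0:
            lo, hi = 170, min(240, cfg.core_length - 12)
            step = max(1, (hi - lo) // max(extra, 1))
            sp_positions.extend(lo + i * step for i in range(extra))
    core_b_arr = np.frombuffer(core_a_ref.encode(), np.uint8).copy()
    _mutate_positions(rng, core_b_arr, np.array(sp_positions, dtype=np.int64))
    core_b_ref = core_b_arr.tobytes().decode("ascii")

    # --- cluster copies ---------------------------------------------------
    alloc = _allocation(cfg)
    copy_orientations: list[str] = []
    copy_gene: list[str] = []
    for gene, _, n_fwd, n_rev in alloc:
        copy_orientations.extend(["+"] * n_fwd + ["C"] * n_rev)
        copy_gene.extend([gene] * (n_fwd + n_rev))

    n = cfg.n_clusters
    flank_mask = np.ones(span, bool)
    flank_mask[core_off:core_off + cfg.core_length] = False
    flank_idx = np.flatnonzero(flank_mask)

    copies_a: list[str] = []
    copies_b_cores: list[str] = []
    core_ident_a: list[float] = []
    core_ident_b: list[float] = []
    avail_b = np.setdiff1d(np.arange(cfg.core_length),
                           np.array(sp_positions, int))
    for i in range(n):
        arr = np.frombuffer(anc.encode(), np.uint8).copy()
        fl = flank_idx[rng.random(flank_idx.size) < cfg.cluster_divergence]
        _mutate_positions(rng, arr, fl)
        k = cap if i == 0 else int(rng.integers(0, cap + 1))
        pos = rng.choice(cfg.core_length, size=k, replace=False) if k else \
            np.empty(0, np.int64)
        _mutate_positions(rng, arr, core_off + np.sort(pos))
        copies_a.append(arr.tobytes().decode("ascii"))
        core_ident_a.append(100.0 * (cfg.core_length - k) / cfg.core_length)
        # each species-B core copy is its own draw around the B reference,
        # so per-source identity to the species consensus respects the floor
        # on both sides; noise avoids the species-level positions to keep
        # the cross-species signature intact in every copy
        kb = cap if i == 0 else int(rng.integers(0, cap + 1))
        arr_bc = np.frombuffer(core_b_ref.encode(), np.uint8).copy()
        pos_b = rng.choice(avail_b, size=kb, replace=False) if kb else \
            np.empty(0, np.int64)
        _mutate_positions(rng, arr_bc, np.sort(pos_b))
        copies_b_cores.append(arr_bc.tobytes().decode("ascii"))
        core_ident_b.append(100.0 * (cfg.core_length - kb) / cfg.core_length)

    # --- assemble species A chromosome ------------------------------------
    parts: list[str] = []
    cursor = 0

    def emit(seq: str) -> tuple[int, int]:
        nonlocal cursor
        parts.append(seq)
        start = cursor + 1
        cursor += len(seq)
        return start, cursor

    genes_a: list[GeneModel] = []
    repeats_a: list[RepeatFeature] = []
    cluster_truth: list[dict] = []
    decoy_cycle = [("L1_BT", "LINE/L1"), ("MIR", "SINE/MIR"),
                   (cfg.line_name, cfg.line_class), ("Bov-tA2", "SINE/BovA"),
                   (cfg.ltr_name, cfg.ltr_class), ("(TG)n", "Simple_repeat")]
    decoy_i = 0
    copy_i = 0

    def emit_intergenic() -> None:
        nonlocal decoy_i
        length = int(rng.integers(cfg.intergenic_range[0],
                                  cfg.intergenic_range[1] + 1))
        start, _ = emit(_rand_dna(rng, length))
        # up to two well-separated decoy annotations, never forming the
        # trinomial pattern at realistic gap tolerances
        offset = 200
        for _ in range(2):
            dlen = int(rng.integers(80, 200))
            if offset + dlen + 200 > length:
                break
            name, klass = decoy_cycle[decoy_i % len(decoy_cycle)]
            strand = "+" if decoy_i % 2 == 0 else "C"
            repeats_a.append(RepeatFeature(
                chrom=cfg.chrom, start=start + offset,
                end=start + offset + dlen - 1, strand=strand,
                repeat_name=name, repeat_class_family=klass,
                sw_score=int(rng.integers(300, 2000)),
                pct_divergence=float(np.round(rng.uniform(2, 20), 1)),
                fragment_id=5000 + decoy_i,
            ))
            decoy_i += 1
            offset += dlen + 300

    def emit_cluster(gene: str) -> None:
        nonlocal copy_i
        i = copy_i
        copy_i += 1
        orient = copy_orientations[i]
        seq = copies_a[i]
        insert = seq if orient == "+" else reverse_complement(seq)
        start, end = emit(insert)
        if orient == "+":
            iv_line1 = (start, start + ll1 - 1)
            iv_ltr = (start + ll1 + gl, start + ll1 + gl + lt - 1)
            iv_line2 = (end - ll2 + 1, end)
            core_start = start + core_off
        else:
            iv_line1 = (start, start + ll2 - 1)          # genomically first
            iv_ltr = (start + ll2 + gr, start + ll2 + gr + lt - 1)
            iv_line2 = (end - ll1 + 1, end)
            core_start = start + (span - core_off - cfg.core_length)
        frag = 1000 + i
        div = float(np.round(cfg.cluster_divergence * 100, 1))
        sw = int(rng.integers(2000, 8000))
        for (s0, e0), nm, kl, fid in (
            (iv_line1, cfg.line_name, cfg.line_class, frag),
            (iv_ltr, cfg.ltr_name, cfg.ltr_class, 2000 + i),
            (iv_line2, cfg.line_name, cfg.line_class, frag),
        ):
            repeats_a.append(RepeatFeature(
                chrom=cfg.chrom, start=s0, end=e0, strand=orient,
                repeat_name=nm, repeat_class_family=kl, sw_score=sw,
                pct_divergence=div, fragment_id=fid,
            ))
        # a transparent simple repeat inside the first gap of the first two
        # forward clusters exercises ignore-class behaviour end to end
        if i < 2 and orient == "+" and gl >= 40:
            repeats_a.append(RepeatFeature(
                chrom=cfg.chrom, start=iv_line1[1] + 6,
                end=iv_line1[1] + 6 + min(gl - 12, 24), strand="+",
                repeat_name="(TG)n", repeat_class_family="Simple_repeat",
                sw_score=25, pct_divergence=5.0, fragment_id=9000 + i,
            ))
        cluster_truth.append({
            "index": i, "gene": gene, "orientation": orient,
            "chrom": cfg.chrom, "span_start": start, "span_end": end,
            "line1": list(iv_line1), "ltr": list(iv_ltr),
            "line2": list(iv_line2), "fragment_id": frag,
            "core_start": core_start,
            "core_end": core_start + cfg.core_length - 1,
            "core_identity_to_ancestor": round(core_ident_a[i], 4),
        })

    for gene, gstrand, n_fwd, n_rev in alloc:
        emit_intergenic()
        gene_start = cursor + 1
        exons: list[tuple[int, int]] = []
        n_hosted = n_fwd + n_rev
        exons.append(emit(_rand_dna(rng, int(rng.integers(
            cfg.exon_length_range[0], cfg.exon_length_range[1] + 1)))))
        if n_hosted == 0:
            emit(_rand_dna(rng, 2 * int(rng.integers(
                cfg.intron_pad_range[0], cfg.intron_pad_range[1] + 1))))
            exons.append(emit(_rand_dna(rng, int(rng.integers(
                cfg.exon_length_range[0], cfg.exon_length_range[1] + 1)))))
        else:
            for _ in range(n_hosted):
                emit(_rand_dna(rng, int(rng.integers(
                    cfg.intron_pad_range[0], cfg.intron_pad_range[1] + 1))))
                emit_cluster(gene)
                emit(_rand_dna(rng, int(rng.integers(
                    cfg.intron_pad_range[0], cfg.intron_pad_range[1] + 1))))
                exons.append(emit(_rand_dna(rng, int(rng.integers(
                    cfg.exon_length_range[0], cfg.exon_length_range[1] + 1)))))
        genes_a.append(GeneModel(
            gene_id=gene, chrom=cfg.chrom, start=gene_start, end=cursor,
            strand=gstrand, exons=exons,
        ))
    emit_intergenic()
    if cursor < cfg.genome_length:
        emit(_rand_dna(rng, cfg.genome_length - cursor))
    genome_a_seq = "".join(parts)

    # --- species B: substitution-only divergence --------------------------
    if cfg.species_divergence == 0 and cfg.core_species_subs == 0:
        # degenerate study condition: the two species are the same genome
        genome_b_seq = genome_a_seq
        for i, ct in enumerate(cluster_truth):
            ct["core_identity_a_vs_b"] = 100.0
            ct["core_identity_to_consensus_b"] = round(core_ident_a[i], 4)
        return _finish_scenario(cfg, rng, genome_a_seq, genome_b_seq,
                                genes_a, repeats_a, cluster_truth,
                                core_a_ref, core_a_ref, sp_positions,
                                span, core_off)
    arr_b = np.frombuffer(genome_a_seq.encode(), np.uint8).copy()
    protect = np.zeros(arr_b.size, bool)
    for ct in cluster_truth:
        protect[ct["core_start"] - 1:ct["core_end"]] = True
    subs = np.flatnonzero((rng.random(arr_b.size) < cfg.species_divergence)
                          & ~protect)
    _mutate_positions(rng, arr_b, subs)
    for i, ct in enumerate(cluster_truth):
        g0 = ct["core_start"] - 1  # 0-based genomic start of the core copy
        orient = ct["orientation"]
        b_core = copies_b_cores[i] if orient == "+" else \
            reverse_complement(copies_b_cores[i])
        arr_b[g0:g0 + cfg.core_length] = np.frombuffer(b_core.encode(), np.uint8)
        a_core = genome_a_seq[g0:g0 + cfg.core_length]
        ct["core_identity_a_vs_b"] = round(
            100.0 * (cfg.core_length - _hamming(a_core, b_core))
            / cfg.core_length, 4)
        ct["core_identity_to_consensus_b"] = round(core_ident_b[i], 4)
    genome_b_seq = arr_b.tobytes().decode("ascii")
    return _finish_scenario(cfg, rng, genome_a_seq, genome_b_seq, genes_a,
                            repeats_a, cluster_truth, core_a_ref, core_b_ref,
                            sp_positions, span, core_off)


def _finish_scenario(cfg: ScenarioConfig, rng: np.random.Generator,
                     genome_a_seq: str, genome_b_seq: str, genes_a,
                     repeats_a, cluster_truth, core_a_ref: str,
                     core_b_ref: str, sp_positions, span: int,
                     core_off: int) -> Scenario:
    """Plant the miRNA database, assemble truth and wrap up a Scenario."""
    mirna_truth: list[dict] = []
    db: list[MiRNARecord] = []
    used_names: set[str] = set()

    def add_record(prefix: str, core_name: str, arm: str, residues: str,
                   category: str, strand: str, locus: Optional[int]) -> None:
        name = f"{prefix}-{core_name}" + ("" if arm == "none" else f"-{arm}")
        if name in used_names:
            raise UsageError(f"internal: duplicate planted name {name}")
        used_names.add(name)
        rec = MiRNARecord(name=name, residues=residues)
        db.append(rec)
        hit_a, mm_a = _expected_hit(rec.residues, core_a_ref,
                                    cfg.scan_min_identity, cfg.scan_min_coverage)
        hit_b, mm_b = _expected_hit(rec.residues, core_b_ref,
                                    cfg.scan_min_identity, cfg.scan_min_coverage)
        mirna_truth.append({
            "name": name, "category": category, "strand_planted": strand,
            "locus_start_in_core": locus,
            "expected_hit_a": hit_a, "expected_hit_b": hit_b,
            "mismatches_vs_a": mm_a, "mismatches_vs_b": mm_b,
        })

    n_common = cfg.n_mirnas - cfg.n_mirnas_a_only - cfg.n_mirnas_b_only
    seed_guard = cfg.scan_seed_k + 2
    forbidden = set(sp_positions)

    def plant(ref: str, mm_count: int, L: int) -> tuple[str, int]:
        """A mature copied from ref with mm_count substitutions outside a
        protected central seed window; returns (sequence, locus)."""
        for _ in range(200):
            locus = int(rng.integers(12, cfg.core_length - 12 - L + 1))
            if not forbidden & set(range(locus, locus + L)):
                break
        else:
            raise UsageError("could not place a planted miRNA away from "
                             "species-level substitutions")
        seq = np.frombuffer(ref[locus:locus + L].encode(), np.uint8).copy()
        c0 = (L - seed_guard) // 2
        free = [p for p in range(L) if not c0 <= p < c0 + seed_guard]
        pos = rng.choice(np.array(free), size=mm_count, replace=False) \
            if mm_count else np.empty(0, np.int64)
        _mutate_positions(rng, seq, np.sort(pos.astype(np.int64)))
        return seq.tobytes().decode("ascii"), locus

    for idx in range(n_common):
        L = int(rng.integers(cfg.mirna_length_range[0],
                             cfg.mirna_length_range[1] + 1))
        mm = cfg.planted_mirna_mismatches[idx % len(cfg.planted_mirna_mismatches)]
        seq, locus = plant(core_a_ref, mm, L)
        strand = "C" if idx % 3 == 2 else "+"
        stored = seq if strand == "+" else reverse_complement(seq)
        prefix = _PREFIX_POOL[idx % len(_PREFIX_POOL)]
        arm = ("5p", "3p", "none")[idx % 3]
        add_record(prefix, f"miR-{100 + 7 * idx}", arm, stored,
                   "planted_common", strand, locus)

    # species-specific matures: length 18 covering the consecutive
    # species-substitution block, so 3 cross-species core differences push
    # identity below the default threshold in exactly one species
    spec_L = 18
    block_start = sp_positions[0] if sp_positions else 0
    for idx in range(cfg.n_mirnas_a_only):
        locus = max(12, min(block_start - (spec_L - 3) // 2 - idx,
                            cfg.core_length - 12 - spec_L))
        seq = core_a_ref[locus:locus + spec_L]
        prefix, core_name, arm = _A_ONLY_NAMES[idx % len(_A_ONLY_NAMES)]
        add_record(prefix, core_name, arm, seq, "planted_a_only", "+", locus)
    for idx in range(cfg.n_mirnas_b_only):
        locus = max(12, min(block_start - (spec_L - 3) // 2 - 1 - idx,
                            cfg.core_length - 12 - spec_L))
        seq = core_b_ref[locus:locus + spec_L]
        prefix, core_name, arm = _B_ONLY_NAMES[idx % len(_B_ONLY_NAMES)]
        strand = "C" if idx % 2 == 1 else "+"
        stored = seq if strand == "+" else reverse_complement(seq)
        add_record(prefix, core_name, arm, stored, "planted_b_only",
                   strand, locus)

    for idx in range(cfg.decoy_ratio * cfg.n_mirnas):
        L = int(rng.integers(cfg.mirna_length_range[0],
                             cfg.mirna_length_range[1] + 1))
        prefix = _PREFIX_POOL[(idx + 5) % len(_PREFIX_POOL)]
        add_record(prefix, f"miR-{5000 + idx}", ("none", "5p", "3p")[idx % 3],
                   _rand_dna(rng, L), "decoy", "+", None)

    genes_b = [GeneModel(g.gene_id, g.chrom, g.start, g.end, g.strand,
                         list(g.exons)) for g in genes_a]
    repeats_b = [RepeatFeature(f.chrom, f.start, f.end, f.strand,
                               f.repeat_name, f.repeat_class_family,
                               f.sw_score, f.pct_divergence, f.fragment_id)
                 for f in repeats_a]

    truth = {
        "config": asdict(cfg),
        "scan_thresholds": {
            "seed_k": cfg.scan_seed_k,
            "min_identity": cfg.scan_min_identity,
            "min_coverage": cfg.scan_min_coverage,
        },
        "core_reference_a": core_a_ref,
        "core_reference_b": core_b_ref,
        "core_species_sub_positions": [int(p) for p in sp_positions],
        "ancestral_span": span,
        "core_offset_in_span": core_off,
        "clusters": cluster_truth,
        "genes": [
            {"gene_id": g.gene_id, "chrom": g.chrom, "start": g.start,
             "end": g.end, "strand": g.strand,
             "exons": [list(e) for e in g.exons]}
            for g in genes_a
        ],
        "mirnas": mirna_truth,
    }
    return Scenario(
        config=cfg,
        genome_a=[NucleotideSequence(cfg.chrom, genome_a_seq)],
        genome_b=[NucleotideSequence(cfg.chrom, genome_b_seq)],
        repeats_a=repeats_a, repeats_b=repeats_b,
        genes_a=genes_a, genes_b=genes_b,
        mirna_db=db, truth=truth,
    )


def generate_scenario(cfg: ScenarioConfig, outdir) -> dict[str, Path]:
    """Materialise a scenario on disk; returns the emitted file paths.

    Configuration problems are raised before any file is written; identical
    configurations produce byte-identical file sets.
    """
    cfg.validate()
    scenario = simulate(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome_a": outdir / "genome_a.fasta",
        "genome_b": outdir / "genome_b.fasta",
        "repeats_a": outdir / "repeats_a.out",
        "repeats_b": outdir / "repeats_b.out",
        "genes_a": outdir / "genes_a.gff3",
        "genes_b": outdir / "genes_b.gff3",
        "mirna_db": outdir / "mirna_db.fasta",
        "truth": outdir / "truth.json",
    }
    write_fasta(scenario.genome_a, paths["genome_a"])
    write_fasta(scenario.genome_b, paths["genome_b"])
    write_repeatmasker_out(scenario.repeats_a, paths["repeats_a"])
    write_repeatmasker_out(scenario.repeats_b, paths["repeats_b"])
    write_gff3(scenario.genes_a, paths["genes_a"])
    write_gff3(scenario.genes_b, paths["genes_b"])
    write_fasta(
        [NucleotideSequence(r.name, r.residues) for r in scenario.mirna_db],
        paths["mirna_db"], rna=True,
    )
    with open(paths["truth"], "w") as fh:
        json.dump(scenario.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
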