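"""Readers and writers for the external formats the pipeline touches.

One in-memory data model is shared by every stage:

* sequences are DNA over ``{A, C, G, T, N}``; RNA ``U`` becomes ``T``,
  lowercase is raised and other IUPAC ambiguity codes collapse to ``N`` at
  read time, so DNA/RNA comparisons share a single alphabet;
* coordinates are 1-based and inclusive on both ends everywhere, hence
  ``length = end - start + 1`` (BED input is converted at the boundary);
* strand uses the RepeatMasker vocabulary ``{"+", "C"}``; ``"-"`` and
  ``"Complement"`` are normalised to ``"C"`` on read.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

log = logging.getLogger("trirec")

__all__ = [
    "FormatError",
    "UsageError",
    "CoordinateError",
    "NucleotideSequence",
    "RepeatFeature",
    "GeneModel",
    "MiRNARecord",
    "normalize_residues",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
    "read_repeatmasker_out",
    "write_repeatmasker_out",
    "read_gene_models",
    "write_gff3",
    "read_mirna_db",
    "parse_mirna_name",
    "mirna_family",
]


class FormatError(ValueError):
    """A file did not conform to its declared format."""


class UsageError(ValueError):
    """An operation was called with out-of-contract arguments."""


class CoordinateError(ValueError):
    """A coordinate fell outside the sequence it refers to."""


# -- sequence alphabet -------------------------------------------------------

_AMBIGUITY = "RYSWKMBDHV"
_NORMALIZE = str.maketrans(
    "acgtunU" + _AMBIGUITY + _AMBIGUITY.lower(),
    "ACGTTNT" + "N" * (2 * len(_AMBIGUITY)),
)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")


def normalize_residues(raw: str) -> str:
    """Normalise raw residue text to uppercase DNA over ``{A,C,G,T,N}``.

    ``U`` maps to ``T``; IUPAC ambiguity codes map to ``N``.  Anything else
    raises :class:`FormatError`.
    """
    s = raw.translate(_NORMALIZE)
    if not _VALID.issuperset(s):
        bad = sorted(set(s) - _VALID)
        raise FormatError(f"invalid residue characters: {bad!r}")
    return s


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass
class NucleotideSequence:
    """A named nucleotide sequence (normalised on construction)."""

    id: str
    residues: str
    description: Optional[str] = None

    def __post_init__(self) -> None:
        self.residues = normalize_residues(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


# -- FASTA -------------------------------------------------------------------

def read_fasta(path) -> list[NucleotideSequence]:
    """Read a FASTA file into normalised :class:`NucleotideSequence` records.

    Input order is preserved.  A malformed header (sequence data before the
    first ``>``, or a bare ``>`` with no name) raises :class:`FormatError`
    naming the offending line.  An empty file yields an empty list with a
    logged warning.
    """
    path = Path(path)
    text = path.read_text()
    n_records = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            if not stripped[1:].strip():
                raise FormatError(f"{path}: malformed FASTA header at line {lineno}")
            n_records += 1
        elif n_records == 0:
            raise FormatError(
                f"{path}: expected FASTA header at line {lineno}, got sequence data"
            )
    if n_records == 0:
        log.warning("FASTA file %s contains no records", path)
        return []
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        desc = rec.description[len(rec.id):].strip() or None
        records.append(NucleotideSequence(rec.id, str(rec.seq), desc))
    for rec in records:
        if len(rec) == 0:
            log.warning("FASTA record %s has an empty body", rec.id)
    return records


def write_fasta(seqs: Iterable[NucleotideSequence], path, *, rna: bool = False,
                wrap: int = 60) -> None:
    """Write records wrapped at ``wrap`` columns; ``rna=True`` re-emits T as U."""
    with open(path, "w") as fh:
        for s in seqs:
            header = s.id if not s.description else f"{s.id} {s.description}"
            fh.write(f">{header}\n")
            body = s.residues.replace("T", "U") if rna else s.residues
            for i in range(0, len(body), wrap):
                fh.write(body[i:i + wrap] + "\n")


# -- RepeatMasker .out -------------------------------------------------------

@dataclass
class RepeatFeature:
    """One row of a RepeatMasker-style repeat annotation."""

    chrom: str
    start: int
    end: int
    strand: str
    repeat_name: str
    repeat_class_family: str
    sw_score: int = 0
    pct_divergence: float = 0.0
    fragment_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise FormatError(
                f"repeat feature {self.repeat_name}: bad interval "
                f"{self.start}..{self.end}"
            )
        if self.strand not in ("+", "C"):
            raise FormatError(f"repeat feature strand must be + or C, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def repeat_class(self) -> str:
        """The class component of class/family (text before the first '/')."""
        return self.repeat_class_family.split("/", 1)[0]


_RM_HEADER = (
    "   SW   perc perc perc  query     position in query            matching"
    "       repeat            position in repeat\n"
    "score   div. del. ins.  sequence  begin  end          (left)   repeat"
    "         class/family      begin  end    (left)  ID\n"
)


def read_repeatmasker_out(path) -> list[RepeatFeature]:
    """Parse the standard 15-column RepeatMasker ``.out`` layout.

    The two header lines (and the blank line after them) are skipped.  Rows
    retain file order; the final ID column populates ``fragment_id`` when
    present.  A trailing ``*`` (higher-scoring overlap marker) is tolerated.
    """
    path = Path(path)
    features = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            first = stripped.split()[0]
            if first in ("SW", "score", "bit"):
                continue
            tok = stripped.split()
            if tok and tok[-1] == "*":
                tok = tok[:-1]
            if len(tok) not in (14, 15):
                raise FormatError(
                    f"{path}: line {lineno}: expected 14 or 15 columns, got {len(tok)}"
                )
            try:
                sw = int(tok[0])
                div = float(tok[1])
                start = int(tok[5])
                end = int(tok[6])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-numeric field: {exc}") from exc
            strand = tok[8]
            if strand == "-":
                strand = "C"
            if strand not in ("+", "C"):
                raise FormatError(f"{path}: line {lineno}: bad strand {tok[8]!r}")
            frag = int(tok[14]) if len(tok) == 15 else None
            features.append(
                RepeatFeature(
                    chrom=tok[4], start=start, end=end, strand=strand,
                    repeat_name=tok[9], repeat_class_family=tok[10],
                    sw_score=sw, pct_divergence=div, fragment_id=frag,
                )
            )
    return features


def write_repeatmasker_out(features: Iterable[RepeatFeature], path) -> None:
    """Emit features in the 15-column ``.out`` dialect (byte-stable round trip).

    Fields the data model does not carry (deletion/insertion percentages,
    repeat-internal coordinates, remaining-length columns) are emitted as
    deterministic placeholders derived from the stored fields.
    """
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        fh.write("\n")
        for f in features:
            rep_len = f.length
            if f.strand == "+":
                rpos = f"{1:>7} {rep_len:>6} {'(0)':>7}"
            else:
                rpos = f"{'(0)':>7} {rep_len:>6} {1:>7}"
            frag = "" if f.fragment_id is None else str(f.fragment_id)
            fh.write(
                f"{f.sw_score:>5} {f.pct_divergence:>5.1f}  0.0  0.0  "
                f"{f.chrom:<10} {f.start:>9} {f.end:>9} {'(0)':>9} "
                f"{f.strand} {f.repeat_name:<16} {f.repeat_class_family:<18} "
                f"{rpos} {frag:>6}\n"
            )


# -- gene models -------------------------------------------------------------

@dataclass
class GeneModel:
    """A gene with its exon structure, 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise FormatError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in ("+", "C"):
            raise FormatError(f"gene {self.gene_id}: strand must be + or C")
        if not self.exons:
            self.exons = [(self.start, self.end)]
        prev_end = None
        for (s, e) in self.exons:
            if s > e or s < self.start or e > self.end:
                raise FormatError(
                    f"gene {self.gene_id}: exon {s}..{e} outside gene body"
                )
            if prev_end is not None and s <= prev_end:
                raise FormatError(
                    f"gene {self.gene_id}: exons unsorted or overlapping at {s}"
                )
            prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out


def _strand_from(text: str) -> str:
    if text in ("-", "C", "Complement", "complement"):
        return "C"
    return "+"


def read_gene_models(path, dialect: str) -> list[GeneModel]:
    """Read gene models from GFF3 or BED12.

    Coordinates are stored 1-based inclusive regardless of dialect (BED's
    0-based half-open convention is converted on read); ``-`` strands map to
    ``C``.
    """
    if dialect == "gff3":
        return _read_gff3(path)
    if dialect == "bed12":
        return _read_bed12(path)
    raise UsageError(f"unknown gene-model dialect {dialect!r} (use gff3 or bed12)")


def _read_gff3(path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = g.attributes.get("Name", [g.id.removeprefix("gene:")])[0]
        exons = [
            (e.start, e.end)
            for e in db.children(g, featuretype="exon", order_by="start")
        ]
        genes.append(
            GeneModel(
                gene_id=gid, chrom=g.seqid, start=g.start, end=g.end,
                strand=_strand_from(g.strand), exons=exons,
            )
        )
    return genes


def _read_bed12(path) -> list[GeneModel]:
    path = Path(path)
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 12:
                raise FormatError(
                    f"{path}: line {lineno}: BED12 needs 12 columns, got {len(cols)}"
                )
            try:
                chrom_start = int(cols[1])
                chrom_end = int(cols[2])
                sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
                offsets = [int(x) for x in cols[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            start = chrom_start + 1
            end = chrom_end
            if end < start:
                raise FormatError(
                    f"{path}: line {lineno}: end < start after BED conversion"
                )
            exons = [
                (chrom_start + off + 1, chrom_start + off + sz)
                for off, sz in zip(offsets, sizes)
            ]
            genes.append(
                GeneModel(
                    gene_id=cols[3], chrom=cols[0], start=start, end=end,
                    strand=_strand_from(cols[5]), exons=exons,
                )
            )
    return genes


def write_gff3(genes: Iterable[GeneModel], path, source: str = "trirec") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            strand = "-" if g.strand == "C" else "+"
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{strand}\t.\t"
                f"ID=gene:{g.gene_id};Name={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{s}\t{e}\t.\t{strand}\t.\t"
                    f"ID=exon:{g.gene_id}.{i};Parent=gene:{g.gene_id}\n"
                )


# -- mature miRNA database ---------------------------------------------------

# miRBase-style mature names: species prefix, family core, optional arm,
# e.g. bta-miR-30a-5p / cli-miR-1416-3p / mtr-miR-5754 / hsa-let-7a.
_NAME_RE = re.compile(r"^([a-z]{3,4})-(.+?)(?:-(5p|3p))?$")
_FAMILY_RE = re.compile(r"^(miR|mir|let|lin|bantam)-?(\d+)", re.IGNORECASE)


def parse_mirna_name(name: str) -> tuple[str, str, str]:
    """Split a mature miRNA name into (species_prefix, core, arm).

    The parse is lossless: ``prefix + "-" + core (+ "-" + arm)`` reproduces
    the input.  ``arm`` is ``"none"`` when absent.
    """
    m = _NAME_RE.match(name)
    if not m or not _FAMILY_RE.match(m.group(2)):
        raise FormatError(f"unparseable miRNA name {name!r}")
    prefix, core, arm = m.group(1), m.group(2), m.group(3) or "none"
    return prefix, core, arm


def mirna_family(name_or_core: str) -> str:
    """Collapse a mature name or core to its family (miR-30a-5p -> miR-30).

    Lettered paralogs and numeric sub-indices after a dash fold into the
    family core; unparseable input returns ``"unknown"``.
    """
    core = name_or_core
    m = _NAME_RE.match(name_or_core)
    if m and _FAMILY_RE.match(m.group(2)):
        core = m.group(2)
    fm = _FAMILY_RE.match(core)
    if not fm:
        return "unknown"
    return f"{fm.group(1)}-{fm.group(2)}"


@dataclass
class MiRNARecord:
    """A mature miRNA with its parsed miRBase-style name."""

    name: str
    residues: str
    species_prefix: str = ""
    family: str = ""
    arm: str = "none"

    def __post_init__(self) -> None:
        self.residues = normalize_residues(self.residues)
        prefix, core, arm = parse_mirna_name(self.name)
        self.species_prefix = prefix
        self.family = mirna_family(core)
        self.arm = arm
        if not 16 <= len(self.residues) <= 30:
            raise FormatError(
                f"mature {self.name}: length {len(self.residues)} outside [16, 30]"
            )


def read_mirna_db(path) -> list[MiRNARecord]:
    """Read a mature-miRNA FASTA database.

    Records whose names do not parse (or whose lengths fall outside the
    mature range) are skipped with a logged warning; duplicate names are a
    format error.  ``U`` is normalised to ``T``.
    """
    records = []
    seen: set[str] = set()
    skipped = 0
    for seq in read_fasta(path):
        if seq.id in seen:
            raise FormatError(f"duplicate miRNA name {seq.id!r}")
        try:
            rec = MiRNARecord(name=seq.id, residues=seq.residues)
        except FormatError as exc:
            log.warning("skipping miRNA record: %s", exc)
            skipped += 1
            continue
        seen.add(seq.id)
        records.append(rec)
    if skipped:
        log.warning("skipped %d unparseable miRNA records", skipped)
    return records
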