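"""Star multiple alignment and conserved-consensus window extraction.

The conserved sequence of a set of homologous regions is defined here by a
deterministic two-threshold rule that replaces manual curation: build a
star multiple alignment, call a consensus residue per column (most frequent
non-gap residue, ties alphabetical), and return the longest contiguous
column window in which every source row reaches ``min_source_identity``
percent identity to the consensus and every column's non-gap occupancy is at
least ``min_occupancy``.  Two equally long windows resolve to the leftmost.

Row identity within a window counts a gap as a non-identical column, and
columns where the consensus call would be gap-dominant can never enter the
window, so the returned consensus carries no gap characters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_formats import NucleotideSequence, UsageError
from .pairwise_alignment import ScoringScheme, align_global

__all__ = ["MultipleAlignment", "ConservedSequence", "build_star_msa",
           "derive_conserved_sequence"]


@dataclass
class MultipleAlignment:
    labels: list[str]
    rows: list[str]
    center_label: str

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise UsageError("labels and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise UsageError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for label, row in zip(self.labels, self.rows):
                fh.write(f">{label}\n")
                for i in range(0, len(row), 60):
                    fh.write(row[i:i + 60] + "\n")


@dataclass
class ConservedSequence:
    """Consensus residues over the maximal conserved window of an MSA."""

    residues: str
    msa_window: Optional[tuple[int, int]]  # 1-based inclusive column range
    per_source_identity: dict[str, float] = field(default_factory=dict)
    min_identity: float = 0.0
    diagnostic: str = ""

    def __len__(self) -> int:
        return len(self.residues)


def build_star_msa(seqs: Sequence[NucleotideSequence],
                   s: ScoringScheme = ScoringScheme(),
                   center_label: Optional[str] = None) -> MultipleAlignment:
    """Star multiple alignment around the most central sequence.

    The center is the sequence maximising summed pairwise global identity
    (ties -> lexicographically smallest label), unless ``center_label``
    pins it (callers that already computed an identity matrix can pass its
    medoid and skip the all-vs-all step).  Every sequence is aligned to the
    center pairwise and the alignments merged under "once a gap, always a
    gap": insertions relative to the center are padded to the longest
    insertion observed at that center position.
    """
    if len(seqs) < 2:
        raise UsageError("star MSA needs at least 2 sequences")
    labels = [x.id for x in seqs]
    if len(set(labels)) != len(labels):
        raise UsageError("duplicate sequence labels")
    if center_label is None:
        totals = {lab: 0.0 for lab in labels}
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                pid = align_global(seqs[i], seqs[j], s).pct_identity
                totals[labels[i]] += pid
                totals[labels[j]] += pid
        center_label = min(totals, key=lambda lab: (-totals[lab], lab))
    elif center_label not in labels:
        raise UsageError(f"center label {center_label!r} not among sequences")
    center = next(x for x in seqs if x.id == center_label)
    L = len(center)

    # per sequence: chars aligned to each center residue, plus insertion
    # strings at each of the L + 1 inter-residue slots
    aligned_at: dict[str, list[str]] = {}
    inserts: dict[str, list[str]] = {}
    slot_len = [0] * (L + 1)
    for seq in seqs:
        if seq.id == center_label:
            continue
        aln = align_global(center, seq, s)
        at = [""] * L
        ins = [""] * (L + 1)
        ci = 0
        for ca, cb in zip(aln.aligned_a, aln.aligned_b):
            if ca == "-":
                ins[ci] += cb
            else:
                at[ci] = cb
                ci += 1
        aligned_at[seq.id] = at
        inserts[seq.id] = ins
        for k in range(L + 1):
            slot_len[k] = max(slot_len[k], len(ins[k]))

    def build_row(at: list[str], ins: list[str]) -> str:
        parts = []
        for k in range(L):
            parts.append(ins[k].ljust(slot_len[k], "-"))
            parts.append(at[k])
        parts.append(ins[L].ljust(slot_len[L], "-"))
        return "".join(parts)

    center_row = build_row(list(center.residues), [""] * (L + 1))
    rows = []
    for seq in seqs:
        if seq.id == center_label:
            rows.append(center_row)
        else:
            rows.append(build_row(aligned_at[seq.id], inserts[seq.id]))
    return MultipleAlignment(labels=list(labels), rows=rows,
                             center_label=center_label)


def derive_conserved_sequence(msa: MultipleAlignment,
                              min_source_identity: float = 95.0,
                              min_occupancy: float = 0.9) -> ConservedSequence:
    """Extract the maximal conserved consensus window from an MSA.

    See the module docstring for the window rule.  Returns an empty
    :class:`ConservedSequence` with a diagnostic when no window satisfies
    the thresholds.
    """
    if not 0 <= min_source_identity <= 100:
        raise UsageError("min_source_identity must be in [0, 100]")
    if not 0 <= min_occupancy <= 1:
        raise UsageError("min_occupancy must be in [0, 1]")
    R = len(msa.rows)
    C = msa.n_columns
    chars = np.array([list(row) for row in msa.rows])
    gap = chars == "-"
    occupancy = 1.0 - gap.sum(axis=0) / R

    # consensus per column: most frequent non-gap residue, ties alphabetical
    counts = np.stack([(chars == b).sum(axis=0) for b in "ACGT"])
    consensus_idx = counts.argmax(axis=0)  # argmax takes the first max: A<C<G<T
    consensus = np.array(list("ACGT"))[consensus_idx]
    nongap_count = counts.sum(axis=0) + (chars == "N").sum(axis=0)
    gap_count = gap.sum(axis=0)
    valid = (
        (occupancy >= min_occupancy)
        & (nongap_count > gap_count)
        & (counts.max(axis=0) > 0)
    )

    match = (chars == consensus[None, :])
    prefix = np.zeros((R, C + 1), dtype=np.int64)
    prefix[:, 1:] = np.cumsum(match, axis=1)
    thr = min_source_identity / 100.0

    best = (0, -1, -1)  # (length, start, end) 0-based inclusive
    # scan each maximal run of valid columns
    c = 0
    while c < C:
        if not valid[c]:
            c += 1
            continue
        run_end = c
        while run_end + 1 < C and valid[run_end + 1]:
            run_end += 1
        for i in range(c, run_end + 1):
            if run_end - i + 1 <= best[0]:
                break
            lens = np.arange(1, run_end - i + 2)
            cnt = prefix[:, i + 1:run_end + 2] - prefix[:, i:i + 1]
            ok = (cnt >= thr * lens - 1e-9).all(axis=0)
            js = np.flatnonzero(ok)
            if js.size:
                j = i + int(js[-1])
                if j - i + 1 > best[0]:
                    best = (j - i + 1, i, j)
        c = run_end + 1

    if best[0] == 0:
        return ConservedSequence(
            residues="", msa_window=None, per_source_identity={},
            min_identity=0.0,
            diagnostic=(
                f"no window satisfies min_source_identity={min_source_identity}"
                f" and min_occupancy={min_occupancy}"
            ),
        )
    _, i, j = best
    window_len = j - i + 1
    per_source = {
        label: 100.0 * float(prefix[r, j + 1] - prefix[r, i]) / window_len
        for r, label in enumerate(msa.labels)
    }
    return ConservedSequence(
        residues="".join(consensus[i:j + 1]),
        msa_window=(i + 1, j + 1),
        per_source_identity=per_source,
        min_identity=min(per_source.values()),
    )
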