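"""Affine-gap pairwise alignment and percent-identity matrices.

Percent identity follows the EMBOSS convention: 100 x identical columns /
total alignment columns, with gap columns counted in the denominator.  An
``N`` never counts as an identical column and scores as a mismatch by
default (``n_policy="mismatch"``) or as neutral zero (``"neutral"``).

Optimal global alignments come from a three-state Gotoh dynamic programme;
local alignments from Smith-Waterman with Waterman-Eggert cell masking for
deterministic suboptimal ("alternative") matches.  Traceback ties resolve
diagonal > up > left, making every alignment bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from . import _dp
from .io_formats import NucleotideSequence, UsageError

__all__ = [
    "ScoringScheme",
    "PairwiseAlignment",
    "IdentityMatrix",
    "align_global",
    "align_local",
    "identity_matrix",
]


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch scores and affine gap costs (both costs positive).

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``.  Defaults
    are EDNAFULL-like: +5 / -4 with gap open 12, extend 2.
    """

    match: int = 5
    mismatch: int = -4
    gap_open: int = 12
    gap_extend: int = 2
    n_policy: str = "mismatch"

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise UsageError("match score must be positive")
        if self.mismatch > 0:
            raise UsageError("mismatch score must be <= 0")
        if not self.gap_open >= self.gap_extend > 0:
            raise UsageError("need gap_open >= gap_extend > 0")
        if self.n_policy not in ("mismatch", "neutral"):
            raise UsageError("n_policy must be 'mismatch' or 'neutral'")

    @property
    def n_score(self) -> int:
        return self.mismatch if self.n_policy == "mismatch" else 0


@dataclass
class PairwiseAlignment:
    """An aligned sequence pair with score and percent identity."""

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: int
    # start/end of the aligned stretch on each input, 1-based inclusive
    # (the full sequences for global alignments)
    a_start: int = 1
    a_end: int = 0
    b_start: int = 1
    b_end: int = 0
    matches: int = field(init=False)
    columns: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise UsageError("aligned rows differ in length")
        self.columns = len(self.aligned_a)
        self.matches = sum(
            1 for x, y in zip(self.aligned_a, self.aligned_b)
            if x == y and x not in ("-", "N")
        )
        if self.a_end == 0:
            self.a_end = len(self.aligned_a.replace("-", ""))
        if self.b_end == 0:
            self.b_end = len(self.aligned_b.replace("-", ""))

    @property
    def pct_identity(self) -> float:
        if self.columns == 0:
            return 0.0
        return 100.0 * self.matches / self.columns


def _as_residues(seq) -> tuple[str, str]:
    if isinstance(seq, NucleotideSequence):
        return seq.id, seq.residues
    raise UsageError("alignment operands must be NucleotideSequence instances")


def align_global(a: NucleotideSequence, b: NucleotideSequence,
                 s: ScoringScheme = ScoringScheme()) -> PairwiseAlignment:
    """Optimal affine-gap global alignment (deterministic traceback)."""
    id_a, ra = _as_residues(a)
    id_b, rb = _as_residues(b)
    if not ra or not rb:
        raise UsageError("cannot globally align an empty sequence")
    ea, eb = _dp.encode(ra), _dp.encode(rb)
    score, PH, PE, PF = _dp.global_fill(
        ea, eb, s.match, s.mismatch, s.n_score, s.gap_open, s.gap_extend
    )
    ops = []
    i, j = len(ra), len(rb)
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            p = PH[i, j]
            if p == 0:
                ops.append("M")
                i -= 1
                j -= 1
            elif p == 1:
                state = "E"
            else:
                state = "F"
        elif state == "E":  # gap in b, consume a
            opened = PE[i, j] == 0
            ops.append("U")
            i -= 1
            state = "H" if opened else "E"
        else:  # gap in a, consume b
            opened = PF[i, j] == 0
            ops.append("L")
            j -= 1
            state = "H" if opened else "F"
    ops.reverse()
    row_a, row_b = [], []
    ia = ib = 0
    for op in ops:
        if op == "M":
            row_a.append(ra[ia]); ia += 1
            row_b.append(rb[ib]); ib += 1
        elif op == "U":
            row_a.append(ra[ia]); ia += 1
            row_b.append("-")
        else:
            row_a.append("-")
            row_b.append(rb[ib]); ib += 1
    return PairwiseAlignment(id_a, id_b, "".join(row_a), "".join(row_b), int(score))


def align_local(a: NucleotideSequence, b: NucleotideSequence,
                s: ScoringScheme = ScoringScheme(),
                max_alternatives: int = 1) -> list[PairwiseAlignment]:
    """Best local alignment plus up to ``max_alternatives - 1`` suboptimal ones.

    Suboptimal alignments are found Waterman-Eggert style: cells used by a
    reported path are masked and the matrix rescanned, so alternatives never
    reuse an aligned cell.  Only positive-scoring alignments are reported;
    an empty list means no positive-scoring local alignment exists.
    """
    id_a, ra = _as_residues(a)
    id_b, rb = _as_residues(b)
    if not ra or not rb:
        raise UsageError("cannot locally align an empty sequence")
    if max_alternatives < 1:
        raise UsageError("max_alternatives must be >= 1")
    ea, eb = _dp.encode(ra), _dp.encode(rb)
    mask = np.zeros((len(ra) + 1, len(rb) + 1), np.uint8)
    out: list[PairwiseAlignment] = []
    for _ in range(max_alternatives):
        best, bi, bj, H, PH, PE, PF = _dp.local_fill(
            ea, eb, s.match, s.mismatch, s.n_score, s.gap_open, s.gap_extend, mask
        )
        if best <= 0:
            break
        ops = []
        i, j = bi, bj
        state = "H"
        path_cells = [(i, j)]
        while True:
            if state == "H":
                p = PH[i, j]
                if p == 0:
                    break
                if p == 1:
                    ops.append("M")
                    i -= 1
                    j -= 1
                    path_cells.append((i, j))
                elif p == 2:
                    state = "E"
                else:
                    state = "F"
            elif state == "E":
                opened = PE[i, j] == 0
                ops.append("U")
                i -= 1
                path_cells.append((i, j))
                state = "H" if opened else "E"
            else:
                opened = PF[i, j] == 0
                ops.append("L")
                j -= 1
                path_cells.append((i, j))
                state = "H" if opened else "F"
        ops.reverse()
        a0, b0 = i, j  # 0-based start offsets
        row_a, row_b = [], []
        ia, ib = a0, b0
        for op in ops:
            if op == "M":
                row_a.append(ra[ia]); ia += 1
                row_b.append(rb[ib]); ib += 1
            elif op == "U":
                row_a.append(ra[ia]); ia += 1
                row_b.append("-")
            else:
                row_a.append("-")
                row_b.append(rb[ib]); ib += 1
        out.append(
            PairwiseAlignment(
                id_a, id_b, "".join(row_a), "".join(row_b), int(best),
                a_start=a0 + 1, a_end=ia, b_start=b0 + 1, b_end=ib,
            )
        )
        for (ci, cj) in path_cells:
            mask[ci, cj] = 1
    return out


@dataclass
class IdentityMatrix:
    """Symmetric all-vs-all percent-identity matrix with summary stats."""

    labels: list[str]
    values: np.ndarray
    min_offdiag: float = 0.0
    max_offdiag: float = 0.0
    argmin_pair: Optional[tuple[str, str]] = None
    argmax_pair: Optional[tuple[str, str]] = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_frame().round(2).to_csv(path, sep="\t", index_label="label")

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "values": [[round(float(v), 4) for v in row] for row in self.values],
            "min_offdiag": round(self.min_offdiag, 4),
            "max_offdiag": round(self.max_offdiag, 4),
            "argmin_pair": list(self.argmin_pair) if self.argmin_pair else None,
            "argmax_pair": list(self.argmax_pair) if self.argmax_pair else None,
        }

    def plot_heatmap(self, path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(0.3 * len(self.labels) + 2,) * 2)
        im = ax.imshow(self.values, vmin=80, vmax=100, cmap="RdYlGn_r")
        ax.set_xticks(range(len(self.labels)), self.labels, rotation=90, fontsize=6)
        ax.set_yticks(range(len(self.labels)), self.labels, fontsize=6)
        fig.colorbar(im, label="% identity")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def identity_matrix(seqs: Sequence[NucleotideSequence], method: str = "global",
                    s: ScoringScheme = ScoringScheme()) -> IdentityMatrix:
    """All-vs-all percent identity, computed once per unordered pair.

    ``method="local"`` uses the best local alignment's identity instead of
    the global one.  Duplicate labels are rejected.
    """
    if len(seqs) < 2:
        raise UsageError("identity_matrix needs at least 2 sequences")
    if method not in ("global", "local"):
        raise UsageError("method must be 'global' or 'local'")
    labels = [x.id for x in seqs]
    if len(set(labels)) != len(labels):
        raise UsageError("duplicate sequence labels")
    n = len(seqs)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            if method == "global":
                pid = align_global(seqs[i], seqs[j], s).pct_identity
            else:
                hits = align_local(seqs[i], seqs[j], s, max_alternatives=1)
                pid = hits[0].pct_identity if hits else 0.0
            values[i, j] = values[j, i] = pid
    mat = IdentityMatrix(labels, values)
    off = values[~np.eye(n, dtype=bool)]
    mat.min_offdiag = float(off.min())
    mat.max_offdiag = float(off.max())
    lo = np.argwhere(values == mat.min_offdiag)
    hi = np.argwhere(values == mat.max_offdiag)
    lo = lo[lo[:, 0] < lo[:, 1]][0]
    hi = hi[hi[:, 0] < hi[:, 1]][0]
    mat.argmin_pair = (labels[lo[0]], labels[lo[1]])
    mat.argmax_pair = (labels[hi[0]], labels[hi[1]])
    return mat
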