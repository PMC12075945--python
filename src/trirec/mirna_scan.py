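"""Seed-and-extend homology search of mature miRNAs against a query.

The search replaces a web BLAST ranked by E-value with explicit,
reproducible criteria: candidate anchors are exact ``seed_k``-mers shared
between a mature and the query (forward, plus the reverse complement when
``both_strands``); each anchor is extended ungapped across the full mature
extent, then refined by one banded gapped pass (band +/-2), and the best
placement per (miRNA, strand, locus) is kept.  Hits are filtered by percent
identity and mature coverage, so stored hits are post-filter only.

Identity of a hit is 100 x (aligned_length - mismatches - gaps) /
aligned_length over the alignment columns; coverage is the fraction of the
mature's residues aligned (below 1 only when the placement runs off a query
end).  Placement quality is ranked by the score
``2*matches - 3*mismatches - 5*gap_columns``, which makes a gap strictly
worse than a mismatch, so the gapped pass only ever changes a placement
when an indel genuinely improves it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import (
    MiRNARecord,
    NucleotideSequence,
    UsageError,
    mirna_family,
    parse_mirna_name,
    reverse_complement,
)

__all__ = ["MiRNAHit", "scan_mirnas", "summarize_hits", "hits_to_bed6"]

MATCH_SCORE = 2
MISMATCH_SCORE = -3
GAP_SCORE = -5
BAND = 2


@dataclass
class MiRNAHit:
    """A database mature matched into a query sequence (post-filter)."""

    mirna_name: str
    query_id: str
    q_start: int  # 1-based inclusive, forward query coordinates
    q_end: int
    strand: str
    aligned_length: int
    mismatches: int
    gaps: int
    coverage: float

    @property
    def identity(self) -> float:
        return 100.0 * (self.aligned_length - self.mismatches - self.gaps) \
            / self.aligned_length


@dataclass
class _Placement:
    q_start: int  # 0-based
    q_end: int    # 0-based exclusive
    columns: int
    matches: int
    mismatches: int
    gaps: int
    coverage: float

    @property
    def score(self) -> int:
        return (MATCH_SCORE * self.matches + MISMATCH_SCORE * self.mismatches
                + GAP_SCORE * self.gaps)


def _ungapped(q: str, m: str, d: int) -> _Placement | None:
    """Place mature m at query offset d (may overhang either query end)."""
    L = len(m)
    ms = max(0, -d)
    me = min(L, len(q) - d)
    if me - ms < 1:
        return None
    mm = sum(1 for k in range(ms, me) if m[k] != q[d + k])
    cols = me - ms
    return _Placement(
        q_start=d + ms, q_end=d + me, columns=cols,
        matches=cols - mm, mismatches=mm, gaps=0,
        coverage=cols / L,
    )


def _banded(q: str, m: str, d: int) -> _Placement | None:
    """Banded gapped alignment of the full mature around diagonal d.

    The mature is aligned globally against the query window
    ``[d - BAND, d + len(m) + BAND)`` with free query end-gaps, keeping the
    alignment within +/-BAND of the anchor diagonal.  Returns the best
    placement, or None when the mature overhangs a query end (clipped
    placements stay ungapped).
    """
    L = len(m)
    w0 = d - BAND
    w1 = d + L + BAND
    if w0 < 0 or w1 > len(q):
        return None
    w = q[w0:w1]
    W = len(w)
    NEG = -(10 ** 9)
    # dp[i][j]: best score of m[:i] against w[:j]; leading query gaps free
    dp = [[NEG] * (W + 1) for _ in range(L + 1)]
    bt = [[0] * (W + 1) for _ in range(L + 1)]  # 1 diag, 2 up (gap in w), 3 left
    for j in range(W + 1):
        dp[0][j] = 0
    for i in range(1, L + 1):
        lo = max(1, i)  # band: |(j - BAND) - i| <= BAND  ->  i <= j <= i + 2*BAND
        hi = min(W, i + 2 * BAND)
        for j in range(lo, hi + 1):
            s = MATCH_SCORE if m[i - 1] == w[j - 1] else MISMATCH_SCORE
            cand = dp[i - 1][j - 1] + s
            ptr = 1
            if dp[i - 1][j] + GAP_SCORE > cand:
                cand = dp[i - 1][j] + GAP_SCORE
                ptr = 2
            if dp[i][j - 1] + GAP_SCORE > cand:
                cand = dp[i][j - 1] + GAP_SCORE
                ptr = 3
            dp[i][j] = cand
            bt[i][j] = ptr
    end_j = max(range(W + 1), key=lambda j: (dp[L][j], -j))
    if dp[L][end_j] <= NEG // 2:
        return None
    i, j = L, end_j
    matches = mm = gaps = cols = 0
    while i > 0:
        p = bt[i][j]
        if p == 1:
            cols += 1
            if m[i - 1] == w[j - 1]:
                matches += 1
            else:
                mm += 1
            i -= 1
            j -= 1
        elif p == 2:
            cols += 1
            gaps += 1
            i -= 1
        else:
            cols += 1
            gaps += 1
            j -= 1
    return _Placement(
        q_start=w0 + j, q_end=w0 + end_j, columns=cols,
        matches=matches, mismatches=mm, gaps=gaps, coverage=1.0,
    )


def _best_placement(q: str, m: str, d: int) -> _Placement | None:
    ug = _ungapped(q, m, d)
    if ug is None:
        return None
    gp = _banded(q, m, d)
    if gp is not None and gp.score > ug.score:
        return gp
    return ug


def scan_mirnas(query: NucleotideSequence, db: Sequence[MiRNARecord],
                seed_k: int = 7, min_identity: float = 85.0,
                min_coverage: float = 0.9,
                both_strands: bool = True) -> list[MiRNAHit]:
    """Scan a mature-miRNA database against a query sequence.

    Returns at most one hit per miRNA per strand per non-overlapping locus,
    sorted by descending identity then ascending name.  See the module
    docstring for the matching model.
    """
    if not 5 <= seed_k <= 12:
        raise UsageError("seed_k must be in [5, 12]")
    if not query.residues:
        raise UsageError("query must be non-empty")
    if not db:
        raise UsageError("miRNA database must be non-empty")
    q = query.residues
    index: dict[str, list[int]] = {}
    for p in range(len(q) - seed_k + 1):
        index.setdefault(q[p:p + seed_k], []).append(p)

    hits: list[MiRNAHit] = []
    for rec in db:
        strands = ["+", "C"] if both_strands else ["+"]
        for strand in strands:
            m = rec.residues if strand == "+" else reverse_complement(rec.residues)
            if len(m) < seed_k:
                continue
            diagonals = set()
            for p in range(len(m) - seed_k + 1):
                for qpos in index.get(m[p:p + seed_k], ()):
                    diagonals.add(qpos - p)
            placements = []
            for d in sorted(diagonals):
                pl = _best_placement(q, m, d)
                if pl is None:
                    continue
                if pl.coverage < min_coverage:
                    continue
                ident = 100.0 * (pl.columns - pl.mismatches - pl.gaps) / pl.columns
                if ident < min_identity:
                    continue
                placements.append(pl)
            for pl in _resolve_loci(placements):
                hits.append(
                    MiRNAHit(
                        mirna_name=rec.name, query_id=query.id,
                        q_start=pl.q_start + 1, q_end=pl.q_end,
                        strand=strand, aligned_length=pl.columns,
                        mismatches=pl.mismatches, gaps=pl.gaps,
                        coverage=pl.coverage,
                    )
                )
    hits.sort(key=lambda h: (-h.identity, h.mirna_name, h.q_start, h.strand))
    return hits


def _resolve_loci(placements: list[_Placement]) -> list[_Placement]:
    """Group overlapping placements into loci; keep the best of each group.

    Best = highest score, then fewer gaps, then smaller q_start.
    """
    if not placements:
        return []
    placements = sorted(placements, key=lambda p: p.q_start)
    groups: list[list[_Placement]] = [[placements[0]]]
    group_end = placements[0].q_end
    for pl in placements[1:]:
        if pl.q_start < group_end:
            groups[-1].append(pl)
            group_end = max(group_end, pl.q_end)
        else:
            groups.append([pl])
            group_end = pl.q_end
    return [
        min(g, key=lambda p: (-p.score, p.gaps, p.q_start))
        for g in groups
    ]


def summarize_hits(hits: Iterable[MiRNAHit],
                   db: Sequence[MiRNARecord] = ()) -> dict:
    """Distinct miRNA names, distinct species prefixes, per-family tallies."""
    names = sorted({h.mirna_name for h in hits})
    prefixes = set()
    families: dict[str, int] = {}
    for name in names:
        try:
            prefix, core, _ = parse_mirna_name(name)
            fam = mirna_family(core)
        except Exception:
            prefix, fam = "unknown", "unknown"
        prefixes.add(prefix)
        families[fam] = families.get(fam, 0) + 1
    return {
        "n_mirnas": len(names),
        "n_species": len(prefixes),
        "families": dict(sorted(families.items())),
        "names": names,
    }


def hits_to_bed6(hits: Iterable[MiRNAHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            strand = "-" if h.strand == "C" else "+"
            fh.write(
                f"{h.query_id}\t{h.q_start - 1}\t{h.q_end}\t{h.mirna_name}\t"
                f"{round(h.identity)}\t{strand}\n"
            )
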