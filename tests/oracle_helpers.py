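"""Independent brute-force oracles used by the test suite.

Every oracle here re-derives a result by exhaustive enumeration (or direct
counting) and shares no code path with the implementation it checks.
"""

from __future__ import annotations

from itertools import combinations


# -- affine-gap alignment by exhaustive enumeration ---------------------------

def enumerate_global_score(a: str, b: str, match: int, mismatch: int,
                           gap_open: int, gap_extend: int,
                           n_score: int | None = None) -> int:
    """Best global affine-gap score by enumerating every alignment.

    A gap of length k costs gap_open + (k-1)*gap_extend.  Exponential in the
    input lengths; intended for sequences of length <= 8.
    """
    if n_score is None:
        n_score = mismatch
    la, lb = len(a), len(b)
    best = [-(10 ** 9)]

    def sub(x: str, y: str) -> int:
        if x == "N" or y == "N":
            return n_score
        return match if x == y else mismatch

    def go(i: int, j: int, score: int, last: str) -> None:
        if i == la and j == lb:
            if score > best[0]:
                best[0] = score
            return
        if i < la and j < lb:
            go(i + 1, j + 1, score + sub(a[i], b[j]), "M")
        if i < la:
            go(i + 1, j, score - (gap_extend if last == "U" else gap_open), "U")
        if j < lb:
            go(i, j + 1, score - (gap_extend if last == "L" else gap_open), "L")

    go(0, 0, 0, "M")
    return best[0]


def enumerate_local_score(a: str, b: str, match: int, mismatch: int,
                          gap_open: int, gap_extend: int) -> int:
    """Best local affine-gap score by enumerating every path prefix from
    every start cell (the empty alignment scores 0)."""
    la, lb = len(a), len(b)
    best = [0]

    def go(i: int, j: int, score: int, last: str) -> None:
        if score > best[0]:
            best[0] = score
        if i < la and j < lb:
            s = match if a[i] == b[j] else mismatch
            go(i + 1, j + 1, score + s, "M")
        if i < la:
            go(i + 1, j, score - (gap_extend if last == "U" else gap_open), "U")
        if j < lb:
            go(i, j + 1, score - (gap_extend if last == "L" else gap_open), "L")

    for i in range(la):
        for j in range(lb):
            go(i, j, 0, "M")
    return best[0]


# -- trinomial detection by exhaustive triple enumeration ---------------------

def brute_force_trinomial(features, line_family: str, ltr_family: str,
                          max_gap: int, ignore_classes, mode: str,
                          require_same_strand: bool):
    """All candidate triples by O(n^3) enumeration, then the same greedy
    left-to-right non-overlapping selection, expressed over sorted indices.

    Returns a set of (chrom, left, ltr, right) coordinate tuples.
    """
    feats = sorted(features, key=lambda f: (f.chrom, f.start, f.end,
                                            f.repeat_name))
    visible = [f for f in feats
               if f.repeat_class_family.split("/", 1)[0] not in ignore_classes]
    n = len(visible)
    candidates = []
    for i, j, k in combinations(range(n), 3):
        left, ltr, right = visible[i], visible[j], visible[k]
        if j != i + 1 or k != j + 1:
            continue  # parts must be consecutive among non-ignored features
        if not (left.chrom == ltr.chrom == right.chrom):
            continue
        if left.repeat_name != line_family or right.repeat_name != line_family:
            continue
        if ltr.repeat_name != ltr_family:
            continue
        if not (left.end < ltr.start and ltr.end < right.start):
            continue
        if ltr.start - left.end - 1 > max_gap:
            continue
        if right.start - ltr.end - 1 > max_gap:
            continue
        if require_same_strand and not (left.strand == ltr.strand == right.strand):
            continue
        if mode == "fragment_id":
            if left.fragment_id is None or left.fragment_id != right.fragment_id:
                continue
        candidates.append((i, j, k))
    used: set[int] = set()
    chosen = set()
    for (i, j, k) in sorted(candidates):
        if used & {i, j, k}:
            continue
        used |= {i, j, k}
        left, ltr, right = visible[i], visible[j], visible[k]
        chosen.add((left.chrom, (left.start, left.end), (ltr.start, ltr.end),
                    (right.start, right.end)))
    return chosen


# -- genomic context by quadratic interval overlap ----------------------------

def brute_force_context(clusters, genes):
    """Quadratic overlap check reproducing the context rules directly."""
    out = []
    for c in clusters:
        overlapping = []
        for g in genes:
            if g.chrom != c.chrom:
                continue
            ov = min(c.span_end, g.end) - max(c.span_start, g.start) + 1
            if ov > 0:
                overlapping.append((g, ov))
        if not overlapping:
            out.append((c.name, None, "intergenic"))
            continue
        overlapping.sort(key=lambda t: (-t[1], t[0].gene_id))
        g = overlapping[0][0]
        if not (g.start <= c.span_start and c.span_end <= g.end):
            ctx = "mixed"
        else:
            exonic = any(
                min(c.span_end, ee) - max(c.span_start, es) + 1 > 0
                for es, ee in g.exons
            )
            ctx = "exonic" if exonic else "intronic"
        out.append((c.name, g.gene_id, ctx))
    return out


# -- conserved window by scanning all O(C^2) windows --------------------------

def brute_force_window(rows, min_source_identity: float, min_occupancy: float):
    """Longest valid window by checking every column window directly.

    Returns ((start, end) 0-based inclusive, consensus string) or None.
    Mirrors the published rule with plain per-window counting.
    """
    R = len(rows)
    C = len(rows[0]) if rows else 0
    consensus = []
    valid = []
    for c in range(C):
        col = [row[c] for row in rows]
        gaps = col.count("-")
        best_base, best_n = None, 0
        for base in "ACGT":
            n = col.count(base)
            if n > best_n:
                best_base, best_n = base, n
        consensus.append(best_base or "-")
        nongap = R - gaps
        valid.append(
            nongap / R >= min_occupancy and nongap > gaps and best_n > 0
        )
    best = None  # (length, start, end)
    for i in range(C):
        for j in range(i, C):
            if not all(valid[i:j + 1]):
                continue
            wl = j - i + 1
            ok = True
            for row in rows:
                ident = sum(
                    1 for c in range(i, j + 1) if row[c] == consensus[c]
                ) / wl
                if ident * 100 < min_source_identity - 1e-9:
                    ok = False
                    break
            if ok and (best is None or wl > best[0]):
                best = (wl, i, j)
    if best is None:
        return None
    _, i, j = best
    return (i, j), "".join(consensus[i:j + 1])


# -- miRNA scan by sliding everything -----------------------------------------

def _semiglobal_window(mature: str, window: str):
    """Full (unbanded) gapped alignment of the whole mature against a short
    query window, free window end-gaps; score 2*m - 3*mm - 5*gaps."""
    L, W = len(mature), len(window)
    NEG = -(10 ** 9)
    dp = [[NEG] * (W + 1) for _ in range(L + 1)]
    bt = [[0] * (W + 1) for _ in range(L + 1)]
    for j in range(W + 1):
        dp[0][j] = 0
    for i in range(1, L + 1):
        dp[i][0] = dp[i - 1][0] - 5
        bt[i][0] = 2
        for j in range(1, W + 1):
            s = 2 if mature[i - 1] == window[j - 1] else -3
            cand, ptr = dp[i - 1][j - 1] + s, 1
            if dp[i - 1][j] - 5 > cand:
                cand, ptr = dp[i - 1][j] - 5, 2
            if dp[i][j - 1] - 5 > cand:
                cand, ptr = dp[i][j - 1] - 5, 3
            dp[i][j] = cand
            bt[i][j] = ptr
    end_j = max(range(W + 1), key=lambda j: (dp[L][j], -j))
    i, j = L, end_j
    matches = mm = gaps = 0
    while i > 0:
        p = bt[i][j]
        if p == 1:
            if mature[i - 1] == window[j - 1]:
                matches += 1
            else:
                mm += 1
            i, j = i - 1, j - 1
        elif p == 2:
            gaps += 1
            i -= 1
        else:
            gaps += 1
            j -= 1
    return dp[L][end_j], matches, mm, gaps, j, end_j


def naive_scan(query: str, db, min_identity: float, min_coverage: float,
               both_strands: bool = True):
    """Slide every mature over every query offset, both strands, score each
    placement directly, filter, and keep the best placement per
    (miRNA, strand, locus).

    Each diagonal's placement is the ungapped overlay, refined by a full
    (unbanded) gapped alignment of a window around the diagonal whenever the
    ungapped overlay shows any promise.  Returns tuples
    (name, strand, q_start_1based, q_end_1based, mismatches, gaps).
    """
    comp = str.maketrans("ACGTN", "TGCAN")
    results = []
    for rec in db:
        strands = ["+", "C"] if both_strands else ["+"]
        for strand in strands:
            m = rec.residues if strand == "+" else \
                rec.residues.translate(comp)[::-1]
            L = len(m)
            placements = []
            for d in range(-(L - 1), len(query)):
                ms, me = max(0, -d), min(L, len(query) - d)
                cols = me - ms
                if cols < 1:
                    continue
                mm = sum(1 for k in range(ms, me) if m[k] != query[d + k])
                score = 2 * (cols - mm) - 3 * mm
                cand = (score, d + ms, d + me, cols, mm, 0, cols / L)
                if cols == L and (cols - mm) / cols >= 0.45:
                    w0, w1 = max(0, d - 2), min(len(query), d + L + 2)
                    if w0 == d - 2 and w1 == d + L + 2:
                        gs, gmat, gmm, ggaps, js, je = _semiglobal_window(
                            m, query[w0:w1])
                        if gs > score:
                            cand = (gs, w0 + js, w0 + je,
                                    gmat + gmm + ggaps, gmm, ggaps, 1.0)
                placements.append(cand)
            kept = []
            for score, qs, qe, cols, mm, gaps, cov in placements:
                if cov < min_coverage:
                    continue
                if 100.0 * (cols - mm - gaps) / cols < min_identity - 1e-9:
                    continue
                kept.append((score, qs, qe, cols, mm, gaps))
            kept.sort(key=lambda t: t[1])
            groups = []
            for pl in kept:
                if groups and pl[1] < groups[-1][1]:
                    groups[-1][0].append(pl)
                    groups[-1][1] = max(groups[-1][1], pl[2])
                else:
                    groups.append([[pl], pl[2]])
            for group, _ in groups:
                best = min(group, key=lambda t: (-t[0], t[5], t[1]))
                results.append((rec.name, strand, best[1] + 1, best[2],
                                best[4], best[5]))
    return set(results)
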