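"""Detection and naming of trinomial LINE/LTR/LINE recombination products.

A trinomial recombination product ("BovLTRBov" for the RTE-BovB/BTLTR1
families) is the genomic signature of an LTR-bearing endogenous retrovirus
inserted into, or recombined with, a LINE: two copies of the configured LINE
family flanking one copy of the LTR family in immediate succession on the
same strand.

Two detection signals are offered because annotation pipelines expose the
pattern in two ways: ``adjacency`` looks for the three parts consecutive in
the annotation stream (features of ignorable classes such as simple repeats
are transparent and may sit inside the gaps), while ``fragment_id``
additionally requires the two LINE copies to share a RepeatMasker fragment
linkage ID - the split-LINE signature left by a nested LTR insertion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .io_formats import RepeatFeature, UsageError

log = logging.getLogger("trirec")

__all__ = ["TrinomialCluster", "detect_trinomial_clusters", "name_clusters",
           "clusters_to_bed6", "DEFAULT_IGNORE_CLASSES"]

DEFAULT_IGNORE_CLASSES = frozenset({"Simple_repeat", "Low_complexity"})


@dataclass
class TrinomialCluster:
    """An ordered LINE-LTR-LINE triple with span, orientation and gaps.

    Names follow the ``+<n>-<gene>`` / ``c<n>-<gene>`` convention: forward
    clusters are numbered in genomic order with prefix ``+``, complement
    clusters with prefix ``c``; the host-gene suffix is ``NA`` until the
    genomic-context stage assigns one.
    """

    chrom: str
    left_line: RepeatFeature
    ltr: RepeatFeature
    right_line: RepeatFeature
    orientation: str
    detection_mode: str
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.left_line.end < self.ltr.start and self.ltr.end < self.right_line.start):
            raise UsageError("cluster parts must be ordered and non-overlapping")

    @property
    def span_start(self) -> int:
        return self.left_line.start

    @property
    def span_end(self) -> int:
        return self.right_line.end

    @property
    def gap_left(self) -> int:
        return self.ltr.start - self.left_line.end - 1

    @property
    def gap_right(self) -> int:
        return self.right_line.start - self.ltr.end - 1


def detect_trinomial_clusters(
    features: Iterable[RepeatFeature],
    line_family: str = "RTE-BovB",
    ltr_family: str = "BTLTR1",
    max_gap: int = 100,
    ignore_classes: frozenset[str] = DEFAULT_IGNORE_CLASSES,
    mode: str = "adjacency",
    require_same_strand: bool = True,
) -> list[TrinomialCluster]:
    """Find LINE/LTR/LINE triples in a repeat-annotation stream.

    The three parts must be consecutive among non-ignored features with both
    inter-part gaps <= ``max_gap`` bp; in ``fragment_id`` mode the flanking
    LINEs must additionally share a fragment linkage ID.  Overlapping
    candidate triples are resolved greedily left to right, so a feature
    belongs to at most one cluster.  Output is sorted by (chrom, span_start);
    detection is deterministic and permutation-invariant (input is sorted
    internally).
    """
    if mode not in ("adjacency", "fragment_id"):
        raise UsageError(f"unknown detection mode {mode!r}")
    if not line_family or not ltr_family:
        raise UsageError("line_family and ltr_family must be non-empty")
    feats = list(features)
    ordered = sorted(feats, key=lambda f: (f.chrom, f.start, f.end, f.repeat_name))
    if feats != ordered:
        log.info("detect_trinomial_clusters: input not sorted; sorting internally")
    visible = [f for f in ordered if f.repeat_class not in ignore_classes]

    clusters: list[TrinomialCluster] = []
    i = 0
    while i <= len(visible) - 3:
        trio = visible[i:i + 3]
        if _is_trinomial(trio, line_family, ltr_family, max_gap, mode,
                         require_same_strand):
            left, ltr, right = trio
            orientation = ltr.strand if not require_same_strand else left.strand
            clusters.append(
                TrinomialCluster(
                    chrom=left.chrom, left_line=left, ltr=ltr, right_line=right,
                    orientation=orientation, detection_mode=mode,
                )
            )
            i += 3
        else:
            i += 1
    clusters.sort(key=lambda c: (c.chrom, c.span_start))
    return clusters


def _is_trinomial(trio: Sequence[RepeatFeature], line_family: str, ltr_family: str,
                  max_gap: int, mode: str, require_same_strand: bool) -> bool:
    left, ltr, right = trio
    if not (left.chrom == ltr.chrom == right.chrom):
        return False
    if left.repeat_name != line_family or right.repeat_name != line_family:
        return False
    if ltr.repeat_name != ltr_family:
        return False
    if not (left.end < ltr.start and ltr.end < right.start):
        return False
    if ltr.start - left.end - 1 > max_gap or right.start - ltr.end - 1 > max_gap:
        return False
    if require_same_strand and not (left.strand == ltr.strand == right.strand):
        return False
    if mode == "fragment_id":
        if left.fragment_id is None or left.fragment_id != right.fragment_id:
            return False
    return True


def name_clusters(clusters: Sequence[TrinomialCluster]) -> list[TrinomialCluster]:
    """Assign conventional cluster names in genomic order.

    Forward clusters become ``+1-NA`` .. ``+n_f-NA``; complement clusters
    ``c1-NA`` .. ``c_n_c-NA``.  The ``NA`` suffix is replaced with the host
    gene once genomic context is assigned.  Input must already be sorted by
    (chrom, span_start); the collection is returned with names set.
    """
    n_fwd = n_rev = 0
    for c in clusters:
        if c.orientation == "+":
            n_fwd += 1
            c.name = f"+{n_fwd}-NA"
        else:
            n_rev += 1
            c.name = f"c{n_rev}-NA"
    return list(clusters)


def clusters_to_bed6(clusters: Sequence[TrinomialCluster], path) -> None:
    """Export cluster spans as BED6 (score = min part Smith-Waterman score)."""
    with open(path, "w") as fh:
        for c in clusters:
            score = min(c.left_line.sw_score, c.ltr.sw_score, c.right_line.sw_score)
            strand = "-" if c.orientation == "C" else "+"
            fh.write(
                f"{c.chrom}\t{c.span_start - 1}\t{c.span_end}\t{c.name}\t"
                f"{score}\t{strand}\n"
            )
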