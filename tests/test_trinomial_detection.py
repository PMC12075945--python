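"""Trinomial cluster detection: planted patterns, brute-force equivalence,
invariances, naming."""

import numpy as np
import pytest

from oracle_helpers import brute_force_trinomial
from trirec.io_formats import RepeatFeature, UsageError
from trirec.trinomial_detection import (
    DEFAULT_IGNORE_CLASSES,
    detect_trinomial_clusters,
    name_clusters,
)

LINE = ("RTE-BovB", "LINE/RTE-BovB")
LTR = ("BTLTR1", "LTR/ERVL")


def feat(start, end, name_class, strand="+", chrom="chr1", frag=None):
    name, klass = name_class
    return RepeatFeature(chrom, start, end, strand, name, klass,
                         sw_score=1000, pct_divergence=5.0, fragment_id=frag)


def coords(clusters):
    return {(c.chrom, (c.left_line.start, c.left_line.end),
             (c.ltr.start, c.ltr.end),
             (c.right_line.start, c.right_line.end)) for c in clusters}


def random_features(rng, n, planted=0, chrom="chr1"):
    """n random decoy features plus `planted` valid triples, sorted layout."""
    pool = [LINE, LTR, ("L1_BT", "LINE/L1"), ("MIR", "SINE/MIR"),
            ("(TG)n", "Simple_repeat")]
    feats = []
    pos = 100
    planted_coords = []
    slots = sorted(rng.choice(max(n, 1), size=planted, replace=False)) \
        if planted else []
    slot_set = set(int(s) for s in slots)
    for i in range(n):
        if i in slot_set:
            s1 = pos
            l1 = feat(s1, s1 + 300, LINE, "+")
            l2 = feat(s1 + 350, s1 + 550, LTR, "+")
            l3 = feat(s1 + 600, s1 + 900, LINE, "+")
            feats += [l1, l2, l3]
            planted_coords.append((chrom, (l1.start, l1.end),
                                   (l2.start, l2.end), (l3.start, l3.end)))
            pos += 1400
        nc = pool[int(rng.integers(len(pool)))]
        length = int(rng.integers(50, 400))
        strand = "+" if rng.integers(2) else "C"
        feats.append(feat(pos, pos + length, nc, strand))
        pos += length + int(rng.integers(150, 600))
    return feats, planted_coords


class TestDetection:
    def test_planted_triple_and_gaps(self):
        feats = [feat(100, 500, LINE), feat(550, 900, LTR),
                 feat(950, 1300, LINE)]
        (c,) = detect_trinomial_clusters(feats, max_gap=100)
        assert (c.gap_left, c.gap_right) == (49, 49)
        assert (c.span_start, c.span_end) == (100, 1300)
        assert c.orientation == "+"

    def test_middle_family_filter(self):
        feats = [feat(100, 500, LINE), feat(550, 900, ("L1_BT", "LINE/L1")),
                 feat(950, 1300, LINE)]
        assert detect_trinomial_clusters(feats) == []

    def test_gap_exceeds_max(self):
        feats = [feat(100, 500, LINE), feat(700, 900, LTR),
                 feat(950, 1300, LINE)]
        assert detect_trinomial_clusters(feats, max_gap=100) == []
        assert len(detect_trinomial_clusters(feats, max_gap=300)) == 1

    def test_strand_requirement(self):
        feats = [feat(100, 500, LINE, "+"), feat(550, 900, LTR, "C"),
                 feat(950, 1300, LINE, "+")]
        assert detect_trinomial_clusters(feats) == []
        (c,) = detect_trinomial_clusters(feats, require_same_strand=False)
        assert c.orientation == "C"  # orientation follows the LTR

    def test_ignored_classes_are_transparent(self):
        feats = [feat(100, 500, LINE), feat(510, 530, ("(TG)n", "Simple_repeat")),
                 feat(550, 900, LTR), feat(950, 1300, LINE)]
        (c,) = detect_trinomial_clusters(feats)
        assert c.gap_left == 49
        # without transparency the simple repeat breaks adjacency
        assert detect_trinomial_clusters(feats, ignore_classes=frozenset()) == []

    def test_fragment_id_mode(self):
        feats = [feat(100, 500, LINE, frag=7), feat(550, 900, LTR, frag=8),
                 feat(950, 1300, LINE, frag=7)]
        assert len(detect_trinomial_clusters(feats, mode="fragment_id")) == 1
        feats[2].fragment_id = 9
        assert detect_trinomial_clusters(feats, mode="fragment_id") == []
        assert len(detect_trinomial_clusters(feats, mode="adjacency")) == 1

    def test_unknown_mode(self):
        with pytest.raises(UsageError):
            detect_trinomial_clusters([], mode="nope")

    def test_greedy_chain_resolution(self):
        # LINE,LTR,LINE,LTR,LINE yields one cluster from the leftmost triple
        feats = [feat(100, 200, LINE), feat(250, 350, LTR),
                 feat(400, 500, LINE), feat(550, 650, LTR),
                 feat(700, 800, LINE)]
        clusters = detect_trinomial_clusters(feats)
        assert len(clusters) == 1
        assert clusters[0].span_start == 100

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_equivalence_with_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        feats, planted = random_features(rng, 60, planted=7)
        for max_gap in (60, 100, 400):
            got = detect_trinomial_clusters(feats, max_gap=max_gap)
            oracle = brute_force_trinomial(
                feats, "RTE-BovB", "BTLTR1", max_gap,
                DEFAULT_IGNORE_CLASSES, "adjacency", True)
            assert coords(got) == oracle
        got = detect_trinomial_clusters(feats, max_gap=100)
        assert set(planted) <= coords(got)

    def test_permutation_invariance(self):
        import random

        rng = np.random.default_rng(5)
        feats, _ = random_features(rng, 40, planted=4)
        ref = coords(detect_trinomial_clusters(feats))
        shuffler = random.Random(5)
        for _ in range(3):
            shuffler.shuffle(feats)
            assert coords(detect_trinomial_clusters(list(feats))) == ref

    def test_max_gap_monotonicity(self):
        rng = np.random.default_rng(11)
        feats, _ = random_features(rng, 80, planted=5)
        prev = set()
        for g in (10, 50, 100, 300, 1000):
            cur = coords(detect_trinomial_clusters(feats, max_gap=g))
            assert prev <= cur
            prev = cur

    def test_no_false_positives_without_pattern(self):
        rng = np.random.default_rng(6)
        feats, _ = random_features(rng, 120, planted=0)
        # remove any chance adjacency of the target families
        feats = [f for f in feats if f.repeat_name != "BTLTR1"]
        assert detect_trinomial_clusters(feats) == []

    def test_scenario_recovery(self, canonical_scenario):
        truth = canonical_scenario.truth["clusters"]
        got = detect_trinomial_clusters(canonical_scenario.repeats_a)
        assert {(c.span_start, c.span_end, c.orientation) for c in got} == \
            {(t["span_start"], t["span_end"], t["orientation"]) for t in truth}

    def test_scenario_fragment_id_mode_agrees(self, canonical_scenario):
        adj = detect_trinomial_clusters(canonical_scenario.repeats_a)
        fid = detect_trinomial_clusters(canonical_scenario.repeats_a,
                                        mode="fragment_id")
        assert coords(adj) == coords(fid)


class TestNaming:
    def test_counting(self):
        feats = [feat(100, 200, LINE), feat(250, 350, LTR),
                 feat(400, 500, LINE),
                 feat(1000, 1100, LINE), feat(1150, 1250, LTR),
                 feat(1300, 1400, LINE),
                 feat(2000, 2100, LINE, "C"), feat(2150, 2250, LTR, "C"),
                 feat(2300, 2400, LINE, "C")]
        clusters = name_clusters(detect_trinomial_clusters(feats))
        assert [c.name for c in clusters] == ["+1-NA", "+2-NA", "c1-NA"]

    def test_empty(self):
        assert name_clusters([]) == []

    def test_twenty_forward_ten_complement(self, canonical_scenario):
        clusters = name_clusters(
            detect_trinomial_clusters(canonical_scenario.repeats_a))
        names = [c.name for c in clusters]
        fwd = [n for n in names if n.startswith("+")]
        rev = [n for n in names if n.startswith("c")]
        assert [n.split("-")[0] for n in fwd] == [f"+{i}" for i in range(1, 21)]
        assert [n.split("-")[0] for n in rev] == [f"c{i}" for i in range(1, 11)]
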