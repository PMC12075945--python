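"""Shared / species-specific breakdown of miRNA hit sets and family rollup.

The comparison key is the full mature name, species prefix included, so
homologs of one family contributed by different species count separately;
``strip_prefix=True`` switches to prefix-stripped comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .io_formats import UsageError, mirna_family, parse_mirna_name

__all__ = ["SpeciesHitSets", "compare_hit_sets", "family_rollup",
           "species_prefix_counts"]


def _names(hits) -> set[str]:
    out = set()
    for h in hits:
        out.add(h if isinstance(h, str) else h.mirna_name)
    return out


@dataclass
class SpeciesHitSets:
    """Two species' miRNA hit sets with their set algebra precomputed."""

    label_a: str
    label_b: str
    set_a: set[str]
    set_b: set[str]
    common: set[str] = field(init=False)
    only_a: set[str] = field(init=False)
    only_b: set[str] = field(init=False)
    family_breakdown: dict[str, tuple[int, int, int]] = field(init=False)

    def __post_init__(self) -> None:
        self.common = self.set_a & self.set_b
        self.only_a = self.set_a - self.set_b
        self.only_b = self.set_b - self.set_a
        breakdown: dict[str, list[int]] = {}
        for idx, names in enumerate((self.common, self.only_a, self.only_b)):
            for name in names:
                fam = _family_or_unknown(name)
                breakdown.setdefault(fam, [0, 0, 0])[idx] += 1
        self.family_breakdown = {
            fam: tuple(v) for fam, v in sorted(breakdown.items())
        }

    def to_dict(self) -> dict:
        return {
            "label_a": self.label_a,
            "label_b": self.label_b,
            "n_a": len(self.set_a),
            "n_b": len(self.set_b),
            "n_common": len(self.common),
            "n_only_a": len(self.only_a),
            "n_only_b": len(self.only_b),
            "common": sorted(self.common),
            "only_a": sorted(self.only_a),
            "only_b": sorted(self.only_b),
            "family_breakdown": {
                fam: {"common": c, "only_a": a, "only_b": b}
                for fam, (c, a, b) in self.family_breakdown.items()
            },
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _family_or_unknown(name: str) -> str:
    try:
        _, core, _ = parse_mirna_name(name)
        return mirna_family(core)
    except Exception:
        return "unknown"


def compare_hit_sets(hits_a: Iterable, hits_b: Iterable, label_a: str,
                     label_b: str, strip_prefix: bool = False) -> SpeciesHitSets:
    """Build the shared/specific comparison of two species' hit sets.

    ``hits_a``/``hits_b`` may be :class:`~trirec.mirna_scan.MiRNAHit`
    collections or plain name collections; sets are built on distinct
    mature names.
    """
    if label_a == label_b:
        raise UsageError("species labels must differ")
    set_a, set_b = _names(hits_a), _names(hits_b)
    if strip_prefix:
        def strip(name: str) -> str:
            try:
                prefix, core, arm = parse_mirna_name(name)
            except Exception:
                return name
            return core if arm == "none" else f"{core}-{arm}"
        set_a = {strip(n) for n in set_a}
        set_b = {strip(n) for n in set_b}
    return SpeciesHitSets(label_a, label_b, set_a, set_b)


def family_rollup(s: SpeciesHitSets) -> dict:
    """Per-family counts plus the dominant family of the A-only set.

    The dominant family is the largest family among ``only_a`` names (ties
    to the lexicographically smaller family); its share is
    ``count / |only_a|``.
    """
    only_a_fams: dict[str, int] = {}
    for name in s.only_a:
        fam = _family_or_unknown(name)
        only_a_fams[fam] = only_a_fams.get(fam, 0) + 1
    if only_a_fams:
        dominant = min(only_a_fams, key=lambda f: (-only_a_fams[f], f))
        share = only_a_fams[dominant] / len(s.only_a)
    else:
        dominant, share = None, 0.0
    return {
        "families": {
            fam: {"common": c, "only_a": a, "only_b": b}
            for fam, (c, a, b) in s.family_breakdown.items()
        },
        "dominant_family_only_a": dominant,
        "dominant_share_only_a": share,
    }


def plot_venn(s: SpeciesHitSets, path) -> None:
    """Two-circle Venn figure of the shared/specific hit counts (optional;
    requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.add_patch(Circle((0.38, 0.5), 0.32, alpha=0.4, color="tab:blue"))
    ax.add_patch(Circle((0.62, 0.5), 0.32, alpha=0.4, color="tab:orange"))
    ax.text(0.25, 0.5, str(len(s.only_a)), ha="center", fontsize=14)
    ax.text(0.5, 0.5, str(len(s.common)), ha="center", fontsize=14)
    ax.text(0.75, 0.5, str(len(s.only_b)), ha="center", fontsize=14)
    ax.text(0.25, 0.88, s.label_a, ha="center")
    ax.text(0.75, 0.88, s.label_b, ha="center")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.axis("off")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def species_prefix_counts(names: Iterable[str]) -> dict[str, int]:
    """Tally of species prefixes in a name set (the "different species" count)."""
    counts: dict[str, int] = {}
    for name in names:
        try:
            prefix, _, _ = parse_mirna_name(name)
        except Exception:
            prefix = "unknown"
        counts[prefix] = counts.get(prefix, 0) + 1
    return dict(sorted(counts.items()))
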