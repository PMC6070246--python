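"""Multi-comparison set algebra and directional expression patterns.

The Venn partition assigns every feature in the union of the per-comparison
DE sets to exactly one region — the subset of comparisons it is significant
in (15 regions for four comparisons).  Pattern classification applies only
to features significant in all four comparisons: the ordered signs of their
log2 fold-changes over (CV_BDE-47, CV_BDE-99, GF_BDE-47, GF_BDE-99) define
the pattern, with named aliases for the four recurring profiles:

* ``(+ + + +)`` — up-regulated by both congeners in both enterotypes,
* ``(- - - -)`` — down-regulated everywhere,
* ``(- - - +)`` — down everywhere except up by BDE-99 without microbiome,
* ``(+ + - -)`` — up with microbiome, down without.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .expression import DEResult

__all__ = [
    "DEFAULT_COMPARISON_ORDER",
    "PATTERN_ALIASES",
    "PatternVector",
    "venn_partition",
    "venn_counts_frame",
    "common_unique",
    "classify_pattern",
    "pattern_table",
]

DEFAULT_COMPARISON_ORDER = (
    "CV_CO_vs_CV_BDE-47",
    "CV_CO_vs_CV_BDE-99",
    "GF_CO_vs_GF_BDE-47",
    "GF_CO_vs_GF_BDE-99",
)

PATTERN_ALIASES: dict[tuple[str, ...], str] = {
    ("+", "+", "+", "+"): "Pattern1-up",
    ("-", "-", "-", "-"): "Pattern2-down",
    ("-", "-", "-", "+"): "Pattern3",
    ("+", "+", "-", "-"): "Pattern4",
}


@dataclass(frozen=True)
class PatternVector:
    """Ordered log2fc signs over the comparisons, for an all-four-significant
    feature, with the conventional alias when one exists."""

    signs: tuple[str, ...]
    comparisons: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.signs) != len(self.comparisons):
            raise ValueError("signs and comparisons must have equal length")
        if any(s not in ("+", "-") for s in self.signs):
            raise ValueError(f"signs must be '+' or '-', got {self.signs}")

    @property
    def alias(self) -> Optional[str]:
        return PATTERN_ALIASES.get(self.signs)

    @property
    def label(self) -> str:
        return self.alias or "".join(self.signs)


def venn_partition(sets: Mapping[str, Iterable[str]]) -> dict[frozenset, set]:
    """Partition the union of the input sets by membership profile.

    Returns a mapping from every non-empty subset of set names (as a
    frozenset) to the features belonging to exactly those sets.  Regions are
    pairwise disjoint; their union is the union of the inputs.
    """
    names = sorted(sets)
    if not 2 <= len(names) <= 6:
        raise ValueError(f"venn_partition supports 2-6 sets, got {len(names)}")
    materialized = {n: set(sets[n]) for n in names}

    from itertools import combinations
    regions: dict[frozenset, set] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            regions[frozenset(combo)] = set()
    universe = set().union(*materialized.values())
    for feature in universe:
        profile = frozenset(n for n in names if feature in materialized[n])
        regions[profile].add(feature)
    return regions


def region_label(region: frozenset) -> str:
    return "&".join(sorted(region))


def venn_counts_frame(regions: Mapping[frozenset, set]) -> pd.DataFrame:
    rows = sorted(
        ((len(region), region_label(region), len(members))
         for region, members in regions.items()),
    )
    return pd.DataFrame(
        [(label, n) for _, label, n in rows], columns=["region", "count"],
    )


def common_unique(sets: Mapping[str, Iterable[str]],
                  ) -> tuple[set, dict[str, set]]:
    """The all-sets-common region and the unique-to-each singleton regions."""
    regions = venn_partition(sets)
    names = sorted(sets)
    common = regions[frozenset(names)]
    unique = {n: regions[frozenset([n])] for n in names}
    return common, unique


def classify_pattern(results: Iterable[DEResult],
                     comparisons: Sequence[str] = DEFAULT_COMPARISON_ORDER,
                     ) -> Optional[PatternVector]:
    """Sign vector of one feature's log2fc across the comparisons.

    Returns None unless the feature is significant in every comparison.
    """
    by_comparison: dict[str, DEResult] = {}
    feature_ids = set()
    for r in results:
        if r.comparison in comparisons:
            by_comparison[r.comparison] = r
            feature_ids.add(r.feature_id)
    if len(feature_ids) > 1:
        raise ValueError(
            f"classify_pattern takes results for one feature, got {sorted(feature_ids)}"
        )
    if any(c not in by_comparison for c in comparisons):
        missing = [c for c in comparisons if c not in by_comparison]
        raise ValueError(f"missing comparisons: {missing}")
    if not all(by_comparison[c].significant for c in comparisons):
        return None
    signs = []
    for c in comparisons:
        fc = by_comparison[c].log2fc
        if fc == 0.0:
            raise ValueError(
                f"{by_comparison[c].feature_id}: significant in {c} with log2fc 0"
            )
        signs.append("+" if fc > 0 else "-")
    return PatternVector(signs=tuple(signs), comparisons=tuple(comparisons))


def pattern_table(de_results: Iterable[DEResult],
                  comparisons: Sequence[str] = DEFAULT_COMPARISON_ORDER,
                  ) -> pd.DataFrame:
    """Pattern label per feature significant in all comparisons."""
    by_feature: dict[str, list[DEResult]] = {}
    for r in de_results:
        by_feature.setdefault(r.feature_id, []).append(r)
    rows = []
    for fid in sorted(by_feature):
        try:
            vector = classify_pattern(by_feature[fid], comparisons)
        except ValueError:
            continue  # feature not tested in every comparison
        if vector is not None:
            rows.append((fid, "".join(vector.signs), vector.label))
    return pd.DataFrame(rows, columns=["feature_id", "signs", "pattern"])
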