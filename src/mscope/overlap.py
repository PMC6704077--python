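"""Thresholded-overlap statistics between montage pairs.

Each montage's field is thresholded at a fraction (default 50%) of its own
maximum, giving the set of nodes the montage stimulates substantially.
For a dorsal/ventral montage pair the overlap count N_overlap is the size
of the intersection of the two sets, the proportion

    p = N_overlap / N_above        (N_above of the first, dorsal, montage)

measures how much of the dorsal territory the ventral montage re-covers,
and for two pairs the contrast ratio

    r = |p1 - p2| / (p1 + p2)  in [0, 1]

quantifies whether the overlap proportion actually changed between the two
configurations (r -> 0: same proportion; r -> 1: one proportion vanishes
relative to the other).

Because the threshold is a fraction of each field's own maximum, every
quantity here is invariant under global positive scaling of a field — in
particular under changes of the injected current.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import FieldVector, MscopeError, logger


@dataclass
class ThresholdedSet:
    """Nodes of one montage with field value strictly above threshold."""

    montage_name: str
    threshold: float
    node_ids: frozenset[int]

    @property
    def n_above(self) -> int:
        return len(self.node_ids)


@dataclass
class OverlapResult:
    """Overlap of one dorsal/ventral pair of thresholded sets."""

    pair: tuple[str, str]
    n_overlap: int
    p: float


@dataclass
class PairComparison:
    p1: float
    p2: float
    r: float


def threshold_field(field: FieldVector, fraction: float = 0.5
                    ) -> ThresholdedSet:
    """Nodes with value strictly greater than fraction * max(field).

    Ties at exactly the threshold are excluded; the maximum node itself is
    always included (max > fraction * max for fraction < 1 and max > 0).
    """
    if not 0.0 < fraction < 1.0:
        raise MscopeError("threshold fraction must lie in (0, 1)")
    if len(field) == 0:
        raise MscopeError("empty field")
    vmax = float(field.value.max())
    if vmax <= 0:
        raise MscopeError("cannot threshold an all-zero field")
    threshold = fraction * vmax
    above = field.node_id[field.value > threshold]
    return ThresholdedSet(montage_name=field.montage_name,
                          threshold=threshold,
                          node_ids=frozenset(int(i) for i in above))


def count_overlap(a: ThresholdedSet, b: ThresholdedSet) -> int:
    """Number of above-threshold nodes common to both montages."""
    return len(a.node_ids & b.node_ids)


def overlap_proportion(n_overlap: int, n_above: int) -> float:
    """p = N_overlap / N_above (N_above of the first montage of the pair)."""
    if n_above <= 0:
        raise MscopeError("N_above must be positive")
    if not 0 <= n_overlap <= n_above:
        raise MscopeError("N_overlap must lie in [0, N_above]")
    if n_overlap == 0:
        logger.info("overlap proportion is 0 (the p > 0 qualifier of the "
                    "defining formula is relaxed at this boundary)")
    return n_overlap / n_above


def pair_ratio(p1: float, p2: float) -> PairComparison:
    """r = |p1 - p2| / (p1 + p2); symmetric, in [0, 1]."""
    if p1 < 0 or p2 < 0:
        raise MscopeError("proportions must be non-negative")
    if p1 + p2 == 0:
        raise MscopeError("r is undefined when p1 + p2 = 0")
    return PairComparison(p1=p1, p2=p2, r=abs(p1 - p2) / (p1 + p2))


def pair_overlap(dorsal: ThresholdedSet, ventral: ThresholdedSet
                 ) -> OverlapResult:
    """Overlap count and proportion for one dorsal/ventral pair."""
    n = count_overlap(dorsal, ventral)
    return OverlapResult(pair=(dorsal.montage_name, ventral.montage_name),
                         n_overlap=n,
                         p=overlap_proportion(n, dorsal.n_above))


def all_pairs_overlap(dorsal: list[ThresholdedSet],
                      ventral: list[ThresholdedSet]) -> list[OverlapResult]:
    """Overlap results for every dorsal x ventral combination
    (row-major: all ventral cells of the first dorsal montage first)."""
    if not dorsal or not ventral:
        raise MscopeError("need at least one montage per pathway")
    return [pair_overlap(d, v) for d in dorsal for v in ventral]
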