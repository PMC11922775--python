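"""±1 cumulative coordinated-expression scan along the ordered gene list.

Walking the importance-ordered central genes, the score rises by 1 for an
upregulated gene and falls by 1 for a downregulated one.  A flat trace means
directions are randomly mixed; a sustained slope marks a run of
topographically related genes with coordinated expression — a "zone".
Zones are detected by a windowed-slope rule and ranked by strength.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .centrality import OrderedGeneList
from .network import DiffExpressionTable

logger = logging.getLogger("ciliagraph")


@dataclasses.dataclass
class ScanProfile:
    """Cumulative ±1 trace along an ordered gene list.

    ``cumulative`` has length ``len(genes) + 1`` with S_0 = 0 and
    S_i = S_{i-1} + increment_i; increments lie in {-1, 0, +1}.
    """

    genes: list[str]
    increments: list[int]
    cumulative: np.ndarray

    @property
    def final(self) -> int:
        return int(self.cumulative[-1])


@dataclasses.dataclass(frozen=True)
class Zone:
    """A sustained-slope region of the scan profile.

    ``start`` and ``end`` are offsets into the cumulative trace (0-based, so
    the zone covers list ranks start+1 .. end, 1-based).  Strength is the net
    change per position, |S_end − S_start| / (end − start), in [0, 1].
    """

    start: int
    end: int
    sign: int
    strength: float


def cumulative_scan(
    order: OrderedGeneList, table: DiffExpressionTable
) -> ScanProfile:
    """Accumulate +1/−1 per up/down-regulated gene along the central sublist.

    Genes with log2fc exactly 0 contribute 0 and stay in the list, preserving
    the topographic ordering.  A gene missing from the table is an error.
    """
    directions = table.directions()
    genes = list(order.central)
    increments: list[int] = []
    for g in genes:
        if g not in directions:
            raise KeyError(f"gene {g!r} missing from expression table")
        increments.append(int(directions[g]))
    n_zero = increments.count(0)
    if n_zero:
        logger.info("%d scanned genes have zero fold change", n_zero)
    cumulative = np.concatenate([[0], np.cumsum(increments, dtype=int)])
    return ScanProfile(genes=genes, increments=increments, cumulative=cumulative)


def detect_zones(profile: ScanProfile, window: int, slope_min: float) -> list[Zone]:
    """Find maximal runs of sustained windowed slope.

    The slope at offset i is (S_{i+window} − S_i)/window.  Offsets where
    |slope| ≥ slope_min form same-sign runs; runs of equal sign separated by
    fewer than window/2 offsets are merged; a run [a, b] yields the zone
    [a, b + window].  Zones shorter than ``window`` are discarded and the
    result is sorted by strength (descending), ties by start.
    """
    if window < 2:
        raise ValueError(f"window must be ≥ 2, got {window}")
    if not 0.0 < slope_min <= 1.0:
        raise ValueError(f"slope_min must lie in (0,1], got {slope_min}")
    s = profile.cumulative
    n = len(profile.genes)
    if window >= n:
        logger.warning("window %d ≥ list length %d; no zones", window, n)
        return []

    slopes = (s[window:] - s[: n - window + 1]) / window
    signs = np.where(slopes >= slope_min, 1, np.where(slopes <= -slope_min, -1, 0))

    # maximal runs of constant nonzero sign
    runs: list[tuple[int, int, int]] = []  # (first offset, last offset, sign)
    i = 0
    while i < len(signs):
        if signs[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < len(signs) and signs[j + 1] == signs[i]:
            j += 1
        runs.append((i, j, int(signs[i])))
        i = j + 1

    # merge same-sign runs separated by < window/2 offsets
    merged: list[tuple[int, int, int]] = []
    for run in runs:
        if merged and run[2] == merged[-1][2] and run[0] - merged[-1][1] - 1 < window / 2:
            merged[-1] = (merged[-1][0], run[1], run[2])
        else:
            merged.append(run)

    zones = []
    for a, b, sign in merged:
        start, end = a, b + window
        if end - start < window:
            continue
        net_change = int(s[end] - s[start])
        strength = abs(net_change) / (end - start)
        zones.append(Zone(start=start, end=end, sign=sign, strength=float(strength)))
    zones.sort(key=lambda z: (-z.strength, z.start))
    return zones


def pathway_coordination_strength(
    pathway_members: list[str],
    order: OrderedGeneList,
    table: DiffExpressionTable,
) -> float | None:
    """|#up − #down| / #nonzero among the pathway's genes in the ordered list.

    1 means every listed gene moves the same way; 0 means perfectly balanced.
    Returns None (reported as missing) when the pathway has no listed gene
    with a nonzero direction.
    """
    listed = set(order.central)
    directions = table.directions()
    present = [g for g in pathway_members if g in listed]
    if not present:
        return None
    nonzero = [directions[g] for g in present if directions.get(g, 0) != 0]
    if not nonzero:
        return None
    return abs(sum(nonzero)) / len(nonzero)
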