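"""Synthetic pathway universes and expression tables with planted truth.

The generator emulates the study design the pipeline targets: a proteome-wide
differential-expression contrast (treated vs vehicle hippocampus) analysed
against a curated pathway database.  It plants verifiable structure — a
pathway overlapping the autophagy anchor, a pathway disconnected from it, a
gene sitting in many pathways, and a block of co-directed genes in a known
ordering — so that every downstream stage can be tested for recovery without
any external download.  It makes no attempt to model mass-spec intensities,
missingness or quantification noise: only signed fold changes and adjusted
p-values matter downstream.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .network import DiffExpressionTable, PathwayCollection

#: Amino-acid alphabet with valine and proline removed: background drawn from
#: it can never create a spurious VxPx match.
_BACKGROUND_ALPHABET = "ACDEFGHIKLMNQRSTWY"

#: Planted motif instances of the 400-residue receptor C-terminal fixture:
#: (1-based start, tetramer).  Mirrors the five ciliary-targeting sites of
#: the GPR158 C-terminal domain.
FIXTURE_MOTIFS: tuple[tuple[int, str], ...] = (
    (212, "VCPW"),
    (277, "VCPW"),
    (300, "VLPG"),
    (331, "VAPK"),
    (377, "VCPW"),
)
FIXTURE_LENGTH = 400


@dataclasses.dataclass
class SyntheticSpec:
    """Parameters of one synthetic universe.

    Defaults describe a desk-scale stand-in for a hippocampal proteomics
    contrast against a pathway database: 500 quantified features, 40
    pathways of 10–30 members with moderate sharing, roughly a third of
    features significant, and |log2fc| around 1.5 for significant ones.
    """

    seed: int = 0
    n_genes: int = 500
    n_pathways: int = 40
    pathway_size_range: tuple[int, int] = (10, 30)
    overlap_rate: float = 0.2
    frac_significant: float = 0.35
    effect_size_scale: float = 1.5
    alpha: float = 0.05
    anchor_name: str = "autophagy"
    planted_near_pathway: str | None = None
    planted_far_pathway: str | None = None
    planted_zone: tuple[int, int, int] | None = None  # (1-based start rank, length, ±1)
    planted_regulator_gene: str | None = None
    regulator_membership: float = 0.7  # fraction of pathways holding the regulator
    near_anchor_overlap: float = 0.5  # fraction of near pathway copied from anchor

    def __post_init__(self) -> None:
        lo, hi = self.pathway_size_range
        if self.n_genes < 1 or self.n_pathways < 2:
            raise ValueError("need ≥1 gene and ≥2 pathways")
        if not 1 <= lo <= hi:
            raise ValueError(f"bad pathway_size_range {self.pathway_size_range}")
        if hi > self.n_genes:
            raise ValueError("pathway size range exceeds gene count")
        for name, val in (
            ("overlap_rate", self.overlap_rate),
            ("frac_significant", self.frac_significant),
            ("regulator_membership", self.regulator_membership),
            ("near_anchor_overlap", self.near_anchor_overlap),
        ):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {val}")
        if self.effect_size_scale <= 0:
            raise ValueError("effect_size_scale must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0,1)")
        if self.planted_zone is not None:
            start, length, direction = self.planted_zone
            if direction not in (-1, 1):
                raise ValueError("planted zone direction must be ±1")
            if start < 1 or length < 1 or start + length - 1 > self.n_genes:
                raise ValueError("planted zone exceeds gene list")
            n_sig = round(self.frac_significant * self.n_genes)
            if start + length - 1 > n_sig:
                raise ValueError(
                    "planted zone does not fit inside the significant gene list"
                )


@dataclasses.dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    anchor: str
    near_pathway: str | None = None
    far_pathway: str | None = None
    regulator_gene: str | None = None
    zone_order: list[str] | None = None  # ordering in which the block is planted
    zone_start: int | None = None  # 1-based rank in zone_order
    zone_length: int | None = None
    zone_direction: int | None = None
    significant: list[str] = dataclasses.field(default_factory=list)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path


def generate_universe(
    spec: SyntheticSpec,
) -> tuple[PathwayCollection, DiffExpressionTable, GroundTruth]:
    """Draw one seeded universe: pathways, expression table, ground truth.

    Construction order is fixed for reproducibility: gene pool, far-pathway
    private pool, pathway memberships (overlap copied from earlier pathways),
    regulator insertion, significance assignment (planted pathways forced to
    retain genes), p-values and fold changes, then the zone ordering.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i + 1:04d}" for i in range(spec.n_genes)]
    lo, hi = spec.pathway_size_range

    names: list[str] = [spec.anchor_name]
    for i in range(2, spec.n_pathways + 1):
        names.append(f"pathway_{i:02d}")
    if spec.planted_near_pathway:
        names[1] = spec.planted_near_pathway
    if spec.planted_far_pathway:
        names[-1] = spec.planted_far_pathway

    # Private pool for the far pathway: its genes occur in no other pathway,
    # so it is provably ≥4 membership hops (actually disconnected) from the
    # anchor.
    far_size = int(rng.integers(lo, hi + 1))
    far_pool: list[str] = []
    if spec.planted_far_pathway:
        eligible = [g for g in genes if g != spec.planted_regulator_gene]
        far_idx = rng.choice(len(eligible), size=far_size, replace=False)
        far_pool = [eligible[i] for i in sorted(far_idx)]
    shared_pool = [g for g in genes if g not in set(far_pool)]

    pathway_sets: dict[str, list[str]] = {}
    for name in names:
        if name == spec.planted_far_pathway:
            pathway_sets[name] = list(far_pool)
            continue
        size = int(rng.integers(lo, hi + 1))
        members: list[str] = []
        if name == spec.planted_near_pathway:
            anchor_members = pathway_sets[spec.anchor_name]
            n_copy = min(round(spec.near_anchor_overlap * size), len(anchor_members))
            idx = rng.choice(len(anchor_members), size=n_copy, replace=False)
            members.extend(anchor_members[i] for i in sorted(idx))
        elif pathway_sets and spec.overlap_rate > 0:
            donors = [n for n in pathway_sets if n != spec.planted_far_pathway]
            if donors:
                donor = pathway_sets[donors[int(rng.integers(len(donors)))]]
                n_copy = min(round(spec.overlap_rate * size), len(donor))
                idx = rng.choice(len(donor), size=n_copy, replace=False)
                members.extend(donor[i] for i in sorted(idx))
        fresh_pool = [g for g in shared_pool if g not in set(members)]
        n_fresh = size - len(members)
        idx = rng.choice(len(fresh_pool), size=n_fresh, replace=False)
        members.extend(fresh_pool[i] for i in sorted(idx))
        pathway_sets[name] = members

    # Plant the regulator in a fixed fraction of pathways (never the far one),
    # swapping out an existing member so sizes stay in range.
    if spec.planted_regulator_gene:
        reg = spec.planted_regulator_gene
        if reg not in genes:
            raise ValueError(f"regulator {reg!r} not in gene pool")
        if reg in set(far_pool):
            raise ValueError("regulator cannot live in the far pathway's pool")
        hosts = [n for n in names if n != spec.planted_far_pathway]
        n_hosts = max(1, round(spec.regulator_membership * len(hosts)))
        chosen = [hosts[i] for i in sorted(rng.choice(len(hosts), size=n_hosts, replace=False))]
        for name in chosen:
            members = pathway_sets[name]
            if reg not in members:
                members[int(rng.integers(len(members)))] = reg

    # Significance: planted structure must survive the DEG filter, so a few
    # members of the anchor and of each planted pathway (and the regulator
    # and zone genes) are forced significant.
    n_sig = round(spec.frac_significant * spec.n_genes)
    forced: list[str] = []
    if n_sig > 0:
        for name in filter(None, (spec.anchor_name, spec.planted_near_pathway,
                                  spec.planted_far_pathway)):
            members = pathway_sets[name]
            k = min(3, len(members))
            idx = rng.choice(len(members), size=k, replace=False)
            forced.extend(members[i] for i in sorted(idx))
        if spec.planted_regulator_gene:
            forced.append(spec.planted_regulator_gene)
        forced = list(dict.fromkeys(forced))
    if len(forced) > n_sig:
        raise ValueError(
            f"frac_significant too small to retain planted structure "
            f"({len(forced)} forced > {n_sig} allowed)"
        )
    rest = [g for g in genes if g not in set(forced)]
    idx = rng.choice(len(rest), size=n_sig - len(forced), replace=False)
    significant = sorted(forced + [rest[i] for i in sorted(idx)])
    sig_set = set(significant)

    p_adj = np.empty(spec.n_genes)
    log2fc = np.empty(spec.n_genes)
    for i, g in enumerate(genes):
        if g in sig_set:
            p_adj[i] = rng.uniform(1e-6, spec.alpha)
            magnitude = abs(rng.normal(0.0, spec.effect_size_scale)) + 0.1
            log2fc[i] = magnitude * (1 if rng.random() < 0.5 else -1)
        else:
            p_adj[i] = rng.uniform(spec.alpha, 1.0)
            log2fc[i] = rng.normal(0.0, 0.25)

    truth = GroundTruth(
        anchor=spec.anchor_name,
        near_pathway=spec.planted_near_pathway,
        far_pathway=spec.planted_far_pathway,
        regulator_gene=spec.planted_regulator_gene,
        significant=significant,
    )

    if spec.planted_zone is not None:
        start, length, direction = spec.planted_zone
        order = list(significant)
        rng.shuffle(order)
        zone_genes = order[start - 1 : start - 1 + length]
        lfc_index = {g: i for i, g in enumerate(genes)}
        for g in zone_genes:
            i = lfc_index[g]
            log2fc[i] = abs(log2fc[i]) * direction
        truth.zone_order = order
        truth.zone_start = start
        truth.zone_length = length
        truth.zone_direction = direction

    table = DiffExpressionTable.from_records(
        list(zip(genes, log2fc.tolist(), p_adj.tolist()))
    )
    collection = PathwayCollection(
        pathways=pathway_sets, anchor_name=spec.anchor_name
    )
    return collection, table, truth


def generate_motif_fixture(seed: int = 0, seq_id: str = "synthetic_gpr158_cterm") -> tuple[str, str]:
    """A 400-residue synthetic receptor C-terminus with five VxPx motifs.

    Background residues are drawn from an alphabet without V and P, so the
    only V..P. tetramers are the planted ones: VCPW at 212–215, 277–280 and
    377–380, VLPG at 300–303, VAPK at 331–334.  Returns (id, sequence).
    """
    rng = np.random.default_rng(seed)
    chars = [
        _BACKGROUND_ALPHABET[i]
        for i in rng.integers(len(_BACKGROUND_ALPHABET), size=FIXTURE_LENGTH)
    ]
    for start, tetramer in FIXTURE_MOTIFS:
        chars[start - 1 : start + 3] = list(tetramer)
    return seq_id, "".join(chars)
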