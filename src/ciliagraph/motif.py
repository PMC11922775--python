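"""VxPx ciliary-targeting motif scanning and motif-ablating mutagenesis.

The VxPx signal is a four-residue motif — valine, any residue, proline, any
residue — that routes membrane proteins to the primary cilium.  The scanner
reports every occurrence (overlaps included, 1-based inclusive coordinates);
the mutator ablates chosen occurrences, by default V→A and P→A, with
per-instance overrides for alternative replacements.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping

logger = logging.getLogger("ciliagraph")


@dataclasses.dataclass(frozen=True)
class MotifHit:
    """One VxPx occurrence; ``start``/``end`` are 1-based inclusive."""

    seq_id: str
    start: int
    tetramer: str

    @property
    def end(self) -> int:
        return self.start + 3


@dataclasses.dataclass
class MutationPlan:
    """Residue substitutions applied per motif occurrence.

    The default rule replaces the valine (motif position 1) and the proline
    (motif position 3) with alanine.  ``overrides`` maps a hit's start
    position to {motif position (1-based, 1..4) -> replacement residue} and
    takes precedence over the default rule for that occurrence.
    """

    default_rule: dict[int, str] = dataclasses.field(
        default_factory=lambda: {1: "A", 3: "A"}
    )
    overrides: dict[int, dict[int, str]] = dataclasses.field(default_factory=dict)

    def substitutions_for(self, hit: MotifHit) -> dict[int, str]:
        """Absolute-position -> residue map for one hit."""
        rule = dict(self.default_rule)
        rule.update(self.overrides.get(hit.start, {}))
        for offset, residue in rule.items():
            if not 1 <= offset <= 4:
                raise ValueError(f"motif position {offset} outside 1..4")
            if len(residue) != 1 or not residue.isalpha():
                raise ValueError(f"invalid replacement residue {residue!r}")
        return {hit.start + offset - 1: residue.upper() for offset, residue in rule.items()}


def scan_vxpx(sequence: str, seq_id: str = "seq") -> list[MotifHit]:
    """All positions i (1-based) with V at i and P at i+2, overlaps allowed.

    The 'x' positions admit any residue, valine and proline included.
    Sequences shorter than 4 yield no hits (with a warning); non-alphabetic
    characters are an error.
    """
    seq = sequence.upper()
    if seq and not seq.isalpha():
        bad = next(c for c in seq if not c.isalpha())
        raise ValueError(f"non-alphabetic character {bad!r} in sequence {seq_id!r}")
    if len(seq) < 4:
        logger.warning("sequence %r shorter than 4 residues; no motifs", seq_id)
        return []
    hits = []
    for i in range(len(seq) - 3):
        if seq[i] == "V" and seq[i + 2] == "P":
            hits.append(MotifHit(seq_id=seq_id, start=i + 1, tetramer=seq[i : i + 4]))
    return hits


def design_mutant(
    sequence: str,
    hits: Iterable[MotifHit],
    plan: MutationPlan | None = None,
) -> str:
    """Apply the mutation plan to the given hits; length is preserved.

    Overlapping hits may not demand different residues at the same position.
    After mutation no hit position may still match V..P. (the plan must
    actually ablate the motif).
    """
    seq = sequence.upper()
    plan = plan or MutationPlan()
    hits = list(hits)
    combined: dict[int, str] = {}
    for hit in hits:
        if not 1 <= hit.start <= len(seq) - 3:
            raise ValueError(f"hit at {hit.start} outside sequence of length {len(seq)}")
        for pos, residue in plan.substitutions_for(hit).items():
            if pos in combined and combined[pos] != residue:
                raise ValueError(
                    f"conflicting substitutions at position {pos}: "
                    f"{combined[pos]!r} vs {residue!r}"
                )
            combined[pos] = residue
    chars = list(seq)
    for pos, residue in combined.items():
        chars[pos - 1] = residue
    mutated = "".join(chars)
    for hit in hits:
        window = mutated[hit.start - 1 : hit.start + 3]
        if window[0] == "V" and window[2] == "P":
            raise ValueError(
                f"plan fails to ablate motif at {hit.start}: {window!r}"
            )
    return mutated
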