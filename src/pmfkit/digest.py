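"""In-silico proteolysis: cleavage-site enumeration and missed-cleavage digest.

Trypsin cleaves C-terminal to Lys/Arg but not before Pro (the standard Keil
specificity); both the residue sets and the missed-cleavage budget are
configurable.  The digest of a protein with ``c`` internal cleavage sites
yields ``c + 1`` fragments with zero missed cleavages, and every peptide with
``k`` missed cleavages is the concatenation of ``k + 1`` consecutive
fragments, so there are exactly ``c + 1 - k`` of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .chem import (
    Modification,
    ModificationState,
    ResidueMassTable,
    enumerate_mod_states,
    mh_plus,
    peptide_neutral_mass,
)


@dataclass(frozen=True)
class CleavageRule:
    """Protease specificity: cleave after ``cleave_after`` unless the next
    residue is in ``blocked_by_next``; allow up to ``max_missed`` missed
    cleavages."""

    cleave_after: frozenset[str] = frozenset("KR")
    blocked_by_next: frozenset[str] = frozenset("P")
    max_missed: int = 1

    def __post_init__(self) -> None:
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")
        if not self.cleave_after:
            raise ValueError("cleave_after must be non-empty")
        object.__setattr__(self, "cleave_after", frozenset(self.cleave_after))
        object.__setattr__(self, "blocked_by_next", frozenset(self.blocked_by_next))


@dataclass(frozen=True)
class TheoreticalPeptide:
    """One digest product: a parent span, its missed-cleavage count, one
    modification state, and the resulting neutral and MH+ masses.

    ``start``/``end`` are 1-based inclusive residue coordinates in the parent.
    """

    sequence: str
    start: int
    end: int
    missed_cleavages: int
    state: ModificationState
    neutral_mass: float
    mh: float

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def identity(self) -> tuple:
        """Span + modification state: the unit compared across gel spots."""
        return (self.start, self.end, self.state.key())


def cleavage_sites(sequence: str, rule: CleavageRule) -> list[int]:
    """1-based positions after which the protease cuts, ascending.

    The terminal residue is never a site (cutting there produces nothing).
    """
    if not sequence:
        raise ValueError("empty sequence")
    sites = []
    for i in range(1, len(sequence)):  # position i is 1-based index of residue
        if sequence[i - 1] in rule.cleave_after and sequence[i] not in rule.blocked_by_next:
            sites.append(i)
    return sites


def fragments(sequence: str, rule: CleavageRule) -> list[tuple[int, int]]:
    """The zero-missed-cleavage fragment spans, in order, covering the parent."""
    sites = cleavage_sites(sequence, rule)
    bounds = [0] + sites + [len(sequence)]
    return [(bounds[i] + 1, bounds[i + 1]) for i in range(len(bounds) - 1)]


def digest(
    sequence: str,
    rule: CleavageRule | None = None,
    mods: Iterable[Modification] = (),
    table: ResidueMassTable | None = None,
    min_length: int = 1,
    min_mass: float | None = None,
) -> list[TheoreticalPeptide]:
    """Every peptide of 1..(max_missed+1) consecutive fragments, expanded over
    all modification states, ordered by start position then missed cleavages.

    ``min_length``/``min_mass`` filters default to off (length >= 1, no mass
    floor).
    """
    rule = rule or CleavageRule()
    table = table or ResidueMassTable.default()
    mods = list(mods)
    frags = fragments(sequence, rule)
    peptides: list[TheoreticalPeptide] = []
    for i in range(len(frags)):
        for k in range(min(rule.max_missed, len(frags) - 1 - i) + 1):
            start = frags[i][0]
            end = frags[i + k][1]
            pep_seq = sequence[start - 1:end]
            if len(pep_seq) < min_length:
                continue
            for state in enumerate_mod_states(pep_seq, mods):
                neutral = peptide_neutral_mass(pep_seq, state, table, mods)
                if min_mass is not None and neutral < min_mass:
                    continue
                peptides.append(
                    TheoreticalPeptide(
                        sequence=pep_seq,
                        start=start,
                        end=end,
                        missed_cleavages=k,
                        state=state,
                        neutral_mass=neutral,
                        mh=mh_plus(neutral, table),
                    )
                )
    peptides.sort(key=lambda p: (p.start, p.missed_cleavages,
                                 p.state.total_variable, p.mh))
    return peptides
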