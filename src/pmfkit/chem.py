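"""Residue chemistry: monoisotopic masses, modifications, peptide mass arithmetic.

All masses are monoisotopic (reflector-mode MALDI resolves monoisotopic
peaks); average masses are deliberately unsupported.  A peptide's neutral
mass is the sum of its residue masses plus one water (the termini), and the
singly protonated ion MH+ adds one proton.  Variable modifications are
enumerated by *count*, not position: peptide-mass-fingerprinting matches on
mass alone, so positional isomers are indistinguishable and enumerating them
would only duplicate masses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

#: Mass of H2O (monoisotopic, Da) — added once per peptide for the termini.
WATER_MONO = 18.010565
#: Mass of a proton (Da) — charge carrier for MH+.
PROTON_MONO = 1.007276

#: Carbamidomethylation of Cys by iodoacetamide, the usual fixed modification
#: for gel-separated proteins reduced and alkylated before digestion.
CARBAMIDOMETHYL_DELTA = 57.02146
#: Oxidation of Met, the usual variable modification.
OXIDATION_DELTA = 15.99491


class UnknownResidueError(ValueError):
    """A sequence contains a character with no mass in the table."""

    def __init__(self, residue: str, position: int):
        self.residue = residue
        self.position = position  # 1-based
        super().__init__(
            f"unknown residue {residue!r} at position {position}; "
            "add it to extra_residues or correct the sequence"
        )


@dataclass(frozen=True)
class ResidueMassTable:
    """Monoisotopic residue masses plus the physical constants behind MH+.

    ``extra_residues`` lets callers register non-standard residues (e.g. the
    pentafluoro-phenylalanine of synthetic calibrant peptides) with a
    user-supplied mass.
    """

    residue_mass: Mapping[str, float]
    water_mass: float = WATER_MONO
    proton_mass: float = PROTON_MONO
    extra_residues: Mapping[str, float] = field(default_factory=dict)

    STANDARD_CODES = "ACDEFGHIKLMNPQRSTVWY"

    def __post_init__(self) -> None:
        missing = [c for c in self.STANDARD_CODES if c not in self.residue_mass]
        if missing:
            raise ValueError(f"mass table missing standard residues: {missing}")
        for code, m in itertools.chain(
            self.residue_mass.items(), self.extra_residues.items()
        ):
            if not m > 0:
                raise ValueError(f"non-positive mass for residue {code!r}: {m}")
        if abs(self.water_mass - WATER_MONO) > 1e-3:
            raise ValueError(f"implausible water mass {self.water_mass}")
        if abs(self.proton_mass - PROTON_MONO) > 1e-4:
            raise ValueError(f"implausible proton mass {self.proton_mass}")

    def mass_of(self, residue: str, position: int = 0) -> float:
        m = self.residue_mass.get(residue)
        if m is None:
            m = self.extra_residues.get(residue)
        if m is None:
            raise UnknownResidueError(residue, position)
        return m

    def knows(self, residue: str) -> bool:
        return residue in self.residue_mass or residue in self.extra_residues

    @classmethod
    def default(cls, extra_residues: Mapping[str, float] | None = None
                ) -> "ResidueMassTable":
        """Load the packaged plain-text mass table (auditable, overridable)."""
        text = (
            resources.files("pmfkit.data").joinpath("residue_masses.tsv")
            .read_text()
        )
        table: dict[str, float] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            code, mass = line.split()
            table[code] = float(mass)
        return cls(residue_mass=table, extra_residues=dict(extra_residues or {}))


@dataclass(frozen=True)
class Modification:
    """A mass shift applied to a set of target residues.

    ``mode`` is ``"fixed"`` (always applied to every target residue, as with
    iodoacetamide alkylation of Cys) or ``"variable"`` (each target residue may
    or may not carry it, as with Met oxidation).
    """

    name: str
    target_residues: frozenset[str]
    delta_mass: float
    mode: str  # "fixed" | "variable"

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "variable"):
            raise ValueError(f"mode must be 'fixed' or 'variable', got {self.mode!r}")
        if not (self.delta_mass == self.delta_mass and abs(self.delta_mass) < 1e6):
            raise ValueError(f"delta_mass not finite: {self.delta_mass}")
        object.__setattr__(self, "target_residues", frozenset(self.target_residues))

    def n_targets(self, sequence: str) -> int:
        return sum(1 for c in sequence if c in self.target_residues)


def carbamidomethyl_cys() -> Modification:
    """Fixed Cys carbamidomethylation (+57.02146 Da, iodoacetamide)."""
    return Modification("carbamidomethyl", frozenset("C"), CARBAMIDOMETHYL_DELTA,
                        "fixed")


def oxidation_met() -> Modification:
    """Variable Met oxidation (+15.99491 Da)."""
    return Modification("oxidation", frozenset("M"), OXIDATION_DELTA, "variable")


def default_modifications() -> list[Modification]:
    """The default search configuration: fixed Cys CAM + variable Met ox."""
    return [carbamidomethyl_cys(), oxidation_met()]


def validate_modifications(mods: Iterable[Modification]) -> None:
    """Reject configurations where a fixed and a variable mod share a target."""
    fixed_targets: set[str] = set()
    variable_targets: set[str] = set()
    for mod in mods:
        (fixed_targets if mod.mode == "fixed" else variable_targets).update(
            mod.target_residues)
    clash = fixed_targets & variable_targets
    if clash:
        raise ValueError(
            f"fixed and variable modifications both target residues {sorted(clash)}"
        )


@dataclass(frozen=True)
class ModificationState:
    """How many of each variable modification a peptide carries.

    ``fixed_applied`` records whether the configuration's fixed modifications
    are applied (they always are in a normal search); ``variable_counts`` maps
    modification name -> count, with every count bounded by the number of
    target residues in the peptide.
    """

    fixed_applied: bool = True
    variable_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, n in self.variable_counts.items():
            if n < 0:
                raise ValueError(f"negative count for modification {name!r}")
        # hashable, order-insensitive representation
        object.__setattr__(
            self, "variable_counts",
            dict(sorted(self.variable_counts.items()))
        )

    @property
    def total_variable(self) -> int:
        return sum(self.variable_counts.values())

    def key(self) -> tuple:
        return (self.fixed_applied, tuple(self.variable_counts.items()))

    def label(self) -> str:
        """Human-readable state, e.g. ``'2xoxidation'`` or ``'unmodified'``."""
        parts = [f"{n}x{name}" for name, n in self.variable_counts.items() if n]
        return "+".join(parts) if parts else "unmodified"


def peptide_neutral_mass(
    sequence: str,
    state: ModificationState,
    table: ResidueMassTable,
    mods: Iterable[Modification] = (),
) -> float:
    """Neutral monoisotopic mass: residues + water + applied modification deltas.

    Raises :class:`UnknownResidueError` naming the offending character and its
    1-based position, and ``ValueError`` if ``state`` claims more variable
    modifications than the peptide has target residues.
    """
    if not sequence:
        raise ValueError("empty peptide has no defined mass")
    mass = table.water_mass
    for i, residue in enumerate(sequence, start=1):
        mass += table.mass_of(residue, i)
    by_name = {m.name: m for m in mods}
    for mod in by_name.values():
        if mod.mode == "fixed" and state.fixed_applied:
            mass += mod.delta_mass * mod.n_targets(sequence)
    for name, count in state.variable_counts.items():
        if count == 0:
            continue
        mod = by_name.get(name)
        if mod is None:
            raise ValueError(f"state references unknown modification {name!r}")
        if count > mod.n_targets(sequence):
            raise ValueError(
                f"{count}x{name} exceeds {mod.n_targets(sequence)} target "
                f"residues in {sequence!r}"
            )
        mass += mod.delta_mass * count
    return mass


def mh_plus(neutral_mass: float, table: ResidueMassTable) -> float:
    """Singly protonated ion mass MH+ = M + proton (charge state +1)."""
    if not neutral_mass > 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    if neutral_mass <= table.water_mass + 1e-9:
        raise ValueError("neutral mass is water only: empty peptide")
    return neutral_mass + table.proton_mass


def enumerate_mod_states(
    sequence: str, mods: Iterable[Modification]
) -> list[ModificationState]:
    """All distinct-by-mass modification states of a peptide.

    Fixed modifications are always applied to every target.  Each variable
    modification contributes counts 0..n_targets, and independent variable
    modifications combine as a Cartesian product.  States are ordered by total
    variable count ascending (then by name-wise counts) so the unmodified
    state comes first.
    """
    mods = list(mods)
    validate_modifications(mods)
    variable = [m for m in mods if m.mode == "variable"]
    ranges = [range(m.n_targets(sequence) + 1) for m in variable]
    states = [
        ModificationState(
            fixed_applied=True,
            variable_counts={m.name: c for m, c in zip(variable, combo) if c},
        )
        for combo in itertools.product(*ranges)
    ]
    states.sort(key=lambda s: (s.total_variable, tuple(s.variable_counts.items())))
    return states
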