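"""Seeded synthetic fixtures: proteins, MALDI peak lists, and spot tables.

The peak-list simulator emulates a reflector spectrum of an in-gel tryptic
digest: the zero-missed-cleavage peptides of a (possibly truncated) protein
are each detected with probability ``1 - dropout``, singly-missed-cleavage
peptides appear at a lower rate, every mass is distorted through the inverse
of an affine calibration model plus Gaussian ppm-scale noise, the internal
standards appear at their distorted positions, and uniform contaminant peaks
round out the spectrum.  Intensities are log-normal.  Mass error is applied
in the instrument frame — ``observed = (true - b) / a`` before noise — so
that fitting the calibration on the calibrant peaks is a well-posed recovery
of ``(a, b)``.

Everything is driven by one :class:`numpy.random.Generator`; identical
config + seed gives bit-identical output.  The noise-free limit (zero noise,
identity calibration, no dropout, no contaminants) reproduces the
theoretical digest masses exactly.

What this does *not* emulate: isotope envelopes, peak shapes and centroiding
error, chemical-noise baselines, or intensity structure correlated with
peptide physicochemistry.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import InternalStandard, PeakList, default_standards
from .chem import Modification, ResidueMassTable, default_modifications
from .digest import CleavageRule, TheoreticalPeptide, digest
from .spots import SpotTable

#: Approximate vertebrate amino-acid frequencies (SwissProt-like), normalised.
DEFAULT_RESIDUE_FREQUENCIES: dict[str, float] = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0674, "G": 0.0708, "H": 0.0227, "I": 0.0593,
    "L": 0.0965, "K": 0.0582, "M": 0.0241, "F": 0.0386, "P": 0.0472,
    "S": 0.0660, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0687,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic measurement process.

    Defaults describe a routine reflector acquisition: a mid-size protein,
    a slightly miscalibrated mass axis (a few hundred ppm of gain error and
    a small constant offset), 5 ppm mass noise, 10% detection dropout, and a
    handful of contaminant peaks across the working m/z range.
    """

    seed: int = 0
    protein_length: int = 300
    residue_frequencies: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESIDUE_FREQUENCIES))
    calibration_a: float = 1.0002
    calibration_b: float = 0.05
    mass_noise_ppm: float = 5.0
    dropout: float = 0.10
    missed_cleavage_rate: float = 0.2
    n_contaminants: int = 10
    contaminant_range: tuple[float, float] = (800.0, 3500.0)
    log_intensity_mean: float = 6.9  # ln(arbitrary units); e^6.9 ~ 1000
    log_intensity_sigma: float = 1.0
    #: (terminus, cut) — "N" keeps residues cut..L, "C" keeps 1..cut.
    truncation: tuple[str, int] | None = None
    # spot-table conditions
    n_spots: int = 500
    n_per_group: int = 4
    spot_cv: float = 0.25
    planted_fold: float = 2.0
    n_planted: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout <= 1 or not 0 <= self.missed_cleavage_rate <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.mass_noise_ppm < 0:
            raise ValueError("mass noise must be >= 0")
        if self.truncation is not None:
            terminus, cut = self.truncation
            if terminus not in ("N", "C") or not 1 <= cut <= self.protein_length:
                raise ValueError(f"invalid truncation {self.truncation!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class PeakOrigin:
    """Ground-truth identity of one simulated peak."""

    kind: str  # "peptide" | "calibrant" | "contaminant"
    label: str
    peptide: TheoreticalPeptide | None = None


@dataclass(frozen=True)
class SimulatedSpectrum:
    """A peak list plus everything the simulator knows about it."""

    peaks: PeakList
    origins: tuple[PeakOrigin, ...]  # aligned with peaks
    detected_peptides: tuple[TheoreticalPeptide, ...]  # full-protein coordinates
    calibration_a: float
    calibration_b: float
    removed_span: tuple[int, int] | None = None  # residues absent by truncation

    def origin_of(self, peak_index: int) -> PeakOrigin:
        return self.origins[peak_index]


def gen_protein(config: SimulationConfig,
                rng: np.random.Generator | None = None) -> str:
    """Random protein sequence at the configured residue frequencies."""
    if config.protein_length < 1:
        raise ValueError("protein_length must be >= 1")
    rng = rng or config.rng()
    codes = list(config.residue_frequencies)
    freqs = np.array([config.residue_frequencies[c] for c in codes], dtype=float)
    if (freqs < 0).any() or freqs.sum() <= 0:
        raise ValueError("residue frequencies must be non-negative, not all zero")
    freqs = freqs / freqs.sum()
    return "".join(rng.choice(codes, size=config.protein_length, p=freqs))


def simulate_peaklist(
    sequence: str,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    standards: Sequence[InternalStandard] | None = None,
    mods: Sequence[Modification] | None = None,
    rule: CleavageRule | None = None,
    table: ResidueMassTable | None = None,
) -> SimulatedSpectrum:
    """Simulate a reflector peak list for ``sequence`` (truncated per config).

    Peptide spans in the ground truth are in full-protein coordinates so
    they can be compared with reports built against the full sequence.
    """
    rng = rng or config.rng()
    standards = list(default_standards() if standards is None else standards)
    mods = list(default_modifications() if mods is None else mods)
    rule = rule or CleavageRule()
    table = table or ResidueMassTable.default()

    offset = 0
    removed: tuple[int, int] | None = None
    working = sequence
    if config.truncation is not None:
        terminus, cut = config.truncation
        if terminus == "N":
            working = sequence[cut - 1:]
            offset = cut - 1
            removed = (1, cut - 1) if cut > 1 else None
        else:
            working = sequence[:cut]
            removed = (cut + 1, len(sequence)) if cut < len(sequence) else None

    base_state_peptides = [
        p for p in digest(working, rule, mods, table)
        if p.state.total_variable == 0
    ]
    detected: list[TheoreticalPeptide] = []
    for pep in base_state_peptides:
        if pep.missed_cleavages == 0:
            keep = rng.random() >= config.dropout
        elif pep.missed_cleavages == 1:
            keep = rng.random() < config.missed_cleavage_rate
        else:
            keep = False
        if keep:
            detected.append(dataclasses.replace(
                pep, start=pep.start + offset, end=pep.end + offset))

    a, b = config.calibration_a, config.calibration_b
    sigma = config.mass_noise_ppm * 1e-6

    entries: list[tuple[float, float, PeakOrigin]] = []

    def observe(true_mh: float) -> float:
        mz = (true_mh - b) / a
        if sigma > 0:
            mz *= 1.0 + rng.normal(0.0, sigma)
        return mz

    def draw_intensity() -> float:
        return float(rng.lognormal(config.log_intensity_mean,
                                   config.log_intensity_sigma))

    for pep in detected:
        entries.append((
            observe(pep.mh), draw_intensity(),
            PeakOrigin("peptide", f"{pep.start}-{pep.end}", pep)))
    for std in standards:
        entries.append((
            observe(std.theoretical_mh), draw_intensity(),
            PeakOrigin("calibrant", std.name)))
    lo, hi = config.contaminant_range
    for i in range(config.n_contaminants):
        entries.append((
            float(rng.uniform(lo, hi)), draw_intensity(),
            PeakOrigin("contaminant", f"contaminant_{i}")))

    entries.sort(key=lambda e: e[0])
    peaks = PeakList(
        peaks=tuple((mz, inten) for mz, inten, _ in entries),
        source_id=f"simulated(seed={config.seed})",
    )
    return SimulatedSpectrum(
        peaks=peaks,
        origins=tuple(origin for _, _, origin in entries),
        detected_peptides=tuple(detected),
        calibration_a=a,
        calibration_b=b,
        removed_span=removed,
    )


def gen_spot_table(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    group_labels: tuple[str, str] = ("group1", "group2"),
) -> tuple[SpotTable, np.ndarray]:
    """Log-normal replicate spot quantities with planted differential spots.

    The first ``n_planted`` spots carry a true ``planted_fold`` increase in
    ``group2``; all others are null.  Returns the table and a boolean truth
    vector marking the planted spots.
    """
    if config.n_per_group < 2:
        raise ValueError("need >= 2 replicates per group")
    rng = rng or config.rng()
    n, m = config.n_spots, config.n_per_group
    # between-spot abundance spread, then within-spot replicate noise at the
    # requested coefficient of variation
    base = rng.lognormal(mean=np.log(500.0), sigma=1.0, size=n)
    sigma_rep = float(np.sqrt(np.log1p(config.spot_cv ** 2)))
    truth = np.zeros(n, dtype=bool)
    truth[: config.n_planted] = True
    fold = np.where(truth, config.planted_fold, 1.0)

    noise = rng.lognormal(mean=-0.5 * sigma_rep ** 2, sigma=sigma_rep,
                          size=(n, 2 * m))
    quantities = base[:, None] * noise
    quantities[:, m:] *= fold[:, None]

    columns = [f"{group_labels[0]}_{i + 1}" for i in range(m)] + \
              [f"{group_labels[1]}_{i + 1}" for i in range(m)]
    frame = pd.DataFrame(
        quantities,
        index=[f"spot_{i + 1}" for i in range(n)],
        columns=columns,
    )
    groups = {c: group_labels[0] for c in columns[:m]}
    groups.update({c: group_labels[1] for c in columns[m:]})
    return SpotTable(quantities=frame, groups=groups), truth
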