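"""Tolerance matching of observed peaks to a theoretical digest, and the
per-protein identification report.

The report partitions every observed peak into exactly one of three bins —
calibrant-assigned, best-matched, unmatched — and summarises sequence
coverage (union of matched residue spans) and signal fractions.  A peak may
lie within tolerance of several theoretical peptides; every such pair is
listed with its signed ppm error, but statistics use only the best match per
peak (smallest |ppm|, ties broken toward fewer missed cleavages, then fewer
variable modifications, then lower mass).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .calibration import (
    DEFAULT_CALIBRANT_WINDOW,
    CalibrationModel,
    InternalStandard,
    PeakList,
    apply_calibration,
    fit_calibration,
    fit_calibration_robust,
    match_calibrants,
)
from .digest import CleavageRule, TheoreticalPeptide, digest
from .chem import Modification, ResidueMassTable

#: The default peptide mass tolerance (Da) for reflector PMF searches.
DEFAULT_TOLERANCE_DA = 0.15


@dataclass(frozen=True)
class PeakMatch:
    """One (peak, peptide) pair within tolerance."""

    peak_index: int
    peptide: TheoreticalPeptide
    error_ppm: float
    error_da: float
    is_best_for_peak: bool = False


@dataclass(frozen=True)
class MatchReport:
    """The full identification report for one candidate protein."""

    accession: str
    protein_length: int
    matches: tuple[PeakMatch, ...]
    coverage_percent: float
    matched_signal_fraction: float
    calibrant_signal_fraction: float
    unmatched_peaks: tuple[tuple[float, float], ...]  # sorted by intensity desc
    calibrant_assignments: tuple[tuple[str, int], ...]  # (standard name, peak idx)
    parameters: dict
    calibration: CalibrationModel | None = None
    warnings: tuple[str, ...] = ()

    @property
    def best_matches(self) -> list[PeakMatch]:
        return [m for m in self.matches if m.is_best_for_peak]

    @property
    def best_peptides(self) -> list[TheoreticalPeptide]:
        return [m.peptide for m in self.best_matches]


def _tolerance_da(mh: float, tolerance: float, unit: str) -> float:
    if unit == "da":
        return tolerance
    if unit == "ppm":
        return tolerance * 1e-6 * mh
    raise ValueError(f"tolerance unit must be 'da' or 'ppm', got {unit!r}")


def match_peaks(
    peaks: PeakList,
    peptides: Sequence[TheoreticalPeptide],
    tolerance: float = DEFAULT_TOLERANCE_DA,
    unit: str = "da",
    skip_indices: set[int] | None = None,
) -> list[PeakMatch]:
    """All (peak, peptide) pairs with |observed - MH+| within tolerance.

    For each peak the pair with minimal |ppm error| carries
    ``is_best_for_peak``; exact ties fall through (fewer missed cleavages,
    fewer variable modifications, lower mass), and candidates still tied
    after the whole chain have identical mass — they are indistinguishable
    by mass fingerprinting and are all flagged.  ``skip_indices`` excludes
    peaks already assigned to calibrants.  Deterministic for fixed input.
    """
    if not tolerance > 0:
        raise ValueError("tolerance must be > 0")
    if not peptides:
        raise ValueError("peptide list is empty: nothing to match against")
    skip = skip_indices or set()
    mhs = np.array([p.mh for p in peptides])
    order = np.argsort(mhs, kind="stable")
    sorted_mhs = mhs[order]
    matches: list[PeakMatch] = []
    for j, (mz, _) in enumerate(peaks.peaks):
        if j in skip:
            continue
        # widest possible Da window for this peak (ppm tolerance grows with mass)
        tol_hi = _tolerance_da(mz + (1.0 if unit == "ppm" else tolerance), tolerance, unit)
        lo = np.searchsorted(sorted_mhs, mz - tol_hi - 1e-9, side="left")
        hi = np.searchsorted(sorted_mhs, mz + tol_hi + 1e-9, side="right")
        candidates: list[PeakMatch] = []
        for idx in order[lo:hi]:
            pep = peptides[idx]
            err_da = mz - pep.mh
            if abs(err_da) <= _tolerance_da(pep.mh, tolerance, unit):
                candidates.append(
                    PeakMatch(
                        peak_index=j,
                        peptide=pep,
                        error_ppm=1e6 * err_da / pep.mh,
                        error_da=err_da,
                    )
                )
        if not candidates:
            continue

        def rank(m: PeakMatch) -> tuple:
            return (abs(m.error_ppm), m.peptide.missed_cleavages,
                    m.peptide.state.total_variable, m.peptide.mh)

        # Candidates that tie through the whole chain have identical mass and
        # are indistinguishable by PMF; all of them carry the best flag.
        best_key = min(rank(m) for m in candidates)
        for m in candidates:
            matches.append(
                PeakMatch(m.peak_index, m.peptide, m.error_ppm, m.error_da,
                          is_best_for_peak=(rank(m) == best_key))
            )
    return matches


def coverage_percent(matches: Sequence[PeakMatch], protein_length: int) -> float:
    """100 x |union of best-matched residue spans| / protein length."""
    if not protein_length > 0:
        raise ValueError("protein_length must be > 0")
    covered: set[int] = set()
    for m in matches:
        if m.is_best_for_peak:
            if not (1 <= m.peptide.start <= m.peptide.end <= protein_length):
                raise ValueError(
                    f"match span {m.peptide.span} outside protein of length "
                    f"{protein_length}")
            covered.update(range(m.peptide.start, m.peptide.end + 1))
    return 100.0 * len(covered) / protein_length


def signal_fractions(
    peaks: PeakList,
    matches: Sequence[PeakMatch],
    calibrant_assignments: Sequence[tuple[InternalStandard, int]] | Sequence[tuple[str, int]],
) -> tuple[float, float, list[str]]:
    """(matched_signal_fraction, calibrant_signal_fraction, warnings).

    The calibrant fraction is over *all* ion signal; the matched fraction is
    over the non-calibrant signal, so the two denominators answer different
    questions (how much of the spectrum is standards vs how much of the
    sample signal the candidate protein explains).
    """
    notes: list[str] = []
    intensity = peaks.intensity
    total = float(intensity.sum()) if len(peaks) else 0.0
    if total <= 0:
        if len(peaks):
            notes.append("total ion intensity is zero; signal fractions set to 0")
        else:
            notes.append("empty peak list; signal fractions set to 0")
        return 0.0, 0.0, notes
    calibrant_idx = {j for _, j in calibrant_assignments}
    calibrant_signal = float(intensity[sorted(calibrant_idx)].sum()) if calibrant_idx else 0.0
    best_idx = {m.peak_index for m in matches if m.is_best_for_peak} - calibrant_idx
    matched_signal = float(intensity[sorted(best_idx)].sum()) if best_idx else 0.0
    non_calibrant = total - calibrant_signal
    matched_fraction = matched_signal / non_calibrant if non_calibrant > 0 else 0.0
    if non_calibrant <= 0:
        notes.append("all signal is calibrant; matched fraction set to 0")
    return matched_fraction, calibrant_signal / total, notes


def build_report(
    accession: str,
    sequence: str,
    peaks: PeakList,
    standards: Sequence[InternalStandard] = (),
    tolerance: float = DEFAULT_TOLERANCE_DA,
    unit: str = "da",
    rule: CleavageRule | None = None,
    mods: Sequence[Modification] = (),
    table: ResidueMassTable | None = None,
    calibrate: bool = True,
    calibrant_window: float = DEFAULT_CALIBRANT_WINDOW,
) -> MatchReport:
    """Digest, assign calibrants, optionally recalibrate, match, summarise.

    The returned report partitions the peaks exhaustively and disjointly into
    calibrant-assigned, best-matched, and unmatched.
    """
    rule = rule or CleavageRule()
    table = table or ResidueMassTable.default()
    peptides = digest(sequence, rule, mods, table)
    notes: list[str] = []

    assignments = match_calibrants(peaks, list(standards), calibrant_window)
    model: CalibrationModel | None = None
    working = peaks
    if calibrate and assignments:
        pairs = [(std.theoretical_mh, peaks.peaks[j][0]) for std, j in assignments]
        model, kept = fit_calibration_robust(pairs)
        if len(kept) < len(assignments):
            dropped = [assignments[i][0].name for i in range(len(assignments))
                       if i not in kept]
            notes.append(
                "calibrant pairing(s) rejected as outliers and released to "
                f"matching: {', '.join(dropped)}")
            assignments = [assignments[i] for i in kept]
        working = apply_calibration(peaks, model)
    elif calibrate and not assignments:
        notes.append("no calibrant peaks found; proceeding uncalibrated")

    calibrant_idx = {j for _, j in assignments}
    matches = match_peaks(working, peptides, tolerance, unit,
                          skip_indices=calibrant_idx)
    cov = coverage_percent(matches, len(sequence))
    matched_frac, calibrant_frac, frac_notes = signal_fractions(
        working, matches, assignments)
    notes.extend(frac_notes)

    best_idx = {m.peak_index for m in matches if m.is_best_for_peak}
    unmatched = [
        (mz, inten)
        for j, (mz, inten) in enumerate(working.peaks)
        if j not in calibrant_idx and j not in best_idx
    ]
    unmatched.sort(key=lambda p: -p[1])

    params = {
        "tolerance": tolerance,
        "tolerance_unit": unit,
        "max_missed": rule.max_missed,
        "cleave_after": "".join(sorted(rule.cleave_after)),
        "blocked_by_next": "".join(sorted(rule.blocked_by_next)),
        "fixed_mods": sorted(m.name for m in mods if m.mode == "fixed"),
        "variable_mods": sorted(m.name for m in mods if m.mode == "variable"),
        "charge_state": 1,
        "calibrated": model is not None,
    }
    return MatchReport(
        accession=accession,
        protein_length=len(sequence),
        matches=tuple(matches),
        coverage_percent=cov,
        matched_signal_fraction=matched_frac,
        calibrant_signal_fraction=calibrant_frac,
        unmatched_peaks=tuple(unmatched),
        calibrant_assignments=tuple((std.name, j) for std, j in assignments),
        parameters=params,
        calibration=model,
        warnings=tuple(notes),
    )
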