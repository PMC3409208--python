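"""Peak-to-digest matching, coverage, signal fractions, and the report."""

import numpy as np
import pytest

from pmfkit import (
    CleavageRule,
    InternalStandard,
    PeakList,
    build_report,
    coverage_percent,
    default_modifications,
    digest,
    match_peaks,
    signal_fractions,
)
from pmfkit.matching import PeakMatch


def brute_force_match(peaks, peptides, tolerance, unit):
    """Independent oracle: exhaustive scan over all peak x peptide pairs."""
    out = []
    for j, (mz, _) in enumerate(peaks.peaks):
        cands = []
        for pep in peptides:
            tol = tolerance if unit == "da" else tolerance * 1e-6 * pep.mh
            err = mz - pep.mh
            if abs(err) <= tol:
                cands.append((pep, 1e6 * err / pep.mh, err))
        if not cands:
            continue
        keys = [(abs(ppm), p.missed_cleavages, p.state.total_variable, p.mh)
                for p, ppm, _ in cands]
        best = min(keys)
        for (pep, ppm, err), key in zip(cands, keys):
            out.append((j, pep.start, pep.end, pep.state.key(),
                        round(ppm, 9), key == best))
    return sorted(out)


def as_tuples(matches):
    return sorted(
        (m.peak_index, m.peptide.start, m.peptide.end, m.peptide.state.key(),
         round(m.error_ppm, 9), m.is_best_for_peak)
        for m in matches)


@pytest.fixture(scope="module")
def small_digest(table):
    return digest("AAKGGRCC", CleavageRule(), table=table)


def test_peak_matches_expected_peptide(table, small_digest):
    peaks = PeakList(peaks=((289.187, 10.0),))
    matches = match_peaks(peaks, small_digest, 0.15, "da")
    best = [m for m in matches if m.is_best_for_peak]
    assert len(best) == 1
    assert best[0].peptide.sequence == "AAK"
    assert best[0].error_ppm == pytest.approx(-0.07, abs=0.05)


def test_far_peak_is_unmatched(small_digest):
    peaks = PeakList(peaks=((5000.0, 10.0),))
    assert match_peaks(peaks, small_digest, 0.15, "da") == []


def test_ambiguous_peak_lists_all_candidates(table, small_digest):
    # AAK (289.18702) and GGR (289.16187) both sit within 0.15 Da
    peaks = PeakList(peaks=((289.175, 10.0),))
    matches = match_peaks(peaks, small_digest, 0.15, "da")
    assert len(matches) == 2
    best = [m for m in matches if m.is_best_for_peak]
    assert len(best) == 1
    assert best[0].peptide.sequence == min(
        matches, key=lambda m: abs(m.error_ppm)).peptide.sequence


def test_invalid_inputs_rejected(small_digest):
    peaks = PeakList(peaks=((289.187, 10.0),))
    with pytest.raises(ValueError):
        match_peaks(peaks, small_digest, -1.0, "da")
    with pytest.raises(ValueError):
        match_peaks(peaks, [], 0.15, "da")
    with pytest.raises(ValueError):
        match_peaks(peaks, small_digest, 0.15, "dalton")


@pytest.mark.parametrize("unit,tolerance", [("da", 0.15), ("ppm", 50.0)])
def test_oracle_equivalence_random_instances(table, mods, unit, tolerance):
    """match_peaks agrees with the brute-force scan on random instances."""
    from pmfkit import SimulationConfig, gen_protein, simulate_peaklist

    for seed in range(15):
        cfg = SimulationConfig(seed=seed, protein_length=120, n_contaminants=6)
        rng = cfg.rng()
        seq = gen_protein(cfg, rng)
        spectrum = simulate_peaklist(seq, cfg, rng)
        peptides = digest(seq, CleavageRule(), mods, table)
        got = as_tuples(match_peaks(spectrum.peaks, peptides, tolerance, unit))
        assert got == brute_force_match(spectrum.peaks, peptides, tolerance, unit)


def test_tolerance_monotonicity(table, mods):
    from pmfkit import SimulationConfig, gen_protein, simulate_peaklist

    cfg = SimulationConfig(seed=7, protein_length=150)
    rng = cfg.rng()
    seq = gen_protein(cfg, rng)
    spectrum = simulate_peaklist(seq, cfg, rng)
    peptides = digest(seq, CleavageRule(), mods, table)
    previous = set()
    for tol in (0.02, 0.05, 0.15, 0.5):
        pairs = {(m.peak_index, m.peptide.start, m.peptide.end,
                  m.peptide.state.key())
                 for m in match_peaks(spectrum.peaks, peptides, tol, "da")}
        assert previous <= pairs
        previous = pairs


class TestCoverage:
    def _match(self, start, end, best=True):
        pep = digest("A" * end, CleavageRule(), table=None)[0]
        import dataclasses
        pep = dataclasses.replace(pep, start=start, end=end,
                                  sequence="A" * (end - start + 1))
        return PeakMatch(0, pep, 0.0, 0.0, is_best_for_peak=best)

    def test_no_matches_zero(self):
        assert coverage_percent([], 8) == 0.0

    def test_disjoint_spans(self):
        matches = [self._match(1, 3), self._match(4, 6)]
        assert coverage_percent(matches, 8) == pytest.approx(75.0)

    def test_overlap_counts_union_not_sum(self):
        matches = [self._match(1, 6), self._match(4, 8)]
        assert coverage_percent(matches, 8) == pytest.approx(100.0)

    def test_non_best_matches_ignored(self):
        matches = [self._match(1, 3), self._match(4, 6, best=False)]
        assert coverage_percent(matches, 8) == pytest.approx(37.5)


class TestSignalFractions:
    def test_three_way_split(self):
        # calibrant 200, matched 300, unmatched 500
        peaks = PeakList(peaks=((1000.0, 200.0), (1100.0, 300.0),
                                (1200.0, 500.0)))
        pep = digest("AAK", CleavageRule())[0]
        matches = [PeakMatch(1, pep, 0.0, 0.0, True)]
        matched, calibrant, notes = signal_fractions(
            peaks, matches, [("std", 0)])
        assert calibrant == pytest.approx(0.2)
        assert matched == pytest.approx(300 / 800)
        assert notes == []

    def test_everything_matched_no_calibrants(self):
        peaks = PeakList(peaks=((1000.0, 10.0), (1100.0, 30.0)))
        pep = digest("AAK", CleavageRule())[0]
        matches = [PeakMatch(0, pep, 0.0, 0.0, True),
                   PeakMatch(1, pep, 0.0, 0.0, True)]
        matched, calibrant, _ = signal_fractions(peaks, matches, [])
        assert (matched, calibrant) == (1.0, 0.0)

    def test_empty_peaklist_warns(self):
        matched, calibrant, notes = signal_fractions(PeakList(peaks=()), [], [])
        assert (matched, calibrant) == (0.0, 0.0)
        assert any("empty" in n for n in notes)


class TestBuildReport:
    def test_partition_is_exhaustive_and_disjoint(self, table, mods):
        from pmfkit import SimulationConfig, default_standards, gen_protein, \
            simulate_peaklist

        for seed in range(5):
            cfg = SimulationConfig(seed=seed, protein_length=200)
            rng = cfg.rng()
            seq = gen_protein(cfg, rng)
            spectrum = simulate_peaklist(seq, cfg, rng)
            report = build_report("P", seq, spectrum.peaks,
                                  default_standards(), mods=mods, table=table)
            calibrant = {j for _, j in report.calibrant_assignments}
            best = {m.peak_index for m in report.best_matches}
            n_unmatched = len(report.unmatched_peaks)
            assert calibrant.isdisjoint(best)
            assert len(calibrant) + len(best) + n_unmatched == len(
                spectrum.peaks)

    def test_calibrants_only_spectrum(self, table, mods):
        standards = [InternalStandard("ACTH", 2465.199, "matrix_standard"),
                     InternalStandard("RfffR", 1042.276, "matrix_standard")]
        peaks = PeakList(peaks=((1042.276, 100.0), (2465.199, 60.0)))
        report = build_report("P", "AAKGGRCC", peaks, standards,
                              mods=mods, table=table)
        assert report.coverage_percent == 0.0
        assert report.calibrant_signal_fraction == pytest.approx(1.0)
        assert report.matched_signal_fraction == 0.0
        assert report.unmatched_peaks == ()

    def test_parameter_echo_defaults(self, table, mods):
        peaks = PeakList(peaks=((289.187, 10.0),))
        report = build_report("P", "AAKGGRCC", peaks, (), mods=mods,
                              table=table, calibrate=False)
        assert report.parameters["tolerance"] == 0.15
        assert report.parameters["tolerance_unit"] == "da"
        assert report.parameters["charge_state"] == 1
        assert report.parameters["max_missed"] == 1

    def test_unmatched_sorted_by_intensity(self, table, mods):
        peaks = PeakList(peaks=((600.0, 5.0), (700.0, 50.0), (800.0, 20.0)))
        report = build_report("P", "AAKGGRCC", peaks, (), mods=mods,
                              table=table, calibrate=False)
        intensities = [i for _, i in report.unmatched_peaks]
        assert intensities == sorted(intensities, reverse=True)
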