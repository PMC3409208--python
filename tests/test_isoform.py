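"""Truncation inference from differential matched-peptide evidence."""

import dataclasses

import numpy as np
import pytest

from pmfkit import (
    CleavageRule,
    ModificationState,
    TheoreticalPeptide,
    compare_matched_sets,
    infer_truncation,
)
from pmfkit.matching import MatchReport, PeakMatch


def peptide(start, end):
    return TheoreticalPeptide(
        sequence="A" * (end - start + 1), start=start, end=end,
        missed_cleavages=0, state=ModificationState(),
        neutral_mass=100.0, mh=101.0)


def report(accession, spans, protein_length=180, params=None):
    matches = tuple(
        PeakMatch(j, peptide(s, e), 0.0, 0.0, True)
        for j, (s, e) in enumerate(spans))
    return MatchReport(
        accession=accession, protein_length=protein_length, matches=matches,
        coverage_percent=0.0, matched_signal_fraction=0.0,
        calibrant_signal_fraction=0.0, unmatched_peaks=(),
        calibrant_assignments=(), parameters=params or {"tolerance": 0.15})


class TestCompareMatchedSets:
    def test_identical_reports(self):
        spans = [(1, 20), (25, 40), (48, 60)]
        missing, retained = compare_matched_sets(
            report("P", spans), report("P", spans))
        assert missing == []
        assert sorted(p.span for p in retained) == spans

    def test_query_missing_two_peptides(self):
        ref_spans = [(1, 20), (25, 40), (48, 60), (61, 180)]
        missing, retained = compare_matched_sets(
            report("P", ref_spans), report("P", ref_spans[2:]))
        assert [p.span for p in missing] == [(1, 20), (25, 40)]
        assert [p.span for p in retained] == [(48, 60), (61, 180)]

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="no evidence base"):
            compare_matched_sets(report("P", []), report("P", [(1, 20)]))

    def test_mismatched_accessions_rejected(self):
        with pytest.raises(ValueError, match="different proteins"):
            compare_matched_sets(report("P", [(1, 20)]), report("Q", [(1, 20)]))

    def test_mismatched_parameters_rejected(self):
        with pytest.raises(ValueError, match="tolerance"):
            compare_matched_sets(
                report("P", [(1, 20)], params={"tolerance": 0.15}),
                report("P", [(1, 20)], params={"tolerance": 0.3}))


class TestInferTruncation:
    def test_n_terminal_call_with_boundary(self):
        missing = [peptide(1, 15), peptide(10, 30)]
        retained = [peptide(48, 60), peptide(80, 120)]
        call = infer_truncation(missing, retained, 180)
        assert call.terminus == "N"
        assert call.boundary_interval == (31, 48)
        assert call.n_missing == 2

    def test_no_missing_is_none(self):
        call = infer_truncation([], [peptide(1, 20)], 180)
        assert call.terminus == "none"
        assert call.boundary_interval is None

    def test_interior_missing_is_internal(self):
        call = infer_truncation([peptide(60, 75)],
                                [peptide(1, 20), peptide(100, 120)], 180)
        assert call.terminus == "internal"

    def test_single_terminal_dropout_is_indeterminate(self):
        call = infer_truncation([peptide(1, 15)], [peptide(48, 60)], 180,
                                min_evidence=2)
        assert call.terminus == "indeterminate"

    def test_both_termini_missing_is_indeterminate(self):
        missing = [peptide(1, 15), peptide(16, 30),
                   peptide(150, 165), peptide(166, 180)]
        call = infer_truncation(missing, [peptide(60, 90)], 180)
        assert call.terminus == "indeterminate"

    def test_interior_dropout_does_not_break_terminal_call(self):
        missing = [peptide(1, 15), peptide(16, 30), peptide(80, 90)]
        retained = [peptide(48, 60), peptide(100, 180)]
        call = infer_truncation(missing, retained, 180)
        assert call.terminus == "N"
        assert "dropout" in call.note

    def test_symmetry_under_sequence_reversal(self):
        """Reversing all spans maps an N call to the mirrored C call."""
        length = 180

        def reverse(p):
            return peptide(length + 1 - p.end, length + 1 - p.start)

        missing = [peptide(1, 15), peptide(10, 30)]
        retained = [peptide(48, 60), peptide(80, 120)]
        fwd = infer_truncation(missing, retained, length)
        rev = infer_truncation([reverse(p) for p in missing],
                               [reverse(p) for p in retained], length)
        assert (fwd.terminus, rev.terminus) == ("N", "C")
        lo, hi = fwd.boundary_interval
        assert rev.boundary_interval == (length + 1 - hi, length + 1 - lo)


def simulate_truncation_call(seed, dropout):
    """One synthetic recovery replicate; returns (ok_terminus, ok_boundary)."""
    from pmfkit import (SimulationConfig, build_report, call_truncation,
                        cleavage_sites, default_modifications,
                        default_standards, gen_protein, simulate_peaklist)

    rng = np.random.default_rng(seed)
    base = SimulationConfig(seed=seed, protein_length=300, dropout=dropout,
                            mass_noise_ppm=2.0, n_contaminants=5)
    seq = gen_protein(base, rng)
    sites = cleavage_sites(seq, CleavageRule())
    interior = [s for s in sites if 0.25 < s / len(seq) < 0.75]
    if len(interior) < 1:
        return None
    terminus = "N" if rng.random() < 0.5 else "C"
    cut_site = int(interior[rng.integers(len(interior))])
    # N keeps cut..L where cut is the first retained residue
    truncation = ("N", cut_site + 1) if terminus == "N" else ("C", cut_site)
    truncated = dataclasses.replace(base, truncation=truncation)

    mods = default_modifications()
    standards = default_standards()
    ref_spec = simulate_peaklist(seq, base, rng)
    qry_spec = simulate_peaklist(seq, truncated, rng)
    kwargs = dict(standards=standards, tolerance=25.0, unit="ppm", mods=mods)
    ref = build_report("P", seq, ref_spec.peaks, **kwargs)
    qry = build_report("P", seq, qry_spec.peaks, **kwargs)
    call = call_truncation(ref, qry)
    if call.terminus != terminus:
        return False, False
    lo, hi = call.boundary_interval
    true_edge = cut_site + 1 if terminus == "N" else cut_site
    return True, lo <= true_edge <= hi


@pytest.mark.parametrize("dropout,min_accuracy", [(0.0, 0.95), (0.1, 0.90)])
def test_simulation_recovery(dropout, min_accuracy):
    """Terminus and boundary recovered on synthetic truncated isoforms."""
    results = [simulate_truncation_call(seed, dropout) for seed in range(40)]
    results = [r for r in results if r is not None]
    assert len(results) >= 35
    terminus_ok = np.mean([t for t, _ in results])
    assert terminus_ok >= min_accuracy
    if dropout == 0.0:
        assert np.mean([b for _, b in results]) >= 0.95
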