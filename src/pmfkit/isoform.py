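"""Truncation-isoform inference from differential peptide evidence.

A truncated protein form running at lower molecular weight on a 2D gel still
yields the tryptic peptides of the retained region, but the peptides of the
removed terminus disappear.  Comparing the best-matched peptide set of a
query spot against that of the full-length reference spot therefore
localises the truncation: missing peptides clustered entirely N-terminal of
all retained evidence indicate an N-terminal truncation (and symmetrically
for the C terminus), while missing peptides inside the retained region are
attributed to detection dropout.  Calls are evidence counts, not
probabilities: a configurable minimum number of terminal missing peptides
(default 2) gates N/C calls so that a single dropped peak cannot fake a
truncation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .digest import TheoreticalPeptide
from .matching import MatchReport

#: Minimum number of terminal missing peptides required for an N/C call.
DEFAULT_MIN_EVIDENCE = 2

#: Minimum peptide MH+ (Da) for absence/presence evidence.  Peaks far below
#: the usable reflector range (single residues, tiny fragments) shift by tens
#: of ppm under a few-mDa calibration-offset error, so their apparent absence
#: in one spot carries no information about the protein.
DEFAULT_MIN_EVIDENCE_MASS = 600.0

#: Digestion/matching parameters that must agree between compared reports.
_COMPARABLE_PARAMS = (
    "tolerance", "tolerance_unit", "max_missed", "cleave_after",
    "blocked_by_next", "fixed_mods", "variable_mods",
)


@dataclass(frozen=True)
class TruncationCall:
    """Result of the isoform comparison.

    ``terminus`` is one of ``N``, ``C``, ``internal``, ``none`` (query carries
    all reference peptides) or ``indeterminate`` (evidence below the gate or
    contradictory).  ``boundary_interval`` brackets the truncation site in
    1-based residue coordinates and is present only for N/C calls.
    """

    terminus: str
    boundary_interval: tuple[int, int] | None
    missing_peptides: tuple[TheoreticalPeptide, ...]
    retained_peptides: tuple[TheoreticalPeptide, ...]
    n_missing: int
    note: str = ""

    def __post_init__(self) -> None:
        if self.terminus not in ("N", "C", "internal", "none", "indeterminate"):
            raise ValueError(f"invalid terminus {self.terminus!r}")
        if (self.terminus == "none") != (len(self.missing_peptides) == 0):
            raise ValueError("terminus 'none' iff no missing peptides")
        if self.boundary_interval is not None and self.terminus not in ("N", "C"):
            raise ValueError("boundary_interval only valid for N/C calls")


def compare_matched_sets(
    reference: MatchReport, query: MatchReport
) -> tuple[list[TheoreticalPeptide], list[TheoreticalPeptide]]:
    """(missing, retained): reference best-matched peptides absent from /
    present in the query, compared by span + modification state.

    Both reports must describe the same protein under the same digestion and
    matching parameters, otherwise the comparison is meaningless.
    """
    if reference.accession != query.accession:
        raise ValueError(
            f"reports describe different proteins: {reference.accession!r} "
            f"vs {query.accession!r}")
    for key in _COMPARABLE_PARAMS:
        if reference.parameters.get(key) != query.parameters.get(key):
            raise ValueError(
                f"reports differ in parameter {key!r}: "
                f"{reference.parameters.get(key)!r} vs {query.parameters.get(key)!r}")
    ref_best = {p.identity(): p for p in reference.best_peptides}
    if not ref_best:
        raise ValueError(
            "reference report has no matched peptides: no evidence base")
    query_ids = {p.identity() for p in query.best_peptides}
    missing = [p for key, p in ref_best.items() if key not in query_ids]
    retained = [p for key, p in ref_best.items() if key in query_ids]
    missing.sort(key=lambda p: (p.start, p.end))
    retained.sort(key=lambda p: (p.start, p.end))
    return missing, retained


def _n_changepoint(missing: list[tuple[int, int, int]],
                   retained: list[tuple[int, int]],
                   protein_length: int
                   ) -> tuple[int, int, list[tuple[int, int, int]]]:
    """Best N-truncation changepoint.

    Scores each candidate first-retained-residue position ``p`` by the number
    of peptides it explains — missing peptides ending before ``p`` plus
    retained peptides starting at or after ``p`` — and returns
    ``(score, p, consistent_missing)`` for the best ``p`` (ties toward the
    smallest, which widens the reported interval toward the evidence gap).
    """
    candidates = {1, protein_length + 1}
    candidates |= {e + 1 for _, e, _ in missing}
    candidates |= {s for s, _ in retained}
    best_score, best_p = -1, 1
    for p in sorted(candidates):
        score = sum(1 for _, e, _ in missing if e < p) + \
            sum(1 for s, _ in retained if s >= p)
        if score > best_score:
            best_score, best_p = score, p
    consistent = [span for span in missing if span[1] < best_p]
    return best_score, best_p, consistent


def infer_truncation(
    missing: Sequence[TheoreticalPeptide],
    retained: Sequence[TheoreticalPeptide],
    protein_length: int,
    min_evidence: int = DEFAULT_MIN_EVIDENCE,
) -> TruncationCall:
    """Classify the missing-peptide pattern as an N/C/internal truncation.

    A terminal truncation at residue ``p`` predicts that peptides ending
    before ``p`` are missing and peptides starting at or after ``p`` are
    retained (mirrored for the C terminus).  Each orientation is scored by
    its best-explaining changepoint; peptides inconsistent with it (missing
    peptides inside the retained region, or stray retained evidence from
    chance matches) are tolerated but not counted.  An orientation qualifies
    when its consistent missing count reaches ``min_evidence``; if both
    qualify the strictly better-scoring one wins and an exact tie is
    ``indeterminate``.  With no qualifying orientation, missing peptides
    overlapping the retained region give ``internal``, otherwise
    ``indeterminate``.  The boundary interval runs from the residue after
    the last consistent missing peptide to the first consistent retained
    residue — the truncation edge lies inside it.
    """
    missing = sorted(missing, key=lambda p: (p.start, p.end))
    if not missing:
        return TruncationCall("none", None, (), tuple(retained), 0)
    if not retained:
        return TruncationCall(
            "indeterminate", None, tuple(missing), (), len(missing),
            note="no retained peptides: cannot orient the truncation")

    L = protein_length
    m_spans = [(p.start, p.end, p.missed_cleavages) for p in missing]
    r_spans = [p.span for p in retained]

    def mirror_m(spans):
        return [(L + 1 - e, L + 1 - s, k) for s, e, k in spans]

    def mirror_r(spans):
        return [(L + 1 - e, L + 1 - s) for s, e in spans]

    score_n, p_n, consist_n = _n_changepoint(m_spans, r_spans, L)
    score_c, p_c_ref, consist_c_ref = _n_changepoint(
        mirror_m(m_spans), mirror_r(r_spans), L)
    qual_n = len(consist_n) >= min_evidence
    qual_c = len(consist_c_ref) >= min_evidence

    def last_missing_end(consistent):
        # A missed-cleavage peptide can straddle the cut, so its end
        # over-reaches the removed region; bound the interval with the fully
        # removed zero-missed peptides when any are available.
        k0 = [e for _, e, k in consistent if k == 0]
        return max(k0 if k0 else [e for _, e, _ in consistent])

    def call(terminus: str) -> TruncationCall:
        if terminus == "N":
            lo = last_missing_end(consist_n) + 1
            hi = min((s for s, _ in r_spans if s >= p_n), default=L)
            n_consistent = len(consist_n)
        else:  # mirror the reflected N analysis back
            lo_ref = last_missing_end(consist_c_ref) + 1
            hi_ref = min((s for s, _ in mirror_r(r_spans) if s >= p_c_ref),
                         default=L)
            lo, hi = L + 1 - hi_ref, L + 1 - lo_ref
            n_consistent = len(consist_c_ref)
        n_stray = len(m_spans) - n_consistent
        return TruncationCall(
            terminus, (max(1, lo), min(hi, L)),
            tuple(missing), tuple(retained), len(missing),
            note=f"{n_stray} missing peptide(s) attributed to dropout"
            if n_stray else "")

    if qual_n and (not qual_c or score_n > score_c):
        return call("N")
    if qual_c and (not qual_n or score_c > score_n):
        return call("C")
    if qual_n and qual_c:
        return TruncationCall(
            "indeterminate", None, tuple(missing), tuple(retained),
            len(missing), note="missing peptides at both termini")
    first_retained = min(s for s, _ in r_spans)
    last_retained = max(e for _, e in r_spans)
    if any(e >= first_retained and s <= last_retained for s, e, _ in m_spans):
        return TruncationCall(
            "internal", None, tuple(missing), tuple(retained), len(missing))
    return TruncationCall(
        "indeterminate", None, tuple(missing), tuple(retained), len(missing),
        note=f"fewer than {min_evidence} consistent terminal missing peptides")


def call_truncation(
    reference: MatchReport,
    query: MatchReport,
    min_evidence: int = DEFAULT_MIN_EVIDENCE,
    min_evidence_mass: float = DEFAULT_MIN_EVIDENCE_MASS,
) -> TruncationCall:
    """Compare two reports and infer the truncation.

    Peptides lighter than ``min_evidence_mass`` are dropped from both
    evidence sets before inference — their peaks sit below the reliable
    reflector range, where tiny calibration-offset errors flip them in and
    out of the match tolerance between spots.
    """
    missing, retained = compare_matched_sets(reference, query)
    missing = [p for p in missing if p.mh >= min_evidence_mass]
    retained = [p for p in retained if p.mh >= min_evidence_mass]
    return infer_truncation(missing, retained, reference.protein_length,
                            min_evidence)
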