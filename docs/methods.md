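# Methods

This note documents the models, defaults and numerical choices behind
pmfkit, what the synthetic fixtures do and do not emulate, and the known
limitations.

## Mass arithmetic

All masses are monoisotopic; reflector-mode MALDI resolves monoisotopic
peaks, and average-mass mode is deliberately unsupported. The residue table
ships as a plain-text file (`pmfkit/data/residue_masses.tsv`) so it is
auditable and overridable; water is 18.010565 Da, the proton 1.007276 Da.
Computing the ACTH 18–39 standard from this table gives MH⁺ = 2465.1983,
agreeing with its catalogue value 2465.199 to sub-mDa level.

Non-standard residues (for example the pentafluoro-phenylalanine of the
synthetic RfffR calibrant peptide) are supported through `extra_residues`
with a user-supplied mass. RfffR's theoretical MH⁺ is therefore *not*
hard-coded from the residue table — its packaged value (1042.276) is the
supplier's quoted mass, editable in `data/calibrants.tsv`.

Variable modifications are enumerated by count, not position. A PMF match
depends only on the peptide's total mass, so the `n_targets + 1` count
states per variable modification (Cartesian product across independent
modifications) cover every distinguishable mass without duplicating
positional isomers. Fixed and variable modifications may not target the
same residue; the configuration is rejected otherwise.

## Digestion

Trypsin specificity is cleave-after-{K,R}, blocked by a following proline
(the standard Keil rule); both sets are configurable, as is the
missed-cleavage budget (default 1). The digest enumerates every run of
1..(max_missed+1) consecutive fragments, so with `c` internal sites there
are exactly `c + 1 − j` peptides with `j` missed cleavages — this counting
law, and exact reconstruction of the parent from the j = 0 peptides, are
property-tested on random sequences. Length/mass floors default to off.

## Calibration

The correction is affine, `corrected = a·observed + b`. Two parameters are
the most the internal-standard count can reliably support, and one calibrant
degrades gracefully to a constant offset (a = 1). Calibrant peaks are found
by nearest-within-window search (default window 0.5 Da — wide enough to
catch a few-hundred-ppm miscalibration before correction), each observed
peak assignable to at most one standard, distance ties broken toward higher
intensity.

Coarse pairing can occasionally hand a *sample* peak to a standard when the
true calibrant peak drifted further from the theoretical mass than a
near-isobaric peptide. One such pair has enough leverage to wreck a plain
least-squares fit, and also to defeat greedy worst-residual rejection. The
report pipeline therefore fits by exhaustive two-point consensus (RANSAC
over all pairs of pairings, inlier threshold 30 ppm, final least-squares
over the inlier set); rejected pairings are released back into the matching
pool. The plain `fit_calibration` (exact least squares, exact two-point and
single-pair behaviour) remains the documented primitive. Calibration is
optional (`--no-calibrate`), since reporting calibrant signal does not
require correcting the axis. Double calibration is an error.

## Matching and reporting

All (peak, peptide) pairs within tolerance are listed; per peak, the
candidate with smallest |ppm error| is flagged best, ties resolved toward
fewer missed cleavages, then fewer variable modifications, then lower mass.
Candidates still tied after that chain have identical mass and are
mass-indistinguishable (e.g. two single-lysine fragments); all of them carry
the best flag, which keeps coverage well-defined in the noise-free limit.
Statistics use best matches only; the report partitions every peak into
exactly one of calibrant-assigned / best-matched / unmatched, an invariant
checked in tests. Coverage is the union (not sum) of best-matched residue
spans. Two signal fractions are reported because their questions differ:
the calibrant fraction over all ion signal, the matched fraction over
non-calibrant signal. Unmatched peaks are listed by descending intensity,
since the bright ones are the ones suggesting a second protein in the spot.
The default tolerance is 0.15 Da with a ppm option; the tolerance, unit,
missed-cleavage budget, modification sets and charge state (+1 only) are
echoed in every report for comparability.

## Truncation inference

A truncated isoform keeps producing the tryptic peptides of its retained
region while the removed terminus's peptides disappear. Given a reference
(full-length) and a query report under identical parameters, the missing
set is the reference's best-matched peptides (by span + modification state)
absent from the query, and the call is a changepoint problem: an
N-truncation with first retained residue `p` predicts missing peptides end
before `p` and retained peptides start at or after `p`. Each orientation is
scored by its best-explaining changepoint; the mirrored computation gives
the C score, which makes the N/C symmetry exact under sequence reversal.
Peptides inconsistent with the winning changepoint — missing peptides
inside the retained region (detection dropout), stray retained evidence
(chance matches within tolerance) — are tolerated but uncounted. On clean
evidence this reduces to the simple rule "all missing strictly terminal of
all retained".

An orientation qualifies with at least `min_evidence` consistent missing
peptides (default 2, so a single dropped peak cannot fake a truncation);
two qualifying orientations resolve by strictly higher score, with an exact
tie indeterminate. No qualifying orientation yields `internal` when missing
peptides overlap the retained region, otherwise `indeterminate`. The
boundary interval runs from the residue after the last consistent missing
peptide to the first consistent retained residue; because a missed-cleavage
peptide can straddle the cut and over-reach the removed region, the lower
bound uses fully-removed (k = 0) missing peptides when any exist.

Evidence is restricted to peptides with MH⁺ ≥ 600 Da (configurable).
Below the usable reflector range a few-mDa calibration-offset error already
exceeds a 25 ppm tolerance, so tiny fragments flip in and out of the match
window between spots and their absence carries no information. Gel-estimated
molecular weight is not used as evidence; the call reports `n_missing` as an
evidence count, not a probability.

## Spot screening

Spot quantities are intensity × area in ppm of total gel signal, four
replicate gels per group in the default simulated design. Selection is the
conjunction fold change > 1.5 (ratio of group means, direction recorded)
and two-sided two-sample t-test p < 0.05. The test runs on log quantities
by default — gel densitometry errors are multiplicative, and on log-normal
replicates the log-scale t-test is exact, which is what makes the null
type-I rate land on its nominal level in the acceptance checks. Equal
variances are pooled by default with a Welch option. No multiple-testing
correction is applied by default; Benjamini–Hochberg is available and then
replaces the raw p in the selection rule. Spots with zero signal in both
groups, or fewer than two complete replicates in a group after missing-value
removal, are excluded with an explicit reason.

The follow-up ranking (`rank_spots`) orders selected spots by a weighted
average of three per-metric ranks: mean intensity (higher better), |log
fold change| (higher better), and the worse within-group coefficient of
variation (lower better), default weights equal, ties broken by spot id. It
is a configurable reconstruction of a shortlisting heuristic, not a
calibrated score, and is labelled as such.

## Synthetic fixtures

The simulator emulates a reflector acquisition of an in-gel digest: k = 0
peptides detected with probability 1 − dropout (default dropout 0.10),
k = 1 peptides at a 0.2 missed-cleavage rate, the seven packaged standards
always present, contaminant peaks uniform over 800–3500 m/z (default 10),
log-normal intensities (median ≈ 1000 a.u., σ_log = 1). The mass axis is
distorted in the instrument frame — `observed = (true − b)/a` then
multiplied by `1 + ε`, `ε ~ N(0, σ_ppm·10⁻⁶)` with σ = 5 ppm by default and
a = 1.0002, b = 0.05 Da — so fitting the calibration on the calibrant peaks
is a well-posed recovery of (a, b). Truncation removes a terminal segment
before digestion; ground truth (per-peak origin, detected peptides in
full-protein coordinates, calibration truth, removed span) is returned
alongside. Proteins are drawn i.i.d. from SwissProt-like residue
frequencies. Everything is bit-reproducible for a fixed seed, and the
noise-free limit reproduces the theoretical digest masses exactly.

Not emulated: isotope envelopes and centroiding error, peak shape, chemical
noise baselines, intensity structure correlated with peptide
physicochemistry, ionisation suppression, and sequence correlation within
proteins. Passing the recovery tests therefore demonstrates correctness of
the algorithms under the stated error model, not instrument-grade
performance on real spectra.

Spot tables are log-normal: a per-spot abundance drawn with σ_log = 1
around 500 ppm, replicate noise at a configurable coefficient of variation
(default 0.25), planted spots multiplied by a configured fold in the second
group. The type-I simulations use 500 spots × 4 + 4 replicates across 200
seeds; power uses planted 2-fold spots at CV 0.1; truncation recovery uses
300-residue proteins, cuts at tryptic sites in the middle half of the
sequence, 2 ppm mass noise and a 25 ppm matching tolerance, 200 replicates
per condition. These sizes keep the whole suite in a few seconds while
leaving the binomial error on the estimated rates well below the margins
being asserted.

## Numerical and interface choices

Residue coordinates are 1-based inclusive everywhere (files, reports,
boundary intervals). Report JSON carries a schema version (currently 1) and
round-trips losslessly through the reader. Peak lists are plain two-column
text (`m/z intensity`, `#` comments); the writer emits sorted by m/z but
the reader accepts any order, and single-column files are accepted with
unit intensities and a warning. Tolerance comparisons use `<=`; ppm errors
are signed, observed minus theoretical over theoretical. The slope of a
calibration model is constrained to (0.9, 1.1) — anything further from
unity indicates mis-pairing, not miscalibration.

## Limitations

Single-enzyme, fully specific digestion only; singly charged ions only; no
probabilistic identification score (no Mowse/Mascot-style scoring, no decoy
FDR) — coverage and signal fractions are descriptive; truncation calls
locate one terminal cut and do not model internal deletions or PTM-driven
spot shifts; the spot screen assumes two groups and does not normalise
across gels beyond the ppm units it is given.
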