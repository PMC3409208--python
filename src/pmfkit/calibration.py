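"""Internal-standard recalibration of MALDI reflector peak lists.

Matrix standards (e.g. ACTH clip 18-39) and trypsin autolysis peptides have
exactly known MH+ values; pairing them with observed peaks gives an affine
correction ``corrected = a * observed + b`` that is applied identically to
every peak before matching.  With a single calibrant the model degrades to a
constant offset (a = 1).  Recalibration is optional: the calibrant
assignments are useful on their own for the signal-fraction report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

#: Coarse pre-calibration search window for calibrant peaks (Da).
DEFAULT_CALIBRANT_WINDOW = 0.5


@dataclass(frozen=True)
class InternalStandard:
    """A calibrant of exactly known singly protonated mass."""

    name: str
    theoretical_mh: float
    kind: str = "matrix_standard"  # matrix_standard | autolysis

    def __post_init__(self) -> None:
        if not self.theoretical_mh > 0:
            raise ValueError(f"theoretical_mh must be > 0 for {self.name!r}")
        if self.kind not in ("matrix_standard", "autolysis"):
            raise ValueError(f"unknown calibrant kind {self.kind!r}")


@dataclass(frozen=True)
class PeakList:
    """An observed spectrum: (m/z, intensity) pairs with provenance.

    Duplicate m/z values are permitted (centroiding artefacts) and reported
    by :attr:`duplicate_mz`.
    """

    peaks: tuple[tuple[float, float], ...]
    source_id: str = ""
    calibrated: bool = False

    def __post_init__(self) -> None:
        peaks = tuple((float(m), float(i)) for m, i in self.peaks)
        for m, i in peaks:
            if not m > 0:
                raise ValueError(f"non-positive m/z {m}")
            if i < 0:
                raise ValueError(f"negative intensity {i} at m/z {m}")
        object.__setattr__(self, "peaks", peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks], dtype=float)

    @property
    def intensity(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks], dtype=float)

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum()) if self.peaks else 0.0

    @property
    def duplicate_mz(self) -> list[float]:
        mz = [m for m, _ in self.peaks]
        seen: set[float] = set()
        dups = []
        for m in mz:
            if m in seen:
                dups.append(m)
            seen.add(m)
        return dups


@dataclass(frozen=True)
class CalibrationModel:
    """Affine mass correction ``corrected = a * observed + b``."""

    a: float
    b: float
    n_calibrants_used: int
    residuals_ppm: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (0.9 < self.a < 1.1):
            raise ValueError(f"slope {self.a} outside plausible range (0.9, 1.1)")

    def correct(self, mz: float) -> float:
        return self.a * mz + self.b

    @property
    def max_residual_ppm(self) -> float:
        return max((abs(r) for r in self.residuals_ppm), default=0.0)


def default_standards() -> list[InternalStandard]:
    """The packaged calibrant list: two matrix standards plus the usual
    porcine trypsin autolysis peaks (plain-text, user-editable)."""
    text = resources.files("pmfkit.data").joinpath("calibrants.tsv").read_text()
    standards = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, mh, kind = line.split("\t")
        standards.append(InternalStandard(name, float(mh), kind))
    return standards


def match_calibrants(
    peaks: PeakList,
    standards: list[InternalStandard],
    window: float = DEFAULT_CALIBRANT_WINDOW,
) -> list[tuple[InternalStandard, int]]:
    """Assign to each standard its nearest observed peak within ``window`` Da.

    Each observed peak goes to at most one standard: when two standards claim
    the same peak the nearer one wins.  When two peaks are equidistant from a
    standard the more intense one is selected.  Returns (standard, peak index)
    pairs; standards with no peak in the window are simply absent.
    """
    if not window > 0:
        raise ValueError("window must be > 0")
    mz = peaks.mz
    intensity = peaks.intensity
    # candidate (distance, -intensity) best peak per standard
    claims: list[tuple[float, int, InternalStandard]] = []
    for std in standards:
        if len(mz) == 0:
            continue
        dist = np.abs(mz - std.theoretical_mh)
        inside = np.flatnonzero(dist <= window)
        if inside.size == 0:
            continue
        # nearest; ties toward higher intensity
        order = sorted(inside, key=lambda j: (dist[j], -intensity[j], mz[j]))
        claims.append((float(dist[order[0]]), int(order[0]), std))
    # resolve peak contention: nearest standard wins
    claims.sort(key=lambda c: c[0])
    taken: set[int] = set()
    assigned: list[tuple[InternalStandard, int]] = []
    for _, j, std in claims:
        if j in taken:
            continue
        taken.add(j)
        assigned.append((std, j))
    assigned.sort(key=lambda p: p[0].theoretical_mh)
    return assigned


def fit_calibration(pairs: list[tuple[float, float]]) -> CalibrationModel:
    """Least-squares affine fit ``theoretical = a * observed + b``.

    ``pairs`` are (theoretical_mh, observed m/z).  With a single pair the
    model is a constant offset (a = 1, b = theoretical - observed).
    Residuals are reported in ppm of the theoretical mass.
    """
    if len(pairs) == 0:
        raise ValueError("cannot fit a calibration from zero calibrant pairs")
    theo = np.array([t for t, _ in pairs], dtype=float)
    obs = np.array([o for _, o in pairs], dtype=float)
    if len(pairs) == 1:
        a, b = 1.0, float(theo[0] - obs[0])
    else:
        if np.ptp(obs) < 1e-9:
            raise ValueError(
                "degenerate calibrant set: observed masses are identical")
        a, b = np.polyfit(obs, theo, 1)
        a, b = float(a), float(b)
    residuals = 1e6 * (a * obs + b - theo) / theo
    return CalibrationModel(
        a=a, b=b, n_calibrants_used=len(pairs),
        residuals_ppm=tuple(float(r) for r in residuals),
    )


def fit_calibration_robust(
    pairs: list[tuple[float, float]],
    inlier_ppm: float = 30.0,
) -> tuple[CalibrationModel, list[int]]:
    """Affine fit robust to mis-paired calibrants (consensus search).

    Coarse pre-calibration pairing can occasionally hand a sample peptide
    peak to a calibrant (a near-isobar closer to the standard's theoretical
    mass than the standard's own drift-shifted peak), and a single such pair
    wrecks a plain least-squares fit — worse, the outlier's leverage can
    make greedy residual rejection discard the *good* pairs.  With three or
    more pairs, every two-pair exact model is tried and the one with the
    largest inlier set (|residual| <= ``inlier_ppm``; ties broken by inlier
    residual sum of squares) wins; the final model is least-squares over its
    inliers.  Returns the model and the kept indices into ``pairs``.
    """
    n = len(pairs)
    if n <= 2:
        return fit_calibration(pairs), list(range(n))
    theo = np.array([t for t, _ in pairs])
    obs = np.array([o for _, o in pairs])
    best: tuple[int, float] | None = None  # (-n_inliers, rss)
    best_inliers: list[int] = []
    for i in range(n):
        for j in range(i + 1, n):
            if abs(obs[i] - obs[j]) < 1e-9:
                continue
            a = (theo[i] - theo[j]) / (obs[i] - obs[j])
            if not 0.9 < a < 1.1:
                continue
            b = theo[i] - a * obs[i]
            residuals = 1e6 * (a * obs + b - theo) / theo
            inliers = np.flatnonzero(np.abs(residuals) <= inlier_ppm)
            key = (-inliers.size, float(np.sum(residuals[inliers] ** 2)))
            if best is None or key < best:
                best = key
                best_inliers = [int(k) for k in inliers]
    if len(best_inliers) < 2:  # no consensus; fall back to the plain fit
        return fit_calibration(pairs), list(range(n))
    model = fit_calibration([pairs[k] for k in best_inliers])
    return model, best_inliers


def apply_calibration(peaks: PeakList, model: CalibrationModel) -> PeakList:
    """Map every m/z through the model; intensities and count are untouched.

    Refuses to calibrate twice — reapplying an affine correction silently
    would corrupt the mass axis.
    """
    if peaks.calibrated:
        raise ValueError(
            f"peak list {peaks.source_id!r} is already calibrated")
    corrected = tuple((model.correct(m), i) for m, i in peaks.peaks)
    return replace(peaks, peaks=corrected, calibrated=True)
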