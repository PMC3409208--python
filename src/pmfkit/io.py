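"""File formats and run configuration.

Formats are deliberately plain text so every input and output can be read,
diffed and edited by hand:

* FASTA for protein sequences (standard; accession = header token before the
  first whitespace);
* peak lists as two whitespace-separated columns ``m/z intensity``, ``#``
  comments and blank lines ignored, one peak per line (a single-column file
  is accepted with unit intensities);
* TSV for digest, match and spot tables;
* JSON for identification reports and truncation calls (schema version 1);
* a TOML run-configuration file.

All residue coordinates in every file are 1-based inclusive.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from . import __version__
from .calibration import CalibrationModel, InternalStandard, PeakList
from .chem import Modification, ModificationState, ResidueMassTable
from .digest import TheoreticalPeptide
from .isoform import TruncationCall
from .matching import MatchReport, PeakMatch

REPORT_SCHEMA_VERSION = 1

VALID_SEQUENCE_CHARS = set("ACDEFGHIKLMNPQRSTVWY") | set("BXZJUO")


def read_fasta(path: str | Path,
               table: ResidueMassTable | None = None) -> list[tuple[str, str]]:
    """Parse FASTA into (accession, upper-cased sequence) pairs, file order.

    Stop codons (``*``) are stripped with a warning; duplicate accessions and
    characters that are neither standard residues nor in the mass table's
    extra residues are errors.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    allowed = set(VALID_SEQUENCE_CHARS)
    if table is not None:
        allowed |= set(table.extra_residues)
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in records:
        accession = rec.id
        if accession in seen:
            raise ValueError(f"duplicate accession {accession!r} in {path}")
        seen.add(accession)
        seq = str(rec.seq).upper()
        if "*" in seq:
            warnings.warn(f"stripping stop codon(s) from {accession}")
            seq = seq.replace("*", "")
        for i, c in enumerate(seq, start=1):
            if c not in allowed:
                raise ValueError(
                    f"illegal character {c!r} at position {i} of record "
                    f"{accession!r}")
        out.append((accession, seq))
    return out


def read_peaklist(path: str | Path) -> PeakList:
    """Parse the two-column plain-text peak format."""
    path = Path(path)
    peaks: list[tuple[float, float]] = []
    warned_single = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        try:
            mz = float(tokens[0])
            intensity = float(tokens[1]) if len(tokens) > 1 else 1.0
        except ValueError as exc:
            raise ValueError(
                f"{path}:{lineno}: cannot parse peak line {raw!r}") from exc
        if len(tokens) == 1 and not warned_single:
            warnings.warn(f"{path}: single-column peak list; assuming unit "
                          "intensities")
            warned_single = True
        peaks.append((mz, intensity))
    return PeakList(peaks=tuple(peaks), source_id=path.name)


def write_peaklist(peaks: PeakList, path: str | Path) -> None:
    """Write peaks sorted by m/z, one ``m/z intensity`` pair per line."""
    path = Path(path)
    lines = [f"# peak list: {peaks.source_id}",
             f"# calibrated: {str(peaks.calibrated).lower()}"]
    for mz, intensity in sorted(peaks.peaks):
        lines.append(f"{mz:.6f}\t{intensity:.6g}")
    path.write_text("\n".join(lines) + "\n")


def read_calibrants(path: str | Path) -> list[InternalStandard]:
    """Read a calibrant TSV: name, theoretical MH+, kind."""
    standards = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated "
                             f"fields, got {len(fields)}")
        standards.append(InternalStandard(fields[0], float(fields[1]), fields[2]))
    return standards


# ---------------------------------------------------------------- reports

def _peptide_to_dict(p: TheoreticalPeptide) -> dict:
    return {
        "sequence": p.sequence, "start": p.start, "end": p.end,
        "missed_cleavages": p.missed_cleavages,
        "fixed_applied": p.state.fixed_applied,
        "variable_counts": dict(p.state.variable_counts),
        "neutral_mass": p.neutral_mass, "mh": p.mh,
    }


def _peptide_from_dict(d: dict) -> TheoreticalPeptide:
    return TheoreticalPeptide(
        sequence=d["sequence"], start=d["start"], end=d["end"],
        missed_cleavages=d["missed_cleavages"],
        state=ModificationState(fixed_applied=d["fixed_applied"],
                                variable_counts=d["variable_counts"]),
        neutral_mass=d["neutral_mass"], mh=d["mh"],
    )


def report_to_dict(report: MatchReport) -> dict:
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "accession": report.accession,
        "protein_length": report.protein_length,
        "coverage_percent": report.coverage_percent,
        "matched_signal_fraction": report.matched_signal_fraction,
        "calibrant_signal_fraction": report.calibrant_signal_fraction,
        "parameters": report.parameters,
        "calibration": None if report.calibration is None else {
            "a": report.calibration.a, "b": report.calibration.b,
            "n_calibrants_used": report.calibration.n_calibrants_used,
            "residuals_ppm": list(report.calibration.residuals_ppm),
        },
        "calibrant_assignments": [
            {"standard": name, "peak_index": j}
            for name, j in report.calibrant_assignments],
        "matches": [
            {"peak_index": m.peak_index,
             "error_ppm": m.error_ppm, "error_da": m.error_da,
             "is_best_for_peak": m.is_best_for_peak,
             "peptide": _peptide_to_dict(m.peptide)}
            for m in report.matches],
        "unmatched_peaks": [
            {"mz": mz, "intensity": i} for mz, i in report.unmatched_peaks],
        "warnings": list(report.warnings),
    }


def report_from_dict(d: dict) -> MatchReport:
    if d.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported report schema version {d.get('schema_version')!r}")
    calibration = None
    if d["calibration"] is not None:
        c = d["calibration"]
        calibration = CalibrationModel(
            a=c["a"], b=c["b"], n_calibrants_used=c["n_calibrants_used"],
            residuals_ppm=tuple(c["residuals_ppm"]))
    return MatchReport(
        accession=d["accession"],
        protein_length=d["protein_length"],
        matches=tuple(
            PeakMatch(m["peak_index"], _peptide_from_dict(m["peptide"]),
                      m["error_ppm"], m["error_da"], m["is_best_for_peak"])
            for m in d["matches"]),
        coverage_percent=d["coverage_percent"],
        matched_signal_fraction=d["matched_signal_fraction"],
        calibrant_signal_fraction=d["calibrant_signal_fraction"],
        unmatched_peaks=tuple(
            (p["mz"], p["intensity"]) for p in d["unmatched_peaks"]),
        calibrant_assignments=tuple(
            (a["standard"], a["peak_index"])
            for a in d["calibrant_assignments"]),
        parameters=d["parameters"],
        calibration=calibration,
        warnings=tuple(d["warnings"]),
    )


def write_report(report: MatchReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report_to_dict(report), indent=2) + "\n")


def read_report(path: str | Path) -> MatchReport:
    return report_from_dict(json.loads(Path(path).read_text()))


def truncation_to_dict(call: TruncationCall) -> dict:
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "terminus": call.terminus,
        "boundary_interval": list(call.boundary_interval)
        if call.boundary_interval else None,
        "n_missing": call.n_missing,
        "note": call.note,
        "missing_peptides": [_peptide_to_dict(p) for p in call.missing_peptides],
        "retained_peptides": [_peptide_to_dict(p) for p in call.retained_peptides],
    }


def matches_to_frame(report: MatchReport) -> pd.DataFrame:
    """Flat TSV-ready table of all matches in a report."""
    rows = [
        {"accession": report.accession,
         "peak_index": m.peak_index,
         "peptide": m.peptide.sequence,
         "start": m.peptide.start, "end": m.peptide.end,
         "missed_cleavages": m.peptide.missed_cleavages,
         "mod_state": m.peptide.state.label(),
         "theoretical_mh": m.peptide.mh,
         "error_ppm": m.error_ppm, "error_da": m.error_da,
         "is_best_for_peak": m.is_best_for_peak}
        for m in report.matches
    ]
    return pd.DataFrame(
        rows, columns=["accession", "peak_index", "peptide", "start", "end",
                       "missed_cleavages", "mod_state", "theoretical_mh",
                       "error_ppm", "error_da", "is_best_for_peak"])


def digest_to_frame(accession: str,
                    peptides: Sequence[TheoreticalPeptide]) -> pd.DataFrame:
    rows = [
        {"accession": accession, "start": p.start, "end": p.end,
         "sequence": p.sequence, "missed_cleavages": p.missed_cleavages,
         "mod_state": p.state.label(),
         "neutral_mass": p.neutral_mass, "mh": p.mh}
        for p in peptides
    ]
    return pd.DataFrame(
        rows, columns=["accession", "start", "end", "sequence",
                       "missed_cleavages", "mod_state", "neutral_mass", "mh"])


# ------------------------------------------------------------- run config

@dataclass
class RunConfig:
    """Every user-facing knob, round-trippable through a TOML file."""

    tolerance: float = 0.15
    tolerance_unit: str = "da"
    max_missed: int = 1
    calibrate: bool = True
    calibrant_window: float = 0.5
    min_evidence: int = 2
    fold_threshold: float = 1.5
    p_threshold: float = 0.05
    log_transform: bool = True
    seed: int = 0
    fixed_mods: list[dict] = field(default_factory=lambda: [
        {"name": "carbamidomethyl", "targets": "C", "delta_mass": 57.02146}])
    variable_mods: list[dict] = field(default_factory=lambda: [
        {"name": "oxidation", "targets": "M", "delta_mass": 15.99491}])
    extra_residues: dict[str, float] = field(default_factory=dict)

    def modifications(self) -> list[Modification]:
        mods = [Modification(m["name"], frozenset(m["targets"]),
                             m["delta_mass"], "fixed")
                for m in self.fixed_mods]
        mods += [Modification(m["name"], frozenset(m["targets"]),
                              m["delta_mass"], "variable")
                 for m in self.variable_mods]
        return mods

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(_to_toml(self.to_dict()))


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    raise TypeError(f"cannot serialise {type(v)} to TOML")


def _to_toml(d: Mapping) -> str:
    """Minimal TOML emitter for the flat-with-tables RunConfig layout."""
    lines: list[str] = []
    tables: list[str] = []
    for key, value in d.items():
        if isinstance(value, list) and value and isinstance(value[0], dict):
            for item in value:
                tables.append(f"[[{key}]]")
                tables.extend(f"{k} = {_toml_value(v)}" for k, v in item.items())
                tables.append("")
        elif isinstance(value, dict):
            if value:
                tables.append(f"[{key}]")
                tables.extend(f"{k} = {_toml_value(v)}" for k, v in value.items())
                tables.append("")
        elif isinstance(value, list):
            lines.append(f"{key} = [" + ", ".join(_toml_value(v) for v in value) + "]")
        else:
            lines.append(f"{key} = {_toml_value(value)}")
    return "\n".join(lines + [""] + tables)


# ------------------------------------------------------------ provenance

def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_provenance(path: str | Path, inputs: Mapping[str, str | Path],
                     parameters: Mapping) -> None:
    """Record tool version, timestamp, input digests and effective settings."""
    record = {
        "tool": "pmfkit",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "inputs": {name: {"path": str(p), "sha256": sha256_of(p)}
                   for name, p in inputs.items() if Path(p).exists()},
        "parameters": dict(parameters),
    }
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")
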