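"""Reading and writing DDA/PRM data and the discovery-stage pre-filters.

Covers MGF round-tripping for DDA spectra, the pre-filters applied before
the crosslink search (removal of heavy precursors, restriction to spectra
unique to one collection-tube condition), ingest of crosslink-candidate
tables with the fragment-count/length confidence filter, and grouping of
PRM runs by isolation target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from pyteomics import mgf as _ptmgf

from .chem import PROTON_MASS, CrosslinkPair

GROUPS = ("S", "F", "E", "A")


@dataclass
class Ms2Spectrum:
    """One MS2 spectrum with peaks sorted by m/z."""

    precursor_mz: float
    precursor_charge: int
    rt: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    group: str = ""
    title: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")

    @property
    def neutral_mass(self) -> float:
        return (self.precursor_mz - PROTON_MASS) * self.precursor_charge


class MgfFormatError(ValueError):
    """Malformed MGF structure (unbalanced BEGIN IONS / END IONS)."""


def _check_mgf_structure(path) -> None:
    open_line = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip().upper()
            if token == "BEGIN IONS":
                if open_line is not None:
                    raise MgfFormatError(
                        f"{path}: line {lineno}: BEGIN IONS while block from "
                        f"line {open_line} is still open"
                    )
                open_line = lineno
            elif token == "END IONS":
                if open_line is None:
                    raise MgfFormatError(
                        f"{path}: line {lineno}: END IONS without matching BEGIN IONS"
                    )
                open_line = None
    if open_line is not None:
        raise MgfFormatError(f"{path}: BEGIN IONS at line {open_line} never closed")


def read_mgf(path) -> list[Ms2Spectrum]:
    """Read an MGF file into a list of spectra.

    RT is converted from RTINSECONDS to minutes. SAMPLE/GROUP local
    parameters, when present, populate the spectrum metadata.
    """
    _check_mgf_structure(path)
    spectra = []
    with _ptmgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            charge = int(params["charge"][0]) if "charge" in params else 0
            rt_s = float(params.get("rtinseconds", 0.0))
            spectra.append(
                Ms2Spectrum(
                    precursor_mz=float(params["pepmass"][0]),
                    precursor_charge=charge,
                    rt=rt_s / 60.0,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                    sample_id=str(params.get("sample", "")),
                    group=str(params.get("group", "")),
                    title=str(params.get("title", "")),
                )
            )
    return spectra


def write_mgf(spectra: Iterable[Ms2Spectrum], path) -> None:
    entries = []
    for i, s in enumerate(spectra):
        params = {
            "TITLE": s.title or f"spectrum_{i}",
            "PEPMASS": s.precursor_mz,
            "CHARGE": f"{s.precursor_charge}+",
            "RTINSECONDS": s.rt * 60.0,
        }
        if s.sample_id:
            params["SAMPLE"] = s.sample_id
        if s.group:
            params["GROUP"] = s.group
        entries.append(
            {"params": params, "m/z array": s.mz, "intensity array": s.intensity}
        )
    _ptmgf.write(entries, str(path), file_mode="w")


def filter_precursor_mass(
    spectra: Iterable[Ms2Spectrum], max_mass: float = 8000.0
) -> list[Ms2Spectrum]:
    """Keep spectra whose precursor neutral mass is <= max_mass (Da).

    Crosslink searches bog down on very heavy precursors; the neutral mass
    is computed from precursor m/z and charge.
    """
    return [s for s in spectra if s.neutral_mass <= max_mass]


def group_unique_spectra(
    spectra_by_group: Mapping[str, list[Ms2Spectrum]],
    mz_tol: float = 0.01,
    rt_tol: float = 2.0,
) -> dict[str, list[Ms2Spectrum]]:
    """Restrict each condition group to spectra seen in no other group.

    Two spectra match when their precursor m/z agree within ``mz_tol`` (Th),
    charges are identical, and RTs agree within ``rt_tol`` (minutes).
    Matching spectra are removed from every group involved, so the retained
    sets are condition-specific by construction.
    """
    if len(spectra_by_group) < 2:
        raise ValueError("need at least two groups to compute group-unique spectra")
    groups = list(spectra_by_group)
    flagged: dict[str, set[int]] = {g: set() for g in groups}
    for gi in range(len(groups)):
        for gj in range(gi + 1, len(groups)):
            a, b = groups[gi], groups[gj]
            for i, sa in enumerate(spectra_by_group[a]):
                for j, sb in enumerate(spectra_by_group[b]):
                    if (
                        sa.precursor_charge == sb.precursor_charge
                        and abs(sa.precursor_mz - sb.precursor_mz) <= mz_tol
                        and abs(sa.rt - sb.rt) <= rt_tol
                    ):
                        flagged[a].add(i)
                        flagged[b].add(j)
    return {
        g: [s for i, s in enumerate(spectra_by_group[g]) if i not in flagged[g]]
        for g in groups
    }


@dataclass(frozen=True)
class CandidateRecord:
    """One crosslink candidate from the discovery search output."""

    pair: CrosslinkPair
    z: int
    n_fragments_matched: int
    rt: float

    @property
    def total_length(self) -> int:
        return len(self.pair.peptide_a) + len(self.pair.peptide_b)

    @property
    def score_ratio(self) -> float:
        """Matched fragment ions over the summed peptide lengths."""
        return self.n_fragments_matched / self.total_length


_CANDIDATE_COLUMNS = ("peptide_a", "peptide_b", "cm", "z", "n_fragments_matched", "rt")


def load_candidates(path) -> list[CandidateRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_CANDIDATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"candidate table missing column(s): {sorted(missing)}")
    records = []
    for rec in df.itertuples(index=False):
        records.append(
            CandidateRecord(
                pair=CrosslinkPair.from_sequences(
                    rec.peptide_a, rec.peptide_b, float(rec.cm)
                ),
                z=int(rec.z),
                n_fragments_matched=int(rec.n_fragments_matched),
                rt=float(rec.rt),
            )
        )
    return records


def filter_candidates(
    records: Iterable[CandidateRecord], threshold: float = 1.5
) -> list[CandidateRecord]:
    """Keep high-confidence candidates: score_ratio strictly greater than threshold."""
    return [r for r in records if r.score_ratio > threshold]


# ---------------------------------------------------------------------------
# PRM runs


@dataclass
class PrmScan:
    """One targeted MS2 scan: retention time plus its peak list (m/z-sorted)."""

    rt: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]


@dataclass
class PrmRun:
    """A PRM acquisition: MS2 scans grouped by isolation-target m/z."""

    sample_id: str
    group: str
    scans_by_target: dict[float, list[PrmScan]] = field(default_factory=dict)

    def targets(self) -> list[float]:
        return sorted(self.scans_by_target)

    def scans_for(self, precursor_mz: float, tol: float = 0.35) -> list[PrmScan]:
        """Scans whose isolation target lies within ``tol`` Th of the precursor.

        Default tolerance is half the 0.7 Th isolation width.
        """
        best, best_d = None, tol
        for target in self.scans_by_target:
            d = abs(target - precursor_mz)
            if d <= best_d:
                best, best_d = target, d
        return self.scans_by_target.get(best, []) if best is not None else []


def read_prm_run(path, sample_id: str = "", group: str = "") -> PrmRun:
    """Read a PRM run from mzML or from the package's chromatogram-table TSV.

    mzML MS2 scans must carry isolation-window metadata; scans are grouped
    by isolation target m/z (rounded to 4 decimals).
    """
    path = Path(path)
    if path.suffix.lower() == ".mzml":
        return _read_prm_mzml(path, sample_id, group)
    return read_prm_table(path, sample_id, group)


def _read_prm_mzml(path: Path, sample_id: str, group: str) -> PrmRun:
    from .mzml import read_mzml  # deferred: mzml depends on this module's types

    return read_mzml(path, sample_id=sample_id, group=group)


_PRM_TABLE_COLUMNS = ("target_mz", "scan", "rt", "mz", "intensity")


def write_prm_table(run: PrmRun, path) -> None:
    """Write a PRM run as a long-format TSV (one row per peak)."""
    rows = []
    for target, scans in sorted(run.scans_by_target.items()):
        for si, scan in enumerate(scans):
            for mz, inten in zip(scan.mz, scan.intensity):
                rows.append((target, si, scan.rt, mz, inten))
    df = pd.DataFrame(rows, columns=_PRM_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_prm_table(path, sample_id: str = "", group: str = "") -> PrmRun:
    df = pd.read_csv(path, sep="\t")
    missing = set(_PRM_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"PRM table missing column(s): {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: no MS2 scan data")
    run = PrmRun(sample_id=sample_id, group=group)
    for target, tgrp in df.groupby("target_mz"):
        scans = []
        for (_, rt), sgrp in tgrp.groupby(["scan", "rt"]):
            scans.append(
                PrmScan(rt=float(rt), mz=sgrp["mz"].to_numpy(),
                        intensity=sgrp["intensity"].to_numpy())
            )
        scans.sort(key=lambda s: s.rt)
        run.scans_by_target[round(float(target), 4)] = scans
    return run
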