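"""Extracted-ion-chromatogram assembly and the PRM validation filter cascade.

A scheduled PRM run monitors each crosslinked precursor over a six-minute
retention-time window. For every theoretical transition an XIC is built by
summing peak intensities within an extraction tolerance of the fragment
m/z, then a strict cascade decides which transitions count as real signal:

1. fragment index must be at least 5 (short b/y ions are not sequence
   specific and routinely match co-isolating background peptides);
2. both peptides of the pair must be at least 7 residues long;
3. the trace apex must exceed the 3000-count noise floor;
4. the intensity-weighted measured m/z at the apex must lie within 1 ppm
   of the theoretical fragment m/z;
5. the precursor is accepted only if at least 5 transitions survive in at
   least one sample of its 12-sample cohort.

Peak areas are trapezoidal integrals of the surviving traces over the RT
window; charge states of the same pair are then combined and areas averaged
across donors within each tube-condition group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import CrosslinkPair, FragmentIon, PrecursorIon, TransitionTarget
from .design import SampleDesign
from .spectra import PrmRun


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the validation cascade (defaults as used throughout)."""

    rt_window_min: float = 6.0
    noise_floor: float = 3000.0
    accept_ppm: float = 1.0
    extract_ppm: float = 10.0
    min_fragment_index: int = 5
    min_peptide_len: int = 7
    min_transitions: int = 5


@dataclass
class ChromatogramTrace:
    """XIC of one transition in one sample over the scheduling window."""

    transition: FragmentIon
    sample_id: str
    group: str
    rt: np.ndarray
    intensity: np.ndarray
    measured_mz: np.ndarray  # NaN where no peaks fell in the window

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.measured_mz = np.asarray(self.measured_mz, dtype=float)

    @property
    def apex_index(self) -> int:
        return int(np.argmax(self.intensity)) if self.intensity.size else 0

    @property
    def apex_intensity(self) -> float:
        return float(self.intensity[self.apex_index]) if self.intensity.size else 0.0

    @property
    def apex_rt(self) -> float:
        return float(self.rt[self.apex_index]) if self.rt.size else math.nan

    @property
    def apex_ppm_deviation(self) -> float:
        """|measured - theoretical| m/z at the apex scan, in ppm."""
        if not self.intensity.size:
            return math.inf
        measured = self.measured_mz[self.apex_index]
        if math.isnan(measured):
            return math.inf
        return abs(measured - self.transition.mz) / self.transition.mz * 1e6

    @property
    def peak_area(self) -> float:
        """Trapezoidal area under the trace over the window (counts x minutes)."""
        if self.rt.size < 2:
            return 0.0
        return float(np.trapezoid(self.intensity, self.rt))


@dataclass
class ValidationResult:
    """Per (precursor, sample) outcome of the filter cascade."""

    precursor: PrecursorIon
    sample_id: str
    group: str
    surviving_transitions: list[ChromatogramTrace] = field(default_factory=list)
    accepted: bool = False
    excluded: bool = False
    exclusion_reason: str | None = None

    @property
    def n_surviving(self) -> int:
        return len(self.surviving_transitions)

    @property
    def total_area(self) -> float:
        return sum(t.peak_area for t in self.surviving_transitions)


def extract_xic(
    run: PrmRun,
    target: TransitionTarget,
    extract_ppm: float = 10.0,
    isolation_tol: float = 0.35,
) -> list[ChromatogramTrace]:
    """Assemble one XIC per transition of a PRM target.

    Per scan, each transition's intensity is the summed intensity of peaks
    within ``extract_ppm`` of the theoretical fragment m/z, and the measured
    m/z is the intensity-weighted mean of those peaks. Scans outside the
    target's RT window contribute nothing; absent signal yields an all-zero
    trace.
    """
    if not target.transitions:
        return []
    scans = run.scans_for(target.precursor.mz_calc, tol=isolation_tol)
    rt_lo, rt_hi = target.rt_window
    scans = [s for s in scans if rt_lo <= s.rt <= rt_hi]

    tmz = np.array([t.mz for t in target.transitions])
    lo = tmz * (1.0 - extract_ppm * 1e-6)
    hi = tmz * (1.0 + extract_ppm * 1e-6)

    n_scans, n_trans = len(scans), len(tmz)
    rts = np.array([s.rt for s in scans])
    inten = np.zeros((n_scans, n_trans))
    mzmeas = np.full((n_scans, n_trans), np.nan)
    for si, scan in enumerate(scans):
        if not scan.mz.size:
            continue
        ci = np.concatenate(([0.0], np.cumsum(scan.intensity)))
        cim = np.concatenate(([0.0], np.cumsum(scan.intensity * scan.mz)))
        i_lo = np.searchsorted(scan.mz, lo, side="left")
        i_hi = np.searchsorted(scan.mz, hi, side="right")
        tot = ci[i_hi] - ci[i_lo]
        wsum = cim[i_hi] - cim[i_lo]
        inten[si] = tot
        with np.errstate(invalid="ignore", divide="ignore"):
            mzmeas[si] = np.where(tot > 0, wsum / np.where(tot > 0, tot, 1.0), np.nan)

    return [
        ChromatogramTrace(
            transition=t,
            sample_id=run.sample_id,
            group=run.group,
            rt=rts,
            intensity=inten[:, ti],
            measured_mz=mzmeas[:, ti],
        )
        for ti, t in enumerate(target.transitions)
    ]


def apply_filter_cascade(
    precursor: PrecursorIon,
    traces: Sequence[ChromatogramTrace],
    config: FilterConfig | None = None,
    sample_id: str | None = None,
    group: str | None = None,
) -> ValidationResult:
    """Run the per-sample stages of the cascade on one precursor's traces.

    Cohort-level acceptance (minimum transitions in at least one sample) is
    decided afterwards by :func:`accept_cohort`.
    """
    cfg = config or FilterConfig()
    sid = sample_id if sample_id is not None else (traces[0].sample_id if traces else "")
    grp = group if group is not None else (traces[0].group if traces else "")
    result = ValidationResult(precursor=precursor, sample_id=sid, group=grp)

    pair = precursor.pair
    short = [
        str(p) for p in (pair.peptide_a, pair.peptide_b)
        if len(p) < cfg.min_peptide_len
    ]
    if short:
        result.excluded = True
        result.exclusion_reason = (
            f"peptide(s) shorter than {cfg.min_peptide_len} residues: "
            + ", ".join(sorted(set(short)))
        )
        return result

    for trace in traces:
        if trace.transition.index < cfg.min_fragment_index:
            continue
        if trace.apex_intensity <= cfg.noise_floor:
            continue
        if trace.apex_ppm_deviation > cfg.accept_ppm:
            continue
        result.surviving_transitions.append(trace)
    return result


def accept_cohort(
    results: Sequence[ValidationResult],
    min_transitions: int = 5,
) -> list[ValidationResult]:
    """Apply cohort-level acceptance across all samples of one precursor.

    The precursor is retained (in every sample) when at least one sample
    shows ``min_transitions`` or more surviving transitions; otherwise it is
    rejected everywhere.
    """
    if not results:
        raise ValueError("accept_cohort requires at least one sample result")
    retained = any(r.n_surviving >= min_transitions for r in results)
    for r in results:
        r.accepted = retained and not r.excluded
    return list(results)


@dataclass
class MergedResult:
    """Per (pair, sample) area after combining charge states."""

    pair: CrosslinkPair
    sample_id: str
    group: str
    total_area: float
    n_precursors: int


def merge_charge_states(results: Iterable[ValidationResult]) -> list[MergedResult]:
    """Combine accepted results over charge states of the same pair.

    Areas of a pair's precursor ions are summed per sample; distinct
    (pair, charge) targets collapse to one record per (pair, sample).
    """
    merged: dict[tuple[str, str], MergedResult] = {}
    for r in results:
        if not r.accepted:
            continue
        key = (r.precursor.pair.label, r.sample_id)
        if key in merged:
            merged[key].total_area += r.total_area
            merged[key].n_precursors += 1
        else:
            merged[key] = MergedResult(
                pair=r.precursor.pair,
                sample_id=r.sample_id,
                group=r.group,
                total_area=r.total_area,
                n_precursors=1,
            )
    return list(merged.values())


def average_donors(
    merged: Iterable[MergedResult],
    design: SampleDesign,
    missing_as_zero: bool = True,
) -> pd.DataFrame:
    """Mean per-(pair, group) area across donors.

    Returns a DataFrame indexed by pair label with one column per group.
    Samples of the design without a result for a pair contribute zero area
    (keeping group means comparable) unless ``missing_as_zero`` is False, in
    which case they are dropped from the mean.
    """
    groups = design.groups
    for g in groups:
        if not design.samples_in(g):
            raise ValueError(f"group {g!r} has no samples in the design")
    areas: dict[tuple[str, str], float] = {}
    pairs: dict[str, CrosslinkPair] = {}
    for m in merged:
        areas[(m.pair.label, m.sample_id)] = (
            areas.get((m.pair.label, m.sample_id), 0.0) + m.total_area
        )
        pairs[m.pair.label] = m.pair
    rows = {}
    for label in sorted(pairs):
        row = {}
        for g in groups:
            samples = design.samples_in(g)
            vals = [
                areas.get((label, sid))
                for sid in samples
            ]
            if missing_as_zero:
                vals = [v if v is not None else 0.0 for v in vals]
            else:
                vals = [v for v in vals if v is not None]
            row[g] = float(np.mean(vals)) if vals else 0.0
        rows[label] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(groups))


def validate_cohort(
    runs: Mapping[str, PrmRun],
    targets: Sequence[TransitionTarget],
    design: SampleDesign,
    config: FilterConfig | None = None,
) -> list[ValidationResult]:
    """Run extraction + cascade + cohort acceptance for every target.

    ``runs`` maps sample_id -> PRM run; returns one ValidationResult per
    (target, sample), with cohort acceptance already applied.
    """
    cfg = config or FilterConfig()
    all_results: list[ValidationResult] = []
    for target in targets:
        per_sample = []
        for sid in design.sample_ids:
            run = runs[sid]
            traces = extract_xic(run, target, extract_ppm=cfg.extract_ppm)
            per_sample.append(
                apply_filter_cascade(
                    target.precursor, traces, cfg,
                    sample_id=sid, group=design.group_of(sid),
                )
            )
        accept_cohort(per_sample, cfg.min_transitions)
        all_results.extend(per_sample)
    return all_results


def results_table(results: Iterable[ValidationResult]) -> pd.DataFrame:
    """Flat per-(pair, charge, sample) summary of the cascade outcome."""
    rows = []
    for r in results:
        rows.append(
            {
                "pair": r.precursor.pair.label,
                "charge": r.precursor.charge,
                "sample_id": r.sample_id,
                "group": r.group,
                "n_surviving": r.n_surviving,
                "total_area": r.total_area,
                "accepted": r.accepted,
                "excluded": r.excluded,
            }
        )
    return pd.DataFrame(rows)
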