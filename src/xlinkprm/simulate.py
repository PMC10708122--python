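"""Synthetic PRM and DDA data with known ground truth.

Emulates the 4-tube-condition x 3-donor PBMC study so every pipeline stage
is testable without instrument files. Each scheduled PRM target gets MS2
scans across its six-minute retention window at a fixed scan interval;
every theoretical transition of an injected crosslink appears as a
Gaussian-in-time elution peak whose apex is the per-pair base intensity
times a group multiplier (high in Streck/formaldehyde samples, low in
EDTA/allantoin), with fragment m/z perturbed by a ppm-scale mass error.
Sparse exponential noise peaks emulate the ~3000-count noise floor and
optional co-isolating interference peptides elute alongside selected
targets in every group.

Noise and interference peaks are kept at least ``noise_exclusion_ppm`` away
from every monitored transition m/z, so the ground truth (which transitions
are detectable after the filter cascade) is exact by construction rather
than probabilistic. Decoy targets are residue-shuffled copies of roster
pairs with one mass-detaching substitution; nothing is injected at their
transitions, so any decoy acceptance is a pipeline false positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import (
    PROTON_MASS,
    CrosslinkPair,
    PeptideSequence,
    TransitionConfig,
    TransitionTarget,
    crosslink_precursor_mz,
    generate_transitions,
)
from .design import GROUPS, SampleDesign, default_design
from .spectra import Ms2Spectrum, PrmRun, PrmScan
from .tables import load_table1
from .validate import FilterConfig


@dataclass(frozen=True)
class RosterEntry:
    """One scheduled precursor: a crosslinked pair at one charge state."""

    pair: CrosslinkPair
    charge: int
    rt_center: float
    is_decoy: bool = False

    @property
    def label(self) -> str:
        return f"{self.pair.label}/z{self.charge}" + ("/decoy" if self.is_decoy else "")


def default_roster() -> tuple[RosterEntry, ...]:
    """All 57 (pair, charge) precursors of the packaged crosslink table."""
    entries = []
    for row in load_table1():
        for z, rt in zip(row.z_list, row.rt_list):
            entries.append(RosterEntry(pair=row.pair, charge=z, rt_center=rt))
    return tuple(entries)


_DECOY_SUBSTITUTION = {"W": "F"}


def make_decoys(
    entries: Sequence[RosterEntry], n: int, rng: np.random.Generator
) -> tuple[RosterEntry, ...]:
    """Decoy targets: shuffled sequences with one mass-detaching substitution.

    Residue shuffling alone preserves the precursor mass (the pair would
    co-isolate with its source target), so the first residue is additionally
    substituted to move the decoy's precursor and fragments away from every
    real m/z.
    """
    decoys = []
    picks = rng.choice(len(entries), size=min(n, len(entries)), replace=False)
    for idx in sorted(picks):
        src = entries[int(idx)]
        shuffled = []
        for pep in (src.pair.peptide_a, src.pair.peptide_b):
            res = list(str(pep))
            rng.shuffle(res)
            res[0] = _DECOY_SUBSTITUTION.get(res[0], "W")
            shuffled.append("".join(res))
        decoys.append(
            RosterEntry(
                pair=CrosslinkPair.from_sequences(
                    shuffled[0], shuffled[1], src.pair.crosslink_mass
                ),
                charge=src.charge,
                rt_center=src.rt_center,
                is_decoy=True,
            )
        )
    return tuple(decoys)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults encode the emulated design: equal crosslink signal in Streck
    (S) and formaldehyde (F) samples, 5% residual intensity in EDTA (E) and
    allantoin (A), three donors per condition, 2-second PRM scan interval,
    0.1-minute chromatographic peak sigma, an exponential noise floor with
    mean 1000 counts, and a 0.3 ppm fragment mass-error sigma (well inside
    the 1 ppm acceptance rule for real signal).
    """

    roster: tuple[RosterEntry, ...] | None = None  # None -> default_roster()
    n_decoys: int = 10
    group_multipliers: tuple[tuple[str, float], ...] = (
        ("S", 1.0), ("F", 1.0), ("E", 0.05), ("A", 0.05),
    )
    n_donors: int = 3
    peak_sigma_min: float = 0.1
    scan_interval_s: float = 2.0
    base_apex_mean: float = 40000.0
    base_apex_cv: float = 0.25
    donor_cv: float = 0.10
    fragment_abundance_range: tuple[float, float] = (0.3, 1.0)
    noise_peaks_per_scan: int = 20
    noise_intensity_mean: float = 1000.0
    noise_mz_range: tuple[float, float] = (150.0, 1800.0)
    noise_exclusion_ppm: float = 25.0
    mass_error_ppm_sigma: float = 0.3
    rt_jitter_sigma_min: float = 0.05
    n_interference: int = 5
    interference_apex: float = 20000.0
    interference_fragments: int = 8
    interference_rt_offset_min: float = 0.8
    min_peak_intensity: float = 1.0
    transition_config: TransitionConfig = TransitionConfig()
    reference_filters: FilterConfig = FilterConfig()
    seed: int = 0

    @property
    def multipliers(self) -> dict[str, float]:
        return dict(self.group_multipliers)


@dataclass
class GroundTruthRecord:
    """What was injected for one (precursor, sample) and whether the
    validation cascade should recover it."""

    entry_label: str
    pair_label: str
    charge: int
    sample_id: str
    group: str
    is_decoy: bool
    injected_apex: float  # per-pair apex before fragment abundance factors
    true_rt: float
    n_detectable_transitions: int
    detectable: bool


@dataclass
class CohortSimulation:
    """A full simulated cohort: runs, targets, design and ground truth."""

    config: SimulationConfig
    design: SampleDesign
    entries: tuple[RosterEntry, ...]
    targets: list[TransitionTarget]
    runs: dict[str, PrmRun]
    truth: list[GroundTruthRecord]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(t) for t in self.truth])


def _target_key(mz: float) -> float:
    return round(mz, 4)


def _scan_grid(rt_start: float, rt_end: float, interval_min: float) -> np.ndarray:
    n = int(np.floor((rt_end - rt_start) / interval_min)) + 1
    return rt_start + interval_min * np.arange(n)


def _away_from(mz: np.ndarray, protected: np.ndarray, ppm: float) -> np.ndarray:
    """Boolean mask of m/z values at least ``ppm`` away from every protected m/z."""
    if protected.size == 0:
        return np.ones(mz.shape, dtype=bool)
    srt = np.sort(protected)
    idx = np.searchsorted(srt, mz)
    ok = np.ones(mz.shape, dtype=bool)
    for shift in (-1, 0):
        j = np.clip(idx + shift, 0, srt.size - 1)
        ok &= np.abs(mz - srt[j]) > srt[j] * ppm * 1e-6
    return ok


def simulate_cohort(config: SimulationConfig | None = None) -> CohortSimulation:
    """Generate the full 4-group x n-donor PRM cohort with ground truth.

    Deterministic under a fixed ``config.seed``.
    """
    cfg = config or SimulationConfig()
    roster = cfg.roster if cfg.roster is not None else default_roster()
    design = default_design(cfg.n_donors)

    ss = np.random.SeedSequence(cfg.seed)
    cohort_rng = np.random.default_rng(ss.spawn(1)[0])
    sample_seeds = ss.spawn(1 + len(design.sample_ids))[1:]

    decoys = make_decoys([e for e in roster if not e.is_decoy], cfg.n_decoys, cohort_rng)
    entries = tuple(roster) + decoys
    targets = [
        generate_transitions(e.pair, e.charge, e.rt_center, cfg.transition_config)
        for e in entries
    ]

    # Cohort-level draws shared across samples: per-pair base apex and
    # per-transition relative fragment abundances (a pair's fragmentation
    # pattern is a property of the analyte, not of the sample).
    base_apex = cfg.base_apex_mean * np.exp(
        cohort_rng.normal(0.0, cfg.base_apex_cv, size=len(entries))
        - 0.5 * cfg.base_apex_cv**2
    )
    lo_u, hi_u = cfg.fragment_abundance_range
    abundances = [
        cohort_rng.uniform(lo_u, hi_u, size=len(t.transitions)) for t in targets
    ]

    # Interference: unrelated co-isolating peptides assigned to the first
    # n_interference real targets; fragment m/z drawn away from every
    # monitored transition, present in every group at full intensity.
    protected_by_key: dict[float, list[float]] = {}
    for e, t in zip(entries, targets):
        key = _target_key(t.precursor.mz_calc)
        protected_by_key.setdefault(key, []).extend(f.mz for f in t.transitions)
    interference: dict[int, np.ndarray] = {}
    real_indices = [i for i, e in enumerate(entries) if not e.is_decoy]
    for i in real_indices[: cfg.n_interference]:
        key = _target_key(targets[i].precursor.mz_calc)
        protected = np.array(protected_by_key[key])
        draws = cohort_rng.uniform(*cfg.noise_mz_range, size=cfg.interference_fragments * 4)
        draws = draws[_away_from(draws, protected, cfg.noise_exclusion_ppm)]
        interference[i] = draws[: cfg.interference_fragments]

    interval_min = cfg.scan_interval_s / 60.0
    runs: dict[str, PrmRun] = {}
    truth: list[GroundTruthRecord] = []

    for (sample_id, group, donor), sseed in zip(design.samples, sample_seeds):
        rng = np.random.default_rng(sseed)
        mult = cfg.multipliers[group]
        run = PrmRun(sample_id=sample_id, group=group)
        # signal-only peak matrices per entry, for exact ground truth
        signal: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []

        for ei, (entry, target) in enumerate(zip(entries, targets)):
            grid = _scan_grid(target.rt_start, target.rt_end, interval_min)
            tmz = np.array([f.mz for f in target.transitions])
            rt_true = entry.rt_center + rng.normal(0.0, cfg.rt_jitter_sigma_min)
            eps = rng.normal(0.0, cfg.mass_error_ppm_sigma, size=tmz.size)
            obs_mz = tmz * (1.0 + eps * 1e-6)
            if entry.is_decoy or mult == 0.0 or tmz.size == 0:
                apex = 0.0
                inten = np.zeros((grid.size, tmz.size))
            else:
                donor_factor = np.exp(
                    rng.normal(0.0, cfg.donor_cv) - 0.5 * cfg.donor_cv**2
                )
                apex = float(base_apex[ei] * mult * donor_factor)
                amp = apex * abundances[ei]
                profile = np.exp(
                    -0.5 * ((grid - rt_true) / cfg.peak_sigma_min) ** 2
                )
                inten = profile[:, None] * amp[None, :]
            inten = np.where(inten > cfg.min_peak_intensity, inten, 0.0)
            signal.append((grid, obs_mz, inten))

            key = _target_key(target.precursor.mz_calc)
            protected = np.array(protected_by_key[key])
            scans = run.scans_by_target.setdefault(key, [])
            imz = interference.get(ei)
            if imz is not None and imz.size:
                irt = entry.rt_center + cfg.interference_rt_offset_min + rng.normal(
                    0.0, cfg.rt_jitter_sigma_min
                )
                iprofile = cfg.interference_apex * np.exp(
                    -0.5 * ((grid - irt) / cfg.peak_sigma_min) ** 2
                )
            n_noise = cfg.noise_peaks_per_scan
            noise_mz_all = rng.uniform(
                *cfg.noise_mz_range, size=(grid.size, n_noise)
            )
            noise_int_all = rng.exponential(
                cfg.noise_intensity_mean, size=(grid.size, n_noise)
            )
            keep_all = _away_from(
                noise_mz_all.ravel(), protected, cfg.noise_exclusion_ppm
            ).reshape(grid.size, n_noise)
            for si, rt in enumerate(grid):
                keep = keep_all[si]
                mz_parts = [obs_mz[inten[si] > 0], noise_mz_all[si][keep]]
                int_parts = [inten[si][inten[si] > 0], noise_int_all[si][keep]]
                if imz is not None and imz.size and iprofile[si] > cfg.min_peak_intensity:
                    mz_parts.append(imz)
                    int_parts.append(np.full(imz.size, iprofile[si]))
                scans.append(
                    PrmScan(rt=float(rt), mz=np.concatenate(mz_parts),
                            intensity=np.concatenate(int_parts))
                )

        for scans in run.scans_by_target.values():
            scans.sort(key=lambda s: s.rt)
        runs[sample_id] = run

        truth.extend(
            _ground_truth_for_sample(
                cfg, entries, targets, signal, sample_id, group,
            )
        )

    return CohortSimulation(
        config=cfg, design=design, entries=entries, targets=targets,
        runs=runs, truth=truth,
    )


def _ground_truth_for_sample(
    cfg: SimulationConfig,
    entries: Sequence[RosterEntry],
    targets: Sequence[TransitionTarget],
    signal: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray]],
    sample_id: str,
    group: str,
) -> list[GroundTruthRecord]:
    """Exact detectability per (entry, sample) from the injected signal.

    Mirrors the XIC definition on the noise-free injected peaks: per
    transition, the trace is the summed intensity of all injected peaks of
    the same isolation-target group within the extraction tolerance; the
    apex intensity and intensity-weighted m/z at the apex are then held to
    the cascade thresholds. Targets sharing one isolation key (isomeric
    precursors) cross-contribute, exactly as in the assembled run.
    """
    fc = cfg.reference_filters
    # group injected peaks by isolation key
    by_key: dict[float, list[int]] = {}
    for ei, t in enumerate(targets):
        by_key.setdefault(_target_key(t.precursor.mz_calc), []).append(ei)

    records = []
    for ei, (entry, target) in enumerate(zip(entries, targets)):
        grid, _, inten = signal[ei]
        apex_injected = float(inten.max()) if inten.size else 0.0
        key = _target_key(target.precursor.mz_calc)
        siblings = by_key[key]
        n_det = 0
        if target.transitions:
            # merged injected peak lists across isomeric siblings
            merged = []
            for sj in siblings:
                g, omz, sint = signal[sj]
                for si in range(g.size):
                    merged.append((g[si], omz, sint[si]))
            merged.sort(key=lambda x: x[0])

            tmz = np.array([f.mz for f in target.transitions])
            idx_ok = np.array(
                [f.index >= fc.min_fragment_index for f in target.transitions]
            )
            lo = tmz * (1.0 - fc.extract_ppm * 1e-6)
            hi = tmz * (1.0 + fc.extract_ppm * 1e-6)
            rt_lo, rt_hi = target.rt_window
            n_scans = sum(1 for rt, _, _ in merged if rt_lo <= rt <= rt_hi)
            trace = np.zeros((n_scans, tmz.size))
            wmz = np.zeros((n_scans, tmz.size))
            si = 0
            for rt, omz, row in merged:
                if not (rt_lo <= rt <= rt_hi):
                    continue
                present = row > 0
                if present.any():
                    pm, pi = omz[present], row[present]
                    o = np.argsort(pm)
                    pm, pi = pm[o], pi[o]
                    ci = np.concatenate(([0.0], np.cumsum(pi)))
                    cim = np.concatenate(([0.0], np.cumsum(pi * pm)))
                    a = np.searchsorted(pm, lo, side="left")
                    b = np.searchsorted(pm, hi, side="right")
                    trace[si] = ci[b] - ci[a]
                    wmz[si] = cim[b] - cim[a]
                si += 1
            for ti in range(tmz.size):
                if not idx_ok[ti]:
                    continue
                col = trace[:, ti]
                if not col.size:
                    continue
                k = int(np.argmax(col))
                apex = col[k]
                if apex <= fc.noise_floor:
                    continue
                measured = wmz[k, ti] / apex
                if abs(measured - tmz[ti]) / tmz[ti] * 1e6 > fc.accept_ppm:
                    continue
                n_det += 1
        short = min(len(entry.pair.peptide_a), len(entry.pair.peptide_b))
        detectable = (
            not entry.is_decoy
            and short >= fc.min_peptide_len
            and n_det >= fc.min_transitions
        )
        records.append(
            GroundTruthRecord(
                entry_label=entry.label,
                pair_label=entry.pair.label,
                charge=entry.charge,
                sample_id=sample_id,
                group=group,
                is_decoy=entry.is_decoy,
                injected_apex=apex_injected,
                true_rt=entry.rt_center,
                n_detectable_transitions=n_det,
                detectable=detectable,
            )
        )
    return records


def simulate_prm_run(
    config: SimulationConfig, sample_id: str
) -> tuple[PrmRun, list[GroundTruthRecord]]:
    """One sample's PRM run plus its ground truth (see simulate_cohort).

    Generated within the full cohort so cohort-level draws (base apexes,
    fragment abundances, decoy sequences) are identical whichever sample is
    requested.
    """
    sim = simulate_cohort(config)
    return sim.runs[sample_id], [t for t in sim.truth if t.sample_id == sample_id]


def write_ground_truth(truth: Sequence[GroundTruthRecord], path) -> None:
    pd.DataFrame([vars(t) for t in truth]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# DDA (discovery-stage) simulation


@dataclass
class DdaGroundTruth:
    """Which spectra are condition-unique and which are too heavy."""

    unique_titles_by_group: dict[str, set[str]]
    heavy_titles: set[str]


def simulate_dda_mgf(
    config: SimulationConfig | None = None,
    n_background: int = 30,
    presence_groups: tuple[str, ...] = ("S", "F"),
    mz_tol: float = 0.01,
    rt_tol: float = 2.0,
) -> tuple[dict[str, list[Ms2Spectrum]], DdaGroundTruth]:
    """Synthetic DDA spectra per group, with known group-unique spectra.

    Each real roster pair yields one spectrum, assigned round-robin to a
    single group of ``presence_groups`` (so the group-uniqueness filter has
    a known expected output); background spectra are present in every group
    at identical precursor m/z, charge and RT. Fragment peaks are the
    theoretical transition m/z values with arbitrary intensities.

    The ground truth accounts for near-isobaric co-eluting roster pairs
    assigned to different groups (same charge, precursor m/z within
    ``mz_tol``, RT within ``rt_tol``): such spectra are condition-shared by
    definition and are expected to be removed from every group involved.
    """
    cfg = config or SimulationConfig()
    roster = cfg.roster if cfg.roster is not None else default_roster()
    entries = [e for e in roster if not e.is_decoy]
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xDDA)))

    by_group: dict[str, list[Ms2Spectrum]] = {g: [] for g in GROUPS}
    unique: dict[str, set[str]] = {g: set() for g in GROUPS}
    heavy: set[str] = set()

    xl_spectra: list[Ms2Spectrum] = []
    for i, entry in enumerate(entries):
        target = generate_transitions(
            entry.pair, entry.charge, entry.rt_center, cfg.transition_config
        )
        if target.excluded:
            continue
        g = presence_groups[i % len(presence_groups)]
        title = f"xl_{i}_{entry.label}"
        mz = np.array([f.mz for f in target.transitions])
        spec = Ms2Spectrum(
            precursor_mz=target.precursor.mz_calc,
            precursor_charge=entry.charge,
            rt=entry.rt_center + float(rng.normal(0.0, cfg.rt_jitter_sigma_min)),
            mz=mz,
            intensity=rng.uniform(1e3, 1e5, size=mz.size),
            sample_id=f"{g}_dda",
            group=g,
            title=title,
        )
        by_group[g].append(spec)
        xl_spectra.append(spec)
        unique[g].add(title)
        if spec.neutral_mass > 8000.0:
            heavy.add(title)

    for i, sa in enumerate(xl_spectra):
        for sb in xl_spectra[i + 1:]:
            if (
                sa.group != sb.group
                and sa.precursor_charge == sb.precursor_charge
                and abs(sa.precursor_mz - sb.precursor_mz) <= mz_tol
                and abs(sa.rt - sb.rt) <= rt_tol
            ):
                unique[sa.group].discard(sa.title)
                unique[sb.group].discard(sb.title)

    for b in range(n_background):
        pre_mz = float(rng.uniform(500.0, 1500.0))
        rt = float(rng.uniform(10.0, 180.0))
        frag = np.sort(rng.uniform(*cfg.noise_mz_range, size=12))
        inten = rng.uniform(1e3, 1e5, size=frag.size)
        for g in GROUPS:
            by_group[g].append(
                Ms2Spectrum(
                    precursor_mz=pre_mz,
                    precursor_charge=4,
                    rt=rt,
                    mz=frag.copy(),
                    intensity=inten.copy(),
                    sample_id=f"{g}_dda",
                    group=g,
                    title=f"bg_{b}",
                )
            )
    return by_group, DdaGroundTruth(unique_titles_by_group=unique, heavy_titles=heavy)
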