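"""Monoisotopic mass and m/z arithmetic for formaldehyde-crosslinked peptides.

Formaldehyde bridges two peptides and shows up in MS as a nominal +12 Da
(one bridging carbon, methylene class) or +24 Da mass addition on the pair.
This module computes theoretical precursor m/z for such pairs, enumerates
b/y fragment transitions with and without the crosslink mass shift, and
exports scheduled-PRM transition lists.

Conventions: exact crosslink masses 12.000 / 24.000 Da (one / two carbon
atoms), proton 1.007276 Da, water 18.010565 Da, carbamidomethyl +57.02146 Da
fixed on every cysteine (iodoacetamide alkylation).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from pyteomics import mass as _ptmass

PROTON_MASS = 1.007276
WATER_MASS = 18.010565
CARBAMIDOMETHYL = 57.02146

#: Monoisotopic residue (amino-acid minus water) masses, Da.
RESIDUE_MASSES: dict[str, float] = dict(_ptmass.std_aa_mass)

#: Default fixed modifications: carbamidomethyl on cysteine.
DEFAULT_FIXED_MODS: dict[str, float] = {"C": CARBAMIDOMETHYL}

CROSSLINK_MASSES = (12.000, 24.000)

_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class UnknownResidueError(ValueError):
    """A sequence contains a character outside the 20 standard letters."""


@dataclass(frozen=True)
class PeptideSequence:
    """A linear peptide with fixed modifications.

    Parameters
    ----------
    residues:
        Sequence over the 20 standard one-letter amino-acid codes.
    fixed_mods:
        Mapping residue letter -> mass delta (Da) applied to every
        occurrence. Defaults to carbamidomethyl on cysteine.
    """

    residues: str
    fixed_mods: tuple[tuple[str, float], ...] = (("C", CARBAMIDOMETHYL),)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("peptide sequence must contain at least one residue")
        for pos, ch in enumerate(self.residues):
            if ch not in _VALID_RESIDUES:
                raise UnknownResidueError(
                    f"unknown residue {ch!r} at position {pos} in {self.residues!r}"
                )
        for res, delta in self.fixed_mods:
            if not (delta >= 0.0 and delta == delta):
                raise ValueError(f"fixed-mod delta for {res!r} must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    @property
    def mod_map(self) -> dict[str, float]:
        return dict(self.fixed_mods)

    def residue_mass(self, index: int) -> float:
        """Monoisotopic mass of residue ``index`` including fixed mods."""
        ch = self.residues[index]
        return RESIDUE_MASSES[ch] + self.mod_map.get(ch, 0.0)


def as_peptide(seq: "PeptideSequence | str") -> PeptideSequence:
    return seq if isinstance(seq, PeptideSequence) else PeptideSequence(seq)


@dataclass(frozen=True)
class CrosslinkPair:
    """Two peptides joined by a formaldehyde crosslink of +12 or +24 Da.

    The pair is order-normalized (lexicographically smaller sequence first)
    so A—B and B—A compare equal; self-pairs are allowed.
    """

    peptide_a: PeptideSequence
    peptide_b: PeptideSequence
    crosslink_mass: float

    def __post_init__(self) -> None:
        if self.crosslink_mass not in CROSSLINK_MASSES:
            raise ValueError(
                f"crosslink mass must be one of {CROSSLINK_MASSES}, "
                f"got {self.crosslink_mass}"
            )
        a, b = self.peptide_a, self.peptide_b
        if b.residues < a.residues:
            object.__setattr__(self, "peptide_a", b)
            object.__setattr__(self, "peptide_b", a)

    @classmethod
    def from_sequences(
        cls, seq_a: str, seq_b: str, crosslink_mass: float
    ) -> "CrosslinkPair":
        return cls(PeptideSequence(seq_a), PeptideSequence(seq_b), float(crosslink_mass))

    @property
    def label(self) -> str:
        return f"{self.peptide_a}--{self.peptide_b}+{self.crosslink_mass:g}"


@dataclass(frozen=True)
class PrecursorIon:
    """One (pair, charge) PRM target with its scheduled retention time."""

    pair: CrosslinkPair
    charge: int
    mz_calc: float
    rt_center: float

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.mz_calc <= 0:
            raise ValueError("mz_calc must be positive")
        if self.rt_center < 0:
            raise ValueError("rt_center must be >= 0")


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical b/y fragment of one peptide of a crosslinked pair."""

    source: Literal["a", "b"]
    series: Literal["b", "y"]
    index: int
    charge: int
    carries_shift: bool
    mz: float

    @property
    def name(self) -> str:
        suffix = "+CM" if self.carries_shift else ""
        return f"{self.source}.{self.series}{self.index}+{self.charge}{suffix}"


def peptide_mono_mass(seq: "PeptideSequence | str") -> float:
    """Neutral monoisotopic mass of a peptide, Da.

    Sum of residue masses plus fixed-modification deltas plus one water.
    """
    pep = as_peptide(seq)
    return sum(pep.residue_mass(i) for i in range(len(pep))) + WATER_MASS


def crosslink_precursor_mz(pair: CrosslinkPair, charge: int) -> float:
    """Theoretical m/z of the crosslinked pair at the given charge.

    (M_a + M_b + CM + z * m_proton) / z, with M the neutral peptide masses
    and CM the crosslink mass class (+12 or +24 Da).
    """
    if charge < 1:
        raise ValueError("charge must be >= 1")
    total = (
        peptide_mono_mass(pair.peptide_a)
        + peptide_mono_mass(pair.peptide_b)
        + pair.crosslink_mass
    )
    return (total + charge * PROTON_MASS) / charge


def fragment_mz(
    seq: "PeptideSequence | str",
    series: str,
    index: int,
    charge: int,
    extra_mass: float = 0.0,
) -> float:
    """m/z of a b- or y-series fragment, optionally carrying an extra mass.

    ``extra_mass`` is 0 for plain fragments or the crosslink mass for
    shift-carrying variants.
    """
    pep = as_peptide(seq)
    n = len(pep)
    if not 1 <= index <= n - 1:
        raise ValueError(f"fragment index {index} out of range for length-{n} peptide")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    if extra_mass < 0:
        raise ValueError("extra_mass must be >= 0")
    if series == "b":
        core = sum(pep.residue_mass(i) for i in range(index))
    elif series == "y":
        core = sum(pep.residue_mass(i) for i in range(n - index, n)) + WATER_MASS
    else:
        raise ValueError(f"series must be 'b' or 'y', got {series!r}")
    return (core + extra_mass + charge * PROTON_MASS) / charge


@dataclass(frozen=True)
class TransitionConfig:
    """Knobs for transition enumeration.

    min_fragment_index drops short, poorly sequence-specific b/y ions
    (default 3: ions of fewer than 3 residues are omitted). Each fragment is
    emitted with and without the crosslink mass when shift variants are on.
    """

    fragment_charges: tuple[int, ...] = (1, 2)
    min_fragment_index: int = 3
    include_shift_variants: bool = True
    min_peptide_length: int = 7
    rt_half_window: float = 3.0


@dataclass
class TransitionTarget:
    """A PRM target: one precursor with its theoretical transitions."""

    precursor: PrecursorIon
    transitions: list[FragmentIon] = field(default_factory=list)
    rt_start: float = 0.0
    rt_end: float = 0.0
    excluded: bool = False
    exclusion_reason: str | None = None

    @property
    def rt_window(self) -> tuple[float, float]:
        return (self.rt_start, self.rt_end)


def generate_transitions(
    pair: CrosslinkPair,
    charge: int,
    rt_center: float,
    config: TransitionConfig | None = None,
) -> TransitionTarget:
    """Enumerate theoretical b/y transitions for one crosslinked precursor.

    Emits, for each constituent peptide, all b and y ions with index >=
    ``config.min_fragment_index`` up to length-1, at each configured
    fragment charge, with and without a flat crosslink-mass addition.
    Pairs containing a peptide shorter than ``config.min_peptide_length``
    return a flagged-excluded target with no transitions (kept so exclusion
    reports can enumerate them). The retention-time window is
    rt_center +/- config.rt_half_window.
    """
    cfg = config or TransitionConfig()
    precursor = PrecursorIon(
        pair=pair,
        charge=charge,
        mz_calc=crosslink_precursor_mz(pair, charge),
        rt_center=rt_center,
    )
    target = TransitionTarget(
        precursor=precursor,
        rt_start=max(rt_center - cfg.rt_half_window, 0.0),
        rt_end=rt_center + cfg.rt_half_window,
    )
    short = [
        str(p)
        for p in (pair.peptide_a, pair.peptide_b)
        if len(p) < cfg.min_peptide_length
    ]
    if short:
        target.excluded = True
        target.exclusion_reason = (
            f"peptide(s) shorter than {cfg.min_peptide_length} residues: "
            + ", ".join(sorted(set(short)))
        )
        return target

    shift_states = (False, True) if cfg.include_shift_variants else (False,)
    seen: set[tuple[str, str, int, int, bool]] = set()
    for source, pep in (("a", pair.peptide_a), ("b", pair.peptide_b)):
        for series in ("b", "y"):
            for index in range(cfg.min_fragment_index, len(pep)):
                for fz in cfg.fragment_charges:
                    for carries in shift_states:
                        key = (source, series, index, fz, carries)
                        if key in seen:
                            continue
                        seen.add(key)
                        extra = pair.crosslink_mass if carries else 0.0
                        target.transitions.append(
                            FragmentIon(
                                source=source,
                                series=series,
                                index=index,
                                charge=fz,
                                carries_shift=carries,
                                mz=fragment_mz(pep, series, index, fz, extra),
                            )
                        )
    return target


_TRANSITION_COLUMNS = (
    "precursor_mz",
    "precursor_charge",
    "fragment_mz",
    "fragment_name",
    "rt_start",
    "rt_end",
)


def write_transition_list(targets: Iterable[TransitionTarget], path) -> None:
    """Export targets as a delimited scheduled-PRM transition list (TSV)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_TRANSITION_COLUMNS)
        for target in targets:
            for frag in target.transitions:
                writer.writerow(
                    [
                        f"{target.precursor.mz_calc:.6f}",
                        target.precursor.charge,
                        f"{frag.mz:.6f}",
                        frag.name,
                        f"{target.rt_start:.3f}",
                        f"{target.rt_end:.3f}",
                    ]
                )


def targets_from_table(
    rows: Sequence, config: TransitionConfig | None = None
) -> list[TransitionTarget]:
    """Build one TransitionTarget per (row, charge) entry of a crosslink table.

    ``rows`` are fixture-style records with pair, z_list and rt_list
    attributes (see :mod:`xlinkprm.tables`).
    """
    targets = []
    for row in rows:
        for z, rt in zip(row.z_list, row.rt_list):
            targets.append(generate_transitions(row.pair, z, rt, config))
    return targets
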