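"""Packaged crosslink and protein-annotation tables and their consistency checks.

The package ships the validated Streck-tube crosslink roster (45 peptide
pairs, 57 precursor ions across charge states, each with calculated and
observed m/z, crosslink mass class and average retention time) and the
protein annotations joined 1:1 by crosslink id. ``verify_table1``
recomputes every calculated precursor m/z from the sequences alone and
reports the deviations, which pins the package's mass conventions to the
published values.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .chem import CrosslinkPair, crosslink_precursor_mz

TABLE1_RESOURCE = "table1_crosslinks.tsv"
TABLE2_RESOURCE = "table2_proteins.tsv"


@dataclass(frozen=True)
class Table1Row:
    """One validated crosslinked pair with its per-charge-state entries."""

    id: int
    pair: CrosslinkPair
    #: sequences in the published order, which carries the protein-annotation
    #: association (pair normalization may swap them)
    peptides_as_printed: tuple[str, str]
    z_list: tuple[int, ...]
    mz_calc_list: tuple[float, ...]
    mz_obs_list: tuple[float, ...]
    cm: int
    rt_list: tuple[float, ...]
    isotope_error_flag: bool

    def __post_init__(self) -> None:
        n = len(self.z_list)
        if not (len(self.mz_calc_list) == len(self.mz_obs_list) == len(self.rt_list) == n):
            raise ValueError(f"row {self.id}: per-charge lists have unequal lengths")
        if self.cm not in (12, 24):
            raise ValueError(f"row {self.id}: crosslink mass class must be 12 or 24")


@dataclass(frozen=True)
class ProteinAnnotation:
    name: str
    mw_kda: str
    gene: str
    uniprot: str

    @property
    def accessions(self) -> tuple[str, ...]:
        """UniProt accessions; more than one when the peptide is shared."""
        return tuple(self.uniprot.split("/"))


@dataclass(frozen=True)
class Table2Row:
    id: int
    protein_1: ProteinAnnotation
    protein_2: ProteinAnnotation


def _data_path(name: str):
    return resources.files("xlinkprm.data").joinpath(name)


def load_table1(path=None) -> list[Table1Row]:
    """Load the packaged crosslink table (or a user table in the same format)."""
    src = path if path is not None else _data_path(TABLE1_RESOURCE)
    df = pd.read_csv(src, sep="\t", dtype=str)
    required = {
        "id", "peptide_a", "peptide_b", "cm", "z_list",
        "mz_calc_list", "mz_obs_list", "rt_list", "isotope_error_flag",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"crosslink table missing column(s): {sorted(missing)}")
    rows = []
    for rec in df.itertuples(index=False):
        rows.append(
            Table1Row(
                id=int(rec.id),
                pair=CrosslinkPair.from_sequences(
                    rec.peptide_a, rec.peptide_b, float(rec.cm)
                ),
                peptides_as_printed=(rec.peptide_a, rec.peptide_b),
                z_list=tuple(int(z) for z in rec.z_list.split()),
                mz_calc_list=tuple(float(v) for v in rec.mz_calc_list.split()),
                mz_obs_list=tuple(float(v) for v in rec.mz_obs_list.split()),
                cm=int(rec.cm),
                rt_list=tuple(float(v) for v in rec.rt_list.split()),
                isotope_error_flag=bool(int(rec.isotope_error_flag)),
            )
        )
    return rows


def load_table2(path=None) -> list[Table2Row]:
    src = path if path is not None else _data_path(TABLE2_RESOURCE)
    df = pd.read_csv(src, sep="\t", dtype=str)
    rows = []
    for rec in df.itertuples(index=False):
        rows.append(
            Table2Row(
                id=int(rec.id),
                protein_1=ProteinAnnotation(rec.name_1, rec.mw_1, rec.gene_1, rec.uniprot_1),
                protein_2=ProteinAnnotation(rec.name_2, rec.mw_2, rec.gene_2, rec.uniprot_2),
            )
        )
    return rows


def verify_table1(rows: list[Table1Row], tolerance: float = 0.005) -> pd.DataFrame:
    """Recompute every calculated precursor m/z and report per-entry deviations.

    Returns one record per (row, charge) entry with the recomputed m/z,
    |recomputed - calc| (``calc_delta``), |obs - calc| (``obs_delta``), a
    ``calc_ok`` flag at ``tolerance`` (Th) and an ``obs_exempt`` flag for
    entries where the discovery search reported an isotope (monoisotopic
    peak assignment) error: those are exempt from the observed-vs-calculated
    comparison but still recomputed.
    """
    records = []
    for row in rows:
        for z, mz_calc, mz_obs, rt in zip(
            row.z_list, row.mz_calc_list, row.mz_obs_list, row.rt_list
        ):
            recomputed = crosslink_precursor_mz(row.pair, z)
            records.append(
                {
                    "id": row.id,
                    "z": z,
                    "mz_calc": mz_calc,
                    "mz_recomputed": recomputed,
                    "mz_obs": mz_obs,
                    "rt": rt,
                    "calc_delta": abs(recomputed - mz_calc),
                    "obs_delta": abs(mz_obs - mz_calc),
                    "calc_ok": abs(recomputed - mz_calc) <= tolerance,
                    "obs_exempt": row.isotope_error_flag,
                }
            )
    return pd.DataFrame.from_records(records)


def special_case_peptide_report(
    table1: list[Table1Row] | None = None,
    table2: list[Table2Row] | None = None,
) -> dict[str, tuple[str, ...]]:
    """Peptides whose protein assignment is ambiguous in the annotations.

    Maps each peptide sequence that carries more than one UniProt accession
    to its accession tuple. On the packaged tables exactly one peptide
    (AVFPSIVGRPR, shared between a POTE-family protein and cytoplasmic
    actin) is ambiguous; the other 67 of the 68 distinct peptides match a
    single protein.
    """
    t1 = table1 if table1 is not None else load_table1()
    t2 = table2 if table2 is not None else load_table2()
    annot = {row.id: row for row in t2}
    ambiguous: dict[str, tuple[str, ...]] = {}
    for row in t1:
        a2 = annot.get(row.id)
        if a2 is None:
            continue
        for pep, prot in zip(row.peptides_as_printed, (a2.protein_1, a2.protein_2)):
            if len(prot.accessions) > 1:
                ambiguous[pep] = prot.accessions
    return ambiguous


def distinct_peptides(rows: list[Table1Row]) -> set[str]:
    """Distinct peptide sequences across all pair slots (exact string identity)."""
    peptides: set[str] = set()
    for row in rows:
        peptides.add(str(row.pair.peptide_a))
        peptides.add(str(row.pair.peptide_b))
    return peptides
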