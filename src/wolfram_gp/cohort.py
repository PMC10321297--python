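"""Patient-registry I/O, eligibility filtering and dose-group assignment.

The registry is a delimited text table, one row per patient: an identifier,
sex, the two allele descriptors in protein-level HGVS-style notation, and
numeric ages of onset (years) for the four cardinal manifestations —
diabetes mellitus (DM), optic atrophy (OA), diabetes insipidus (DI) and
sensorineural hearing loss (HL).  Empty cells mean absent.

Eligibility is per manifestation: a patient is analyzed for a manifestation
only if (i) both allele descriptors are present and classify NSFS or
in-frame, and (ii) a numeric onset age for that manifestation is recorded.
Exclusions carry machine-readable reasons so a run manifest can account for
every dropped row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

from .domains import DomainTable, count_tm_inframe
from .variants import (
    BroadClass,
    ProteinVariant,
    broad_class,
    count_nsfs_alleles,
    parse_protein_descriptor,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Manifestation",
    "Sex",
    "PatientRecord",
    "GroupedPatient",
    "Exclusion",
    "SchemaError",
    "REGISTRY_COLUMNS",
    "read_registry",
    "records_from_frame",
    "filter_eligible",
]


class Manifestation(Enum):
    DM = "DM"
    OA = "OA"
    DI = "DI"
    HL = "HL"


class Sex(Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


ONSET_COLUMNS = {
    Manifestation.DM: "onset_dm",
    Manifestation.OA: "onset_oa",
    Manifestation.DI: "onset_di",
    Manifestation.HL: "onset_hl",
}
REGISTRY_COLUMNS = (
    "patient_id",
    "sex",
    "allele1",
    "allele2",
    "onset_dm",
    "onset_oa",
    "onset_di",
    "onset_hl",
)


class SchemaError(ValueError):
    """Registry file does not conform to the documented schema."""


@dataclass(frozen=True)
class PatientRecord:
    """One registry row; onset ages in years, absent entries omitted from the map."""

    patient_id: str
    sex: Sex
    allele1_text: str | None
    allele2_text: str | None
    onset: dict[Manifestation, float] = field(default_factory=dict)
    source: str = "registry"


@dataclass(frozen=True)
class GroupedPatient:
    """An eligible patient with parsed alleles and dose-group assignments.

    ``tm_dose`` is defined iff the genotype has at least one in-frame allele
    and a domain table was supplied.
    """

    record: PatientRecord
    allele1: ProteinVariant
    allele2: ProteinVariant
    nsfs_dose: int
    tm_dose: int | None
    onset_age: float


@dataclass(frozen=True)
class Exclusion:
    patient_id: str
    reason: str  # missing_allele | unparseable_allele | missing_onset


def _parse_sex(value: object) -> Sex:
    text = str(value).strip().lower() if value is not None else ""
    if text in ("male", "m"):
        return Sex.MALE
    if text in ("female", "f"):
        return Sex.FEMALE
    return Sex.UNKNOWN


def read_registry(path: str | Path) -> list[PatientRecord]:
    """Read a registry TSV/CSV into :class:`PatientRecord` rows.

    The delimiter is chosen from the extension (``.csv`` comma, anything
    else tab).  Non-numeric or negative onset entries (e.g. ``"childhood"``)
    are recorded as absent with a logged warning — such records are later
    excluded per manifestation for lacking a numerical age of onset.

    Raises
    ------
    SchemaError
        If a required column is missing or a patient_id is duplicated.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return records_from_frame(frame)


def records_from_frame(frame: pd.DataFrame) -> list[PatientRecord]:
    """Validate a registry DataFrame (string cells) and build records."""
    missing = [c for c in REGISTRY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"registry is missing required column(s): {missing}")
    ids = frame["patient_id"].astype(str)
    dupes = ids[ids.duplicated()].unique().tolist()
    if dupes:
        raise SchemaError(f"duplicate patient_id(s): {dupes}")

    records: list[PatientRecord] = []
    for row in frame.itertuples(index=False):
        onset: dict[Manifestation, float] = {}
        for manif, col in ONSET_COLUMNS.items():
            cell = str(getattr(row, col)).strip()
            if not cell or cell.lower() in ("na", "nan", "none"):
                continue
            try:
                age = float(cell)
            except ValueError:
                logger.warning(
                    "patient %s: non-numeric %s age %r recorded as absent",
                    row.patient_id, manif.value, cell,
                )
                continue
            if not (age >= 0.0) or age != age or age == float("inf"):
                logger.warning(
                    "patient %s: invalid %s age %r recorded as absent",
                    row.patient_id, manif.value, cell,
                )
                continue
            onset[manif] = age
        a1 = str(row.allele1).strip() or None
        a2 = str(row.allele2).strip() or None
        source = str(getattr(row, "source", "registry")).strip() or "registry"
        records.append(
            PatientRecord(
                patient_id=str(row.patient_id),
                sex=_parse_sex(row.sex),
                allele1_text=a1,
                allele2_text=a2,
                onset=onset,
                source=source,
            )
        )
    return records


def filter_eligible(
    cohort: list[PatientRecord],
    manifestation: Manifestation,
    domains: DomainTable | None = None,
    exclusions: list[Exclusion] | None = None,
) -> list[GroupedPatient]:
    """Apply the eligibility filters for one manifestation and assign doses.

    Retains patients with both allele descriptors present and parsing to a
    usable class (NSFS or in-frame) and a numeric onset age for
    ``manifestation``; attaches ``nsfs_dose`` and, when ``domains`` is given
    and the genotype carries an in-frame allele, ``tm_dose``.

    Pass a list as ``exclusions`` to collect one :class:`Exclusion` per
    dropped patient (reasons: ``missing_allele``, ``unparseable_allele``,
    ``missing_onset``).  An empty result is valid.
    """
    eligible: list[GroupedPatient] = []
    for rec in cohort:
        if rec.allele1_text is None or rec.allele2_text is None:
            if exclusions is not None:
                exclusions.append(Exclusion(rec.patient_id, "missing_allele"))
            continue
        v1 = parse_protein_descriptor(rec.allele1_text)
        v2 = parse_protein_descriptor(rec.allele2_text)
        if broad_class(v1) is BroadClass.OTHER or broad_class(v2) is BroadClass.OTHER:
            if exclusions is not None:
                exclusions.append(Exclusion(rec.patient_id, "unparseable_allele"))
            continue
        if manifestation not in rec.onset:
            if exclusions is not None:
                exclusions.append(Exclusion(rec.patient_id, "missing_onset"))
            continue
        nsfs_dose = count_nsfs_alleles(v1, v2)
        tm_dose: int | None = None
        if domains is not None and nsfs_dose < 2:
            tm_dose = count_tm_inframe(v1, v2, domains)
        eligible.append(
            GroupedPatient(
                record=rec,
                allele1=v1,
                allele2=v2,
                nsfs_dose=nsfs_dose,
                tm_dose=tm_dose,
                onset_age=rec.onset[manifestation],
            )
        )
    return eligible
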