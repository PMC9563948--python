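"""Cohort-level survival data: types, validation, I/O and curation transforms.

One :class:`Cohort` is one published patient cohort: its radiotherapy
schedule (total dose ``D``, dose-per-fraction ``d``, duration ``T``),
treatment type (RT alone, sequential or concurrent chemo-RT), stage mix,
observed 2-year overall survival and patient number.  Published survival
percentages are converted once, at load time, to integer survivor counts so
downstream likelihood code consumes a proper binomial outcome ``(x, N)``.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import pandas as pd

from .exceptions import SchemaError, ValidationError

STAGES = ("I", "II", "IIIA", "IIIB")
HISTOLOGIES = ("squamous", "adeno", "other")
TREATMENTS = ("RT", "sCRT", "cCRT")

#: Reference year for the publication-year covariate Y = max(REF_YEAR - year, 0).
REF_YEAR = 2016

#: Multiplicative dose correction applied to schedules planned without lung
#: tissue heterogeneity corrections.
HET_CORRECTION_FACTOR = 1.05

CSV_COLUMNS = [
    "id", "study", "publication_year", "treatment", "n_patients", "os2_pct",
    "dose_gy", "dose_per_fraction_gy", "n_fractions", "duration_days",
    "f_stage_I", "f_stage_II", "f_stage_IIIA", "f_stage_IIIB",
    "het_corrected", "f_squamous", "f_adeno", "f_other",
]
_REQUIRED_COLUMNS = CSV_COLUMNS[:15]
_OPTIONAL_COLUMNS = CSV_COLUMNS[15:]


class CohortType(enum.Enum):
    """Cohort classification by the IIIB/IIIA patient-fraction ratio."""

    MORE_IIIA = "MoreIIIA"
    MORE_IIIB = "MoreIIIB"
    BALANCED = "Balanced"


@dataclass(frozen=True)
class Cohort:
    """One published patient cohort.

    Parameters
    ----------
    id : str
        Unique cohort identifier.
    n_patients : int
        Number of patients, ``N >= 1``.
    os2_observed : float
        Observed 2-year overall survival in percent, ``[0, 100]``.
    treatment : str
        One of ``"RT"``, ``"sCRT"``, ``"cCRT"``.
    dose_gy : float
        Prescribed total dose ``D`` in Gy.
    dose_per_fraction_gy : float
        Dose-per-fraction ``d`` in Gy.
    n_fractions : int
        Number of fractions.
    duration_days : float
        Overall radiotherapy duration ``T`` in days.
    stage_fractions : mapping
        Patient fraction per stage ``I, II, IIIA, IIIB``; sums to 1.
    publication_year : int
        Calendar year of the source publication.
    het_corrected : bool
        Whether the source doses already include lung heterogeneity
        corrections.
    histology_fractions : mapping, optional
        Patient fraction per histology ``squamous, adeno, other``; sums to 1
        when present.
    study : str
        Source study label (several cohorts may share one study).
    """

    id: str
    n_patients: int
    os2_observed: float
    treatment: str
    dose_gy: float
    dose_per_fraction_gy: float
    n_fractions: int
    duration_days: float
    stage_fractions: Mapping[str, float]
    publication_year: int
    het_corrected: bool = True
    histology_fractions: Optional[Mapping[str, float]] = None
    study: str = ""

    def __post_init__(self):
        self._validate()

    def _validate(self) -> None:
        rid = self.id
        if self.n_patients < 1:
            raise ValidationError(f"cohort {rid!r}: n_patients must be >= 1")
        if not 0.0 <= self.os2_observed <= 100.0:
            raise ValidationError(
                f"cohort {rid!r}: os2_observed {self.os2_observed} outside [0, 100]"
            )
        if self.treatment not in TREATMENTS:
            raise ValidationError(
                f"cohort {rid!r}: treatment {self.treatment!r} not in {TREATMENTS}"
            )
        if self.dose_gy < 0 or self.dose_per_fraction_gy < 0:
            raise ValidationError(f"cohort {rid!r}: doses must be non-negative")
        if self.n_fractions < 1:
            raise ValidationError(f"cohort {rid!r}: n_fractions must be >= 1")
        if self.duration_days < 1:
            raise ValidationError(f"cohort {rid!r}: duration_days must be >= 1")
        missing = [s for s in STAGES if s not in self.stage_fractions]
        if missing:
            raise ValidationError(f"cohort {rid!r}: missing stage fractions {missing}")
        total = sum(self.stage_fractions[s] for s in STAGES)
        if abs(total - 1.0) > 1e-6:
            raise ValidationError(
                f"cohort {rid!r}: stage fractions sum to {total:.6f}, not 1"
            )
        if any(self.stage_fractions[s] < -1e-12 for s in STAGES):
            raise ValidationError(f"cohort {rid!r}: negative stage fraction")
        if self.histology_fractions is not None:
            htot = sum(self.histology_fractions.get(h, 0.0) for h in HISTOLOGIES)
            if abs(htot - 1.0) > 1e-6:
                raise ValidationError(
                    f"cohort {rid!r}: histology fractions sum to {htot:.6f}, not 1"
                )
        # Published schedules round doses: consistency is advisory only.
        expected = self.dose_per_fraction_gy * self.n_fractions
        if expected > 0 and abs(self.dose_gy - expected) > 0.05 * expected:
            warnings.warn(
                f"cohort {rid!r}: dose_gy {self.dose_gy} differs from "
                f"d x n_fractions = {expected:.2f} by more than 5%",
                stacklevel=3,
            )

    @property
    def years_before_reference(self) -> float:
        """Publication-year covariate ``Y = max(2016 - year, 0)``."""
        return max(REF_YEAR - self.publication_year, 0)

    @property
    def survivors(self) -> int:
        """Integer 2-year survivor count, rounded half-up from the OS rate."""
        return survivors_from_os(self.os2_observed, self.n_patients)


def survivors_from_os(os2_pct: float, n: int) -> int:
    """Convert a published OS percentage to an integer survivor count.

    Rounds half-up so that e.g. 35.3% of 51 patients (18.003) gives 18
    and exactly-half values round towards the larger count.
    """
    if not 0.0 <= os2_pct <= 100.0:
        raise ValidationError(f"os2_pct {os2_pct} outside [0, 100]")
    if n < 1:
        raise ValidationError(f"n {n} must be >= 1")
    x = math.floor(os2_pct / 100.0 * n + 0.5)
    return min(max(x, 0), n)


def apply_heterogeneity_correction(c: Cohort) -> Cohort:
    """Scale prescribed dose and dose-per-fraction by 5%.

    Schedules planned without lung-tissue heterogeneity corrections
    understate the dose actually delivered to tumour; their tabulated doses
    are raised by 5% to put all cohorts on a heterogeneity-corrected scale.
    A no-op (with a warning) on cohorts already corrected.
    """
    if c.het_corrected:
        warnings.warn(f"cohort {c.id!r} is already heterogeneity-corrected")
        return c
    return replace(
        c,
        dose_gy=c.dose_gy * HET_CORRECTION_FACTOR,
        dose_per_fraction_gy=c.dose_per_fraction_gy * HET_CORRECTION_FACTOR,
        het_corrected=True,
    )


def classify_cohort_type(c: Cohort) -> CohortType:
    """Classify a cohort by its IIIB/IIIA patient balance.

    ``MORE_IIIA`` when the IIIB fraction is below the IIIA fraction,
    ``MORE_IIIB`` when above, ``BALANCED`` when equal (within 1e-9, or when
    the cohort has neither IIIA nor IIIB patients).
    """
    fa = c.stage_fractions.get("IIIA", 0.0)
    fb = c.stage_fractions.get("IIIB", 0.0)
    if abs(fb - fa) <= 1e-9:
        return CohortType.BALANCED
    return CohortType.MORE_IIIB if fb > fa else CohortType.MORE_IIIA


def _parse_bool(value, rid: str) -> bool:
    s = str(value).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValidationError(f"cohort {rid!r}: cannot parse boolean {value!r}")


def read_cohorts(path, apply_het_correction: bool = False) -> list[Cohort]:
    """Read a cohort CSV table.

    Parameters
    ----------
    path : path-like
        CSV file with the fixed schema (see :data:`CSV_COLUMNS`): stage and
        histology fractions as proportions in [0, 1], OS in percent,
        booleans as ``true``/``false``.  Histology columns may be blank.
    apply_het_correction : bool
        If True, rows with ``het_corrected = false`` have dose and
        dose-per-fraction raised by 5% and are returned flagged corrected.
    """
    df = pd.read_csv(path, dtype={"id": str, "study": str})
    return cohorts_from_frame(df, apply_het_correction=apply_het_correction)


def cohorts_from_frame(df: pd.DataFrame,
                       apply_het_correction: bool = False) -> list[Cohort]:
    """Build validated cohorts from a DataFrame in the CSV schema."""
    missing = [col for col in _REQUIRED_COLUMNS if col not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    cohorts = []
    for _, row in df.iterrows():
        rid = str(row["id"])
        for col in _REQUIRED_COLUMNS:
            if pd.isna(row[col]):
                raise ValidationError(f"cohort {rid!r}: column {col!r} is empty")
        hist = None
        if all(col in df.columns and not pd.isna(row[col]) for col in _OPTIONAL_COLUMNS):
            hist = {
                "squamous": float(row["f_squamous"]),
                "adeno": float(row["f_adeno"]),
                "other": float(row["f_other"]),
            }
        c = Cohort(
            id=rid,
            study=str(row["study"]),
            publication_year=int(row["publication_year"]),
            treatment=str(row["treatment"]),
            n_patients=int(row["n_patients"]),
            os2_observed=float(row["os2_pct"]),
            dose_gy=float(row["dose_gy"]),
            dose_per_fraction_gy=float(row["dose_per_fraction_gy"]),
            n_fractions=int(row["n_fractions"]),
            duration_days=float(row["duration_days"]),
            stage_fractions={s: float(row[f"f_stage_{s}"]) for s in STAGES},
            het_corrected=_parse_bool(row["het_corrected"], rid),
            histology_fractions=hist,
        )
        if apply_het_correction and not c.het_corrected:
            c = apply_heterogeneity_correction(c)
        cohorts.append(c)
    return cohorts


def cohorts_to_frame(cohorts: Sequence[Cohort]) -> pd.DataFrame:
    """Return the cohort list as a DataFrame in the CSV column order."""
    rows = []
    for c in cohorts:
        row = {
            "id": c.id,
            "study": c.study,
            "publication_year": c.publication_year,
            "treatment": c.treatment,
            "n_patients": c.n_patients,
            "os2_pct": c.os2_observed,
            "dose_gy": c.dose_gy,
            "dose_per_fraction_gy": c.dose_per_fraction_gy,
            "n_fractions": c.n_fractions,
            "duration_days": c.duration_days,
            "f_stage_I": c.stage_fractions["I"],
            "f_stage_II": c.stage_fractions["II"],
            "f_stage_IIIA": c.stage_fractions["IIIA"],
            "f_stage_IIIB": c.stage_fractions["IIIB"],
            "het_corrected": c.het_corrected,
        }
        if c.histology_fractions is not None:
            row["f_squamous"] = c.histology_fractions["squamous"]
            row["f_adeno"] = c.histology_fractions["adeno"]
            row["f_other"] = c.histology_fractions["other"]
        else:
            row["f_squamous"] = row["f_adeno"] = row["f_other"] = None
        rows.append(row)
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_cohorts(cohorts: Sequence[Cohort], path) -> None:
    """Write cohorts to CSV with the fixed schema (round-trips with
    :func:`read_cohorts`)."""
    df = cohorts_to_frame(cohorts)
    df["het_corrected"] = df["het_corrected"].map({True: "true", False: "false"})
    df.to_csv(path, index=False)
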