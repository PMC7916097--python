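"""Reading, validating and bundling Phase I dose-toxicity trial summaries.

A trial is summarised per dose level by the number of dose-limiting
toxicities (DLTs) and the number of treated patients.  Because the binomial
likelihood factorises over patients, these per-dose aggregates carry exactly
the information the dose-toxicity model needs; patient-level data are never
required.

Nine completed Caucasian/Japanese trial pairs (three synthetic calibration
sets and six oncology drugs from the bridging-study literature) ship as
CSV fixtures inside the package and are accessible through
:func:`bundled_dataset`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "DoseLevel",
    "TrialDataset",
    "TrialValidationError",
    "MissingColumnError",
    "NonNumericCellError",
    "NonPositiveDoseError",
    "DuplicateDoseError",
    "DltExceedsPatientsError",
    "EmptyTrialError",
    "load_trial_csv",
    "write_trial_csv",
    "bundled_dataset",
    "bundled_names",
    "BUNDLED_PAIRS",
]


class TrialValidationError(ValueError):
    """Base class for all trial-summary validation failures."""


class MissingColumnError(TrialValidationError):
    """The CSV lacks one of the required columns dose/n_dlt/n_patients."""


class NonNumericCellError(TrialValidationError):
    """A cell that should be numeric could not be parsed."""


class NonPositiveDoseError(TrialValidationError):
    """A dose level has dose <= 0."""


class DuplicateDoseError(TrialValidationError):
    """Two rows share the same dose value."""


class DltExceedsPatientsError(TrialValidationError):
    """A row reports more DLTs than treated patients (or negative counts)."""


class EmptyTrialError(TrialValidationError):
    """The trial has no dose level with at least one treated patient."""


@dataclass(frozen=True)
class DoseLevel:
    """One dose level: dose in the trial's native units, DLT and patient counts."""

    dose: float
    n_dlt: int
    n_patients: int

    def __post_init__(self) -> None:
        if not self.dose > 0:
            raise NonPositiveDoseError(f"dose must be positive, got {self.dose}")
        if self.n_dlt < 0 or self.n_patients < 0 or self.n_dlt > self.n_patients:
            raise DltExceedsPatientsError(
                f"need 0 <= n_dlt <= n_patients, got {self.n_dlt}/{self.n_patients} "
                f"at dose {self.dose}"
            )


@dataclass(frozen=True)
class TrialDataset:
    """A completed trial: ordered dose levels plus free-text identification.

    ``declared_mtd`` is the maximum tolerated dose declared by the original
    investigators, kept purely as an annotation; no computation uses it.
    """

    label: str
    dose_levels: tuple[DoseLevel, ...]
    drug: str = ""
    declared_mtd: float | None = None
    note: str = ""

    def __post_init__(self) -> None:
        doses = [lv.dose for lv in self.dose_levels]
        if len(set(doses)) != len(doses):
            raise DuplicateDoseError(f"duplicate dose values in {self.label}: {doses}")
        if sorted(doses) != doses:
            object.__setattr__(
                self,
                "dose_levels",
                tuple(sorted(self.dose_levels, key=lambda lv: lv.dose)),
            )
        if self.total_n < 1:
            raise EmptyTrialError(f"trial {self.label!r} has no treated patients")

    @property
    def total_n(self) -> int:
        """Total number of treated patients across all dose levels."""
        return sum(lv.n_patients for lv in self.dose_levels)

    @property
    def doses(self) -> tuple[float, ...]:
        return tuple(lv.dose for lv in self.dose_levels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dose": [lv.dose for lv in self.dose_levels],
                "n_dlt": [lv.n_dlt for lv in self.dose_levels],
                "n_patients": [lv.n_patients for lv in self.dose_levels],
            }
        )


_REQUIRED = ("dose", "n_dlt", "n_patients")


def _frame_to_trial(
    df: pd.DataFrame,
    label: str,
    *,
    drug: str = "",
    declared_mtd: float | None = None,
    note: str = "",
    source: str = "<frame>",
) -> TrialDataset:
    for col in _REQUIRED:
        if col not in df.columns:
            raise MissingColumnError(f"{source}: missing required column {col!r}")
    levels = []
    for i, row in df.iterrows():
        try:
            dose = float(row["dose"])
            n_dlt = int(row["n_dlt"])
            n_patients = int(row["n_patients"])
            if float(row["n_dlt"]) != n_dlt or float(row["n_patients"]) != n_patients:
                raise ValueError("counts must be integers")
        except (TypeError, ValueError) as exc:
            raise NonNumericCellError(f"{source}, row {i}: {exc}") from exc
        levels.append(DoseLevel(dose, n_dlt, n_patients))
    return TrialDataset(
        label=label,
        dose_levels=tuple(levels),
        drug=drug,
        declared_mtd=declared_mtd,
        note=note,
    )


def _parse_csv_text(
    text: str, label: str, source: str
) -> TrialDataset:
    meta: dict[str, str] = {}
    for line in text.splitlines():
        if line.startswith("#") and ":" in line:
            key, _, val = line.lstrip("# ").partition(":")
            meta[key.strip()] = val.strip()
    try:
        df = pd.read_csv(io.StringIO(text), comment="#", float_precision="round_trip")
    except ValueError as exc:
        raise NonNumericCellError(f"{source}: {exc}") from exc
    mtd = float(meta["declared_mtd"]) if "declared_mtd" in meta else None
    return _frame_to_trial(
        df,
        label or meta.get("population", ""),
        drug=meta.get("drug", ""),
        declared_mtd=mtd,
        note=meta.get("note", ""),
        source=source,
    )


def load_trial_csv(path: str | Path, label: str = "") -> TrialDataset:
    """Load a trial summary from a CSV file.

    The file must have a header row with columns ``dose,n_dlt,n_patients``.
    Lines starting with ``#`` are metadata comments; ``# drug:``,
    ``# population:`` and ``# declared_mtd:`` are recognised.  Rows are
    returned sorted by ascending dose.  Validation failures raise a subclass
    of :class:`TrialValidationError` naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return _parse_csv_text(path.read_text(encoding="utf-8"), label, str(path))


def write_trial_csv(trial: TrialDataset, path: str | Path) -> None:
    """Write a trial back to the bundled CSV layout (round-trips exactly)."""
    path = Path(path)
    lines = []
    if trial.drug:
        lines.append(f"# drug: {trial.drug}")
    if trial.label:
        lines.append(f"# population: {trial.label}")
    if trial.declared_mtd is not None:
        lines.append(f"# declared_mtd: {trial.declared_mtd:g}")
    if trial.note:
        lines.append(f"# note: {trial.note}")
    lines.append("dose,n_dlt,n_patients")
    for lv in trial.dose_levels:
        lines.append(f"{lv.dose!r},{lv.n_dlt},{lv.n_patients}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


#: bundled pair name -> (caucasian fixture, japanese fixture)
BUNDLED_PAIRS: dict[str, tuple[str, str]] = {
    "synthetic1": ("synthetic_caucasian", "synthetic1_japanese"),
    "synthetic2": ("synthetic_caucasian", "synthetic2_japanese"),
    "synthetic3": ("synthetic_caucasian", "synthetic3_japanese"),
    "erilubin": ("erilubin_caucasian", "erilubin_japanese"),
    "lapatinib": ("lapatinib_caucasian", "lapatinib_japanese"),
    "sorafenib": ("sorafenib_caucasian", "sorafenib_japanese"),
    "ixabepilone": ("ixabepilone_caucasian", "ixabepilone_japanese"),
    "edotecarin": ("edotecarin_caucasian", "edotecarin_japanese"),
    "edotecarin_alt": ("edotecarin_caucasian", "edotecarin_japanese_alt"),
    "e7070": ("e7070_caucasian", "e7070_japanese"),
}


def bundled_names() -> tuple[str, ...]:
    """Names accepted by :func:`bundled_dataset`."""
    return tuple(BUNDLED_PAIRS)


def _load_fixture(stem: str, label: str) -> TrialDataset:
    text = (
        resources.files("toxbridge.data").joinpath(f"{stem}.csv").read_text("utf-8")
    )
    return _parse_csv_text(text, label, f"bundled:{stem}")


def bundled_dataset(name: str) -> tuple[TrialDataset, TrialDataset]:
    """Return the (Caucasian, Japanese) trial pair bundled under ``name``.

    ``edotecarin_alt`` is a sensitivity variant whose garbled published
    Japanese top-dose cell is read as two merged cohorts (4/12) instead of
    the default single-cohort reading (2/6).
    """
    key = name.strip().lower().replace("-", "")
    key = {"edotecarinalt": "edotecarin_alt", "edotecarin_alt": "edotecarin_alt"}.get(
        key, key
    )
    if key not in BUNDLED_PAIRS:
        raise KeyError(
            f"unknown bundled dataset {name!r}; valid names: {', '.join(BUNDLED_PAIRS)}"
        )
    stem_c, stem_a = BUNDLED_PAIRS[key]
    return _load_fixture(stem_c, "Caucasian"), _load_fixture(stem_a, "Japanese")
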