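"""Record schema, formulation categorisation and concentrate/dilution classification.

One :class:`DermalRecord` is a single experimental replicate from a human in
vitro dermal-absorption study: the fractions of the applied dose recovered in
each compartment of the diffusion cell (receptor fluid, chamber wash, skin,
successive tape strips), plus the experiment-level metadata needed by the
filtering rules (mean mass-balance recovery, fraction absorbed at half the
sampling duration) and by the classification into one of eight analysis
categories (four formulation-type categories x concentrate/dilution).

Two definitions of "concentrate" are supported:

* ``commercial`` — the undiluted commercially available product, flagged
  per record (``is_undiluted_product``);
* ``scopaff`` — target concentration of active substance above 50 g/L
  (g/kg for solids); anything at or below the cut-off is a dilution.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "DermalRecord",
    "CategoryKey",
    "ConcentrateDefinition",
    "PlausibilityFlag",
    "FORMULATION_CATEGORIES",
    "STATUSES",
    "categorize_formulation",
    "classify_status",
    "validate_plausibility",
    "read_records_csv",
    "write_records_csv",
]

#: Formulation-type codes grouped into the four analysis categories.
_FORMULATION_GROUPS: dict[str, tuple[str, ...]] = {
    "organic_solvent": ("EC", "EW", "DC", "ME", "OD", "OL", "SE"),
    "other": ("GD", "CS", "ZC"),
    "water_based": ("FS", "SC", "SD", "SL"),
    "solid": ("AP", "DP", "GR", "SG", "WG", "WP"),
}

_CODE_TO_CATEGORY: dict[str, str] = {
    code: cat for cat, codes in _FORMULATION_GROUPS.items() for code in codes
}

FORMULATION_CATEGORIES: tuple[str, ...] = (
    "organic_solvent",
    "other",
    "water_based",
    "solid",
)
STATUSES: tuple[str, ...] = ("concentrate", "dilution")

#: SCoPAFF cut-off separating concentrates from dilutions, g/L (g/kg for solids).
SCOPAFF_CUTOFF_G_PER_L = 50.0


@dataclass(frozen=True)
class CategoryKey:
    """One of the eight analysis cells: formulation category x concentration status."""

    formulation_category: str
    status: str

    def __post_init__(self) -> None:
        if self.formulation_category not in FORMULATION_CATEGORIES:
            raise ValueError(
                f"unknown formulation category {self.formulation_category!r}"
            )
        if self.status not in STATUSES:
            raise ValueError(f"unknown concentration status {self.status!r}")

    @staticmethod
    def all_cells() -> tuple["CategoryKey", ...]:
        return tuple(
            CategoryKey(cat, status)
            for cat in FORMULATION_CATEGORIES
            for status in STATUSES
        )


@dataclass(frozen=True)
class ConcentrateDefinition:
    """How records are split into concentrates and dilutions.

    ``commercial`` uses the per-record undiluted-product flag; ``scopaff``
    uses the target-concentration cut-off (strictly above -> concentrate).
    """

    mode: str = "commercial"
    cutoff: float = SCOPAFF_CUTOFF_G_PER_L

    def __post_init__(self) -> None:
        if self.mode not in ("commercial", "scopaff"):
            raise ValueError(f"unknown concentrate definition mode {self.mode!r}")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class DermalRecord:
    """A single replicate of an in vitro dermal-absorption experiment.

    All compartment values are fractions of the applied dose. Tape-strip
    fractions are ordered outermost first (index 1 = first strip applied).
    ``mean_recovery_percent`` and ``absorbed_at_half_duration_percent`` are
    experiment-level means shared by all replicates of the same tested
    concentration within a study.
    """

    study_id: str
    substance: str
    formulation_type: str
    target_concentration: float  # g/L, or g/kg for solids
    replicate_id: str
    receptor_fluid_fraction: float
    chamber_wash_fraction: float
    skin_fraction: float
    tape_strip_fractions: tuple[float, ...] = ()
    is_undiluted_product: bool | None = None
    exposure_hours: float = 8.0
    mean_recovery_percent: float | None = None
    absorbed_at_half_duration_percent: float | None = None
    # optional dosimetry fields used only by the plausibility checks
    skin_area_cm2: float | None = None
    area_dose_ug_per_cm2: float | None = None
    total_dose_ug: float | None = None

    def __post_init__(self) -> None:
        if self.target_concentration <= 0:
            raise ValueError(
                f"replicate {self.replicate_id!r}: target_concentration must be > 0"
            )
        if self.exposure_hours <= 0:
            raise ValueError(
                f"replicate {self.replicate_id!r}: exposure_hours must be > 0"
            )
        for name in ("receptor_fluid_fraction", "chamber_wash_fraction", "skin_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(
                    f"replicate {self.replicate_id!r}: {name}={v} outside [0, 1]"
                )
        self.tape_strip_fractions = tuple(float(f) for f in self.tape_strip_fractions)
        for i, f in enumerate(self.tape_strip_fractions, start=1):
            if not (0 <= f <= 1):
                raise ValueError(
                    f"replicate {self.replicate_id!r}: tape strip {i} fraction {f} "
                    "outside [0, 1]"
                )

    @property
    def experiment_key(self) -> tuple[str, str, str, float]:
        """Grouping key for one tested concentration within a study."""
        return (
            self.study_id,
            self.substance,
            self.formulation_type,
            self.target_concentration,
        )


def categorize_formulation(formulation_type: str) -> str:
    """Map a formulation-type code (EC, SC, WG, ...) to its analysis category.

    The mapping is total over the 20 recognised codes; anything else is an
    error — "other" is a closed set (GD, CS, ZC), not a catch-all bin.
    """
    code = formulation_type.strip().upper()
    try:
        return _CODE_TO_CATEGORY[code]
    except KeyError:
        raise ValueError(
            f"unknown formulation type code {formulation_type!r}; "
            f"recognised codes: {sorted(_CODE_TO_CATEGORY)}"
        ) from None


def classify_status(record: DermalRecord, definition: ConcentrateDefinition) -> str:
    """Classify one replicate as ``concentrate`` or ``dilution``.

    Under the commercial definition the per-record flag decides; under the
    SCoPAFF definition a record is a concentrate iff its target
    concentration is strictly above the cut-off (50 g/L at the cut-off is a
    dilution).
    """
    if definition.mode == "commercial":
        if record.is_undiluted_product is None:
            raise ValueError(
                f"replicate {record.replicate_id!r}: is_undiluted_product flag "
                "required under the commercial concentrate definition"
            )
        return "concentrate" if record.is_undiluted_product else "dilution"
    return (
        "concentrate"
        if record.target_concentration > definition.cutoff
        else "dilution"
    )


def category_key(record: DermalRecord, definition: ConcentrateDefinition) -> CategoryKey:
    """Full eight-way category of one replicate under a concentrate definition."""
    return CategoryKey(
        categorize_formulation(record.formulation_type),
        classify_status(record, definition),
    )


@dataclass(frozen=True)
class PlausibilityFlag:
    """Advisory flag raised by a plausibility check; never auto-drops a record."""

    replicate_id: str
    check: str
    message: str


def validate_plausibility(
    records: Iterable[DermalRecord],
    *,
    dose_rel_tol: float = 0.05,
    low_concentrate_g_per_l: float = 1.0,
    high_dilution_g_per_l: float = 500.0,
) -> list[PlausibilityFlag]:
    """Run dosimetry-consistency and concentration-sanity checks.

    Flags replicates where total dose disagrees with area dose x skin area
    beyond ``dose_rel_tol`` (relative), commercial concentrates with
    implausibly low concentrations, and dilutions with implausibly high
    concentrations. Checks needing absent optional fields are skipped.
    Flags are advisory and meant for manual review against study reports.
    """
    flags: list[PlausibilityFlag] = []
    for rec in records:
        if (
            rec.skin_area_cm2 is not None
            and rec.area_dose_ug_per_cm2 is not None
            and rec.total_dose_ug is not None
        ):
            expected = rec.area_dose_ug_per_cm2 * rec.skin_area_cm2
            denom = max(abs(expected), abs(rec.total_dose_ug), 1e-300)
            if abs(rec.total_dose_ug - expected) / denom > dose_rel_tol:
                flags.append(
                    PlausibilityFlag(
                        rec.replicate_id,
                        "dose_consistency",
                        f"total dose {rec.total_dose_ug} ug vs area dose x skin "
                        f"area = {expected} ug (relative tolerance {dose_rel_tol})",
                    )
                )
        if rec.is_undiluted_product is True and (
            rec.target_concentration < low_concentrate_g_per_l
        ):
            flags.append(
                PlausibilityFlag(
                    rec.replicate_id,
                    "low_concentrate",
                    f"concentrate at {rec.target_concentration} g/L below "
                    f"{low_concentrate_g_per_l} g/L",
                )
            )
        if rec.is_undiluted_product is False and (
            rec.target_concentration > high_dilution_g_per_l
        ):
            flags.append(
                PlausibilityFlag(
                    rec.replicate_id,
                    "high_dilution",
                    f"dilution at {rec.target_concentration} g/L above "
                    f"{high_dilution_g_per_l} g/L",
                )
            )
    return flags


# ---------------------------------------------------------------------------
# flat CSV dialect
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "study_id",
    "substance",
    "formulation_type",
    "target_concentration_g_per_l",
    "is_undiluted_product",
    "exposure_hours",
    "replicate_id",
    "receptor_fluid_fraction",
    "chamber_wash_fraction",
    "skin_fraction",
    "tape_strip_fractions",
    "mean_recovery_percent",
    "absorbed_at_half_duration_percent",
    "skin_area_cm2",
    "area_dose_ug_per_cm2",
    "total_dose_ug",
]


def _opt_float(s: str) -> float | None:
    s = s.strip()
    return float(s) if s else None


def read_records_csv(path) -> list[DermalRecord]:
    """Read replicate records from the package's flat CSV dialect.

    One row per replicate; tape-strip fractions as a ``;``-separated list in
    a single column, outermost strip first; empty cells for absent optional
    fields; booleans as ``true``/``false``.
    """
    records: list[DermalRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_CSV_COLUMNS[:11]) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"input CSV missing required columns: {sorted(missing)}")
        for row in reader:
            strips_raw = (row.get("tape_strip_fractions") or "").strip()
            strips = (
                tuple(float(x) for x in strips_raw.split(";") if x.strip())
                if strips_raw
                else ()
            )
            flag_raw = (row.get("is_undiluted_product") or "").strip().lower()
            if flag_raw in ("true", "1", "yes"):
                flag = True
            elif flag_raw in ("false", "0", "no"):
                flag = False
            elif flag_raw == "":
                flag = None
            else:
                raise ValueError(
                    f"unparseable is_undiluted_product value {flag_raw!r}"
                )
            records.append(
                DermalRecord(
                    study_id=row["study_id"],
                    substance=row["substance"],
                    formulation_type=row["formulation_type"],
                    target_concentration=float(row["target_concentration_g_per_l"]),
                    is_undiluted_product=flag,
                    exposure_hours=float(row.get("exposure_hours") or 8.0),
                    replicate_id=row["replicate_id"],
                    receptor_fluid_fraction=float(row["receptor_fluid_fraction"]),
                    chamber_wash_fraction=float(row["chamber_wash_fraction"]),
                    skin_fraction=float(row["skin_fraction"]),
                    tape_strip_fractions=strips,
                    mean_recovery_percent=_opt_float(
                        row.get("mean_recovery_percent", "")
                    ),
                    absorbed_at_half_duration_percent=_opt_float(
                        row.get("absorbed_at_half_duration_percent", "")
                    ),
                    skin_area_cm2=_opt_float(row.get("skin_area_cm2", "")),
                    area_dose_ug_per_cm2=_opt_float(
                        row.get("area_dose_ug_per_cm2", "")
                    ),
                    total_dose_ug=_opt_float(row.get("total_dose_ug", "")),
                )
            )
    return records


def write_records_csv(records: Sequence[DermalRecord], path) -> None:
    """Write replicate records in the flat CSV dialect read by :func:`read_records_csv`."""

    def fmt(v) -> str:
        if v is None:
            return ""
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, float):
            return repr(v)
        return str(v)

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.study_id,
                    r.substance,
                    r.formulation_type,
                    fmt(r.target_concentration),
                    fmt(r.is_undiluted_product),
                    fmt(r.exposure_hours),
                    r.replicate_id,
                    fmt(r.receptor_fluid_fraction),
                    fmt(r.chamber_wash_fraction),
                    fmt(r.skin_fraction),
                    ";".join(repr(f) for f in r.tape_strip_fractions),
                    fmt(r.mean_recovery_percent),
                    fmt(r.absorbed_at_half_duration_percent),
                    fmt(r.skin_area_cm2),
                    fmt(r.area_dose_ug_per_cm2),
                    fmt(r.total_dose_ug),
                ]
            )
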