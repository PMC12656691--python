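"""Filtering rules and construction of the logit-scale modelling table.

The preprocessing pipeline mirrors the harmonised evaluation rules for in
vitro dermal-absorption studies:

* **recovery filter** — experiments (all replicates of one tested
  concentration within a study) are dropped in full when their mean
  mass-balance recovery is strictly below 90% or strictly above 110%;
* **tape-strip rule** — if on average at least 75% of the material was
  absorbed after half the sampling duration, absorption is considered
  complete and all tape strips are excluded from the absorbed amount;
  otherwise only the two outermost strips (1 and 2) are excluded;
* **potential absorption** — receptor fluid + chamber wash + whole skin +
  the retained tape strips: material that has crossed, or could still
  cross, the stratum corneum.

The retained replicates, classified into the eight analysis categories, are
logit-transformed into a :class:`PreparedDataset` — the modelling table
consumed by the empirical and mixed-model stages.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dataset import CategoryKey, ConcentrateDefinition, DermalRecord, category_key

__all__ = [
    "PreparedDataset",
    "PreprocessingReport",
    "recovery_filter",
    "select_tape_strips",
    "potential_absorption",
    "logit",
    "inv_logit",
    "prepare_dataset",
]

RECOVERY_LOW_PERCENT = 90.0
RECOVERY_HIGH_PERCENT = 110.0
COMPLETE_ABSORPTION_PERCENT = 75.0
#: Outermost strips excluded when absorption is incomplete.
_ALWAYS_EXCLUDED_STRIPS = frozenset({1, 2})


def logit(f: float) -> float:
    """ln(f / (1 - f)) for f strictly inside (0, 1).

    Boundary values are rejected rather than epsilon-clipped: a fraction of
    exactly 0 or 1 cannot arise from a valid mass-balance decomposition and
    indicates a data error.
    """
    if not 0.0 < f < 1.0:
        raise ValueError(f"logit undefined for fraction {f}; need 0 < f < 1")
    return math.log(f / (1.0 - f))


def inv_logit(y: float) -> float:
    """Exact inverse of :func:`logit`, numerically stable for large |y|."""
    if y >= 0:
        return 1.0 / (1.0 + math.exp(-y))
    e = math.exp(y)
    return e / (1.0 + e)


def recovery_filter(
    records: Sequence[DermalRecord],
) -> tuple[list[DermalRecord], list[DermalRecord]]:
    """Drop whole experiments whose mean mass-balance recovery is outside [90, 110].

    The bounds are inclusive: recovery of exactly 90% or 110% is retained.
    Records with no recovery value are excluded with a warning entry (never
    silently kept). Returns ``(retained, excluded)``. The filter is
    idempotent: re-applying it to the retained list changes nothing.
    """
    retained: list[DermalRecord] = []
    excluded: list[DermalRecord] = []
    for rec in records:
        r = rec.mean_recovery_percent
        if r is None or r < RECOVERY_LOW_PERCENT or r > RECOVERY_HIGH_PERCENT:
            excluded.append(rec)
        else:
            retained.append(rec)
    return retained, excluded


def select_tape_strips(
    record: DermalRecord, *, missing_half_duration_complete: bool = False
) -> frozenset[int]:
    """Indices (1-based, outermost first) of tape strips counted as absorbed.

    Absorption complete (>= 75% absorbed on average at half the sampling
    duration) -> no strips counted. Incomplete -> all strips except 1 and 2.
    A missing half-duration value defaults to the conservative incomplete
    branch (strips 3+ retained) unless ``missing_half_duration_complete``.
    """
    half = record.absorbed_at_half_duration_percent
    if half is None:
        complete = missing_half_duration_complete
    else:
        complete = half >= COMPLETE_ABSORPTION_PERCENT
    if complete:
        return frozenset()
    return frozenset(
        i
        for i in range(1, len(record.tape_strip_fractions) + 1)
        if i not in _ALWAYS_EXCLUDED_STRIPS
    )


def potential_absorption(
    record: DermalRecord, included_strips: Iterable[int]
) -> float:
    """Fraction of the applied dose counted as (potentially) absorbed.

    Sum of receptor fluid, chamber wash, whole skin and the included tape
    strips. Values outside the open interval (0, 1) are rejected, not
    clamped — they cannot occur in a plausible mass balance.
    """
    strips = record.tape_strip_fractions
    total = (
        record.receptor_fluid_fraction
        + record.chamber_wash_fraction
        + record.skin_fraction
        + sum(strips[i - 1] for i in included_strips)
    )
    if not 0.0 < total < 1.0:
        raise ValueError(
            f"replicate {record.replicate_id!r}: potential absorption {total} "
            "outside the open interval (0, 1)"
        )
    return total


@dataclass
class PreprocessingReport:
    """Counts per filtering rule, serialisable for traceability."""

    n_input: int = 0
    n_after_recovery_filter: int = 0
    n_excluded_recovery: int = 0
    n_excluded_missing_recovery: int = 0
    n_complete_absorption: int = 0
    n_incomplete_absorption: int = 0
    n_retained: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


@dataclass
class PreparedDataset:
    """Logit-scale modelling table with grouping keys.

    ``table`` columns: substance, study_id, formulation_category, status,
    group_id, target_concentration, fraction_absorbed, y (= logit fraction).
    ``group_id`` identifies one applied concentration of one substance in
    one formulation type within one study — the within-study grouping
    variable of the mixed model.
    """

    table: pd.DataFrame
    definition: ConcentrateDefinition
    report: PreprocessingReport | None = None

    _COLUMNS = (
        "substance",
        "study_id",
        "formulation_category",
        "status",
        "group_id",
        "target_concentration",
        "fraction_absorbed",
        "y",
    )

    def __post_init__(self) -> None:
        missing = set(self._COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"PreparedDataset table missing columns {sorted(missing)}")
        f = self.table["fraction_absorbed"].to_numpy(float)
        if len(f) and not ((f > 0) & (f < 1)).all():
            raise ValueError("fraction_absorbed must lie strictly inside (0, 1)")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def category_keys(self) -> list[CategoryKey]:
        return [
            CategoryKey(c, s)
            for c, s in self.table[["formulation_category", "status"]]
            .drop_duplicates()
            .itertuples(index=False)
        ]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, definition: ConcentrateDefinition | None = None) -> "PreparedDataset":
        return cls(pd.read_csv(path), definition or ConcentrateDefinition())


def prepare_dataset(
    records: Sequence[DermalRecord],
    definition: ConcentrateDefinition | None = None,
    *,
    missing_half_duration_complete: bool = False,
) -> PreparedDataset:
    """Run the full preprocessing pipeline on replicate records.

    Applies the recovery filter, the tape-strip rule and the potential-
    absorption computation, classifies each retained replicate under the
    given concentrate definition, and returns the logit-scale table plus a
    per-rule exclusion report.
    """
    definition = definition or ConcentrateDefinition()
    report = PreprocessingReport(n_input=len(records))

    retained, excluded = recovery_filter(records)
    report.n_after_recovery_filter = len(retained)
    report.n_excluded_missing_recovery = sum(
        1 for r in excluded if r.mean_recovery_percent is None
    )
    report.n_excluded_recovery = len(excluded) - report.n_excluded_missing_recovery

    rows = []
    group_ids: dict[tuple, str] = {}
    for rec in retained:
        strips = select_tape_strips(
            rec, missing_half_duration_complete=missing_half_duration_complete
        )
        if strips:
            report.n_incomplete_absorption += 1
        else:
            report.n_complete_absorption += 1
        fraction = potential_absorption(rec, strips)
        key = category_key(rec, definition)
        gkey = rec.experiment_key
        gid = group_ids.setdefault(gkey, f"g{len(group_ids) + 1}")
        rows.append(
            {
                "substance": rec.substance,
                "study_id": rec.study_id,
                "formulation_category": key.formulation_category,
                "status": key.status,
                "group_id": gid,
                "target_concentration": rec.target_concentration,
                "fraction_absorbed": fraction,
                "y": logit(fraction),
            }
        )
    report.n_retained = len(rows)
    table = pd.DataFrame(rows, columns=list(PreparedDataset._COLUMNS))
    return PreparedDataset(table, definition, report)
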