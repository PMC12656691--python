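"""Synthetic data with the exact hierarchical structure the analysis assumes.

The generator emulates the shape of the BfR2024 dermal-absorption dataset:
substances tested in one or more studies, studies containing a few
within-study concentration groups, groups containing a handful of
replicates. Logit-scale absorption follows the mixed model exactly —
substance-effect pairs from the bivariate normal with covariance ``G``,
study and group intercepts from their variance components, Gaussian
residuals — so generated data carry a known ground truth for parameter
recovery. A second generator decomposes the same fractions into raw
compartment records (receptor fluid, chamber wash, skin, tape strips) with
planted recovery and half-duration values, exercising every preprocessing
rule branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import (
    _FORMULATION_GROUPS,
    ConcentrateDefinition,
    DermalRecord,
    FORMULATION_CATEGORIES,
)
from .model import ModelParams
from .preprocessing import PreparedDataset, inv_logit
from .reference import BFR2024_POSTERIOR_MEANS

__all__ = [
    "SyntheticTruth",
    "RawScenario",
    "GroundTruthEffects",
    "generate_logit_dataset",
    "generate_raw_records",
]

#: Default 8-cell replicate weights, proportional to the BfR2024 category
#: sample sizes (organic solvent / other / water-based / solid x
#: concentrate / dilution).
_DEFAULT_CELL_WEIGHTS = {
    ("organic_solvent", "concentrate"): 847,
    ("other", "concentrate"): 83,
    ("water_based", "concentrate"): 1268,
    ("solid", "concentrate"): 351,
    ("organic_solvent", "dilution"): 1490,
    ("other", "dilution"): 103,
    ("water_based", "dilution"): 1771,
    ("solid", "dilution"): 427,
}


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters and dataset shape for the generator.

    Defaults mimic the BfR2024 scale: ~155 substances, ~356 studies and
    ~6340 replicates, with substances appearing in 1 + Poisson(1.3)
    studies, 1-4 concentration groups per study and 4-10 replicates per
    group. Target concentrations are drawn log-uniformly — concentrates on
    [20, 960] g/L and dilutions on [0.003, 80] g/L — straddling the
    50 g/L cut-off so both concentrate definitions are exercised.
    """

    params: ModelParams = BFR2024_POSTERIOR_MEANS
    n_substances: int = 155
    mean_extra_studies: float = 1.3  # studies per substance = 1 + Poisson(.)
    groups_per_study_weights: tuple[float, ...] = (0.10, 0.40, 0.35, 0.15)
    replicates_per_group: tuple[int, int] = (4, 10)
    cell_weights: dict = field(
        default_factory=lambda: dict(_DEFAULT_CELL_WEIGHTS)
    )
    concentrate_conc_range: tuple[float, float] = (20.0, 960.0)
    dilution_conc_range: tuple[float, float] = (0.003, 80.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_substances < 1:
            raise ValueError("need at least one substance")
        if any(w < 0 for w in self.cell_weights.values()) or not any(
            self.cell_weights.values()
        ):
            raise ValueError("cell weights must be non-negative with positive sum")
        if np.linalg.eigvalsh(self.params.G)[0] < 0:
            raise ValueError("substance covariance G must be positive semi-definite")

    @classmethod
    def reduced(cls, n_substances: int = 40, seed: int = 0, **kwargs) -> "SyntheticTruth":
        """Smaller preset (~100 studies, ~1800 replicates at 40 substances)
        used for fast parameter-recovery runs."""
        kwargs.setdefault("mean_extra_studies", 1.5)
        return cls(n_substances=n_substances, seed=seed, **kwargs)

    def _category_marginals(self):
        cat_tot = {c: 0.0 for c in FORMULATION_CATEGORIES}
        for (cat, _), w in self.cell_weights.items():
            cat_tot[cat] += w
        total = sum(cat_tot.values())
        cat_p = np.array([cat_tot[c] / total for c in FORMULATION_CATEGORIES])
        conc_given_cat = {
            c: (
                self.cell_weights.get((c, "concentrate"), 0.0) / cat_tot[c]
                if cat_tot[c]
                else 0.0
            )
            for c in FORMULATION_CATEGORIES
        }
        return cat_p, conc_given_cat


@dataclass
class GroundTruthEffects:
    """Realised random effects underlying one generated dataset."""

    substance_effects: pd.DataFrame  # index substance, columns dilution/concentrate
    study_effects: pd.Series
    group_effects: pd.Series


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _plan_structure(truth: SyntheticTruth, rng: np.random.Generator):
    """Lay out substances -> studies -> groups with categories and concentrations."""
    cat_p, conc_given_cat = truth._category_marginals()
    groups = []
    study_counter = 0
    for s in range(truth.n_substances):
        substance = f"sub{s + 1:03d}"
        cat = FORMULATION_CATEGORIES[rng.choice(len(cat_p), p=cat_p)]
        n_studies = 1 + rng.poisson(truth.mean_extra_studies)
        for _ in range(n_studies):
            study_counter += 1
            study = f"study{study_counter:04d}"
            n_groups = 1 + rng.choice(
                len(truth.groups_per_study_weights),
                p=np.asarray(truth.groups_per_study_weights)
                / sum(truth.groups_per_study_weights),
            )
            seen_conc: set[float] = set()
            for g in range(n_groups):
                status = (
                    "concentrate"
                    if rng.random() < conc_given_cat[cat]
                    else "dilution"
                )
                lo, hi = (
                    truth.concentrate_conc_range
                    if status == "concentrate"
                    else truth.dilution_conc_range
                )
                conc = _log_uniform(rng, lo, hi)
                while conc in seen_conc:  # pragma: no cover - measure-zero
                    conc = _log_uniform(rng, lo, hi)
                seen_conc.add(conc)
                n_rep = int(
                    rng.integers(
                        truth.replicates_per_group[0],
                        truth.replicates_per_group[1] + 1,
                    )
                )
                groups.append(
                    {
                        "substance": substance,
                        "study": study,
                        "category": cat,
                        "status": status,
                        "concentration": conc,
                        "n_replicates": n_rep,
                    }
                )
    return groups


def generate_logit_dataset(
    truth: SyntheticTruth,
) -> tuple[PreparedDataset, GroundTruthEffects]:
    """Generate a logit-scale modelling table directly from the model.

    Returns the prepared table (commercial-definition status labels) and
    the realised random effects. Byte-identical for identical truth + seed.
    """
    rng = np.random.default_rng(truth.seed)
    p = truth.params
    G = p.G
    evals, evecs = np.linalg.eigh(G)
    if evals.min() < -1e-12:
        raise ValueError("substance covariance G is not positive semi-definite")
    chol = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))

    groups = _plan_structure(truth, rng)
    substances = sorted({g["substance"] for g in groups})
    studies = sorted({g["study"] for g in groups})

    b = (chol @ rng.standard_normal((2, len(substances)))).T  # (S, 2) dilution, conc
    u = rng.standard_normal(len(studies)) * np.sqrt(p.var_study)
    s_idx = {s: i for i, s in enumerate(substances)}
    j_idx = {s: i for i, s in enumerate(studies)}

    beta = {
        "organic_solvent": 0.0,
        "other": p.beta_other,
        "solid": p.beta_solid,
        "water_based": p.beta_water_based,
    }
    rows = []
    w_effects = {}
    for gi, g in enumerate(groups):
        gid = f"g{gi + 1:05d}"
        w = rng.standard_normal() * np.sqrt(p.var_within)
        w_effects[gid] = w
        lp = p.alpha + beta[g["category"]]
        if g["status"] == "concentrate":
            lp += p.beta_concentrate
        sub_effect = b[s_idx[g["substance"]], 1 if g["status"] == "concentrate" else 0]
        mean = lp + sub_effect + u[j_idx[g["study"]]] + w
        eps = rng.standard_normal(g["n_replicates"]) * np.sqrt(p.var_resid)
        for r, y in enumerate(mean + eps):
            rows.append(
                {
                    "substance": g["substance"],
                    "study_id": g["study"],
                    "formulation_category": g["category"],
                    "status": g["status"],
                    "group_id": gid,
                    "target_concentration": g["concentration"],
                    "fraction_absorbed": inv_logit(float(y)),
                    "y": float(y),
                }
            )
    table = pd.DataFrame(rows, columns=list(PreparedDataset._COLUMNS))
    prepared = PreparedDataset(table, ConcentrateDefinition("commercial"))
    effects = GroundTruthEffects(
        substance_effects=pd.DataFrame(
            b, index=substances, columns=["dilution", "concentrate"]
        ),
        study_effects=pd.Series(u, index=studies),
        group_effects=pd.Series(w_effects),
    )
    return prepared, effects


@dataclass(frozen=True)
class RawScenario:
    """Planted preprocessing conditions for raw-record generation.

    Fractions of experiments planted with out-of-range recovery (below 90%
    or above 110%) and with complete absorption at half the sampling
    duration (>= 75%, triggering full tape-strip exclusion).
    """

    frac_recovery_low: float = 0.05
    frac_recovery_high: float = 0.05
    frac_complete_absorption: float = 0.3
    n_tape_strips: int = 5
    excluded_strip_mass: float = 0.01

    def __post_init__(self) -> None:
        if self.frac_recovery_low + self.frac_recovery_high > 1:
            raise ValueError("recovery violation fractions sum above 1")
        if self.n_tape_strips < 2:
            raise ValueError("need at least the two always-excluded strips")


def generate_raw_records(
    truth: SyntheticTruth, scenario: RawScenario | None = None
) -> tuple[list[DermalRecord], PreparedDataset, GroundTruthEffects]:
    """Decompose generated fractions into raw compartment records.

    Each replicate's compartments are constructed so the preprocessing
    pipeline (tape-strip rule included) recovers exactly the generated
    fraction: for complete-absorption experiments all strip mass is
    excluded extra; otherwise strips 3+ carry part of the absorbed
    fraction while strips 1-2 carry excluded extra mass. Recovery values
    are planted inside [90, 110] or outside per the scenario. Returns the
    records plus the underlying prepared table and effects (the planted
    truth, restricted to in-range-recovery experiments, is what the
    pipeline should reproduce).
    """
    scenario = scenario or RawScenario()
    prepared, effects = generate_logit_dataset(truth)
    rng = np.random.default_rng(
        np.random.SeedSequence([truth.seed, 911]).generate_state(1)[0]
    )
    records: list[DermalRecord] = []
    for gid, grp in prepared.table.groupby("group_id", sort=True):
        roll = rng.random()
        if roll < scenario.frac_recovery_low:
            recovery = float(rng.uniform(70.0, 89.5))
        elif roll < scenario.frac_recovery_low + scenario.frac_recovery_high:
            recovery = float(rng.uniform(110.5, 130.0))
        else:
            recovery = float(rng.uniform(92.0, 108.0))
        complete = rng.random() < scenario.frac_complete_absorption
        half_duration = (
            float(rng.uniform(75.0, 99.0)) if complete else float(rng.uniform(5.0, 74.5))
        )
        first = grp.iloc[0]
        for i, (_, row) in enumerate(grp.iterrows()):
            f = float(row["fraction_absorbed"])
            if f >= 1.0:  # pragma: no cover - inv_logit keeps f < 1
                raise ValueError("fraction >= 1 cannot be decomposed into compartments")
            n_strips = scenario.n_tape_strips
            strips = [scenario.excluded_strip_mass] * n_strips
            if complete:
                rf, cw, skin = 0.70 * f, 0.10 * f, 0.20 * f
            else:
                rf, cw, skin = 0.60 * f, 0.10 * f, 0.20 * f
                included = n_strips - 2
                for k in range(2, n_strips):
                    strips[k] = 0.10 * f / included
            records.append(
                DermalRecord(
                    study_id=str(first["study_id"]),
                    substance=str(first["substance"]),
                    formulation_type=_code_for_category(
                        str(first["formulation_category"])
                    ),
                    target_concentration=float(first["target_concentration"]),
                    is_undiluted_product=first["status"] == "concentrate",
                    exposure_hours=8.0,
                    replicate_id=f"{gid}-r{i + 1}",
                    receptor_fluid_fraction=rf,
                    chamber_wash_fraction=cw,
                    skin_fraction=skin,
                    tape_strip_fractions=tuple(strips),
                    mean_recovery_percent=recovery,
                    absorbed_at_half_duration_percent=half_duration,
                )
            )
    return records, prepared, effects


def _code_for_category(category: str) -> str:
    """Representative formulation-type code for a category (first in its group)."""
    return _FORMULATION_GROUPS[category][0]
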