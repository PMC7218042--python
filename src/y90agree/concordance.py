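"""Dose-target classification and cross-observer concordance.

Clinical decisions hinge on whether a treatment reached a dose target:
tumor dose above 200 Gy (efficacy), healthy-liver dose below 50 Gy or below
75 Gy (safety).  A treatment is *discordant* under a rule when its observers
do not all classify it on the same side of the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .cohort import COLUMN_BY_QUANTITY

__all__ = [
    "ThresholdRule",
    "ConcordanceResult",
    "DEFAULT_RULES",
    "classify",
    "discordance_fraction",
]


@dataclass(frozen=True)
class ThresholdRule:
    quantity: str  # "TD" or "THLD"
    cutoff_gy: float
    direction: str  # "greater_than" | "less_than"
    label: str

    def validate(self) -> None:
        if self.cutoff_gy <= 0:
            raise ValueError("cutoff must be > 0")
        if self.direction not in ("greater_than", "less_than"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.quantity not in ("TD", "THLD"):
            raise ValueError(f"rules apply to dose quantities, got {self.quantity!r}")


#: The clinical targets: tumor efficacy and two healthy-liver safety cutoffs.
DEFAULT_RULES = (
    ThresholdRule("TD", 200.0, "greater_than", "TD>200Gy"),
    ThresholdRule("THLD", 50.0, "less_than", "THLD<50Gy"),
    ThresholdRule("THLD", 75.0, "less_than", "THLD<75Gy"),
)


def classify(measurement, rule: ThresholdRule) -> bool:
    """True when the measurement reaches the rule's target.

    The inequality is strict in the stated direction: a value exactly at the
    cutoff does NOT reach the target.  ``measurement`` may be a
    DosimetryMeasurement, a mapping, or a bare number.
    """
    rule.validate()
    if isinstance(measurement, (int, float, np.floating)):
        value = float(measurement)
    elif isinstance(measurement, Mapping):
        value = float(measurement[rule.quantity])
    else:
        value = float(getattr(measurement, rule.quantity))
    if not np.isfinite(value):
        raise ValueError(f"{rule.quantity} is missing or non-finite")
    if rule.direction == "greater_than":
        return value > rule.cutoff_gy
    return value < rule.cutoff_gy


@dataclass(frozen=True)
class ConcordanceResult:
    rule: ThresholdRule
    n_treatments: int
    n_discordant: int
    fraction_discordant: float
    classifications: dict[str, dict[str, bool]]  # treatment -> observer -> reached


def discordance_fraction(table, rule: ThresholdRule) -> ConcordanceResult:
    """Count treatments whose observers disagree on target-reached status.

    ``table`` is a long-format observer table (complete block design
    required).
    """
    rule.validate()
    col = COLUMN_BY_QUANTITY[rule.quantity]
    wide = table.pivot(index="treatment_id", columns="observer_id", values=col)
    if wide.isna().any().any():
        raise ValueError("incomplete block design: missing (treatment, observer)")
    values = wide.to_numpy(dtype=float)
    if rule.direction == "greater_than":
        reached = values > rule.cutoff_gy
    else:
        reached = values < rule.cutoff_gy
    discordant = reached.any(axis=1) & ~reached.all(axis=1)
    classifications = {
        str(t): {
            str(o): bool(reached[i, j]) for j, o in enumerate(wide.columns)
        }
        for i, t in enumerate(wide.index)
    }
    n = len(wide.index)
    nd = int(discordant.sum())
    return ConcordanceResult(
        rule=rule,
        n_treatments=n,
        n_discordant=nd,
        fraction_discordant=nd / n,
        classifications=classifications,
    )
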