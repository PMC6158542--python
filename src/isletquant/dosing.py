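"""Transplant dose–outcome analysis: cell-number dosing vs IEQ dosing.

A transplant series in which each group's dose is recorded both as total
cells per recipient and as IEQ per recipient lets the two dose metrics be
compared directly: does outcome improve monotonically with dose?  In the
canine-islet → diabetic NOD-SCID mouse series reproduced here, cell-number
dose separates outcomes cleanly (every transplant of ≥ 6.17 M cells fully
reversed diabetes, none under 5.13 M did), while IEQ dose does not — the
lowest IEQ dose (2500) produced both a 100%-partial and a 100%-normal group.

Outcome categories are ordered failure < partial < normal_glycemia.  A mixed
group (fractions across categories) counts as "not fully successful" for the
threshold operations and ranks by its expected outcome score (the
fraction-weighted category index) for the monotonicity check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

OUTCOME_ORDER = ("failure", "partial", "normal_glycemia")

DoseMetric = Literal["cells", "ieq"]


@dataclass(frozen=True)
class TransplantGroup:
    """One dosing group: dose under both metrics and its outcome mix.

    ``cells_per_mouse`` is in millions of cells; ``ieq_per_mouse`` is raw IEQ.
    """

    group: str
    cells_per_mouse: float
    ieq_per_mouse: float
    frac_failure: float
    frac_partial: float
    frac_normal: float
    n_mice: Optional[int] = None

    def __post_init__(self) -> None:
        if not (self.cells_per_mouse > 0 and self.ieq_per_mouse > 0):
            raise ValueError(f"group {self.group}: doses must be > 0")
        fr = (self.frac_failure, self.frac_partial, self.frac_normal)
        if any(f < 0 for f in fr) or not math.isclose(sum(fr), 1.0, abs_tol=1e-6):
            raise ValueError(f"group {self.group}: outcome fractions must sum to 1")

    def dose(self, metric: DoseMetric) -> float:
        if metric == "cells":
            return self.cells_per_mouse
        if metric == "ieq":
            return self.ieq_per_mouse
        raise ValueError(f"unknown dose metric: {metric!r}")

    @property
    def fully_successful(self) -> bool:
        return math.isclose(self.frac_normal, 1.0, abs_tol=1e-6)

    @property
    def outcome_score(self) -> float:
        """Expected outcome on the 0 (failure) – 2 (normal glycemia) scale."""
        return self.frac_partial + 2.0 * self.frac_normal

    @property
    def worst_category(self) -> str:
        for cat, frac in zip(
            OUTCOME_ORDER, (self.frac_failure, self.frac_partial, self.frac_normal)
        ):
            if frac > 1e-9:
                return cat
        raise ValueError(f"group {self.group}: no outcome mass")


def reference_canine_study() -> list[TransplantGroup]:
    """The published canine-islet → NOD-SCID mouse transplant series."""
    return [
        TransplantGroup("1", 5.00, 2500, 0.0, 1.0, 0.0),
        TransplantGroup("2", 5.13, 3500, 1 / 3, 1 / 3, 1 / 3),
        TransplantGroup("3", 6.17, 2500, 0.0, 0.0, 1.0),
        TransplantGroup("4", 7.25, 4000, 0.0, 0.0, 1.0),
    ]


def min_full_success_dose(
    groups: Sequence[TransplantGroup], metric: DoseMetric = "cells"
) -> float:
    """Smallest dose among groups achieving 100% normal glycemia."""
    doses = [g.dose(metric) for g in groups if g.fully_successful]
    if not doses:
        raise ValueError("no fully successful group in the series")
    return min(doses)


def max_incomplete_dose(
    groups: Sequence[TransplantGroup], metric: DoseMetric = "cells"
) -> float:
    """Largest dose among groups that did not achieve 100% normal glycemia."""
    doses = [g.dose(metric) for g in groups if not g.fully_successful]
    if not doses:
        raise ValueError("every group in the series was fully successful")
    return max(doses)


def is_dose_monotone(
    groups: Sequence[TransplantGroup], metric: DoseMetric = "cells"
) -> tuple[bool, list[tuple[str, str]]]:
    """Whether outcome is non-decreasing in dose; returns violating group pairs.

    A pair (i, j) violates monotonicity when group i's dose is no larger than
    group j's but its outcome score is strictly better — including equal
    doses with different outcomes, the signature of a metric that fails to
    determine outcome.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    violations: list[tuple[str, str]] = []
    for i, gi in enumerate(groups):
        for j, gj in enumerate(groups):
            if i == j:
                continue
            if gi.dose(metric) <= gj.dose(metric) and gi.outcome_score > gj.outcome_score + 1e-9:
                violations.append((gi.group, gj.group))
    return (not violations), sorted(violations)
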