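"""Spirometric severity grading and analysis-group assignment.

COPD is defined by post-bronchodilator FEV1/FVC < 0.7.  GOLD grades follow
the standard interval scheme on FEV1 percent predicted; PRISm (preserved
ratio, impaired spirometry) is the non-obstructed FEV1 < 80% cell.  The
clock-training control group is never smokers, or former smokers who quit
at least ``quit_years_min`` years ago, with normal spirometry (GOLD 0) and
no CT emphysema (%LAA below ``emphysema_cut``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import pandas as pd


class GoldGrade(str, Enum):
    GOLD0 = "GOLD0"
    GOLD1 = "GOLD1"
    GOLD2 = "GOLD2"
    GOLD3 = "GOLD3"
    GOLD4 = "GOLD4"
    PRISM = "PRISm"
    UNGRADED = "ungraded"


class AnalysisGroup(str, Enum):
    CONTROL_TRAINING = "control_training"
    CURRENT_NO_COPD = "current_no_copd"
    DISEASE = "disease"
    EXCLUDED = "excluded"        # never smokers with COPD/emphysema (~9% in the study)
    OTHER = "other"              # former smokers quit <5 y with normal spirometry


@dataclass(frozen=True)
class GroupDefinition:
    """Thresholds for control/disease grouping.

    ``quit_years_min`` is the training-control quit rule; ``former_30day_days``
    records the separate study-visit former-smoker definition (quit and no
    cigarette in the past 30 days), kept as config because the two
    definitions coexist in cohort descriptions.
    """

    gold0_fev1pct_min: float = 80.0
    ratio_cut: float = 0.7
    emphysema_cut: float = 5.0
    quit_years_min: float = 5.0
    former_30day_days: int = 30

    def __post_init__(self):
        if not (0.0 < self.ratio_cut < 1.0):
            raise ValueError("ratio_cut must lie in (0, 1)")
        if min(self.gold0_fev1pct_min, self.emphysema_cut, self.quit_years_min) <= 0:
            raise ValueError("thresholds must be positive")


def assign_gold_grade(
    fev1_pct_pred: float, fev1_fvc: float, defs: GroupDefinition | None = None
) -> GoldGrade:
    """Grade spirometry into GOLD 0-4 or PRISm.

    GOLD 0: FEV1 >= 80% predicted and FEV1/FVC >= 0.7.  Obstructed
    (ratio < 0.7): GOLD 1 (>=80%), 2 (50-80%), 3 (30-50%), 4 (<30%).
    PRISm: ratio >= 0.7 but FEV1 < 80%.  Missing inputs map to UNGRADED.
    """
    defs = defs or GroupDefinition()
    if fev1_pct_pred is None or fev1_fvc is None:
        return GoldGrade.UNGRADED
    f, r = float(fev1_pct_pred), float(fev1_fvc)
    if math.isnan(f) or math.isnan(r) or math.isinf(f) or math.isinf(r):
        return GoldGrade.UNGRADED
    if r >= defs.ratio_cut:
        return GoldGrade.GOLD0 if f >= defs.gold0_fev1pct_min else GoldGrade.PRISM
    if f >= 80.0:
        return GoldGrade.GOLD1
    if f >= 50.0:
        return GoldGrade.GOLD2
    if f >= 30.0:
        return GoldGrade.GOLD3
    return GoldGrade.GOLD4


_SMOKING = {"never", "former", "current"}


def assign_analysis_group(row, defs: GroupDefinition | None = None) -> AnalysisGroup:
    """Assign a subject to a study analysis group.

    ``row`` is a mapping (or Series) with ``smoking_status``,
    ``fev1_pct_pred``, ``fev1_fvc``, ``emphysema_laa`` and, for former
    smokers, ``years_since_quit``.

    The "normal" test is GOLD 0 spirometry and %LAA below the emphysema
    cut.  Never/long-quit former smokers passing it are training controls;
    current smokers passing it are the current-smoker application group;
    ever-smokers failing it are the disease group; never smokers failing
    it are excluded; recently quit former smokers passing it fit no study
    group and are tagged OTHER.
    """
    defs = defs or GroupDefinition()
    status = row.get("smoking_status") if hasattr(row, "get") else row["smoking_status"]
    if status not in _SMOKING:
        raise ValueError(f"unresolvable smoking status: {status!r}")
    grade = assign_gold_grade(row["fev1_pct_pred"], row["fev1_fvc"], defs)
    if grade is GoldGrade.UNGRADED:
        raise ValueError("cannot group subject with ungradable spirometry")
    laa = float(row["emphysema_laa"])
    normal = grade is GoldGrade.GOLD0 and laa < defs.emphysema_cut
    if status == "never":
        return AnalysisGroup.CONTROL_TRAINING if normal else AnalysisGroup.EXCLUDED
    if status == "current":
        return AnalysisGroup.CURRENT_NO_COPD if normal else AnalysisGroup.DISEASE
    # former smoker
    if not normal:
        return AnalysisGroup.DISEASE
    quit_years = row.get("years_since_quit", float("nan"))
    quit_years = float("nan") if quit_years is None else float(quit_years)
    if not math.isnan(quit_years) and quit_years >= defs.quit_years_min:
        return AnalysisGroup.CONTROL_TRAINING
    return AnalysisGroup.OTHER


def assign_groups(table: pd.DataFrame, defs: GroupDefinition | None = None) -> pd.Series:
    """Vectorized :func:`assign_analysis_group` over a sample table."""
    defs = defs or GroupDefinition()
    out = table.apply(lambda r: assign_analysis_group(r, defs).value, axis=1)
    out.name = "analysis_group"
    return out
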