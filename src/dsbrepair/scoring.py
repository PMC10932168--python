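"""Comet-assay DNA repair-efficiency scoring and quartile ranking.

RepEff is the percent of bleomycin-induced DNA damage repaired after
120 min of recovery: the initial damage is set as 100% and the residual
damage fraction is subtracted, ``RepEff = 100 * (1 - t120/t0)``.  Subjects
are then ranked into four ordinal groups using the quartiles of the
control arm's RepEff distribution; group 1 is the most efficient quartile
and group 4 ("no repair") the least.  A fixed-edge scale at the published
group boundaries is also provided for reproducing the reference study's
grouping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import study_data

GROUP_LABELS = study_data.GROUP_LABELS


class DegenerateScaleError(ValueError):
    """Control RepEff distribution cannot support a quartile scale."""


def compute_repeff(damage_t0, damage_t120):
    """Percent of induced damage repaired after 120 min.

    Accepts scalars or arrays.  Values above 100 are impossible
    (damage_t120 >= 0); negative values mean damage increased during
    recovery and are retained (they rank in the worst group).
    """
    t0 = np.asarray(damage_t0, dtype=float)
    t120 = np.asarray(damage_t120, dtype=float)
    if np.any(t0 <= 0):
        raise ValueError("damage_t0 must be positive")
    out = 100.0 * (1.0 - t120 / t0)
    return out.item() if out.ndim == 0 else out


@dataclass(frozen=True)
class RepairRankScale:
    """Three strictly increasing percent-repaired cut points defining the
    four repair groups (group 4 below the first cut, group 1 at or above
    the last)."""

    cut_points: tuple[float, float, float]

    def __post_init__(self):
        c1, c2, c3 = self.cut_points
        if not (c1 < c2 < c3):
            raise DegenerateScaleError(
                f"cut points must be strictly increasing, got {self.cut_points}")

    @classmethod
    def from_control_scores(cls, control_scores) -> "RepairRankScale":
        """Quartile scale from the control arm's RepEff scores.

        Cut points are the 25th/50th/75th percentiles with linear
        interpolation between order statistics.
        """
        scores = np.asarray(control_scores, dtype=float)
        if scores.size < 4:
            raise ValueError("need at least 4 control scores for quartiles")
        cuts = np.percentile(scores, [25, 50, 75])
        return cls(tuple(float(c) for c in cuts))

    @classmethod
    def fixed_edges(cls) -> "RepairRankScale":
        """The published group boundaries of the reference study."""
        return cls(study_data.REPAIR_BIN_EDGES)

    def label(self, group: int) -> str:
        return GROUP_LABELS[group]


def assign_group(score, scale: RepairRankScale):
    """Repair group (1 = highly efficient .. 4 = no repair) for a score.

    Intervals are half-open with each cut point belonging to the
    higher-efficiency side: group 4 = (-inf, c1), group 3 = [c1, c2),
    group 2 = [c2, c3), group 1 = [c3, inf).  Vectorised over arrays.
    """
    c1, c2, c3 = scale.cut_points
    s = np.asarray(score, dtype=float)
    group = np.where(s < c1, 4, np.where(s < c2, 3, np.where(s < c3, 2, 1)))
    return int(group) if group.ndim == 0 else group


def group_to_code(group):
    """Classifier coding of the repair rank: 0..3 with 3 = group 4."""
    return np.asarray(group) - 1 if np.ndim(group) else int(group) - 1


def group_to_quartile(group):
    """Control-quartile number for a repair group (quartile 4 = best)."""
    return 5 - np.asarray(group) if np.ndim(group) else 5 - int(group)


def score_cohort(frame: pd.DataFrame,
                 scale: RepairRankScale | None = None,
                 mode: str = "quartile") -> pd.DataFrame:
    """Score and rank every subject of a cohort table.

    ``mode="quartile"`` builds the scale from the cohort's own control
    arm (the study's procedure); ``mode="fixed"`` uses the published
    edges.  An explicit ``scale`` overrides both.  Returns a frame with
    ``subject_id``, ``arm``, ``repeff``, ``group`` and the classifier
    code ``x1``.
    """
    repeff = compute_repeff(frame["damage_t0"].to_numpy(),
                            frame["damage_t120"].to_numpy())
    if scale is None:
        if mode == "fixed":
            scale = RepairRankScale.fixed_edges()
        elif mode == "quartile":
            controls = repeff[(frame["arm"] == "control").to_numpy()]
            scale = RepairRankScale.from_control_scores(controls)
        else:
            raise ValueError(f"unknown rank mode {mode!r}")
    group = assign_group(repeff, scale)
    return pd.DataFrame({
        "subject_id": frame["subject_id"].to_numpy(),
        "arm": frame["arm"].to_numpy(),
        "repeff": repeff,
        "group": group,
        "x1": group - 1,
    })


def group_count_table(scored: pd.DataFrame) -> pd.DataFrame:
    """2 x 4 arm-by-group count table from a scored cohort.

    Rows are ``control`` and ``case``; columns are groups 1..4.  Row sums
    equal the arm sizes.  Subjects with a missing group raise.
    """
    if scored["group"].isna().any():
        raise ValueError("cohort contains unranked subjects")
    table = pd.DataFrame(0, index=list(study_data.ARMS), columns=[1, 2, 3, 4])
    counts = scored.groupby(["arm", "group"]).size()
    for (arm, group), n in counts.items():
        table.loc[arm, int(group)] = int(n)
    return table


def published_group_counts() -> pd.DataFrame:
    """The reference study's 2 x 4 repair-group table."""
    return pd.DataFrame(
        {g + 1: [study_data.REPAIR_GROUP_COUNTS[arm][g]
                 for arm in study_data.ARMS]
         for g in range(4)},
        index=list(study_data.ARMS),
    )
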