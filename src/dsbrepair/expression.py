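"""qPCR relative expression (delta-Ct / 2^-dCt) and arm comparisons.

Expression of each DSB-repair gene is quantified relative to a single
reference gene (RPLP1 in the reference study):
``dCt = Ct_target - Ct_reference`` and ``fold = 2^-dCt``, one doubling of
relative abundance per delta-Ct unit.  Arms are compared on the fold
scale with per-arm medians and the Mann-Whitney rank-sum test (the
always-nonparametric policy of this package).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import MannWhitneyResult, mann_whitney


@dataclass(frozen=True)
class ExpressionRecord:
    gene: str
    ct_target: float
    ct_reference: float

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference

    @property
    def fold(self) -> float:
        return 2.0 ** (-self.delta_ct)


def fold_expression(ct_target: float, ct_reference: float,
                    gene: str = "") -> ExpressionRecord:
    """Relative expression record from a Ct pair (errors on non-finite Ct)."""
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return ExpressionRecord(gene=gene, ct_target=float(ct_target),
                            ct_reference=float(ct_reference))


@dataclass(frozen=True)
class ExpressionComparison:
    gene: str
    median_control: float
    median_case: float
    test: MannWhitneyResult

    @property
    def p_value(self) -> float:
        return self.test.p_value


def cohort_folds(frame: pd.DataFrame, gene: str) -> pd.DataFrame:
    """Per-subject expression folds of one gene from a cohort table."""
    t_col, r_col = f"{gene}_ct_target", f"{gene}_ct_ref"
    if t_col not in frame.columns or r_col not in frame.columns:
        raise KeyError(f"no Ct columns for gene {gene!r}")
    delta = frame[t_col].to_numpy(float) - frame[r_col].to_numpy(float)
    return pd.DataFrame({
        "subject_id": frame["subject_id"].to_numpy(),
        "arm": frame["arm"].to_numpy(),
        "fold": np.exp2(-delta),
    })


def compare_expression(frame: pd.DataFrame, gene: str) -> ExpressionComparison:
    """Median fold per arm and the Mann-Whitney p for one gene."""
    folds = cohort_folds(frame, gene)
    by_arm = {arm: folds.loc[folds["arm"] == arm, "fold"].to_numpy()
              for arm in ("control", "case")}
    for arm, values in by_arm.items():
        if values.size < 2:
            raise ValueError(f"need >= 2 subjects with {gene} records in {arm}")
    return ExpressionComparison(
        gene=gene,
        median_control=float(np.median(by_arm["control"])),
        median_case=float(np.median(by_arm["case"])),
        test=mann_whitney(by_arm["case"], by_arm["control"]),
    )


def expression_summary(frame: pd.DataFrame, genes) -> pd.DataFrame:
    """Tidy per-gene summary table (arm medians and p-value)."""
    rows = []
    for gene in genes:
        cmp_ = compare_expression(frame, gene)
        rows.append({"gene": gene,
                     "median_control": cmp_.median_control,
                     "median_case": cmp_.median_case,
                     "p_value": cmp_.p_value})
    return pd.DataFrame(rows)
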