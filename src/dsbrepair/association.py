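"""Case-control association statistics.

Implements the statistical toolkit of the analysis: contingency-table
odds ratios with Woolf (log-scale normal) confidence intervals, binomial
logistic regression fitted by iteratively reweighted least squares with
Wald intervals, the Mann-Whitney U rank-sum test with tie and continuity
corrections, the Hodges-Lehmann two-sample location-shift estimator, and
the Hosmer-Lemeshow goodness-of-fit test for fitted logistic models.

The study outcome is binary (RA vs healthy), so logistic regression is
binomial throughout; categorical predictors enter via dummy coding
against a declared reference category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

#: Normal quantile used for 95% intervals; the conventional 1.96 matches
#: the reference study's printed intervals.
Z_95 = 1.96


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 exposure-by-outcome table: ``a`` exposed cases, ``b`` unexposed
    cases, ``c`` exposed controls, ``d`` unexposed controls."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError("cell counts must be non-negative")
        if sum(cells) <= 0:
            raise ValueError("table is empty")

    def swap_exposure(self) -> "TwoByTwo":
        return TwoByTwo(self.b, self.a, self.d, self.c)


@dataclass
class OddsRatioResult:
    """Cross-product odds ratio with a 95% Woolf interval.

    ``defined`` is False when a zero cell makes the estimate or its
    interval degenerate (the estimate is then 0, inf or nan and the
    undefined interval bound is nan), mirroring how such rows are
    reported as "NA" in genotype tables.
    """

    or_value: float
    ci_low: float
    ci_high: float
    label: str = ""
    reference_label: str = ""
    defined: bool = True

    def contains(self, value: float) -> bool:
        """Whether the interval covers ``value`` (False if undefined)."""
        return bool(self.defined and self.ci_low <= value <= self.ci_high)


def odds_ratio_woolf(table: TwoByTwo, zero_cell: str = "na",
                     z: float = Z_95) -> OddsRatioResult:
    """Odds ratio ``ad/bc`` with the Woolf 95% confidence interval.

    The interval is ``exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d))``.
    With ``zero_cell="na"`` any empty cell flags the result undefined;
    ``zero_cell="haldane"`` applies the Haldane-Anscombe correction
    (+0.5 to every cell) instead.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if zero_cell == "haldane" and min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    elif zero_cell not in ("na", "haldane"):
        raise ValueError(f"unknown zero_cell policy {zero_cell!r}")
    if min(a, b, c, d) > 0:
        or_value = (a * d) / (b * c)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        log_or = np.log(or_value)
        return OddsRatioResult(or_value,
                               float(np.exp(log_or - z * se)),
                               float(np.exp(log_or + z * se)))
    # zero cell under the "na" policy: report the degenerate point value
    # (0 when the numerator vanishes, inf when the denominator does) with
    # undefined interval bounds.
    if a * d == 0 and b * c == 0:
        value = float("nan")
    elif a * d == 0:
        value = 0.0
    else:
        value = float("inf")
    return OddsRatioResult(value, 0.0 if value == 0.0 else float("nan"),
                           float("nan"), defined=False)


def genotype_or_table(counts: pd.DataFrame, reference: str | None = None,
                      zero_cell: str = "na", z: float = Z_95
                      ) -> list[OddsRatioResult]:
    """Per-genotype odds ratios against a reference genotype.

    ``counts`` is a genotype x arm table with ``control`` and ``case``
    columns (as produced by :func:`dsbrepair.cohort.genotype_count_frame`).
    The reference defaults to the first-listed genotype.  One result is
    returned per non-reference genotype.
    """
    counts = pd.DataFrame(counts)
    if reference is None:
        reference = counts.index[0]
    if reference not in counts.index:
        raise ValueError(f"reference genotype {reference!r} absent")
    if counts.loc[reference, "control"] == 0:
        raise ValueError("reference genotype unobserved in controls")
    results = []
    for genotype in counts.index:
        if genotype == reference:
            continue
        table = TwoByTwo(a=counts.loc[genotype, "case"],
                         b=counts.loc[reference, "case"],
                         c=counts.loc[genotype, "control"],
                         d=counts.loc[reference, "control"])
        res = odds_ratio_woolf(table, zero_cell=zero_cell, z=z)
        res.label = str(genotype)
        res.reference_label = str(reference)
        results.append(res)
    return results


def genotype_counts_from_cohort(frame: pd.DataFrame, snp_id: str,
                                genotype_order=None) -> pd.DataFrame:
    """Genotype x arm count table observed in a cohort table."""
    if snp_id not in frame.columns:
        raise KeyError(snp_id)
    if genotype_order is None:
        genotype_order = sorted(frame[snp_id].unique())
    out = pd.DataFrame(0, index=list(genotype_order),
                       columns=["control", "case"])
    for arm in out.columns:
        counts = frame.loc[frame["arm"] == arm, snp_id].value_counts()
        for genotype, n in counts.items():
            if genotype not in out.index:
                warnings.warn(
                    f"genotype {genotype!r} of {snp_id} not in declared "
                    "order; skipped")
                continue
            out.loc[genotype, arm] = int(n)
    return out


def repeff_crude_ors(group_counts: pd.DataFrame, zero_cell: str = "na",
                     z: float = Z_95) -> list[OddsRatioResult]:
    """Crude RA odds ratios of repair groups 2, 3 and 4 versus group 1.

    ``group_counts`` is the 2 x 4 arm-by-group table from
    :func:`dsbrepair.scoring.group_count_table`.  An empty reference
    cell yields undefined-flagged results under the ``na`` policy rather
    than an error.
    """
    results = []
    for group in (2, 3, 4):
        table = TwoByTwo(a=group_counts.loc["case", group],
                         b=group_counts.loc["case", 1],
                         c=group_counts.loc["control", group],
                         d=group_counts.loc["control", 1])
        res = odds_ratio_woolf(table, zero_cell=zero_cell, z=z)
        res.label = f"group {group}"
        res.reference_label = "group 1"
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# logistic regression

class CollinearityError(ValueError):
    """Design matrix is rank-deficient; names the offending columns."""


@dataclass
class LogisticFit:
    """Maximum-likelihood binomial logistic fit.

    Coefficients are on the log-odds scale; ``odds_ratios`` are their
    exponentials with Wald 95% intervals.  ``converged`` is False when
    IRLS did not reach the coefficient-change tolerance (e.g. under
    perfect separation); ``diagnostic`` then carries a short reason.
    """

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    log_likelihood: float
    converged: bool
    n_iterations: int
    fitted: np.ndarray
    diagnostic: str = ""
    z: float = Z_95

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci_low(self) -> np.ndarray:
        return np.exp(self.coef - self.z * self.se)

    @property
    def ci_high(self) -> np.ndarray:
        return np.exp(self.coef + self.z * self.se)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coef, "se": self.se, "or": self.odds_ratios,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
        }, index=self.names)


def dummy_code(values, reference=None, name: str = "x"):
    """Dummy-code a categorical vector against a reference level.

    Returns ``(matrix, column_names, levels)`` with one indicator column
    per non-reference level, ordered by sorted level.
    """
    values = pd.Series(values)
    levels = sorted(values.unique(), key=str)
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not observed")
    others = [lv for lv in levels if lv != reference]
    cols = np.column_stack([(values == lv).to_numpy(float) for lv in others]) \
        if others else np.empty((len(values), 0))
    names = [f"{name}[{lv}]" for lv in others]
    return cols, names, levels


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    # greedy scan: a column is implicated if dropping it restores rank
    bad = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(X):
            bad.append(names[j])
    raise CollinearityError(
        f"collinear design columns: {bad or names}")


def fit_logistic(outcome, predictors, feature_names=None,
                 tol: float = 1e-10, max_iter: int = 100,
                 z: float = Z_95) -> LogisticFit:
    """Fit a binomial logistic regression by IRLS.

    ``outcome`` is a 0/1 vector; ``predictors`` a numeric (already
    dummy-coded) matrix without intercept (one is added).  Convergence is
    a maximum coefficient change below ``tol`` within ``max_iter``
    Newton/IRLS steps.  Constant predictor columns and collinear dummy
    sets raise :class:`CollinearityError` naming the columns.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if feature_names is None:
        feature_names = [f"x{j + 1}" for j in range(X.shape[1])]
    names = ["intercept"] + list(feature_names)
    for j in range(X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            raise CollinearityError(
                f"predictor column {feature_names[j]!r} is constant")
    X = np.column_stack([np.ones_like(y), X])
    _check_rank(X, names)

    beta = np.zeros(X.shape[1])
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        H = (X.T * w) @ X
        grad = X.T @ (y - mu)
        try:
            delta = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(H, grad, rcond=None)[0]
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break

    mu = expit(X @ beta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    H = (X.T * w) @ X
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.nan)
    eps = 1e-300
    loglik = float(np.sum(y * np.log(mu + eps)
                          + (1 - y) * np.log(1 - mu + eps)))
    diagnostic = ""
    if not converged:
        diagnostic = "IRLS did not converge"
        if np.max(np.abs(beta)) > 15:
            diagnostic += "; coefficients diverging (possible perfect separation)"
    return LogisticFit(names=names, coef=beta, se=se, log_likelihood=loglik,
                       converged=converged, n_iterations=n_iter, fitted=mu,
                       diagnostic=diagnostic, z=z)


# ---------------------------------------------------------------------------
# rank statistics

@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_value: float
    z_score: float


def mann_whitney(x, y) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U rank-sum test.

    U is computed from midrank sums for the first sample; the two-sided p
    uses the normal approximation with tie correction and a continuity
    correction of 0.5 toward the null mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mean = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all observations identical
        return MannWhitneyResult(u1, 1.0, 0.0)
    diff = u1 - mean
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var) if diff != 0 else 0.0
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return MannWhitneyResult(u1, float(p), float(z))


def hodges_lehmann(x, y) -> float:
    """Hodges-Lehmann shift: median of all pairwise differences x_i - y_j."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(np.median(np.subtract.outer(x, y)))


# ---------------------------------------------------------------------------
# calibration

@dataclass(frozen=True)
class HosmerLemeshowResult:
    statistic: float
    p_value: float
    n_groups: int
    dof: int


def hosmer_lemeshow(fitted_probs, outcome, g: int = 10
                    ) -> HosmerLemeshowResult:
    """Hosmer-Lemeshow deciles-of-risk goodness-of-fit test.

    Subjects are sorted by fitted probability and cut into ``g``
    near-equal groups, never splitting ties across a boundary.  The
    statistic sums ``(O - E)^2 / E`` over both outcome classes in every
    group and is referred to chi-square with ``g - 2`` degrees of freedom
    (never below 1).  Groups whose expected count for either class is
    zero are merged into the neighbouring group with a warning.
    """
    p = np.asarray(fitted_probs, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if g < 2:
        raise ValueError("g must be >= 2")
    order = np.argsort(p, kind="stable")
    p, y = p[order], y[order]
    n = p.size
    boundaries = []
    for k in range(1, g):
        b = int(round(n * k / g))
        while 0 < b < n and p[b - 1] == p[b]:
            b += 1
        boundaries.append(min(b, n))
    edges = [0] + sorted(set(boundaries)) + [n]
    groups = [(lo, hi) for lo, hi in zip(edges[:-1], edges[1:]) if hi > lo]

    def cell(lo, hi):
        e1 = float(p[lo:hi].sum())
        o1 = float(y[lo:hi].sum())
        size = hi - lo
        return [o1, e1, size - o1, size - e1]

    table = [cell(lo, hi) for lo, hi in groups]
    merged = []
    for row in table:
        if merged and (row[1] == 0 or row[3] == 0
                       or merged[-1][1] == 0 or merged[-1][3] == 0):
            warnings.warn("merging risk group with zero expected count")
            merged[-1] = [m + r for m, r in zip(merged[-1], row)]
        else:
            merged.append(row)
    stat = 0.0
    for o1, e1, o0, e0 in merged:
        if e1 > 0:
            stat += (o1 - e1) ** 2 / e1
        if e0 > 0:
            stat += (o0 - e0) ** 2 / e0
    n_groups = len(merged)
    dof = max(n_groups - 2, 1)
    p_value = float(stats.chi2.sf(stat, dof)) if stat > 0 else 1.0
    return HosmerLemeshowResult(float(stat), p_value, n_groups, dof)


# ---------------------------------------------------------------------------
# display helpers

def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal rounding with ties away from zero, for table display."""
    if not np.isfinite(value):
        return value
    factor = 10 ** decimals
    return np.floor(abs(value) * factor + 0.5) / factor * np.sign(value)


def format_or(result: OddsRatioResult, decimals: int = 2) -> str:
    """Render an odds-ratio row the way association tables print them."""
    def fmt(v):
        return "NA" if not np.isfinite(v) else f"{round_half_up(v, decimals):.{decimals}f}"
    return f"{fmt(result.or_value)} ({fmt(result.ci_low)}-{fmt(result.ci_high)})"
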