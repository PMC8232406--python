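"""The study's statistical plan behind one uniform result surface.

One-way ANOVA across groups or time frames, one-way repeated-measures ANOVA
for longitudinal cage metrics, two-way ANOVA (group x fiber type, Type-II
sums of squares for unbalanced data), Tukey HSD post hoc at alpha 0.05, and
Pearson chi-squared comparisons of count distributions (capillaries per
fiber, fiber CSA) at the multiple-comparison-corrected alpha 0.0167
(= 0.05/3 for three group pairs).

Computation is delegated to scipy.stats and statsmodels; this module owns
the validation, the degenerate-case conventions (zero between-group
variance -> F = 0, p = 1), and the low-expected-count pooling rule for
chi-squared (merge adjacent bins until all expected counts >= 1 and at
least 80% are >= 5, after Cochran).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_ALPHA",
    "CHI2_CORRECTED_ALPHA",
    "StatResult",
    "PosthocPair",
    "one_way_anova",
    "repeated_measures_anova",
    "two_way_anova",
    "tukey_hsd",
    "chi_squared_distribution_test",
    "pool_low_expected_bins",
]

DEFAULT_ALPHA = 0.05
CHI2_CORRECTED_ALPHA = 0.0167  # 0.05 / 3 pairwise group comparisons


@dataclass(frozen=True)
class PosthocPair:
    pair: Tuple[object, object]
    adjusted_p: float
    significant: bool


@dataclass
class StatResult:
    """One test's outcome: statistic, degrees of freedom, p, optional post hoc."""

    test: str
    statistic: float
    df: Tuple[float, ...]
    p_value: float
    alpha: float = DEFAULT_ALPHA
    posthoc: List[PosthocPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_row(self) -> Dict[str, object]:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "df": "/".join(f"{d:g}" for d in self.df),
            "p_value": self.p_value,
            "alpha": self.alpha,
            "significant": self.significant,
        }


def _as_groups(groups: Sequence[Sequence[float]]) -> List[np.ndarray]:
    out = [np.asarray(g, dtype=float) for g in groups]
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(out):
        if len(g) < 2:
            raise ValueError(f"group {i} has n < 2")
    return out


def one_way_anova(
    groups: Sequence[Sequence[float]],
    alpha: float = DEFAULT_ALPHA,
    posthoc: bool = False,
) -> StatResult:
    """Classical between/within one-way ANOVA, df (k-1, N-k).

    With ``posthoc=True`` a Tukey HSD pass is attached when the omnibus F is
    significant at ``alpha``.
    """
    arrays = _as_groups(groups)
    k = len(arrays)
    n_total = sum(len(g) for g in arrays)
    f_stat, p = stats.f_oneway(*arrays)
    if not np.isfinite(f_stat):  # zero within- and between-variance
        f_stat, p = 0.0, 1.0
    result = StatResult(
        test="one_way_anova",
        statistic=float(f_stat),
        df=(k - 1, n_total - k),
        p_value=float(p),
        alpha=alpha,
    )
    if posthoc and result.significant:
        result.posthoc = tukey_hsd(arrays, alpha=alpha).posthoc
    return result


def repeated_measures_anova(
    matrix: np.ndarray | pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> StatResult:
    """Within-subject one-way ANOVA on a complete subject x timepoint matrix.

    Subject effects are removed; df = (t-1, (t-1)(n-1)); sphericity is
    assumed (no Greenhouse-Geisser correction).  Missing cells raise (no
    imputation).  A matrix with no timepoint effect and no residual
    variance (all timepoints equal per subject) returns F = 0, p = 1.
    """
    data = np.asarray(
        matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else matrix, dtype=float
    )
    if data.ndim != 2:
        raise ValueError("expected a 2-D subject x timepoint matrix")
    if np.isnan(data).any():
        raise ValueError("missing cells are not allowed (no imputation)")
    n, t = data.shape
    if n < 2 or t < 2:
        raise ValueError("need >= 2 subjects and >= 2 timepoints")

    grand = data.mean()
    subj_means = data.mean(axis=1, keepdims=True)
    time_means = data.mean(axis=0, keepdims=True)
    ss_time = n * float(((time_means - grand) ** 2).sum())
    residual = data - subj_means - time_means + grand
    ss_error = float((residual**2).sum())
    df_time = t - 1
    df_error = (t - 1) * (n - 1)
    if ss_time <= 1e-12 * max(ss_error, 1.0) and ss_error <= 1e-12:
        f_stat, p = 0.0, 1.0
    elif ss_error <= 1e-12:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (ss_time / df_time) / (ss_error / df_error)
        p = float(stats.f.sf(f_stat, df_time, df_error))
    return StatResult(
        test="repeated_measures_anova",
        statistic=float(f_stat),
        df=(df_time, df_error),
        p_value=float(p),
        alpha=alpha,
    )


def two_way_anova(
    data: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
    alpha: float = DEFAULT_ALPHA,
) -> Dict[str, StatResult]:
    """Two-way ANOVA with Type-II sums of squares for unbalanced data.

    Returns StatResults keyed ``factor_a``, ``factor_b`` and
    ``"interaction"``.  Every factor combination must be observed (empty
    cells raise).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for factor in (factor_a, factor_b):
        if data[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} needs >= 2 levels")
    cell_counts = data.groupby([factor_a, factor_b], observed=True).size()
    full = data[factor_a].nunique() * data[factor_b].nunique()
    if len(cell_counts) < full or (cell_counts < 1).any():
        raise ValueError("empty factor cells")

    local = data[[response, factor_a, factor_b]].rename(
        columns={response: "y", factor_a: "fa", factor_b: "fb"}
    )
    model = smf.ols("y ~ C(fa) * C(fb)", data=local).fit()
    table = sm.stats.anova_lm(model, typ=2)
    df_resid = float(table.loc["Residual", "df"])

    def _extract(term: str, label: str) -> StatResult:
        row = table.loc[term]
        return StatResult(
            test=f"two_way_anova[{label}]",
            statistic=float(row["F"]),
            df=(float(row["df"]), df_resid),
            p_value=float(row["PR(>F)"]),
            alpha=alpha,
        )

    return {
        factor_a: _extract("C(fa)", factor_a),
        factor_b: _extract("C(fb)", factor_b),
        "interaction": _extract("C(fa):C(fb)", "interaction"),
    }


def tukey_hsd(
    groups: Sequence[Sequence[float]],
    labels: Sequence[object] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> StatResult:
    """Studentized-range-adjusted pairwise comparisons (Tukey HSD)."""
    arrays = _as_groups(groups)
    labels = list(labels) if labels is not None else list(range(len(arrays)))
    res = stats.tukey_hsd(*arrays)
    pairs: List[PosthocPair] = []
    max_p = 0.0
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            p = float(np.clip(res.pvalue[i, j], 0.0, 1.0))
            max_p = max(max_p, p)
            pairs.append(
                PosthocPair(pair=(labels[i], labels[j]), adjusted_p=p, significant=p < alpha)
            )
    return StatResult(
        test="tukey_hsd",
        statistic=float(min(p.adjusted_p for p in pairs)),
        df=(len(arrays), sum(len(g) for g in arrays) - len(arrays)),
        p_value=float(min(p.adjusted_p for p in pairs)),
        alpha=alpha,
        posthoc=pairs,
    )


def pool_low_expected_bins(table: np.ndarray) -> np.ndarray:
    """Merge adjacent histogram bins until expected counts satisfy Cochran.

    ``table`` is a 2 x k contingency of two observed histograms on shared
    bin edges.  Adjacent columns are merged (smallest expected column into
    its smaller neighbor) until every expected count is >= 1 and at least
    80% are >= 5.  Proportional tables (statistic 0) are unchanged in
    statistic by pooling.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("expected a 2-D contingency table")

    def _expected(t: np.ndarray) -> np.ndarray:
        return np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()

    while table.shape[1] > 1:
        exp = _expected(table)
        ok = np.all(exp >= 1.0) and (exp >= 5.0).mean() >= 0.8
        if ok:
            break
        col = int(np.argmin(exp.sum(axis=0)))
        if col == 0:
            neighbor = 1
        elif col == table.shape[1] - 1:
            neighbor = col - 1
        else:
            neighbor = col - 1 if exp[:, col - 1].sum() <= exp[:, col + 1].sum() else col + 1
        lo, hi = sorted((col, neighbor))
        merged = table[:, lo] + table[:, hi]
        table = np.delete(table, hi, axis=1)
        table[:, lo] = merged
    return table


def chi_squared_distribution_test(
    observed_a: Sequence[float],
    observed_b: Sequence[float],
    alpha: float = CHI2_CORRECTED_ALPHA,
    pool: bool = True,
) -> StatResult:
    """Pearson chi-squared on the 2 x k contingency of two histograms.

    The histograms must share bin edges; judged at the corrected alpha
    (default 0.0167).  Low-expected-count bins are pooled first (see
    :func:`pool_low_expected_bins`); identical histograms give statistic 0,
    p = 1.
    """
    a = np.asarray(observed_a, dtype=float)
    b = np.asarray(observed_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("histograms must share bin edges")
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("all-zero histogram")
    table = np.vstack([a, b])
    if pool:
        table = pool_low_expected_bins(table)
    if table.shape[1] < 2:
        return StatResult(
            test="chi_squared",
            statistic=0.0,
            df=(1,),
            p_value=1.0,
            alpha=alpha,
        )
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return StatResult(
        test="chi_squared",
        statistic=float(chi2),
        df=(float(dof),),
        p_value=float(p),
        alpha=alpha,
    )
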