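"""Yield validation regression and the statistical comparison toolbox.

The packaged 21-site table of literature versus modeled aboveground
dry-mass yields (Mg ha-1) anchors the validation: ordinary least squares of
modeled on literature yield gives r^2 = 0.82 for the cane sites.  The
comparison machinery used on annual model output is: paired t-tests (each
simulation year is a paired replicate across soils or land uses, n = 15),
the Wilcoxon rank-sum test where variances differ, the Fligner-Killeen test
for heteroscedasticity, and a Storey-style positive-FDR q-value procedure
for the matrix of pairwise comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from ._resources import packaged_csv_path

__all__ = [
    "YieldRecord",
    "RegressionResult",
    "PairedTestResult",
    "load_yield_table",
    "load_table2_fixture",
    "yield_regression",
    "paired_t",
    "wilcoxon_rank_sum",
    "fligner_killeen",
    "storey_fdr",
    "comparison_matrix",
]

_YIELD_TABLE_ROWS = 21


@dataclass(frozen=True)
class YieldRecord:
    """One validation site: literature vs modeled yield plus site climate."""

    site: str
    lit_yield: float     # Mg dry mass ha-1
    model_yield: float   # Mg dry mass ha-1
    tmax: float          # mean annual max temperature, degC
    tmin: float
    precip: float        # mean annual precipitation, mm
    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if self.lit_yield <= 0 or self.model_yield <= 0:
            raise ValueError("yields must be positive")
        if abs(self.latitude) > 90 or abs(self.longitude) > 180:
            raise ValueError("coordinates out of range")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")
        if self.n < 3:
            raise ValueError("regression needs n >= 3")


@dataclass(frozen=True)
class PairedTestResult:
    test: str
    statistic: float
    p_value: float
    df: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def load_yield_table() -> list[YieldRecord]:
    """The packaged 21-row literature-vs-model cane yield table."""
    df = pd.read_csv(packaged_csv_path("validation_yields.csv"))
    if len(df) != _YIELD_TABLE_ROWS:
        raise RuntimeError(
            f"packaged yield table corrupt: {len(df)} rows, "
            f"expected {_YIELD_TABLE_ROWS}")
    return [YieldRecord(**row) for row in df.to_dict(orient="records")]


# alias kept for discoverability from the validation workflow
load_table2_fixture = load_yield_table


def yield_regression(records: list[YieldRecord]) -> RegressionResult:
    """OLS of modeled yield on literature yield.

    Note r^2 is symmetric in the two orientations for simple regression;
    slope and intercept are reported for the modeled-on-literature fit.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    x = np.array([r.lit_yield for r in records])
    y = np.array([r.model_yield for r in records])
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate predictor: zero variance")
    fit = _sps.linregress(x, y)
    return RegressionResult(slope=float(fit.slope),
                            intercept=float(fit.intercept),
                            r_squared=float(fit.rvalue ** 2), n=len(records))


def paired_t(x, y) -> PairedTestResult:
    """Two-sided paired t-test: t = mean(d) / (sd(d)/sqrt(n)), df = n - 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need equal-length 1-d samples with n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero variance of paired differences")
    n = d.size
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * _sps.t.sf(abs(t), n - 1)
    return PairedTestResult(test="paired_t", statistic=float(t),
                            p_value=float(p), df=float(n - 1))


def wilcoxon_rank_sum(x, y) -> PairedTestResult:
    """Wilcoxon rank-sum / Mann-Whitney test (two-sided).

    The reported statistic W is the Mann-Whitney U of the first sample
    (its rank sum minus n(n+1)/2), the convention of R's ``wilcox.test``;
    complete separation of two n = 15 samples gives the maximal W = 225.
    Exact p-values for small untied samples, normal approximation with tie
    correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = _sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return PairedTestResult(test="wilcoxon_rank_sum",
                            statistic=float(res.statistic),
                            p_value=float(res.pvalue))


def fligner_killeen(*groups) -> PairedTestResult:
    """Fligner-Killeen test for homogeneity of variances across groups.

    Rank-based normal scores on |x - group median|; the statistic is
    chi-squared with k - 1 degrees of freedom under the null.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs n >= 2")
    stat, p = _sps.fligner(*groups)
    return PairedTestResult(test="fligner_killeen", statistic=float(stat),
                            p_value=float(p), df=float(len(groups) - 1))


def storey_fdr(p_values, lambda_: float = 0.5) -> tuple[float, np.ndarray]:
    """Storey's pFDR q-values.

    pi0 is estimated as ``#{p > lambda} / ((1 - lambda) m)`` clipped to 1;
    q-values follow the step-up formula ``q_(i) = min_{j >= i}
    pi0 * m * p_(j) / j`` and are monotone non-decreasing in p.
    Returns ``(pi0, q_values)`` with q in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 < lambda_ < 1.0:
        raise ValueError("lambda_ must lie in (0, 1)")
    m = p.size
    pi0 = min(1.0, np.count_nonzero(p > lambda_) / ((1.0 - lambda_) * m))
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return float(pi0), q


def comparison_matrix(frames: dict[str, pd.Series | np.ndarray],
                      pairs: list[tuple[str, str]],
                      variables: list[str] | None = None,
                      lambda_: float = 0.5) -> pd.DataFrame:
    """Paired-test matrix over annual series with a Storey q-value column.

    ``frames`` maps scenario labels to DataFrames of annual values (or to
    1-d series when ``variables`` is None); each requested pair is compared
    with a paired t-test per variable, and the whole matrix of p-values is
    FDR-adjusted.
    """
    rows = []
    for a, b in pairs:
        fa, fb = frames[a], frames[b]
        cols = variables or (list(fa.columns) if hasattr(fa, "columns") else [None])
        for var in cols:
            xa = fa[var] if var is not None else fa
            xb = fb[var] if var is not None else fb
            try:
                res = paired_t(np.asarray(xa), np.asarray(xb))
                rows.append({"pair": f"{a} vs {b}", "variable": var or "value",
                             "t": res.statistic, "df": res.df,
                             "p_value": res.p_value})
            except ValueError:
                rows.append({"pair": f"{a} vs {b}", "variable": var or "value",
                             "t": np.nan, "df": np.nan, "p_value": np.nan})
    df = pd.DataFrame(rows)
    mask = df["p_value"].notna()
    if mask.any():
        pi0, q = storey_fdr(df.loc[mask, "p_value"].to_numpy(), lambda_)
        df.loc[mask, "q_value"] = q
        df.attrs["pi0"] = pi0
    return df
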