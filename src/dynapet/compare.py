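"""Cross-reconstruction comparison statistics.

For every pair of reconstruction methods the cohort analysis computes an
ordinary-least-squares regression between per-subject parameter values
(slope, intercept, squared Pearson correlation) and two-sided t-tests — the
paired Student t on the per-subject differences and the Welch unequal-
variance two-sample t with Welch–Satterthwaite degrees of freedom — at
alpha = 0.05, plus per-method group summaries (mean, SD, n).  Both t-test
variants are reported because clinical method-agreement tables are phrased
either way; no multiple-testing correction is applied, though a Bonferroni
column is emitted for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionResult",
    "PairedTestResult",
    "GroupSummary",
    "linear_regression",
    "paired_tests",
    "permutation_welch_pvalue",
    "method_comparison_report",
    "ALPHA",
]

ALPHA = 0.05


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    degrees_of_freedom: float
    p_value: float
    variant: str  # "paired_t" | "welch"
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sd: float
    n: int
    label: str


def linear_regression(x, y) -> RegressionResult:
    """OLS of y on x; r_squared is the squared Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x: slope undefined")
    res = stats.linregress(x, y)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r_squared=float(res.rvalue**2), n=int(x.size))


def paired_tests(a, b) -> tuple[PairedTestResult, PairedTestResult]:
    """Two-sided paired-t and Welch-t results for two samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("paired test needs equal-length samples of size >= 2")
    d = a - b
    if np.ptp(d) == 0 and np.all(d == d[0]):
        if d[0] == 0:
            # identical samples: t = 0 by convention
            paired = PairedTestResult(0.0, float(a.size - 1), 1.0, "paired_t")
        else:
            raise ValueError("zero variance of differences: paired test degenerate")
    else:
        tr = stats.ttest_rel(a, b)
        paired = PairedTestResult(float(tr.statistic), float(a.size - 1),
                                  float(tr.pvalue), "paired_t")
    tw = stats.ttest_ind(a, b, equal_var=False)
    welch = PairedTestResult(float(tw.statistic), float(tw.df), float(tw.pvalue), "welch")
    return paired, welch


def permutation_welch_pvalue(a, b, n_permutations: int = 10_000, seed=0) -> float:
    """Sign-flip permutation approximation to the two-sided location test.

    Pairs are kept and signs of differences flipped, the natural null
    resampling for same-subject method comparisons.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = a - b
    rng = np.random.default_rng(seed)
    obs = abs(d.mean())
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, d.size))
    null = np.abs((signs * d).mean(axis=1))
    return float((np.sum(null >= obs - 1e-15) + 1) / (n_permutations + 1))


def _pairwise_table(values: pd.DataFrame, parameter: str) -> pd.DataFrame:
    """One row per method pair for a wide per-subject value table."""
    methods = list(values.columns)
    rows = []
    n_pairs = len(list(combinations(methods, 2)))
    for m1, m2 in combinations(methods, 2):
        x, y = values[m1].to_numpy(), values[m2].to_numpy()
        reg = linear_regression(x, y)
        paired, welch = paired_tests(x, y)
        rows.append({
            "parameter": parameter,
            "pair": f"{m1}-{m2}",
            "slope": reg.slope,
            "intercept": reg.intercept,
            "r_squared": reg.r_squared,
            "p_paired": paired.p_value,
            "p_welch": welch.p_value,
            "welch_df": welch.degrees_of_freedom,
            "significant_welch": welch.p_value < ALPHA,
            "p_welch_bonferroni": min(welch.p_value * n_pairs, 1.0),
            "n": reg.n,
        })
    return pd.DataFrame(rows)


def method_comparison_report(fits: pd.DataFrame, suvs: pd.DataFrame | None = None):
    """Pairwise regressions/t-tests and group summaries across methods.

    ``fits`` needs columns subject, method, K1, k2; ``suvs`` (optional)
    subject, method, t_min, suv_mean.  Subjects missing any method are
    dropped with a warning.  Returns dict with 'pairwise' and 'group'
    DataFrames; a pure function of its inputs.
    """
    import warnings

    methods = sorted(fits["method"].unique())
    counts = fits.groupby("subject")["method"].nunique()
    complete = counts[counts == len(methods)].index
    dropped = set(fits["subject"].unique()) - set(complete)
    if dropped:
        warnings.warn(f"dropping subjects missing methods: {sorted(dropped)}", stacklevel=2)
    fits = fits[fits["subject"].isin(complete)]

    tables = []
    for param in ("K1", "k2"):
        wide = fits.pivot(index="subject", columns="method", values=param)[methods]
        tables.append(_pairwise_table(wide, param))
    group_rows = [
        {"parameter": param, "method": m,
         "mean": float(fits.loc[fits["method"] == m, param].mean()),
         "sd": float(fits.loc[fits["method"] == m, param].std(ddof=1)),
         "n": int((fits["method"] == m).sum())}
        for param in ("K1", "k2") for m in methods
    ]

    if suvs is not None:
        suvs = suvs[suvs["subject"].isin(complete)]
        for t in sorted(suvs["t_min"].unique()):
            sub = suvs[suvs["t_min"] == t]
            wide = sub.pivot(index="subject", columns="method", values="suv_mean")[methods]
            tables.append(_pairwise_table(wide, f"SUV_{t:g}min"))
            for m in methods:
                vals = sub.loc[sub["method"] == m, "suv_mean"]
                group_rows.append({"parameter": f"SUV_{t:g}min", "method": m,
                                   "mean": float(vals.mean()),
                                   "sd": float(vals.std(ddof=1)),
                                   "n": int(vals.size)})

    return {
        "pairwise": pd.concat(tables, ignore_index=True),
        "group": pd.DataFrame(group_rows),
    }
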