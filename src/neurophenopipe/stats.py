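"""Group-level inference: ANOVA, Dunnett many-to-one, exact tests, power.

The study design compares several treated groups (vehicle and three dose
levels) against a shared untreated control, so the post-hoc procedure of
choice is Dunnett's many-to-one test, which controls the family-wise
error rate through the joint multivariate-t distribution of the
comparison statistics (equicorrelated with ρ = 1/2 in the balanced case;
exact ρᵢⱼ = √(nᵢnⱼ/((nᵢ+n₀)(nⱼ+n₀))) otherwise).  Categorical outcomes
(seizure incidence, severity category distributions) use Fisher's exact
and Pearson χ² tests; non-normal outcomes can be rank-transformed before
ANOVA; a-priori per-group sample sizes come from two-sample t power.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as spstats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import AnovaRM, anova_lm

__all__ = [
    "TestResult",
    "anova",
    "dunnett",
    "dunnett_critical_value",
    "dunnett_tstats",
    "fisher_exact",
    "chi_square",
    "rank_transform",
    "required_n",
]

ALPHA = 0.05


@dataclass
class TestResult:
    """Uniform container for a statistical test outcome."""

    name: str
    statistic: float
    df: tuple[float, ...] | float | None
    p_value: float
    table: pd.DataFrame | None = None
    alpha: float = ALPHA
    details: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def anova(data: pd.DataFrame, dv: str = "value",
          factors: Sequence[str] = ("group",),
          subject: str | None = None) -> TestResult:
    """Factorial ANOVA on a tidy table (Type-II sums of squares).

    ``factors`` holds one or two categorical column names; with two
    factors the interaction is included.  With ``subject`` set, a
    repeated-measures ANOVA (within-subject factors, balanced design) is
    run instead via :class:`statsmodels.stats.anova.AnovaRM`.

    Returns the first factor's F and p as the headline statistic, with
    the full per-term table attached.
    """
    factors = list(factors)
    if not 1 <= len(factors) <= 2:
        raise ValueError("one or two factors supported")
    for f in factors:
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than two levels")
    if subject is not None:
        res = AnovaRM(data, depvar=dv, subject=subject,
                      within=factors).fit()
        tab = res.anova_table
        first = factors[0]
        return TestResult(
            name="rm-anova", statistic=float(tab.loc[first, "F Value"]),
            df=(float(tab.loc[first, "Num DF"]),
                float(tab.loc[first, "Den DF"])),
            p_value=float(tab.loc[first, "Pr > F"]), table=tab)
    terms = [f"C(Q('{f}'))" for f in factors]
    if len(terms) == 2:
        formula = f"Q('{dv}') ~ {terms[0]} * {terms[1]}"
    else:
        formula = f"Q('{dv}') ~ {terms[0]}"
    fit = ols(formula, data=data).fit()
    tab = anova_lm(fit, typ=2)
    first_term = terms[0]
    return TestResult(
        name="anova", statistic=float(tab.loc[first_term, "F"]),
        df=(float(tab.loc[first_term, "df"]),
            float(tab.loc["Residual", "df"])),
        p_value=float(tab.loc[first_term, "PR(>F)"]), table=tab,
        details={"type": "II"})


def _groups_from_table(data: pd.DataFrame, dv: str, group: str,
                       control: str) -> tuple[np.ndarray, list, list]:
    if control not in set(data[group]):
        raise ValueError(f"control group {control!r} absent from table")
    ctrl = data.loc[data[group] == control, dv].to_numpy(dtype=float)
    labels = [g for g in pd.unique(data[group]) if g != control]
    if not labels:
        raise ValueError("need at least one treated group")
    treated = [data.loc[data[group] == g, dv].to_numpy(dtype=float)
               for g in labels]
    return ctrl, labels, treated


def dunnett(data: pd.DataFrame, control: str, dv: str = "value",
            group: str = "group", alpha: float = ALPHA,
            seed: int | None = 0) -> TestResult:
    """Dunnett's many-to-one comparison of every group against a control.

    Input is a tidy table with a group column and a value column.
    Adjusted p-values come from the multivariate-t distribution of the
    comparison statistics (single-step procedure); ``seed`` fixes the
    quasi–Monte-Carlo evaluation of its tail so results are reproducible.

    The result table has one row per treated group with the t statistic
    and family-wise adjusted p-value.
    """
    ctrl, labels, treated = _groups_from_table(data, dv, group, control)
    res = spstats.dunnett(*treated, control=ctrl,
                          random_state=np.random.default_rng(seed))
    tab = pd.DataFrame({
        "comparison": [f"{g} vs {control}" for g in labels],
        "group": labels,
        "n": [len(t) for t in treated],
        "statistic": res.statistic,
        "p_adj": res.pvalue,
    })
    worst = int(np.argmin(res.pvalue))
    return TestResult(name="dunnett",
                      statistic=float(res.statistic[worst]),
                      df=None, p_value=float(res.pvalue[worst]),
                      table=tab, alpha=alpha,
                      details={"control": control,
                               "n_control": len(ctrl)})


def dunnett_tstats(control: np.ndarray,
                   treated: Sequence[np.ndarray]) -> np.ndarray:
    """Many-to-one t statistics with the pooled within-group variance.

    Supports batched simulation: each input may be ``(..., n)`` with a
    common leading shape; statistics are returned with that leading
    shape and one trailing axis per treated group.
    """
    control = np.asarray(control, dtype=float)
    treated = [np.asarray(t, dtype=float) for t in treated]
    n0 = control.shape[-1]
    ns = [t.shape[-1] for t in treated]
    ss = ((control - control.mean(axis=-1, keepdims=True)) ** 2).sum(axis=-1)
    for t in treated:
        ss = ss + ((t - t.mean(axis=-1, keepdims=True)) ** 2).sum(axis=-1)
    df = n0 + sum(ns) - (len(treated) + 1)
    s2 = ss / df
    stats = [
        (t.mean(axis=-1) - control.mean(axis=-1))
        / np.sqrt(s2 * (1.0 / n + 1.0 / n0))
        for t, n in zip(treated, ns)
    ]
    return np.stack(stats, axis=-1)


def dunnett_critical_value(n_control: int, n_treated: Sequence[int],
                           alpha: float = ALPHA, seed: int = 0,
                           two_sided: bool = True) -> float:
    """Critical |t| of the single-step Dunnett procedure.

    Solves ``P(max_i |T_i| > c) = alpha`` where the ``T_i`` follow a
    multivariate t with the many-to-one correlation structure
    ``ρᵢⱼ = √(nᵢ nⱼ / ((nᵢ+n₀)(nⱼ+n₀)))`` and pooled-variance degrees of
    freedom.  Evaluated by quasi–Monte-Carlo integration (seeded).
    """
    ns = np.asarray(list(n_treated), dtype=float)
    n0 = float(n_control)
    k = len(ns)
    df = int(n0 + ns.sum() - (k + 1))
    lam = np.sqrt(ns / (ns + n0))
    corr = np.outer(lam, lam)
    np.fill_diagonal(corr, 1.0)
    mvt = spstats.multivariate_t(loc=np.zeros(k), shape=corr, df=df)

    def fwer(c: float) -> float:
        rng = np.random.default_rng(seed)
        lower = -c * np.ones(k) if two_sided else -np.inf * np.ones(k)
        inside = mvt.cdf(c * np.ones(k), lower_limit=lower,
                         random_state=rng)
        return 1.0 - inside

    return float(optimize.brentq(lambda c: fwer(c) - alpha, 1.0, 8.0,
                                 xtol=1e-4))


def fisher_exact(table: np.ndarray | Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher exact test for a 2×2 contingency table.

    The two-sided p-value sums hypergeometric probabilities (margins
    fixed) of all tables no more probable than the observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("fisher_exact needs a 2×2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t < 0) or np.any(t != np.floor(t)):
            raise ValueError("counts must be non-negative integers")
        t = t.astype(int)
    res = spstats.fisher_exact(t, alternative="two-sided")
    return TestResult(name="fisher-exact", statistic=float(res.statistic),
                      df=None, p_value=float(res.pvalue))


def chi_square(table: np.ndarray | pd.DataFrame) -> TestResult:
    """Pearson χ² test of independence for an r×k count table."""
    t = np.asarray(table, dtype=float)
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero-margin row or column")
    res = spstats.chi2_contingency(t, correction=False)
    return TestResult(name="chi-square", statistic=float(res.statistic),
                      df=float(res.dof), p_value=float(res.pvalue))


def rank_transform(values: Sequence[float]) -> np.ndarray:
    """Ranks 1..n with ties mid-ranked, for rank-based ANOVA."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("rank_transform needs at least one value")
    return spstats.rankdata(arr)


def _t_power(n: int, d: float, alpha: float, two_sided: bool) -> float:
    df = 2 * n - 2
    nc = d * np.sqrt(n / 2.0)
    if two_sided:
        tcrit = spstats.t.ppf(1.0 - alpha / 2.0, df)
        # the opposite-tail term underflows to nan at huge noncentrality
        lower = np.nan_to_num(spstats.nct.cdf(-tcrit, df, nc))
        return float(spstats.nct.sf(tcrit, df, nc) + lower)
    tcrit = spstats.t.ppf(1.0 - alpha, df)
    return float(spstats.nct.sf(tcrit, df, nc))


def required_n(effect_size_d: float, alpha: float = ALPHA,
               power: float = 0.8, two_sided: bool = True,
               n_max: int = 100000) -> int:
    """Smallest per-group n giving a two-sample t test the target power.

    Uses the noncentral-t power function with noncentrality
    ``d·√(n/2)`` and increments n until the target is reached (the
    a-priori sample-size computation of standard power software).
    """
    if effect_size_d <= 0:
        raise ValueError("effect size must be positive")
    for n in range(2, n_max + 1):
        if _t_power(n, effect_size_d, alpha, two_sided) >= power:
            return n
    raise ValueError("no attainable n below n_max")
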