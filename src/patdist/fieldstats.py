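"""Supporting field statistics: contingency chi-square, exact binomial
test, ML logistic regression with likelihood-ratio tests, and one-way
ANOVA with Tukey HSD.

These are the classical tests used around the image analysis: 2x2
chi-square for behavioral count tables (no continuity correction — the
printed field statistics match the uncorrected form), the exact binomial
tail for win/loss records, logistic regression of a binary body-color
outcome (brown vs green) on month and snout-vent length with per-term
likelihood-ratio chi-squares, and ANOVA/Tukey for body-length differences
among pattern classes. Logistic models are plain maximum likelihood; a
grouping variable such as year can be included as a fixed covariate but
no random-effect (GEE) machinery is provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.api import Logit
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .imaging import ValidationError


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b) in row 1 and (c, d) in row 2; rows are groups,
    columns are outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValidationError("cells must be non-negative integers")
        if sum(cells) < 1:
            raise ValidationError("empty table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def chi2_2x2(
    table: ContingencyTable2x2 | tuple[int, int, int, int],
    method: str = "pearson",
) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) for a 2x2 table.

    Returns (statistic, df=1, p). The statistic is the closed form
    N(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); the p-value comes from the
    chi-square distribution with 1 df. ``method="fisher"`` returns
    Fisher's exact test instead (statistic is then the odds ratio).
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(*table)
    a, b, c, d = table.a, table.b, table.c, table.d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        raise ValidationError("degenerate table: a row or column margin is zero")
    if method == "fisher":
        res = stats.fisher_exact([[a, b], [c, d]])
        return float(res.statistic), 1, float(res.pvalue)
    if method != "pearson":
        raise ValidationError(f"unknown method {method!r}")
    n = table.total
    statistic = n * (a * d - b * c) ** 2 / np.prod([float(m) for m in margins])
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), 1, p


def binomial_exact_test(
    k: int, n: int, null_p: float = 0.5, alternative: str = "greater"
) -> float:
    """Exact binomial tail probability.

    ``greater`` gives P(X >= k) under Binomial(n, null_p); ``two_sided``
    is the standard exact two-sided test (sum of outcomes no more likely
    than the observed one).
    """
    if not 0 <= k <= n:
        raise ValidationError("need 0 <= k <= n")
    if not 0 < null_p < 1:
        raise ValidationError("null_p must lie strictly inside (0, 1)")
    alt = {"greater": "greater", "two_sided": "two-sided"}.get(alternative)
    if alt is None:
        raise ValidationError(f"unknown alternative {alternative!r}")
    return float(stats.binomtest(k, n, null_p, alternative=alt).pvalue)


@dataclass
class LogisticFitResult:
    """ML logistic fit with per-term likelihood-ratio tests.

    ``params`` maps 'intercept' and each predictor to its coefficient on
    the logit scale; ``lr_chi2``/``lr_p`` hold the 1-df likelihood-ratio
    chi-square for dropping each predictor from the full model.
    """

    params: dict[str, float]
    llf: float
    lr_chi2: dict[str, float]
    lr_p: dict[str, float]
    n: int
    positive_level: str


def _fit_logit(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    model = Logit(y, X)
    try:
        fit = model.fit(disp=0, method="newton", maxiter=100, tol=1e-8)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ValidationError(f"logistic fit failed to converge: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise ValidationError("logistic fit did not converge")
    return np.asarray(fit.params), float(fit.llf)


def logistic_fit_lr(
    data: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    positive_level: str | None = None,
) -> LogisticFitResult:
    """Fit P(outcome = positive level) ~ logistic(linear predictors) by
    maximum likelihood and test each term by likelihood ratio.

    The outcome column may be numeric 0/1 or two-level labels (e.g.
    brown/green); by default the lexicographically first level is modeled
    as the positive outcome. Each term's LR chi-square is
    2(LL_full - LL_without_term), df = 1.
    """
    if outcome not in data.columns:
        raise ValidationError(f"outcome column {outcome!r} not in data")
    for p in predictors:
        if p not in data.columns:
            raise ValidationError(f"predictor column {p!r} not in data")
    ycol = data[outcome]
    levels = sorted(pd.unique(ycol.astype(str)))
    if len(levels) != 2:
        raise ValidationError(
            f"outcome must take exactly 2 values, got {levels}"
        )
    if positive_level is None:
        positive_level = levels[0]
    elif str(positive_level) not in levels:
        raise ValidationError(f"positive level {positive_level!r} not among {levels}")
    y = (ycol.astype(str) == str(positive_level)).to_numpy(dtype=float)
    n = len(y)
    if n <= len(predictors) + 2:
        raise ValidationError("too few observations for the requested model")
    X = np.column_stack(
        [np.ones(n)] + [data[p].to_numpy(dtype=float) for p in predictors]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("design matrix is rank deficient")
    params, llf = _fit_logit(y, X)
    names = ["intercept"] + list(predictors)
    lr_chi2, lr_p = {}, {}
    for j, term in enumerate(predictors, start=1):
        X_red = np.delete(X, j, axis=1)
        _, llf_red = _fit_logit(y, X_red)
        chi2 = max(0.0, 2.0 * (llf - llf_red))
        lr_chi2[term] = chi2
        lr_p[term] = float(stats.chi2.sf(chi2, df=1))
    return LogisticFitResult(
        params=dict(zip(names, params.tolist())),
        llf=llf,
        lr_chi2=lr_chi2,
        lr_p=lr_p,
        n=n,
        positive_level=str(positive_level),
    )


@dataclass
class AnovaTukeyResult:
    F: float
    df1: int
    df2: int
    p: float
    tukey: pd.DataFrame  # columns: group1, group2, meandiff, p_adj, reject


def anova_tukey(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> AnovaTukeyResult:
    """One-way fixed-effects ANOVA plus all-pairs Tukey HSD.

    The HSD uses the studentized-range distribution with the
    Tukey-Kramer unequal-n generalization.
    """
    names = sorted(groups)
    if len(names) < 2:
        raise ValidationError("need >= 2 groups")
    arrays = []
    for name in names:
        vals = np.asarray(groups[name], dtype=float)
        if len(vals) < 2:
            raise ValidationError(f"group {name!r} has < 2 values")
        arrays.append(vals)
    if all(np.var(a) == 0 for a in arrays):
        raise ValidationError("zero within-group variance in every group")
    F, p = stats.f_oneway(*arrays)
    df1 = len(names) - 1
    df2 = sum(len(a) for a in arrays) - len(names)
    values = np.concatenate(arrays)
    labels = np.concatenate([[name] * len(a) for name, a in zip(names, arrays)])
    hsd = pairwise_tukeyhsd(values, labels, alpha=alpha)
    tukey = pd.DataFrame(
        hsd.summary().data[1:], columns=[str(c) for c in hsd.summary().data[0]]
    ).rename(columns={"p-adj": "p_adj"})
    return AnovaTukeyResult(F=float(F), df1=df1, df2=df2, p=float(p), tukey=tukey)
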