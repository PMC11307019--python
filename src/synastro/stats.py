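"""Normality-gated test selection and multiple-comparison orchestration.

Two-group comparisons follow a fixed decision tree: Shapiro-Wilk
normality is checked per group and Levene's test for homogeneity of
variances on the pair; when neither gate is significant at alpha the
comparison is a Student t-test, otherwise a Mann-Whitney U test.  Every
decision is returned as a complete audit record so it can be replayed.
Factorial designs are analyzed with an ordinary-least-squares ANOVA
(statsmodels), and pairwise follow-ups receive a Bonferroni correction
(adjusted p = min(1, m*p)).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


@dataclass
class TestDecision:
    """Audit record for one gated two-group comparison."""

    shapiro_p: tuple[float, float]
    levene_p: float
    chosen_test: str  # "t_test" | "mann_whitney"
    test_statistic: float
    p_value: float
    alpha: float = ALPHA
    degenerate: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def two_group(x, y, alpha: float = ALPHA) -> TestDecision:
    """Gated two-group comparison (two-sided).

    t-test iff Shapiro-Wilk is non-significant in *both* groups AND
    Levene's test is non-significant; otherwise Mann-Whitney.  Groups
    with zero variance cannot be gated (Shapiro-Wilk is undefined) and
    are returned as a degenerate Mann-Whitney decision.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each group needs at least 3 observations")

    if np.ptp(x) == 0 or np.ptp(y) == 0:
        stat, p = sps.mannwhitneyu(x, y, alternative="two-sided")
        return TestDecision(
            shapiro_p=(float("nan"), float("nan")),
            levene_p=float("nan"),
            chosen_test="mann_whitney",
            test_statistic=float(stat),
            p_value=float(p),
            alpha=alpha,
            degenerate=True,
        )

    sw_x = sps.shapiro(x).pvalue
    sw_y = sps.shapiro(y).pvalue
    lev = sps.levene(x, y).pvalue
    normal_and_homoscedastic = sw_x > alpha and sw_y > alpha and lev > alpha
    if normal_and_homoscedastic:
        res = sps.ttest_ind(x, y)
        chosen = "t_test"
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided")
        chosen = "mann_whitney"
    return TestDecision(
        shapiro_p=(float(sw_x), float(sw_y)),
        levene_p=float(lev),
        chosen_test=chosen,
        test_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alpha=alpha,
    )


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size if m is None else int(m)
    return np.minimum(1.0, m * p)


def factorial_anova(
    table: pd.DataFrame,
    response: str,
    factors: list[str],
    correction: str = "bonferroni",
) -> dict:
    """Factorial (e.g. two-way) ANOVA with corrected pairwise follow-ups.

    ``table`` is tidy, with the response column and one column per
    factor.  Main effects and all interactions are reported from a
    type-II OLS ANOVA; pairwise comparisons between all factor-level
    cells use t-tests with Bonferroni adjustment over the family.

    Raises
    ------
    ValueError
        If any factor-level cell is empty (named in the message).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for col in [response, *factors]:
        if col not in table.columns:
            raise ValueError(f"column {col!r} missing from table")
    levels = [sorted(table[f].unique()) for f in factors]
    cells = {}
    import itertools

    for combo in itertools.product(*levels):
        sel = np.ones(len(table), dtype=bool)
        for f, lev in zip(factors, combo):
            sel &= (table[f] == lev).to_numpy()
        if not np.any(sel):
            raise ValueError(f"empty design cell: {dict(zip(factors, combo))}")
        cells[combo] = table.loc[sel, response].to_numpy(dtype=float)

    formula = f"{response} ~ " + " * ".join(f"C({f})" for f in factors)
    model = smf.ols(formula, data=table).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    pairs = list(combinations(sorted(cells), 2))
    raw = []
    for a, b in pairs:
        raw.append(float(sps.ttest_ind(cells[a], cells[b]).pvalue))
    if correction == "bonferroni":
        adj = bonferroni(raw)
    elif correction in (None, "none"):
        adj = np.asarray(raw)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    pairwise = pd.DataFrame(
        {
            "cell_a": [a for a, _ in pairs],
            "cell_b": [b for _, b in pairs],
            "p_raw": raw,
            "p_adjusted": adj,
        }
    )
    return {"anova": anova, "pairwise": pairwise, "n_comparisons": len(pairs)}
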