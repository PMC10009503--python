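"""Statistical harness for the panel analysis.

Paired tests on poverty-status dynamics (McNemar, Wilcoxon signed
rank), one-way ANOVA with Tukey HSD or Fisher LSD post-hoc comparisons
summarised as a compact letter display, and the asset -> income
ordinary-least-squares regressions.

Conventions
-----------
* McNemar: plain chi-squared on the discordant counts,
  chi2 = (b - c)^2 / (b + c), without continuity correction; the exact
  two-sided binomial variant is used automatically when b + c < 25.
* Wilcoxon signed rank: zero differences dropped, average ranks for
  ties; exact (full sign-permutation) null for n <= 15 nonzero
  differences, tie-corrected normal approximation above.
* Tukey HSD uses the studentized-range distribution with the
  Tukey-Kramer unequal-n adjustment; Fisher LSD is pairwise t tests on
  the pooled within-group mean square with no multiplicity adjustment.
* Groups share a compact-display letter iff their pairwise comparison
  is not significant at the stated alpha (insert-and-absorb algorithm).
* Every test consumes untrimmed data; any outlier trimming is a
  display-only concern and never happens here.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.api import OLS, add_constant
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

__all__ = [
    "ComparisonResult",
    "mcnemar_paired",
    "wilcoxon_strata_movement",
    "anova_posthoc",
    "compact_letter_display",
    "asset_income_regression",
    "education_income_analysis",
    "STRATUM_CODES",
]

#: Ordinal codes for the prosperity strata used by the Wilcoxon test.
STRATUM_CODES = {"Low": 1, "Medium": 2, "High": 3}

#: Discordant-pair count below which McNemar switches to the exact test.
MCNEMAR_EXACT_THRESHOLD = 25

#: Nonzero-difference count up to which the Wilcoxon null is enumerated
#: exactly (2^n sign patterns); above, the tie-corrected normal
#: approximation is used.
WILCOXON_EXACT_MAX_N = 15


@dataclass
class ComparisonResult:
    """Outcome of one statistical comparison."""

    test: str
    statistic: float
    p_value: float
    groups: list[str] = field(default_factory=list)
    n: dict[str, int] = field(default_factory=dict)
    estimates: dict[str, dict[str, float]] = field(default_factory=dict)
    letters: Optional[dict[str, str]] = None
    pairwise: Optional[pd.DataFrame] = None
    alpha: Optional[float] = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


# ---------------------------------------------------------------------------
# Paired tests on poverty dynamics
# ---------------------------------------------------------------------------

def mcnemar_paired(status_round1: Sequence[bool], status_round2: Sequence[bool],
                   exact: Optional[bool] = None) -> ComparisonResult:
    """McNemar test on a paired binary status (e.g. above/below a line).

    ``exact=None`` (default) selects the exact binomial variant when the
    discordant count b + c is below 25 and the plain chi-squared
    otherwise; pass True/False to force either.  With no discordant
    pairs the test is degenerate: statistic 0, p = 1.
    """
    s1 = np.asarray(status_round1, dtype=bool)
    s2 = np.asarray(status_round2, dtype=bool)
    if s1.shape != s2.shape:
        raise ValueError("paired statuses must have equal length")
    a = int(np.sum(s1 & s2))
    b = int(np.sum(s1 & ~s2))
    c = int(np.sum(~s1 & s2))
    d = int(np.sum(~s1 & ~s2))
    counts = {"concordant_true": a, "b": b, "c": c, "concordant_false": d}

    if b + c == 0:
        return ComparisonResult(
            test="mcnemar", statistic=0.0, p_value=1.0,
            n={"pairs": len(s1), "discordant": 0},
            estimates={"counts": counts}, degenerate=True,
        )
    use_exact = (b + c) < MCNEMAR_EXACT_THRESHOLD if exact is None else exact
    table = [[a, b], [c, d]]
    res = _sm_mcnemar(table, exact=use_exact, correction=False)
    return ComparisonResult(
        test="mcnemar_exact" if use_exact else "mcnemar_chi2",
        statistic=float(res.statistic),
        p_value=min(float(res.pvalue), 1.0),
        n={"pairs": len(s1), "discordant": b + c},
        estimates={"counts": counts},
    )


def wilcoxon_strata_movement(codes_round1: Sequence[int],
                             codes_round2: Sequence[int]) -> ComparisonResult:
    """Wilcoxon signed-rank test on paired ordinal stratum codes.

    Differences of zero (households that stayed put) are dropped; ties
    among the remaining |differences| receive average ranks.  The null
    distribution is enumerated exactly for up to 15 nonzero differences
    and approximated normally (with tie correction) above.
    """
    c1 = np.asarray(codes_round1, dtype=float)
    c2 = np.asarray(codes_round2, dtype=float)
    if c1.shape != c2.shape:
        raise ValueError("paired codes must have equal length")
    diffs = c2 - c1
    nonzero = diffs[diffs != 0]
    n = len(nonzero)
    if n == 0:
        return ComparisonResult(
            test="wilcoxon_signed_rank", statistic=0.0, p_value=1.0,
            n={"pairs": len(c1), "nonzero": 0}, degenerate=True,
        )
    if n <= WILCOXON_EXACT_MAX_N:
        method = stats.PermutationMethod(n_resamples=2 ** WILCOXON_EXACT_MAX_N,
                                         rng=0)
        name = "wilcoxon_signed_rank_exact"
    else:
        method = "approx"
        name = "wilcoxon_signed_rank_normal"
    res = stats.wilcoxon(nonzero, zero_method="wilcox", correction=False,
                         alternative="two-sided", method=method)
    return ComparisonResult(
        test=name, statistic=float(res.statistic),
        p_value=min(float(res.pvalue), 1.0),
        n={"pairs": len(c1), "nonzero": n},
        estimates={"movement": {
            "up": int(np.sum(diffs > 0)), "down": int(np.sum(diffs < 0)),
        }},
    )


# ---------------------------------------------------------------------------
# One-way ANOVA with post-hoc letters
# ---------------------------------------------------------------------------

def compact_letter_display(groups: Sequence[str],
                           significant_pairs: set[tuple[str, str]]
                           ) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups share a letter iff their pair is *not* in
    ``significant_pairs`` (order within a pair is ignored).  Every group
    receives at least one letter.
    """
    groups = list(groups)
    sig = {frozenset(p) for p in significant_pairs}
    columns: list[set[str]] = [set(groups)]
    for pair in sig:
        i, j = tuple(pair)
        for col in [c for c in columns if i in c and j in c]:
            columns.remove(col)
            columns.extend([col - {i}, col - {j}])
        # absorb: drop columns contained in another
        columns = [c for c in columns
                   if c and not any(c < other for other in columns)]
        # deduplicate
        seen: list[set[str]] = []
        for c in columns:
            if c not in seen:
                seen.append(c)
        columns = seen
    # stable ordering: columns sorted by their first group's position
    order = {g: k for k, g in enumerate(groups)}
    columns.sort(key=lambda c: min(order[g] for g in c))
    alphabet = itertools.chain(
        string.ascii_lowercase,
        ("".join(t) for t in itertools.product(string.ascii_lowercase, repeat=2)),
    )
    letters = {g: [] for g in groups}
    for col, letter in zip(columns, alphabet):
        for g in col:
            letters[g].append(letter)
    return {g: ",".join(sorted(ls)) for g, ls in letters.items()}


def _fisher_lsd(samples: dict[str, np.ndarray], alpha: float) -> pd.DataFrame:
    """Pairwise t tests on the pooled within-group mean square (no adjustment)."""
    names = list(samples)
    ns = {g: len(v) for g, v in samples.items()}
    means = {g: float(np.mean(v)) for g, v in samples.items()}
    n_total = sum(ns.values())
    df_within = n_total - len(names)
    mse = sum(((v - means[g]) ** 2).sum() for g, v in samples.items()) / df_within
    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        se = np.sqrt(mse * (1.0 / ns[g1] + 1.0 / ns[g2]))
        diff = means[g1] - means[g2]
        if se == 0:
            t = 0.0 if diff == 0 else np.inf * np.sign(diff)
        else:
            t = diff / se
        p = 2.0 * stats.t.sf(abs(t), df_within) if np.isfinite(t) else 0.0
        if diff == 0 and se == 0:
            p = 1.0
        rows.append({"group1": g1, "group2": g2, "diff": diff,
                     "statistic": t, "p_value": p,
                     "significant": p <= alpha})
    return pd.DataFrame(rows)


def _tukey_kramer(samples: dict[str, np.ndarray], alpha: float) -> pd.DataFrame:
    """Tukey HSD via the studentized range, Tukey-Kramer for unequal n."""
    names = list(samples)
    ns = {g: len(v) for g, v in samples.items()}
    means = {g: float(np.mean(v)) for g, v in samples.items()}
    k = len(names)
    df_within = sum(ns.values()) - k
    mse = sum(((v - means[g]) ** 2).sum() for g, v in samples.items()) / df_within
    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        diff = means[g1] - means[g2]
        se = np.sqrt(mse / 2.0 * (1.0 / ns[g1] + 1.0 / ns[g2]))
        if se == 0:
            q = 0.0 if diff == 0 else np.inf
            p = 1.0 if diff == 0 else 0.0
        else:
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df_within))
        rows.append({"group1": g1, "group2": g2, "diff": diff,
                     "statistic": q, "p_value": min(p, 1.0),
                     "significant": min(p, 1.0) <= alpha})
    return pd.DataFrame(rows)


def anova_posthoc(values: Sequence[float], group_labels: Sequence[str],
                  method: str = "tukey_hsd",
                  alpha: float = 0.05) -> ComparisonResult:
    """One-way ANOVA with post-hoc pairwise comparisons and letters.

    ``method`` is ``"tukey_hsd"`` (studentized range, Tukey-Kramer for
    unequal group sizes) or ``"fisher_lsd"`` (unadjusted pairwise t
    tests on the pooled mean square).  Groups sharing a letter are not
    significantly different at ``alpha``.
    """
    if method not in ("tukey_hsd", "fisher_lsd"):
        raise ValueError(f"unknown post-hoc method {method!r}")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if values.shape != labels.shape:
        raise ValueError("values and group labels must have equal length")
    names = list(pd.unique(labels))
    samples = {g: values[labels == g] for g in names}
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in samples.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")

    degenerate = all(np.ptp(v) == 0 for v in samples.values()) and \
        np.ptp([np.mean(v) for v in samples.values()]) == 0
    if degenerate:
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = stats.f_oneway(*samples.values())
        f_stat, p = float(f_stat), float(p)

    pairwise = (_tukey_kramer if method == "tukey_hsd" else _fisher_lsd)(
        samples, alpha)
    sig_pairs = {(r.group1, r.group2)
                 for r in pairwise.itertuples() if r.significant}
    letters = compact_letter_display(names, sig_pairs)
    return ComparisonResult(
        test=f"anova+{method}", statistic=f_stat, p_value=min(p, 1.0),
        groups=names,
        n={g: len(v) for g, v in samples.items()},
        estimates={g: {"mean": float(np.mean(v)),
                       "median": float(np.median(v))}
                   for g, v in samples.items()},
        letters=letters, pairwise=pairwise, alpha=alpha,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Regressions
# ---------------------------------------------------------------------------

def asset_income_regression(outcome: Sequence[float],
                            predictors: pd.DataFrame,
                            log1p: bool = False):
    """OLS of (round-2) farm income on baseline productive assets.

    ``predictors`` is a frame of baseline covariates (e.g. round-1 land,
    TLU, off-farm income).  With ``log1p=True`` both sides are log(1+x)
    transformed.  Returns the fitted statsmodels results object (with
    ``params``, ``pvalues``, ``bse``, ``conf_int`` ...).  A
    rank-deficient design raises, naming the collinear columns.
    """
    y = np.asarray(outcome, dtype=float)
    X = predictors.astype(float).copy()
    if len(y) != len(X):
        raise ValueError("outcome and predictors must have equal length")
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    if log1p:
        y = np.log1p(y)
        X = np.log1p(X)
    Xc = add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        collinear = []
        cols = Xc.to_numpy()
        for j, name in enumerate(Xc.columns):
            others = np.delete(cols, j, axis=1)
            resid = cols[:, j] - others @ np.linalg.lstsq(
                others, cols[:, j], rcond=None)[0]
            if np.allclose(resid, 0, atol=1e-8 * max(1.0, np.abs(cols[:, j]).max())):
                collinear.append(str(name))
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    return OLS(y, Xc).fit()


def education_income_analysis(education: Sequence[str],
                              farm_income: Sequence[float],
                              off_farm_income: Sequence[float],
                              alpha: float = 0.05
                              ) -> dict[str, Optional[ComparisonResult]]:
    """ANOVA + Fisher LSD of income across education attainment levels.

    Run separately for farm and off-farm income.  With fewer than two
    represented levels the analysis is skipped (None entries).
    """
    edu = np.asarray(education)
    out: dict[str, Optional[ComparisonResult]] = {}
    for name, income in (("farm_income", farm_income),
                         ("off_farm_income", off_farm_income)):
        income = np.asarray(income, dtype=float)
        levels, counts = np.unique(edu, return_counts=True)
        usable = levels[counts >= 2]
        mask = np.isin(edu, usable)
        if len(usable) < 2:
            out[name] = None
            continue
        out[name] = anova_posthoc(income[mask], edu[mask],
                                  method="fisher_lsd", alpha=alpha)
    return out
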