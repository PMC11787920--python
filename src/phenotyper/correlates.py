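"""Phenotype-correlate and phenotype-outcome statistics.

Group comparisons across phenotypes mirror the standard reporting layout
for profile analyses: one row per variable with per-group summaries,
compact significance letters (groups share a letter iff their pairwise
test is not significant at alpha), the omnibus statistic and its p-value.
Continuous variables use one-way ANOVA with unadjusted pairwise Welch
t-tests; categorical variables use Pearson chi-square with pairwise 2x2
chi-squares.  No multiple-testing correction is applied by default.

The prospective attempt analysis builds the phenotype x any-attempt
contingency table among participants eligible for follow-up, tests it
with an exact conditional (fixed-margins multivariate hypergeometric)
test — the r x c generalization of Fisher's exact test, with the
two-sided "probability at most that of the observed table" rule — and
summarizes effect size with Cramer's V = sqrt(chi2 / (n * min(r-1, c-1))).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

_REL_TOL = 1.0 + 1e-7  # tie tolerance when ranking table probabilities


@dataclass
class ContingencyTable:
    """r x c observed counts with labelled margins."""

    counts: np.ndarray
    row_labels: list | None = None
    col_labels: list | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)) or np.any(self.counts < 0):
                raise ValueError("counts must be non-negative integers")
            self.counts = self.counts.astype(int)
        if self.counts.sum() < 1:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def oneway_anova(groups: Sequence[Sequence[float]]):
    """Classical one-way fixed-effects ANOVA.

    Returns ``(F, df_between, df_within, p)``.  Errors on fewer than two
    groups or when the F ratio is undefined (no within- and no
    between-group variation).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    gs = [g[~np.isnan(g)] for g in gs]
    if len(gs) < 2 or any(len(g) == 0 for g in gs):
        raise ValueError("need >=2 groups, each with >=1 value")
    n = sum(len(g) for g in gs)
    k = len(gs)
    if n - k < 1:
        raise ValueError("need at least one group with >=2 values")
    grand = np.concatenate(gs).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df1, df2 = k - 1, n - k
    if ssw == 0.0:
        if ssb == 0.0:
            raise ValueError("F undefined: zero variance everywhere")
        return np.inf, df1, df2, 0.0
    F = (ssb / df1) / (ssw / df2)
    return float(F), df1, df2, float(stats.f.sf(F, df1, df2))


def compact_letters(significant: np.ndarray, symbols: str = "abcdefghijklmnopqrstuvwxyz") -> list[str]:
    """Compact letter display from a boolean pairwise-significance matrix.

    Greedy insert-absorb: groups share a letter iff their pair is *not*
    significant.
    """
    sig = np.asarray(significant, dtype=bool)
    k = sig.shape[0]
    sets: list[set[int]] = [set(range(k))]
    for i, j in itertools.combinations(range(k), 2):
        if not sig[i, j]:
            continue
        new_sets = []
        for s in sets:
            if i in s and j in s:
                new_sets += [s - {i}, s - {j}]
            else:
                new_sets.append(s)
        # absorb subsets
        sets = []
        for s in sorted(new_sets, key=len, reverse=True):
            if s and not any(s <= t for t in sets):
                sets.append(s)
    sets.sort(key=lambda s: (min(s), -len(s)))
    letters = ["" for _ in range(k)]
    for symbol, s in zip(symbols, sets):
        for g in s:
            letters[g] += symbol
    return letters


def pairwise_letters(
    groups,
    alpha: float = 0.05,
    method: str = "welch",
) -> list[str]:
    """Compact letters from all pairwise tests at unadjusted alpha.

    ``method="welch"``: groups are value lists, pairwise Welch t-tests.
    ``method="tukey"``: Tukey HSD adjusted p-values (optional variant).
    ``method="counts"``: groups are (successes, total) pairs, pairwise
    2x2 chi-square tests.
    """
    k = len(groups)
    sig = np.zeros((k, k), dtype=bool)
    if method == "tukey":
        res = stats.tukey_hsd(*[np.asarray(g, float) for g in groups])
        sig = res.pvalue < alpha
        np.fill_diagonal(sig, False)
        return compact_letters(sig)
    for i, j in itertools.combinations(range(k), 2):
        if method == "welch":
            a = np.asarray(groups[i], float)
            b = np.asarray(groups[j], float)
            a, b = a[~np.isnan(a)], b[~np.isnan(b)]
            p = stats.ttest_ind(a, b, equal_var=False).pvalue
        elif method == "counts":
            (k1, n1), (k2, n2) = groups[i], groups[j]
            tab = np.array([[k1, n1 - k1], [k2, n2 - k2]])
            if np.any(tab.sum(axis=0) == 0):
                p = 1.0
            else:
                p = stats.chi2_contingency(tab, correction=False).pvalue
        else:
            raise ValueError(f"unknown method {method!r}")
        sig[i, j] = sig[j, i] = bool(p < alpha)
    return compact_letters(sig)


def pearson_chi_square(table: ContingencyTable):
    """Pearson chi-square of independence. Returns (chi2, df, p)."""
    if np.any(table.row_margins == 0) or np.any(table.col_margins == 0):
        raise ValueError("zero row or column margin")
    res = stats.chi2_contingency(table.counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def cramers_v(table: ContingencyTable) -> float:
    """Cramer's V effect size, in [0, 1]."""
    r, c = table.counts.shape
    if min(r, c) < 2:
        raise ValueError("V undefined for a single row or column")
    chi2, _, _ = pearson_chi_square(table)
    return float(np.sqrt(chi2 / (table.n * (min(r, c) - 1))))


def _log_table_prob(counts: np.ndarray) -> float:
    """Log multivariate-hypergeometric probability under fixed margins."""
    r = counts.sum(axis=1)
    c = counts.sum(axis=0)
    n = counts.sum()
    return float(
        gammaln(r + 1).sum() + gammaln(c + 1).sum()
        - gammaln(n + 1) - gammaln(counts + 1).sum()
    )


def _enumeration_size(row_margins, col_margins) -> float:
    c = len(col_margins)
    size = 1.0
    for r in row_margins[:-1]:
        size *= np.prod([(r + j) / j for j in range(1, c)])  # C(r+c-1, c-1)
    return size


def fisher_exact(
    table: ContingencyTable,
    method: str = "auto",
    seed: int | None = None,
    mc_samples: int = 100_000,
    enumeration_guard: float = 1e7,
):
    """Two-sided exact conditional test for an r x c table.

    Under fixed margins every table has a multivariate hypergeometric
    probability; the two-sided p-value sums the probabilities of all
    tables no more probable than the observed one.  For 2x2 tables this is
    the classical two-sided Fisher test.  When full enumeration would
    exceed ``enumeration_guard`` candidate tables, a seeded Monte-Carlo
    estimate over ``mc_samples`` fixed-margin tables is used instead
    (add-one rule).
    """
    counts = table.counts
    if np.any(table.row_margins == 0) or np.any(table.col_margins == 0):
        raise ValueError("zero row or column margin")
    logp_obs = _log_table_prob(counts)
    cutoff = logp_obs + np.log(_REL_TOL)

    if counts.shape == (2, 2) and method != "mc":
        r1 = counts[0].sum()
        r2 = counts[1].sum()
        c1 = counts[:, 0].sum()
        xs = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
        pmf = stats.hypergeom.pmf(xs, counts.sum(), r1, c1)
        return float(pmf[np.log(np.maximum(pmf, 1e-300)) <= cutoff].sum())

    do_mc = method == "mc" or (
        method == "auto"
        and _enumeration_size(table.row_margins, table.col_margins) > enumeration_guard
    )
    if do_mc:
        rng = np.random.default_rng(seed)
        dist = stats.random_table(table.row_margins, table.col_margins)
        samples = dist.rvs(mc_samples, method="patefield", random_state=rng)
        logps = np.array([_log_table_prob(s) for s in samples])
        return float((1 + (logps <= cutoff).sum()) / (mc_samples + 1))

    # exhaustive enumeration, row by row
    row_m = table.row_margins
    col_m = table.col_margins
    n_rows, n_cols = counts.shape
    total = 0.0

    def rec(row: int, remaining_cols: np.ndarray, acc: list[np.ndarray]) -> None:
        nonlocal total
        if row == n_rows - 1:
            last = remaining_cols
            if np.any(last < 0):
                return
            tab = np.vstack(acc + [last])
            lp = _log_table_prob(tab)
            if lp <= cutoff:
                total += np.exp(lp)
            return
        for comp in _compositions(row_m[row], remaining_cols):
            rec(row + 1, remaining_cols - comp, acc + [comp])

    def _compositions(total_r: int, caps: np.ndarray):
        # all vectors 0 <= v <= caps with sum == total_r
        def go(idx: int, left: int, cur: list[int]):
            if idx == len(caps) - 1:
                if 0 <= left <= caps[idx]:
                    yield np.array(cur + [left])
                return
            for v in range(min(left, caps[idx]) + 1):
                yield from go(idx + 1, left - v, cur + [v])

        yield from go(0, int(total_r), [])

    rec(0, col_m.copy(), [])
    return float(min(1.0, total))


@dataclass
class GroupComparison:
    """One comparison row: per-group summaries, test, letters, effect size."""

    variable: str
    kind: str                      # "continuous" | "categorical"
    overall: str
    group_summaries: list[str]
    statistic: float
    p_value: float
    letters: list[str]
    effect_size: float | None = None


def _fmt_count(k: int, n: int) -> str:
    return f"{k} ({100 * k / n:.0f}%)" if n else "0"


def profile_correlates(
    assignments: pd.Series,
    baseline: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[list[GroupComparison], list[str]]:
    """Compare baseline covariates across phenotypes, one row per variable.

    Numeric columns get ANOVA + Welch-t compact letters; boolean columns
    get chi-square + pairwise 2x2 letters.  ``attempt_history`` expands
    into any/multiple history flags.  Returns the comparison rows and a
    list of skipped (entirely missing or untestable) variables.
    """
    df = baseline.loc[baseline.index.intersection(assignments.index)].copy()
    labels = assignments.loc[df.index]
    phenos = sorted(labels.unique())
    if "attempt_history" in df.columns:
        df["attempt_history_any"] = (df["attempt_history"] != "none").astype("boolean")
        df["attempt_history_multiple"] = (df["attempt_history"] == "multiple").astype("boolean")
        df = df.drop(columns=["attempt_history"])
    if "gender" in df.columns:
        df["gender_female"] = (df["gender"].astype(str).str.lower() == "female").astype("boolean")
        df = df.drop(columns=["gender"])

    rows: list[GroupComparison] = []
    skipped: list[str] = []
    for col in df.columns:
        series = df[col]
        if series.isna().all():
            skipped.append(col)
            continue
        is_flag = series.dtype == bool or str(series.dtype) == "boolean"
        try:
            if is_flag:
                vals = series.astype("boolean")
                counts = [int(vals[labels == g].sum()) for g in phenos]
                totals = [int(vals[labels == g].notna().sum()) for g in phenos]
                tab = ContingencyTable(
                    np.array([[k, n - k] for k, n in zip(counts, totals)])
                )
                chi2, _, p = pearson_chi_square(tab)
                letters = pairwise_letters(list(zip(counts, totals)), alpha, method="counts")
                rows.append(GroupComparison(
                    col, "categorical",
                    _fmt_count(sum(counts), sum(totals)),
                    [_fmt_count(k, n) for k, n in zip(counts, totals)],
                    chi2, p, letters, cramers_v(tab),
                ))
            elif pd.api.types.is_numeric_dtype(series):
                groups = [series[labels == g].dropna().to_numpy(float) for g in phenos]
                F, _, _, p = oneway_anova(groups)
                letters = pairwise_letters(groups, alpha, method="welch")
                rows.append(GroupComparison(
                    col, "continuous",
                    f"{series.dropna().mean():.1f}",
                    [f"{g.mean():.1f}" for g in groups],
                    F, p, letters,
                ))
            else:
                skipped.append(col)
        except ValueError:
            skipped.append(col)
    return rows, skipped


def comparisons_frame(rows: list[GroupComparison], group_names: list[str]) -> pd.DataFrame:
    """Render comparison rows as a report table (summary+letters per group)."""
    recs = []
    for r in rows:
        rec = {"variable": r.variable, "overall": r.overall}
        for name, summ, let in zip(group_names, r.group_summaries, r.letters):
            rec[name] = f"{summ}_{let}" if let else summ
        rec["statistic"] = round(r.statistic, 2)
        rec["p_value"] = round(r.p_value, 4)
        if r.effect_size is not None:
            rec["cramers_v"] = round(r.effect_size, 2)
        recs.append(rec)
    return pd.DataFrame(recs)


@dataclass
class FollowupAssociation:
    """Prospective phenotype -> suicide-attempt analysis."""

    table: ContingencyTable
    p_value: float
    cramers_v: float
    attempters: list[int]          # per phenotype
    group_sizes: list[int]
    attempts: list[int]            # attempt weeks per phenotype
    total_attempts: int
    history: dict | None = None


def followup_association(
    assignments: pd.Series,
    summaries: pd.DataFrame,
    pooled: bool = False,
    history: pd.Series | None = None,
    seed: int | None = None,
) -> FollowupAssociation:
    """Test whether prospective attempt occurrence differs by phenotype.

    Only participants eligible for follow-up (``included``) enter.  The
    default table is phenotype x any-attempt with one row per phenotype;
    ``pooled=True`` collapses all but the lowest-intensity (last) phenotype
    into one row.  Reports the exact-test p-value, Cramer's V, attempter
    and attempt counts, and (when a past-attempt-history indicator is
    given) the history-stratified repeat-attempt rates.
    """
    inc = summaries[summaries["included"]]
    ids = inc.index.intersection(assignments.index)
    if len(ids) == 0:
        raise ValueError("no included participants with phenotype assignments")
    labels = assignments.loc[ids]
    outcome = inc.loc[ids, "any_attempt"].astype(int)
    weeks = inc.loc[ids, "n_attempt_weeks"].astype(int)
    phenos = sorted(assignments.unique())

    attempters = [int(outcome[labels == g].sum()) for g in phenos]
    sizes = [int((labels == g).sum()) for g in phenos]
    attempts = [int(weeks[labels == g].sum()) for g in phenos]

    if pooled and len(phenos) > 2:
        counts = np.array([
            [sum(attempters[:-1]), sum(sizes[:-1]) - sum(attempters[:-1])],
            [attempters[-1], sizes[-1] - attempters[-1]],
        ])
        row_labels = [f"phenotype {phenos[0]}-{phenos[-2]}", f"phenotype {phenos[-1]}"]
    else:
        counts = np.array([[a, n - a] for a, n in zip(attempters, sizes)])
        row_labels = [f"phenotype {g}" for g in phenos]
    table = ContingencyTable(counts, row_labels, ["attempt", "no attempt"])
    if counts.shape[0] < 2 or np.any(counts.sum(axis=0) == 0):
        # one profile, or no attempts (or only attempts) anywhere: no
        # association to test
        p, v = 1.0, 0.0
    else:
        p = fisher_exact(table, seed=seed)
        v = cramers_v(table)

    hist = None
    if history is not None:
        h_ids = ids.intersection(history.index[history.astype(bool)])
        h_labels = labels.loc[h_ids]
        h_out = outcome.loc[h_ids]
        h_sizes = [int((h_labels == g).sum()) for g in phenos]
        h_att = [int(h_out[h_labels == g].sum()) for g in phenos]
        upper_n = sum(h_sizes[:-1])
        hist = {
            "n_history": int(len(h_ids)),
            "sizes": h_sizes,
            "attempters": h_att,
            "repeat_rate_upper": 100.0 * sum(h_att[:-1]) / upper_n if upper_n else np.nan,
            "repeat_rate_lowest": 100.0 * h_att[-1] / h_sizes[-1] if h_sizes[-1] else np.nan,
        }
    return FollowupAssociation(table, p, v, attempters, sizes, attempts,
                               int(weeks.sum()), hist)
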