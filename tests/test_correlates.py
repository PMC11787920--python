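"""Group-comparison statistics: ANOVA, compact letters, chi-square, exact
tests, Cramer's V, and the prospective attempt analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenotyper.correlates import (
    ContingencyTable,
    compact_letters,
    cramers_v,
    fisher_exact,
    followup_association,
    oneway_anova,
    pairwise_letters,
    pearson_chi_square,
    profile_correlates,
)

ATTEMPT_TABLE = np.array([[4, 7], [3, 8], [0, 14]])     # phenotype x attempt
HISTORY_TABLE = np.array([[7, 10], [0, 19]])            # history x attempt


def chi2_oracle(counts):
    counts = np.asarray(counts, float)
    E = np.outer(counts.sum(1), counts.sum(0)) / counts.sum()
    return float(((counts - E) ** 2 / E).sum())


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        F, df1, df2, p = oneway_anova([[1, 2, 3], [1, 2, 3]])
        assert F == 0.0 and p == pytest.approx(1.0)

    def test_textbook_sums_of_squares(self):
        F, df1, df2, p = oneway_anova([[0, 1], [10, 11]])
        assert (F, df1, df2) == (pytest.approx(200.0), 1, 2)
        assert p == pytest.approx(stats.f.sf(200, 1, 2))

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(m, 1, 12) for m in (0, 0.5, 1.5)]
        F, _, _, p = oneway_anova(groups)
        ref = stats.f_oneway(*groups)
        assert F == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            oneway_anova([[1, 2, 3]])

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            oneway_anova([[2, 2], [2, 2]])


class TestCompactLetters:
    def test_all_pairs_significant(self):
        sig = ~np.eye(3, dtype=bool)
        assert compact_letters(sig) == ["a", "b", "c"]

    def test_no_pair_significant(self):
        assert compact_letters(np.zeros((3, 3), bool)) == ["a", "a", "a"]

    def test_partial_pattern(self):
        # groups 1,2 indistinguishable; 3 differs from both
        sig = np.zeros((3, 3), bool)
        for i, j in [(0, 2), (1, 2)]:
            sig[i, j] = sig[j, i] = True
        assert compact_letters(sig) == ["a", "a", "b"]

    def test_reconstruction_property(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            k = int(rng.integers(2, 7))
            sig = np.zeros((k, k), bool)
            for i, j in itertools.combinations(range(k), 2):
                sig[i, j] = sig[j, i] = rng.random() < 0.4
            letters = compact_letters(sig)
            for i, j in itertools.combinations(range(k), 2):
                shares = bool(set(letters[i]) & set(letters[j]))
                assert shares == (not sig[i, j])

    def test_welch_letters_on_shifted_groups(self):
        rng = np.random.default_rng(4)
        g1 = rng.normal(0, 1, 30)
        g2 = rng.normal(0.1, 1, 30)
        g3 = rng.normal(5, 1, 30)
        assert pairwise_letters([g1, g2, g3], 0.05, method="welch") == ["a", "a", "b"]


class TestChiSquare:
    def test_perfect_independence(self):
        chi2, df, p = pearson_chi_square(ContingencyTable([[5, 5], [5, 5]]))
        assert chi2 == 0.0 and df == 1 and p == pytest.approx(1.0)

    @pytest.mark.parametrize("counts", [ATTEMPT_TABLE, HISTORY_TABLE])
    def test_formula_oracle(self, counts):
        chi2, _, _ = pearson_chi_square(ContingencyTable(counts))
        assert chi2 == pytest.approx(chi2_oracle(counts))

    def test_row_column_permutation_invariance(self):
        t = ContingencyTable(ATTEMPT_TABLE)
        perm = ContingencyTable(ATTEMPT_TABLE[[2, 0, 1]][:, [1, 0]])
        assert pearson_chi_square(t)[0] == pytest.approx(pearson_chi_square(perm)[0])

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            pearson_chi_square(ContingencyTable([[0, 0], [3, 4]]))


class TestCramersV:
    def test_published_effect_sizes(self):
        assert cramers_v(ContingencyTable(ATTEMPT_TABLE)) == pytest.approx(0.40, abs=0.005)
        assert cramers_v(ContingencyTable(HISTORY_TABLE)) == pytest.approx(0.52, abs=0.005)

    def test_bounds(self):
        assert cramers_v(ContingencyTable([[5, 5], [5, 5]])) == 0.0
        perm = np.diag([7, 5, 9])
        assert cramers_v(ContingencyTable(perm)) == pytest.approx(1.0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            t = rng.integers(1, 20, size=(3, 2))
            assert 0.0 <= cramers_v(ContingencyTable(t)) <= 1.0 + 1e-12


class TestFisherExact:
    def test_hand_enumerated_2x2(self):
        assert fisher_exact(ContingencyTable([[3, 1], [1, 3]])) == pytest.approx(34 / 70)

    def test_published_p_values(self):
        assert fisher_exact(ContingencyTable(HISTORY_TABLE)) == pytest.approx(0.002, abs=5e-4)
        assert fisher_exact(ContingencyTable(ATTEMPT_TABLE)) == pytest.approx(0.040, abs=2e-3)

    def test_rxc_enumeration_matches_montecarlo(self):
        t = ContingencyTable(ATTEMPT_TABLE)
        exact = fisher_exact(t)
        mc = fisher_exact(t, method="mc", seed=0, mc_samples=200_000)
        assert mc == pytest.approx(exact, abs=0.005)

    def test_exhaustive_2x2_equivalence_small_n(self):
        # spot sweep here (full n <= 40 sweep runs with the acceptance suite)
        for n in range(2, 16):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        tab = np.array([[a, b], [c, d]])
                        if tab.sum(0).min() == 0 or tab.sum(1).min() == 0:
                            continue
                        mine = fisher_exact(ContingencyTable(tab))
                        ref = stats.fisher_exact(tab).pvalue
                        assert mine == pytest.approx(ref, rel=1e-9, abs=1e-12)


class TestProfileCorrelates:
    @staticmethod
    def _cohort(rng, shift=0.0):
        n = 90
        labels = pd.Series(rng.integers(1, 4, n),
                           index=[f"p{i:03d}" for i in range(n)])
        base = pd.DataFrame(index=labels.index)
        base["BSSI"] = rng.normal(15, 5, n) + shift * 5 * (labels == 1)
        base["MDD"] = pd.array(rng.random(n) < 0.5, dtype="boolean")
        base["attempt_history"] = np.where(rng.random(n) < 0.3, "multiple", "none")
        base["gender"] = np.where(rng.random(n) < 0.7, "female", "male")
        return labels, base

    def test_shifted_covariate_flagged_with_distinct_letter(self):
        rng = np.random.default_rng(0)
        labels, base = self._cohort(rng, shift=2.0)
        rows, skipped = profile_correlates(labels, base)
        bssi = next(r for r in rows if r.variable == "BSSI")
        assert bssi.p_value < 0.001
        assert bssi.letters[0] not in bssi.letters[1] + bssi.letters[2]

    def test_null_covariates_mostly_nonsignificant(self):
        hits = 0
        total = 0
        for seed in range(12):
            rng = np.random.default_rng(100 + seed)
            labels, base = self._cohort(rng)
            rows, _ = profile_correlates(labels, base)
            hits += sum(r.p_value < 0.05 for r in rows)
            total += len(rows)
        # 5% nominal rate: allow generous binomial slack
        assert hits / total < 0.15

    def test_expanded_variables_present(self):
        rng = np.random.default_rng(1)
        labels, base = self._cohort(rng)
        rows, _ = profile_correlates(labels, base)
        names = {r.variable for r in rows}
        assert {"BSSI", "MDD", "attempt_history_any",
                "attempt_history_multiple", "gender_female"} <= names


class TestFollowupAssociation:
    @staticmethod
    def _published_cohort():
        """Assignments + summaries matching the printed attempt counts."""
        sizes = [11, 11, 14]
        attempters = [4, 3, 0]
        attempt_weeks = [[5, 2, 4, 1], [2, 1, 1], []]
        ids, phen, rows = [], [], []
        k = 0
        for g, (n, a) in enumerate(zip(sizes, attempters), start=1):
            for i in range(n):
                pid = f"p{k:03d}"
                k += 1
                ids.append(pid)
                phen.append(g)
                weeks = attempt_weeks[g - 1][i] if i < a else 0
                rows.append({"participant_id": pid, "any_attempt": int(weeks > 0),
                             "n_attempt_weeks": weeks, "included": True})
        assignments = pd.Series(phen, index=ids)
        summaries = pd.DataFrame(rows).set_index("participant_id")
        return assignments, summaries

    def test_published_counts_reproduce_statistics(self):
        assignments, summaries = self._published_cohort()
        history = pd.Series(False, index=assignments.index)
        # 7 / 7 / 3 past attempters; all follow-up attempters among them
        hist_ids = (
            [f"p{i:03d}" for i in range(7)]                   # phenotype 1
            + [f"p{i:03d}" for i in range(11, 18)]            # phenotype 2
            + [f"p{i:03d}" for i in range(22, 25)]            # phenotype 3
        )
        history[hist_ids] = True
        res = followup_association(assignments, summaries, history=history)
        assert res.attempters == [4, 3, 0]
        assert res.group_sizes == [11, 11, 14]
        assert res.attempts == [12, 4, 0]
        assert res.total_attempts == 16
        assert res.cramers_v == pytest.approx(0.40, abs=0.005)
        assert res.p_value == pytest.approx(0.040, abs=2e-3)
        assert res.history["sizes"] == [7, 7, 3]
        assert res.history["repeat_rate_upper"] == pytest.approx(50.0)
        assert res.history["repeat_rate_lowest"] == 0.0

    def test_no_attempts_anywhere(self):
        assignments, summaries = self._published_cohort()
        summaries["any_attempt"] = 0
        summaries["n_attempt_weeks"] = 0
        res = followup_association(assignments, summaries)
        assert res.p_value == 1.0 and res.cramers_v == 0.0

    def test_pooled_table_mode(self):
        assignments, summaries = self._published_cohort()
        res = followup_association(assignments, summaries, pooled=True)
        assert res.table.counts.tolist() == [[7, 15], [0, 14]]

    def test_excluded_participants_do_not_enter(self):
        assignments, summaries = self._published_cohort()
        summaries.loc["p000", "included"] = False
        res = followup_association(assignments, summaries)
        assert res.group_sizes[0] == 10
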