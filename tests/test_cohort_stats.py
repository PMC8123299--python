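"""Cohort aggregation, Mann-Whitney/AUC oracles, correlations, box plots."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pnpcyto.cohort_stats import (
    SampleSummary,
    boxplot_table,
    compare_groups,
    correlate,
    mann_whitney_u,
    subtype_auc,
    summarize_cohort,
    summarize_sample,
)
from pnpcyto.errors import DataError


def cells_frame(counts, lineage="T", sample="s0"):
    return pd.DataFrame(
        {"sample_id": sample, "lineage": lineage, "pnp_count": counts}
    )


def make_summary(group, lam_t, sample_id="x", serum=None):
    return SampleSummary(
        sample_id=sample_id, group=group,
        lambda_by_subtype={"T": lam_t, "AllPBMC": lam_t},
        n_cells_by_subtype={"T": 100, "AllPBMC": 100},
        stratification={}, serum_value=serum,
    )


def exact_mw_pvalue(x, y):
    """Exhaustive permutation null of the U statistic (two-sided)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_stat(a, b):
        u = 0.0
        for xi in a:
            for yi in b:
                u += (xi > yi) + 0.5 * (xi == yi)
        return u

    observed = u_stat(x, y)
    mu = len(x) * len(y) / 2
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(comb)] = True
        u = u_stat(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - mu) >= abs(observed - mu) - 1e-12:
            count += 1
    return count / total


class TestSummarizeSample:
    def test_lambda_is_the_mean_count(self):
        s = summarize_sample(cells_frame([0, 1, 2, 3, 4]))
        assert s.lambda_by_subtype["T"] == pytest.approx(2.0)

    def test_all_zero_counts_stratify_fully_low(self):
        s = summarize_sample(cells_frame([0] * 10))
        assert s.lambda_by_subtype["T"] == 0.0
        assert s.stratification["T"] == {"low": 1.0, "medium": 0.0, "high": 0.0}

    def test_missing_subtype_recorded_as_missing_not_zero(self):
        s = summarize_sample(cells_frame([1, 2], lineage="B"))
        assert "NK" not in s.lambda_by_subtype
        assert s.n_cells_by_subtype["NK"] == 0

    def test_stratification_cutoffs_and_sum(self):
        s = summarize_sample(cells_frame([0, 4, 5, 9, 10, 20]))
        strat = s.stratification["T"]
        assert strat["low"] == pytest.approx(2 / 6)     # counts < 5
        assert strat["medium"] == pytest.approx(2 / 6)  # 5 <= c < 10
        assert strat["high"] == pytest.approx(2 / 6)    # c >= 10
        assert sum(strat.values()) == pytest.approx(1.0)

    def test_stratification_invariant_to_cell_order(self, rng):
        counts = rng.poisson(6, size=50)
        a = summarize_sample(cells_frame(counts))
        b = summarize_sample(cells_frame(counts[::-1]))
        assert a.stratification == b.stratification

    def test_excluded_cells_enter_all_pbmc_but_not_subtypes(self):
        df = pd.DataFrame(
            {"sample_id": "s", "lineage": ["T", "Excluded", "NotLeukocyte"],
             "pnp_count": [2, 10, 99]}
        )
        s = summarize_sample(df)
        assert s.n_cells_by_subtype["AllPBMC"] == 2  # T + Excluded, not the non-leukocyte
        assert s.lambda_by_subtype["AllPBMC"] == pytest.approx(6.0)


class TestMannWhitneyOracle:
    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_exhaustive_permutation(self, seed):
        r = np.random.default_rng(seed)
        n1, n2 = int(r.integers(2, 6)), int(r.integers(2, 6))
        # continuous draws: tie-free with probability 1
        x = np.round(r.normal(0, 1, n1), 6)
        y = np.round(r.normal(0.5, 1, n2), 6)
        u, p = mann_whitney_u(x, y)
        assert p == pytest.approx(exact_mw_pvalue(x, y), abs=1e-9)

    def test_identical_groups_give_half_u_and_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.warns(UserWarning):
            u, p = mann_whitney_u(np.ones(4), np.ones(4))
        assert u == 8.0 and p == 1.0
        # symmetric non-degenerate case
        u2, p2 = mann_whitney_u(x, x[::-1])
        assert u2 == pytest.approx(8.0)
        assert p2 == pytest.approx(1.0)


class TestAuc:
    def brute_force_auc(self, a, b):
        wins = sum((ai > bi) + 0.5 * (ai == bi) for ai in a for bi in b)
        return wins / (len(a) * len(b))

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_equals_pairwise_win_fraction(self, seed):
        r = np.random.default_rng(seed)
        summaries = [make_summary("patient", float(v), f"p{i}")
                     for i, v in enumerate(r.poisson(5, 8))]
        summaries += [make_summary("control", float(v), f"c{i}")
                      for i, v in enumerate(r.poisson(3, 5))]
        a = [s.lambda_by_subtype["T"] for s in summaries if s.group == "patient"]
        b = [s.lambda_by_subtype["T"] for s in summaries if s.group == "control"]
        auc = subtype_auc(summaries)["T"]
        assert auc == pytest.approx(self.brute_force_auc(a, b))

    def test_perfect_separation_gives_one(self):
        summaries = [make_summary("patient", 10 + i, f"p{i}") for i in range(4)]
        summaries += [make_summary("control", i, f"c{i}") for i in range(4)]
        assert subtype_auc(summaries)["T"] == 1.0

    def test_identical_groups_give_half(self):
        summaries = [make_summary("patient", float(i), f"p{i}") for i in range(4)]
        summaries += [make_summary("control", float(i), f"c{i}") for i in range(4)]
        assert subtype_auc(summaries)["T"] == 0.5

    def test_empty_group_raises(self):
        with pytest.raises(DataError):
            subtype_auc([make_summary("patient", 1.0)])


class TestCompareGroups:
    def test_cohort_power_at_study_means(self):
        """Patient vs control T-cell means (4.36 vs 1.38), 14 vs 7 samples of
        1,000 cells: the U test should reject at 0.05 in nearly every run."""
        rng = np.random.default_rng(0)
        significant = 0
        runs = 200
        for _ in range(runs):
            pats = [make_summary("patient", rng.poisson(4.36, 1000).mean(), f"p{i}")
                    for i in range(14)]
            ctls = [make_summary("control", rng.poisson(1.38, 1000).mean(), f"c{i}")
                    for i in range(7)]
            res = compare_groups(pats + ctls)
            p = res.mannwhitney.set_index("subtype").loc["T", "p"]
            significant += p < 0.05
        assert significant / runs >= 0.95

    def test_all_zero_samples_degenerate(self):
        pats = [make_summary("patient", 0.0, f"p{i}") for i in range(4)]
        ctls = [make_summary("control", 0.0, f"c{i}") for i in range(4)]
        with pytest.warns(UserWarning, match="identical"):
            res = compare_groups(pats + ctls)
        p = res.mannwhitney.set_index("subtype").loc["T", "p"]
        assert p == 1.0

    def test_shapiro_reported_but_not_gating(self):
        rng = np.random.default_rng(1)
        pats = [make_summary("patient", float(v), f"p{i}")
                for i, v in enumerate(rng.exponential(4, 8))]
        ctls = [make_summary("control", float(v), f"c{i}")
                for i, v in enumerate(rng.exponential(2, 5))]
        res = compare_groups(pats + ctls)
        assert not res.shapiro.empty
        assert "p" in res.mannwhitney


class TestCorrelations:
    def test_perfect_linear_relation(self):
        summaries = []
        for i in range(6):
            s = make_summary("patient", float(i), f"p{i}")
            s.lambda_by_subtype["B"] = 2.0 * i + 1.0
            summaries.append(s)
        df = correlate(summaries)
        row = df[(df["a"] == "T") & (df["b"] == "B")].iloc[0]
        assert row["r2"] == pytest.approx(1.0)

    def test_independent_vectors_have_low_mean_r2(self):
        rng = np.random.default_rng(2)
        r2s = []
        for _ in range(200):
            summaries = []
            for i in range(14):
                s = make_summary("patient", float(rng.normal()), f"p{i}")
                s.lambda_by_subtype["B"] = float(rng.normal())
                summaries.append(s)
            df = correlate(summaries)
            r2s.append(df[(df["a"] == "T") & (df["b"] == "B")]["r2"].iloc[0])
        assert np.mean(r2s) < 0.15

    def test_constant_vector_recorded_missing_with_warning(self):
        summaries = []
        for i in range(5):
            s = make_summary("patient", 3.0, f"p{i}")  # constant T
            s.lambda_by_subtype["B"] = float(i)
            summaries.append(s)
        with pytest.warns(UserWarning, match="constant"):
            df = correlate(summaries)
        row = df[(df["a"] == "T") & (df["b"] == "B")].iloc[0]
        assert np.isnan(row["r2"])

    def test_serum_included_only_when_present(self):
        summaries = [make_summary("patient", float(i), f"p{i}", serum=10.0 * i)
                     for i in range(5)]
        df = correlate(summaries)
        assert (df["b"] == "Serum").any()
        row = df[(df["a"] == "T") & (df["b"] == "Serum")].iloc[0]
        assert row["r2"] == pytest.approx(1.0)


class TestBoxplots:
    def test_outliers_beyond_1p5_iqr(self):
        vals = [1.0, 2.0, 3.0, 4.0, 100.0]
        summaries = [make_summary("patient", v, f"p{i}") for i, v in enumerate(vals)]
        table = boxplot_table(summaries)
        row = table[(table["subtype"] == "T")].iloc[0]
        q1, q3 = np.percentile(vals, [25, 75])
        assert row["outliers"] == [100.0]
        assert row["whisker_high"] == 4.0
        assert row["q1"] == pytest.approx(q1) and row["q3"] == pytest.approx(q3)


class TestSummarizeCohort:
    def test_groups_and_serum_joined_from_metadata(self):
        cells = pd.concat([
            cells_frame([1, 2, 3], sample="a"),
            cells_frame([5, 6, 7], sample="b"),
        ])
        meta = pd.DataFrame(
            {"sample_id": ["a", "b"], "group": ["control", "patient"],
             "serum": [np.nan, 420.0]}
        )
        out = summarize_cohort(cells, meta)
        by_id = {s.sample_id: s for s in out}
        assert by_id["a"].group == "control" and by_id["a"].serum_value is None
        assert by_id["b"].serum_value == 420.0

    def test_sample_missing_from_metadata_raises(self):
        cells = cells_frame([1], sample="zz")
        meta = pd.DataFrame({"sample_id": ["a"], "group": ["control"]})
        with pytest.raises(DataError):
            summarize_cohort(cells, meta)
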