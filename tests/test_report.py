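"""Cross-population reporting: tables, regressions, contrasts, correlation."""

import numpy as np
import pandas as pd
import pytest

from polythresh.age_adjust import age_adjust_dataset
from polythresh.io import PopulationDataset, load_published_summaries
from polythresh.report import (
    completed_vs_over60_correlation,
    polygyny_gini_regression,
    prop_rich_contrast,
    subsistence_means,
    table_report,
)


@pytest.fixture(scope="module")
def published():
    df = load_published_summaries()
    return df.rename(
        columns={
            "wealth_gini": "gini_median",
            "wealth_ratio": "wealth_ratio_median",
            "proportion_rich": "proportion_rich_median",
            "polygyny": "polygyny_median",
            "polygyny_over60": "polygyny_over60",
        }
    )


class TestSummaryTable:
    def test_uncensored_two_class_site_recovers_closed_form(
        self, uncensored_twoclass_records
    ):
        ds = PopulationDataset(records=uncensored_twoclass_records)
        completed = age_adjust_dataset(ds, seed=7, n_draws=150)
        table = table_report(ds, completed)
        row = table.populations.iloc[0]
        # theta=0.2, m_r=6: Gini 0.40, proportion rich 0.20 (binomial noise)
        assert row["gini_median"] == pytest.approx(0.40, abs=0.05)
        assert row["proportion_rich_median"] == pytest.approx(0.20, abs=0.05)
        assert row["wealth_ratio_median"] == pytest.approx(6.0, abs=0.8)

    def test_site_without_old_men_reports_missing_over60(self):
        from polythresh.simulate import archetype_config, generate_population

        cfg = archetype_config("foraging", "young", n_males=300, age_max=59)
        ds = PopulationDataset(records=generate_population(cfg, 19))
        completed = age_adjust_dataset(ds, seed=8, n_draws=100)
        assert np.isnan(completed.population_summary["polygyny_over60"].iloc[0])

    def test_subsistence_means_match_member_rows(self, published):
        means = subsistence_means(published).set_index("subsistence")
        for cat, grp in published.groupby("subsistence"):
            assert means.loc[cat, "gini_median"] == pytest.approx(
                grp["gini_median"].mean()
            )
        # block means of the published medians, to printed precision
        assert round(means.loc["agriculture", "polygyny_median"], 2) == 0.26
        assert round(means.loc["foraging", "gini_median"], 2) == 0.26
        assert round(means.loc["horticulture", "polygyny_median"], 2) == 0.59
        assert round(means.loc["agropastoral", "polygyny_median"], 2) == 0.84

    def test_single_member_category_mean_is_member(self, published):
        one = published[published["id"].isin([1, 26])]
        means = subsistence_means(one).set_index("subsistence")
        assert means.loc["foraging", "polygyny_median"] == pytest.approx(0.66)


class TestRegression:
    def test_collinear_toy_slope(self):
        table = pd.DataFrame(
            {
                "subsistence": "horticulture",
                "gini_median": [0.1, 0.2, 0.3, 0.4],
                "polygyny_median": [0.2, 0.4, 0.6, 0.8],
            }
        )
        res = polygyny_gini_regression(table, "horticulture")
        assert res.slope == pytest.approx(2.0)

    def test_flat_polygyny_slope_zero(self):
        table = pd.DataFrame(
            {
                "subsistence": "agropastoral",
                "gini_median": [0.1, 0.3, 0.5, 0.7],
                "polygyny_median": [0.4, 0.4, 0.4, 0.4],
            }
        )
        assert polygyny_gini_regression(table, "agropastoral").slope == pytest.approx(0.0)

    def test_published_agropastoral_slope_positive_and_matches_lstsq(self, published):
        res = polygyny_gini_regression(published, "agropastoral")
        sub = published[published["subsistence"] == "agropastoral"]
        x, y = sub["gini_median"].to_numpy(), sub["polygyny_median"].to_numpy()
        slope_oracle = np.polyfit(x, y, 1)[0]
        assert res.slope > 0
        assert res.slope == pytest.approx(slope_oracle, abs=1e-10)

    def test_too_few_populations_raises(self, published):
        with pytest.raises(ValueError, match="at least 3"):
            polygyny_gini_regression(published.head(2), "foraging")


class TestContrast:
    def test_identical_groups_zero_difference(self):
        table = pd.DataFrame(
            {
                "subsistence": ["horticulture"] * 3 + ["agriculture"] * 3,
                "proportion_rich_median": [0.2, 0.3, 0.4, 0.2, 0.3, 0.4],
            }
        )
        c = prop_rich_contrast(table, "horticulture")
        assert c.difference == pytest.approx(0.0)
        assert c.lo < 0 < c.hi

    def test_published_horticultural_richer_than_agricultural(self, published):
        c = prop_rich_contrast(published, "horticulture")
        assert c.difference > 0
        # group means 0.27 vs 0.11 from the printed column
        assert c.difference == pytest.approx(0.267 - 0.113, abs=0.01)

    def test_small_group_raises(self, published):
        solo = published[published["id"].isin([1, 26, 27])]
        with pytest.raises(ValueError, match=">= 2 populations"):
            prop_rich_contrast(solo, "foraging")

    def test_welch_interval_matches_direct_formula(self):
        a = np.array([0.30, 0.25, 0.40, 0.35])
        b = np.array([0.10, 0.05, 0.12])
        table = pd.DataFrame(
            {
                "subsistence": ["horticulture"] * 4 + ["agriculture"] * 3,
                "proportion_rich_median": np.concatenate([a, b]),
            }
        )
        c = prop_rich_contrast(table, "horticulture")
        # brute-force Welch statistic
        se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
        df = se**4 / (
            (a.var(ddof=1) / a.size) ** 2 / (a.size - 1)
            + (b.var(ddof=1) / b.size) ** 2 / (b.size - 1)
        )
        from scipy import stats

        tcrit = stats.t.ppf(0.95, df)
        assert c.difference == pytest.approx(a.mean() - b.mean())
        assert c.lo == pytest.approx(a.mean() - b.mean() - tcrit * se, abs=1e-9)
        assert c.hi == pytest.approx(a.mean() - b.mean() + tcrit * se, abs=1e-9)


class TestCorrelation:
    def test_identical_columns(self):
        table = pd.DataFrame(
            {"polygyny_median": [0.1, 0.5, 0.9], "polygyny_over60": [0.1, 0.5, 0.9]}
        )
        assert completed_vs_over60_correlation(table) == pytest.approx(1.0)

    def test_three_pair_hand_computation(self):
        # r = cov/(sx sy) = 0.15/(0.40825*0.36818) = 0.99796
        table = pd.DataFrame(
            {"polygyny_median": [0.0, 0.5, 1.0], "polygyny_over60": [0.0, 0.4, 0.9]}
        )
        assert completed_vs_over60_correlation(table) == pytest.approx(0.99796, abs=1e-4)

    def test_published_columns_pairwise_complete(self, published):
        # two populations lack the over-60 column: 27 pairs, rho = 0.93
        rho = completed_vs_over60_correlation(published)
        assert round(rho, 2) == 0.93
        assert published["polygyny_over60"].notna().sum() == 27

    def test_too_few_pairs_raises(self):
        table = pd.DataFrame(
            {"polygyny_median": [0.1, 0.5], "polygyny_over60": [0.1, np.nan]}
        )
        with pytest.raises(ValueError, match="3 complete pairs"):
            completed_vs_over60_correlation(table)
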