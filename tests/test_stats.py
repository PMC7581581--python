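"""Repeated-measures battery: transforms, split-plot ANOVA, post hocs, Pearson."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ttest_rel

from chromassay import (
    CohortDesign,
    analyze_dataset,
    default_effect_model,
    generate_cohort,
    greenhouse_geisser_epsilon,
    log_transform,
    mixed_anova,
    pairwise_posthoc,
    partial_eta_squared,
    pearson,
)
from chromassay.pipeline_io import score_table


def _paired_frame(rng, n=20, delta=0.1, sd=0.15):
    w = rng.normal(3.8, 0.2, n)
    b = w + delta + rng.normal(0, sd, n)
    return pd.DataFrame(
        {
            "subject": list(range(n)) * 2,
            "background": ["white"] * n + ["black"] * n,
            "y": np.concatenate([w, b]),
        }
    )


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def test_log_transform_values():
    assert log_transform([1.0])[0] == 0.0
    assert log_transform([20.0])[0] == pytest.approx(2.9957, abs=1e-4)
    assert log_transform([0.0], offset=1.0)[0] == 0.0


def test_log_transform_rejects_nonpositive():
    with pytest.raises(ValueError, match="observation 1"):
        log_transform([2.0, 0.0])


@pytest.mark.parametrize("ss_e, ss_r, expected", [(0, 5, 0.0), (5, 5, 0.5), (3, 7, 0.3)])
def test_partial_eta_squared_values(ss_e, ss_r, expected):
    assert partial_eta_squared(ss_e, ss_r) == pytest.approx(expected)


def test_partial_eta_squared_undefined_at_zero():
    with pytest.raises(ValueError):
        partial_eta_squared(0.0, 0.0)


# ---------------------------------------------------------------------------
# Greenhouse-Geisser epsilon
# ---------------------------------------------------------------------------

def test_gg_epsilon_is_one_for_two_levels():
    assert greenhouse_geisser_epsilon(np.array([[1.0, 0.3], [0.3, 2.0]])) == 1.0


def test_gg_epsilon_is_one_under_compound_symmetry():
    S = np.full((3, 3), 0.4) + np.eye(3) * 0.6
    assert greenhouse_geisser_epsilon(S) == pytest.approx(1.0)


def test_gg_epsilon_matches_direct_formula():
    rng = np.random.default_rng(8)
    A = rng.normal(size=(3, 3))
    S = A @ A.T
    k = 3
    P = np.eye(k) - np.ones((k, k)) / k
    Sc = P @ S @ P
    direct = np.trace(Sc) ** 2 / ((k - 1) * np.trace(Sc @ Sc))
    assert greenhouse_geisser_epsilon(S) == pytest.approx(np.clip(direct, 1 / (k - 1), 1.0))


def test_gg_epsilon_rejects_non_square():
    with pytest.raises(ValueError, match="square"):
        greenhouse_geisser_epsilon(np.zeros((2, 3)))


# ---------------------------------------------------------------------------
# Mixed ANOVA
# ---------------------------------------------------------------------------

def test_background_f_equals_paired_t_squared(rng):
    df = _paired_frame(rng)
    tab = mixed_anova(df, dv="y", within="background", subject="subject")
    row = tab[tab["effect"] == "background"].iloc[0]
    w = df[df.background == "white"].sort_values("subject")["y"].to_numpy()
    b = df[df.background == "black"].sort_values("subject")["y"].to_numpy()
    t = ttest_rel(b, w)
    assert row["F"] == pytest.approx(t.statistic**2, rel=1e-10)
    assert row["p"] == pytest.approx(t.pvalue, rel=1e-10)
    assert row["gg_epsilon"] == 1.0
    assert row["p_gg"] == pytest.approx(row["p"], rel=1e-12)


def test_mixed_anova_matches_pingouin_one_between(rng):
    """Independent oracle: pingouin's mixed ANOVA on a 1-between design."""
    pg = pytest.importorskip("pingouin")
    df = _paired_frame(rng, n=24)
    df["dose"] = (df["subject"] % 4).map({0: 0, 1: 10, 2: 100, 3: 1000})
    mine = mixed_anova(df, dv="y", within="background", subject="subject", between=["dose"])
    theirs = pg.mixed_anova(data=df, dv="y", within="background", between="dose", subject="subject")
    pairs = {"dose": "dose", "background": "background", "background:dose": "Interaction"}
    for my_name, pg_name in pairs.items():
        my_row = mine[mine["effect"] == my_name].iloc[0]
        pg_row = theirs[theirs["Source"] == pg_name].iloc[0]
        assert my_row["SS"] == pytest.approx(pg_row["SS"], rel=1e-8)
        assert my_row["F"] == pytest.approx(pg_row["F"], rel=1e-8)
        assert my_row["p"] == pytest.approx(pg_row["p_unc"], rel=1e-8)
        assert my_row["partial_eta_sq"] == pytest.approx(pg_row["np2"], rel=1e-8)


def test_mixed_anova_unbalanced_design_runs(rng):
    df = _paired_frame(rng, n=22)
    # 10 controls vs 12 treated: unbalanced Type-III fit
    df["dose"] = np.where(df["subject"] < 10, 0, 1000)
    tab = mixed_anova(df, dv="y", within="background", subject="subject", between=["dose"])
    assert set(tab["effect"]) >= {"dose", "background", "background:dose"}
    assert (tab["SS"].dropna() >= 0).all()


def test_mixed_anova_reports_missing_subjects(rng):
    df = _paired_frame(rng).iloc[:-1]  # drop one black observation
    with pytest.raises(ValueError, match="missing"):
        mixed_anova(df, dv="y", within="background", subject="subject")


def test_mixed_anova_rejects_duplicate_observations(rng):
    df = _paired_frame(rng)
    df = pd.concat([df, df.iloc[[0]]])
    with pytest.raises(ValueError, match="duplicate"):
        mixed_anova(df, dv="y", within="background", subject="subject")


def test_mixed_anova_rejects_singular_between(rng):
    df = _paired_frame(rng, n=8)
    df["dose"] = (df["subject"] % 4) * 10
    df["trial"] = df["subject"] % 4  # fully aliased with dose -> empty cells
    with pytest.raises(ValueError, match="singular"):
        mixed_anova(df, dv="y", within="background", subject="subject", between=["dose", "trial"])


# ---------------------------------------------------------------------------
# Post hoc pairwise comparisons
# ---------------------------------------------------------------------------

def test_posthoc_pair_count_and_bonferroni(rng):
    df = pd.DataFrame(
        {
            "g": np.repeat(list("abcd"), 10),
            "y": rng.normal(size=40),
        }
    )
    tab = pairwise_posthoc(df, factor="g", response="y")
    assert len(tab) == 6  # k(k-1)/2 with k=4
    assert (tab["family_size"] == 6).all()
    assert np.allclose(tab["p_bonferroni"], np.minimum(1.0, 6 * tab["p_raw"]))
    assert (tab["p_bonferroni"] >= tab["p_raw"]).all()


def test_posthoc_identical_groups_not_significant():
    y = np.tile([1.0, 2.0, 3.0, 4.0], 2)
    df = pd.DataFrame({"g": np.repeat(["a", "b"], 4), "y": y})
    tab = pairwise_posthoc(df, factor="g", response="y")
    assert tab["p_raw"].iloc[0] == pytest.approx(1.0)
    assert tab["p_bonferroni"].iloc[0] == pytest.approx(1.0)


def test_posthoc_rejects_tiny_level():
    df = pd.DataFrame({"g": ["a", "a", "b"], "y": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError, match="fewer than 2"):
        pairwise_posthoc(df, factor="g", response="y")


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

def test_pearson_perfect_line():
    x = np.arange(10.0)
    res = pearson(x, 2 * x + 1)
    assert res.r == pytest.approx(1.0)
    assert res.r_squared == pytest.approx(1.0)


def test_pearson_matches_formula_oracle():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([1.0, -1.0, 1.0, -1.0])
    oracle = np.sum((x - x.mean()) * (y - y.mean())) / (
        np.sqrt(np.sum((x - x.mean()) ** 2)) * np.sqrt(np.sum((y - y.mean()) ** 2))
    )
    res = pearson(x, y)
    assert res.r == pytest.approx(oracle, rel=1e-12)
    assert res.r_squared == pytest.approx(oracle**2, rel=1e-12)


def test_pearson_r_squared_is_exact_square():
    # a correlation of 0.793 implies r^2 = 0.6288..., i.e. ~0.629
    assert 0.793**2 == pytest.approx(0.629, abs=5e-4)


def test_pearson_input_validation():
    with pytest.raises(ValueError, match="zero variance"):
        pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="at least 3"):
        pearson([1.0, 2.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# Full battery
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def scored_cohort():
    design = CohortDesign(trials=(1, 2), concentrations=(0, 1000),
                          exposure_times=("1h", "1wk"), replicates_per_treatment=6, seed=17)
    bundle = generate_cohort(design, default_effect_model())
    return score_table(bundle.table)


def test_analyze_detects_injected_background_effect(scored_cohort):
    report = analyze_dataset(scored_cohort, responses=("coefficient",))
    aov = report.anovas["coefficient"]
    row = aov[aov["effect"] == "background"].iloc[0]
    assert row["p"] < 0.001
    assert row["gg_epsilon"] == 1.0


def test_analyze_produces_trial_subsets(scored_cohort):
    report = analyze_dataset(scored_cohort, responses=("coefficient",))
    assert ("coefficient", 1) in report.trial_subsets
    assert ("coefficient", 2) in report.trial_subsets
    sub = report.trial_subsets[("coefficient", 1)]
    assert "background" in set(sub["effect"])


def test_analyze_background_shift_summary(scored_cohort):
    report = analyze_dataset(scored_cohort, responses=("coefficient",))
    shift = report.background_shift["coefficient"]
    lo, hi = shift["ci95"]
    assert lo < shift["mean_percent"] < hi
    assert shift["n_units"] == scored_cohort["specimen_id"].nunique() * 2  # x exposure times


def test_analyze_requires_a_response():
    with pytest.raises(ValueError, match="response"):
        analyze_dataset(pd.DataFrame({"specimen_id": [], "exposure_time": [], "background": []}))
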