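"""Response aggregation, win probabilities, and the within-subjects ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromaglint.design import build_pc_trials
from chromaglint.observers import ObserverParams, simulate_choices
from chromaglint.psychophysics import (
    aggregate_matches,
    pc_probability,
    rm_anova,
    validate_matches,
)


def _match_df(rows):
    return pd.DataFrame(
        rows, columns=["observer", "hue", "relief", "roughness", "slant", "L", "C"]
    )


def test_single_response_aggregation():
    df = _match_df([("o1", 40.0, 0.1, 0.1, 15.0, 60.0, 60.0)])
    out = aggregate_matches(df)
    assert len(out) == 1
    assert out.loc[0, "mean_S"] == pytest.approx(1.0)
    assert out.loc[0, "n_trials"] == 1


def test_mean_chroma_over_two_responses():
    df = _match_df(
        [("o1", 40.0, 0.1, 0.1, 15.0, 60.0, 60.0),
         ("o1", 40.0, 0.1, 0.1, 15.0, 60.0, 82.5)]
    )
    out = aggregate_matches(df)
    assert out.loc[0, "mean_C"] == pytest.approx(71.25)


def test_saturation_rules_differ():
    # {(L=30, C=60), (L=60, C=30)}: mean of ratios 1.25, ratio of means 1.0
    df = _match_df(
        [("o1", 40.0, 0.1, 0.1, 15.0, 30.0, 60.0),
         ("o1", 40.0, 0.1, 0.1, 15.0, 60.0, 30.0)]
    )
    mor = aggregate_matches(df, rule="mean-of-ratios").loc[0, "mean_S"]
    rom = aggregate_matches(df, rule="ratio-of-means").loc[0, "mean_S"]
    assert mor == pytest.approx(1.25)
    assert rom == pytest.approx(1.0)
    with pytest.raises(ValueError):
        aggregate_matches(df, rule="median")


def test_grid_validation_rejects_off_grid_settings(small_grid):
    df = _match_df([("o1", 40.0, 0.1, 0.1, 15.0, 44.0, 30.0)])
    with pytest.raises(ValueError, match="not on the matching grid"):
        validate_matches(df, small_grid)


def _choices(rows):
    return pd.DataFrame(
        rows,
        columns=["observer", "task", "hue", "slant", "relief1", "roughness1",
                 "relief2", "roughness2", "chosen"],
    )


def test_pc_probability_simple_counts():
    rows = []
    for k in range(60):
        rows.append(("o1", "gloss", 40.0, 15.0, 0.025, 0.01, 0.2, 0.4,
                     1 if k < 30 else 2))
    p = pc_probability(_choices(rows))
    a = p[np.isclose(p["relief"], 0.025)].iloc[0]
    assert a["p"] == pytest.approx(0.5)
    assert a["n_presentations"] == 60
    b = p[np.isclose(p["relief"], 0.2)].iloc[0]
    assert b["p"] == pytest.approx(0.5)


def test_pc_probability_extremes_and_pair_sums():
    rows = [("o1", "gloss", 40.0, 15.0, 0.025, 0.01, 0.2, 0.4, 1)] * 10
    rows += [("o1", "gloss", 40.0, 15.0, 0.2, 0.4, 0.025, 0.01, 2)] * 10
    p = pc_probability(_choices(rows))
    winner = p[np.isclose(p["relief"], 0.025)].iloc[0]
    loser = p[np.isclose(p["relief"], 0.2)].iloc[0]
    assert winner["p"] == 1.0 and loser["p"] == 0.0
    # wins(i over j) + wins(j over i) equals the pair's presentation count
    total_wins = (p["p"] * p["n_presentations"]).sum()
    assert total_wins == len(rows)


def test_round_robin_wins_sum_to_trial_count(pc_block):
    trials = build_pc_trials(pc_block, seed=3)
    choices = simulate_choices(
        ObserverParams(seed=0), trials, "gloss", observers=("o1",)
    )
    p = pc_probability(choices)
    assert len(p) == 16
    assert (p["n_presentations"] == 30).all()
    assert (p["p"] * p["n_presentations"]).sum() == pytest.approx(240)


def test_pc_probability_with_designed_trial_list_denominator(pc_block):
    trials = build_pc_trials(pc_block, seed=3)
    choices = simulate_choices(
        ObserverParams(seed=0), trials, "gloss", observers=("o1",)
    )
    # drop some recorded choices: designed denominators keep 30 presentations
    partial = choices.iloc[:200]
    p = pc_probability(partial, trials=trials.to_frame())
    assert (p["n_presentations"] == 30).all()
    assert (p["p"] * 30).sum() == pytest.approx(200)


def test_pc_probability_schema_validation():
    with pytest.raises(ValueError, match="missing columns"):
        pc_probability(pd.DataFrame({"observer": []}))
    bad = _choices([("o1", "gloss", 40.0, 15.0, 0.025, 0.01, 0.2, 0.4, 3)])
    with pytest.raises(ValueError, match="chosen"):
        pc_probability(bad)


# -- repeated-measures ANOVA ------------------------------------------------

def _long(data, subjects, factors):
    """data indexed [subject, level_1, ..., level_k] -> long DataFrame."""
    idx = pd.MultiIndex.from_product(
        [subjects] + [range(n) for n in data.shape[1:]],
        names=["observer"] + factors,
    )
    return pd.Series(data.ravel(), index=idx, name="y").reset_index()


def test_df_pattern_one_factor_nine_subjects(rng):
    data = rng.normal(size=(9, 5))
    out = rm_anova(_long(data, [f"s{i}" for i in range(9)], ["roughness"]),
                   "y", ["roughness"])
    assert (out.loc[0, "df1"], out.loc[0, "df2"]) == (4, 32)


def test_df_pattern_two_factors_four_subjects(rng):
    data = rng.normal(size=(4, 4, 4))
    out = rm_anova(
        _long(data, list("abcd"), ["roughness", "relief"]),
        "y", ["roughness", "relief"],
    )
    inter = out[out["effect"] == "roughness:relief"].iloc[0]
    assert (inter["df1"], inter["df2"]) == (9, 27)


def test_two_level_factor_equals_paired_t_test(rng):
    # with one two-level factor, F must equal the squared paired t statistic
    data = rng.normal(size=(6, 2))
    df = _long(data, [f"s{i}" for i in range(6)], ["A"])
    out = rm_anova(df, "y", ["A"])
    t, p = stats.ttest_rel(data[:, 0], data[:, 1])
    assert out.loc[0, "F"] == pytest.approx(t**2, rel=1e-10)
    assert out.loc[0, "p"] == pytest.approx(p, rel=1e-10)


def test_matches_statsmodels_on_random_designs(rng):
    from statsmodels.stats.anova import AnovaRM

    for shape in [(5, 3), (4, 2, 3), (6, 2, 2)]:
        data = rng.normal(size=shape)
        factors = [f"f{i}" for i in range(len(shape) - 1)]
        df = _long(data, [f"s{i}" for i in range(shape[0])], factors)
        mine = rm_anova(df, "y", factors).set_index("effect")
        ref = AnovaRM(df, "y", "observer", within=factors).fit().anova_table
        for effect, row in ref.iterrows():
            assert mine.loc[effect, "F"] == pytest.approx(
                row["F Value"], abs=1e-10
            )


def test_invariant_to_subject_constant_shift(rng):
    data = rng.normal(size=(5, 3, 2))
    subjects = [f"s{i}" for i in range(5)]
    df = _long(data, subjects, ["A", "B"])
    base = rm_anova(df, "y", ["A", "B"])
    shifted = df.copy()
    shifted.loc[shifted["observer"] == "s2", "y"] += 100.0
    after = rm_anova(shifted, "y", ["A", "B"])
    assert np.allclose(base["F"], after["F"], atol=1e-8)


def test_missing_cells_and_few_subjects_raise(rng):
    data = rng.normal(size=(4, 3))
    df = _long(data, list("abcd"), ["A"])
    with pytest.raises(ValueError, match="missing cells"):
        rm_anova(df.iloc[:-1], "y", ["A"])
    solo = df[df["observer"] == "a"]
    with pytest.raises(ValueError, match="2 subjects"):
        rm_anova(solo, "y", ["A"])
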