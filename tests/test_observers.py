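"""Synthetic observer generator: cue templates, simulators, reproducibility."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromaglint.design import (
    HUES,
    RELIEFS,
    ROUGHNESS_PC,
    SLANTS,
    SurfaceCondition,
    build_matching_grid,
    build_pc_trials,
    enumerate_conditions,
)
from chromaglint.observers import (
    ObserverParams,
    latent_setting_means,
    make_dataset,
    simulate_choices,
    simulate_latent_cues,
    simulate_matching,
)
from chromaglint.psychophysics import pc_probability


@pytest.fixture(scope="module")
def params():
    return ObserverParams(seed=11)


def test_cues_bounded_and_deterministic(params):
    conds = enumerate_conditions(HUES, RELIEFS, ROUGHNESS_PC, SLANTS)
    a = simulate_latent_cues(params, conds)
    b = simulate_latent_cues(params, conds)
    pd.testing.assert_frame_equal(a, b)
    assert a[["gloss", "coverage"]].min().min() >= 0.0
    assert a[["gloss", "coverage"]].max().max() <= 1.0


def test_gloss_strictly_decreases_with_roughness(params):
    conds = enumerate_conditions(HUES, RELIEFS, ROUGHNESS_PC, SLANTS)
    cues = simulate_latent_cues(params, conds)
    for _, blk in cues.groupby(["hue", "relief", "slant"]):
        g = blk.sort_values("roughness")["gloss"].to_numpy()
        assert np.all(np.diff(g) < 0)


def test_low_relief_inversion_flag(params):
    inv = ObserverParams(seed=11, low_relief_gloss_inversion=True)
    conds = enumerate_conditions([HUES[0]], RELIEFS, ROUGHNESS_PC, [15.0])
    cues = simulate_latent_cues(inv, conds)
    low = cues[np.isclose(cues["relief"], 0.025)].sort_values("roughness")
    assert np.all(np.diff(low["gloss"]) > 0)  # rises with roughness
    high = cues[np.isclose(cues["relief"], 0.2)].sort_values("roughness")
    assert np.all(np.diff(high["gloss"]) < 0)


def test_coverage_slopes_flip_sign_between_slants(params):
    conds = enumerate_conditions(
        [HUES[0]], [0.025, 0.2], [0.01, 0.4], [15.0, 45.0]
    )
    cues = simulate_latent_cues(params, conds).set_index(
        ["relief", "roughness", "slant"]
    )["coverage"]
    for lo, hi, other in [
        ((0.025,), (0.2,), 0.01),  # relief finite difference at roughness 0.01
        ((0.01,), (0.4,), 0.025),  # roughness finite difference at relief 0.025
    ]:
        if other in (0.01, 0.4):
            d15 = cues[(hi[0], other, 15.0)] - cues[(lo[0], other, 15.0)]
            d45 = cues[(hi[0], other, 45.0)] - cues[(lo[0], other, 45.0)]
        else:
            d15 = cues[(other, hi[0], 15.0)] - cues[(other, lo[0], 15.0)]
            d45 = cues[(other, hi[0], 45.0)] - cues[(other, lo[0], 45.0)]
        assert d15 > 0 and d45 < 0


def test_matching_noise_free_snaps_to_nearest_cell(red_grid_clip):
    p = ObserverParams(seed=2, setting_noise_sd=0.0)
    conds = enumerate_conditions([HUES[0]], RELIEFS, ROUGHNESS_PC, SLANTS)
    resp = simulate_matching(p, conds, red_grid_clip)
    means = latent_setting_means(p, simulate_latent_cues(p, conds))
    for col, levels in (("L", red_grid_clip.lightness_levels),
                        ("C", red_grid_clip.chroma_levels)):
        target = means[f"{col}_mean"].to_numpy()
        snapped = levels[np.argmin(np.abs(target[:, None] - levels[None, :]), axis=1)]
        assert np.array_equal(resp[col].to_numpy(), snapped)


def test_midpoint_ties_break_to_lower_level():
    from chromaglint.observers import _snap

    levels = np.array([18.75, 22.5, 26.25])
    assert _snap(np.array([20.625]), levels)[0] == 18.75
    assert _snap(np.array([24.375]), levels)[0] == 22.5
    assert _snap(np.array([0.0]), levels)[0] == 18.75  # clipped to edge
    assert _snap(np.array([99.0]), levels)[0] == 26.25


def test_matching_cells_match_discretized_gaussian(red_grid_clip):
    # one condition, setting noise of one grid step: the distribution over
    # chosen lightness levels must match direct discretization of the normal
    p = ObserverParams(seed=5, setting_noise_sd=3.75)
    conds = enumerate_conditions([HUES[0]], [0.1], [0.1], [15.0])
    observers = [f"o{i}" for i in range(10_000)]
    resp = simulate_matching(p, conds, red_grid_clip, observers=observers)
    mean_L = latent_setting_means(p, simulate_latent_cues(p, conds))["L_mean"][0]
    levels = red_grid_clip.lightness_levels
    edges = np.concatenate(
        [[-np.inf], (levels[:-1] + levels[1:]) / 2, [np.inf]]
    )
    expected = np.diff(stats.norm.cdf(edges, loc=mean_L, scale=3.75)) * len(observers)
    observed = np.array([(resp["L"] == lv).sum() for lv in levels])
    keep = expected > 5
    chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
    pval = stats.chi2.sf(chi2, keep.sum() - 1)
    assert pval > 0.01


def test_out_of_grid_means_warn(small_grid):
    # an extreme weight pushes setting means outside the small grid
    p = ObserverParams(seed=3, true_W_sat=-1.0, true_W_light=-1.0)
    tiny = build_matching_grid(HUES[0], 48.75, 56.25, 26.25, 30.0, 3.75)
    conds = enumerate_conditions([HUES[0]], RELIEFS, ROUGHNESS_PC, SLANTS)
    with pytest.warns(UserWarning, match="outside the matching grid"):
        simulate_matching(p, conds, tiny)


def test_choices_deterministic_without_noise(pc_block):
    p = ObserverParams(seed=7, choice_noise_sd=0.0)
    trials = build_pc_trials(pc_block, seed=1)
    choices = simulate_choices(p, trials, "gloss")
    cues = simulate_latent_cues(p, pc_block).set_index(
        ["relief", "roughness"]
    )["gloss"]
    for row in choices.itertuples(index=False):
        d = cues[(row.relief1, row.roughness1)] - cues[(row.relief2, row.roughness2)]
        assert row.chosen == (1 if d > 0 else 2)


def test_equal_cues_choose_half_the_time():
    a = SurfaceCondition(40.0, 0.1, 0.1, 15.0)
    b = SurfaceCondition(40.0, 0.1, 0.1, 15.0)
    # identical cue values via two distinct conditions with equal templates:
    # use two conditions symmetric in the template (same rn, qn)
    a = SurfaceCondition(40.0, 0.1, 0.2, 15.0)
    b = SurfaceCondition(40.0, 0.1, 0.2, 30.0)  # gloss has no slant term
    p = ObserverParams(seed=9, choice_noise_sd=0.3)
    trials_df = [(a, b)] * 1000 + [(b, a)] * 1000
    from chromaglint.design import TrialList

    tl = TrialList(design="paired-comparison", trials=tuple(trials_df), seed=0)
    choices = simulate_choices(p, tl, "gloss")
    rate = (choices["chosen"] == 1).mean()
    n = len(choices)
    assert abs(rate - 0.5) < 3 * np.sqrt(0.25 / n)


def test_win_probability_converges_to_thurstone_closed_form():
    # two conditions, 250 simulated observers -> 500 presentations per pair;
    # empirical win rate must approach Phi(delta / (sqrt(2) sd))
    a = SurfaceCondition(40.0, 0.025, 0.01, 15.0)
    b = SurfaceCondition(40.0, 0.2, 0.01, 15.0)
    p = ObserverParams(seed=4, choice_noise_sd=0.25)
    cues = simulate_latent_cues(p, [a, b])
    delta = float(cues["coverage"][0] - cues["coverage"][1])
    expected = stats.norm.cdf(delta / (np.sqrt(2) * 0.25))
    tl = build_pc_trials([a, b], seed=0)
    choices = simulate_choices(
        p, tl, "coverage", observers=[f"o{i}" for i in range(250)]
    )
    probs = pc_probability(choices)
    est = probs.groupby(["relief"])["p"].mean()
    assert est[0.025] == pytest.approx(expected, abs=0.03)
    assert est[0.2] == pytest.approx(1 - expected, abs=0.03)


def test_noiseless_choices_reproduce_cue_ranking(pc_block):
    p = ObserverParams(seed=6, choice_noise_sd=0.0)
    trials = build_pc_trials(pc_block, seed=2)
    choices = simulate_choices(p, trials, "coverage")
    probs = pc_probability(choices).sort_values(
        ["relief", "roughness"]
    ).reset_index(drop=True)
    cues = simulate_latent_cues(p, pc_block).sort_values(
        ["relief", "roughness"]
    ).reset_index(drop=True)
    assert np.array_equal(
        np.argsort(probs["p"].to_numpy(), kind="stable"),
        np.argsort(cues["coverage"].to_numpy(), kind="stable"),
    )


def test_dataset_bit_reproducible(red_grid_clip):
    p = ObserverParams(seed=21)
    grids = {h: build_matching_grid(h, validate_gamut="clip") for h in HUES}
    kwargs = dict(
        hues=HUES, slants=SLANTS, reliefs=RELIEFS, roughnesses=ROUGHNESS_PC,
        grid_by_hue=grids, n_matching_observers=3, n_choice_observers=2,
    )
    d1 = make_dataset(p, **kwargs)
    d2 = make_dataset(p, **kwargs)
    pd.testing.assert_frame_equal(d1.matching, d2.matching)
    pd.testing.assert_frame_equal(d1.gloss_choices, d2.gloss_choices)
    pd.testing.assert_frame_equal(d1.coverage_choices, d2.coverage_choices)
    assert d1.trial_seeds == d2.trial_seeds
    assert d1.ground_truth()["true_W_sat"] == 0.41


def test_end_to_end_recovery_of_true_weight():
    """The full chain (simulate -> aggregate -> sweep) recovers the
    generating saturation weight to within half a grid-step band, with a
    median error below 0.05 over 100 seeds at default noise."""
    import warnings

    from chromaglint.pipeline import RunConfig, run_pipeline

    errs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in range(100):
            rep = run_pipeline(RunConfig(seed=seed, run_anova=False))
            errs.append(rep.recovery["saturation"]["pooled_W"] - 0.41)
    assert abs(np.median(errs)) <= 0.05
    assert np.percentile(np.abs(errs), 90) <= 0.15
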