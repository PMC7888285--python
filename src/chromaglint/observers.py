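"""Synthetic observers with known ground truth.

The human data behind the original experiments are not deposited, so every
downstream stage is exercised on simulated observers whose generative
structure mirrors the analysis assumptions:

* latent gloss and coverage cues are smooth deterministic surfaces over
  (relief, roughness, slant), qualitatively shaped like the reported
  percepts — gloss declines with specular roughness; the coverage slopes in
  relief and roughness flip sign between the 15 deg and 45 deg slants;
* color percepts follow the weighted linear model
  P' = W * coverage + (1 - W) * (1 - gloss) with independent true weights
  for saturation and lightness;
* matching settings are an affine map of the percepts into (L*, C*) grid
  space plus Gaussian setting noise, snapped to the nearest grid cell;
* paired-comparison choices follow a Thurstonian rule: choose the first
  stimulus iff cue(first) - cue(second) + N(0, sd) > 0.

All randomness flows from one seed, split into labelled substreams
(matching / gloss choices / coverage choices), so a dataset is bit-identical
under regeneration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .design import MatchingGrid, SurfaceCondition, TrialList, conditions_to_frame

__all__ = [
    "ObserverParams",
    "SyntheticDataset",
    "simulate_latent_cues",
    "simulate_matching",
    "simulate_choices",
    "make_dataset",
]

# Reference ranges used to normalise relief / roughness into [0, 1];
# these span the experimental level sets.
_RELIEF_RANGE = (0.025, 0.200)
_ROUGH_RANGE = (0.010, 0.400)

_SUBSTREAMS = {"matching": 1, "gloss": 2, "coverage": 3}


@dataclass(frozen=True)
class ObserverParams:
    """Ground-truth parameters of a synthetic observer population.

    ``true_W_sat`` / ``true_W_light`` are the cue-combination weights that
    generate the saturation and lightness percepts.  ``setting_noise_sd``
    is in LCH units (the matching grid step is 3.75); ``choice_noise_sd``
    is in latent cue units (cue surfaces live in [0, 1]).
    ``hue_W_offsets`` optionally shifts the true weights per hue angle,
    emulating hue-dependent cue weighting without asserting its cause.
    """

    true_W_sat: float = 0.41
    true_W_light: float = 0.34
    setting_noise_sd: float = 3.75
    choice_noise_sd: float = 0.25
    low_relief_gloss_inversion: bool = False
    hue_W_offsets: Mapping[float, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.setting_noise_sd < 0 or self.choice_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")


def _norm(x, lo, hi):
    return (np.asarray(x, float) - lo) / (hi - lo)


def _slant_sign(slant):
    """+1 at 15 deg, 0 at 30 deg, -1 at 45 deg (linear in slant)."""
    return (30.0 - np.asarray(slant, float)) / 15.0


def simulate_latent_cues(
    params: ObserverParams, conditions
) -> pd.DataFrame:
    """Deterministic latent gloss and coverage cues per condition, in [0, 1].

    Gloss is strictly decreasing in roughness (unless the optional
    low-relief inversion is enabled, which makes the lowest-relief rows
    increase with roughness and plateau, as reported for near-flat
    surfaces).  The coverage surface combines a slant-signed linear trend
    in relief and roughness with a slant-independent inverted-U component
    in roughness, so its relief and roughness slopes are positive at
    15 deg and negative at 45 deg.
    """
    df = conditions_to_frame(conditions)
    rn = _norm(df["relief"], *_RELIEF_RANGE)
    qn = _norm(df["roughness"], *_ROUGH_RANGE)
    s = _slant_sign(df["slant"])

    # Amplitudes keep pairwise cue differences within ~1.5 x the Thurstonian
    # choice noise, the near-linear regime of the win-probability transform
    # that the downstream correlation analysis assumes.  Cue surfaces carry
    # no slant main effect: win probabilities are centred within each
    # hue x slant block, so a between-block cue shift could never be
    # recovered from them.
    gloss = 0.72 - 0.28 * qn + 0.06 * (0.5 - rn)
    if params.low_relief_gloss_inversion:
        low = rn < 0.15
        inv = 0.40 + 0.30 * np.tanh(2.5 * qn) / np.tanh(2.5)
        gloss = np.where(low, inv, gloss)

    u = 0.25 - (qn - 0.5) ** 2  # inverted U, 0 at the roughness extremes
    coverage = 0.5 + s * (0.22 * (rn - 0.5) + 0.14 * (qn - 0.5)) + 0.24 * u - 0.06

    out = df.copy()
    out["gloss"] = np.clip(gloss, 0.0, 1.0)
    out["coverage"] = np.clip(coverage, 0.0, 1.0)
    return out


def _true_weights(params: ObserverParams, hue) -> tuple[np.ndarray, np.ndarray]:
    off = np.array([params.hue_W_offsets.get(float(h), 0.0) for h in np.atleast_1d(hue)])
    return params.true_W_sat + off, params.true_W_light + off


#: Affine map of model-space percepts into matching-grid settings.
#: L* = 60 + 25 (p_light - 1/2); saturation = 1 + 0.6 (p_sat - 1/2);
#: C* = L* x saturation.  For cue surfaces in [0.13, 0.93] the means stay
#: inside the 18.75-97.5 (L*) x 22.5-101.25 (C*) grid.
_L_GAIN = 25.0
_S_GAIN = 0.6


def latent_setting_means(params: ObserverParams, cues: pd.DataFrame) -> pd.DataFrame:
    """Noise-free (L*, C*) setting means implied by the generative model."""
    W_sat, W_light = _true_weights(params, cues["hue"].to_numpy())
    gloss = cues["gloss"].to_numpy()
    coverage = cues["coverage"].to_numpy()
    p_sat = W_sat * coverage + (1.0 - W_sat) * (1.0 - gloss)
    p_light = W_light * coverage + (1.0 - W_light) * (1.0 - gloss)
    L = 60.0 + _L_GAIN * (p_light - 0.5)
    S = 1.0 + _S_GAIN * (p_sat - 0.5)
    out = cues.copy()
    out["L_mean"] = L
    out["C_mean"] = L * S
    return out


def _snap(values: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Nearest grid level, ties broken to the lower index; clips to edges."""
    d = np.abs(values[:, None] - levels[None, :])
    return levels[np.argmin(d, axis=1)]


def simulate_matching(
    params: ObserverParams,
    conditions,
    grid: MatchingGrid,
    observers=("o1",),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Matching responses: noisy settings snapped to the grid.

    Warns when the noise-free setting means of more than 10% of conditions
    fall outside the grid (a sign the affine map is mis-configured).
    """
    if rng is None:
        rng = np.random.default_rng([params.seed, _SUBSTREAMS["matching"]])
    cues = simulate_latent_cues(params, conditions)
    means = latent_setting_means(params, cues)
    out_of_grid = (
        (means["L_mean"] < grid.lightness_levels[0])
        | (means["L_mean"] > grid.lightness_levels[-1])
        | (means["C_mean"] < grid.chroma_levels[0])
        | (means["C_mean"] > grid.chroma_levels[-1])
    )
    if out_of_grid.mean() > 0.10:
        warnings.warn(
            f"{out_of_grid.mean():.0%} of setting means fall outside the "
            "matching grid; check the percept-to-setting affine map",
            stacklevel=2,
        )
    observers = list(observers)
    n_obs, n_cond = len(observers), len(means)
    L = means["L_mean"].to_numpy()[None, :] + rng.normal(
        0, params.setting_noise_sd, (n_obs, n_cond)
    )
    C = means["C_mean"].to_numpy()[None, :] + rng.normal(
        0, params.setting_noise_sd, (n_obs, n_cond)
    )
    df = pd.concat([means[["hue", "relief", "roughness", "slant"]]] * n_obs,
                   ignore_index=True)
    df.insert(0, "observer", np.repeat(observers, n_cond))
    df["L"] = _snap(L.ravel(), grid.lightness_levels)
    df["C"] = _snap(C.ravel(), grid.chroma_levels)
    return df


def simulate_choices(
    params: ObserverParams,
    trial_list: TrialList,
    cue: str,
    observers=("o1",),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Thurstonian (Case V) paired-comparison choices on one cue.

    Each stimulus carries independent latent noise N(0, choice_noise_sd):
    choice = first iff (cue(first) + e1) - (cue(second) + e2) > 0, so the
    win probability is Phi(delta_cue / (sqrt(2) * sd)).  Deterministic when
    the noise SD is 0.
    """
    if cue not in ("gloss", "coverage"):
        raise ValueError("cue must be 'gloss' or 'coverage'")
    if rng is None:
        rng = np.random.default_rng([params.seed, _SUBSTREAMS[cue]])
    observers = list(observers)
    pair_conditions = sorted({c for pair in trial_list.trials for c in pair})
    cues = simulate_latent_cues(params, pair_conditions)
    lookup = {
        SurfaceCondition(r.hue, r.relief, r.roughness, r.slant): getattr(r, cue)
        for r in cues.itertuples(index=False)
    }
    firsts = [a for a, _ in trial_list.trials]
    seconds = [b for _, b in trial_list.trials]
    delta = np.array([lookup[a] - lookup[b] for a, b in trial_list.trials])
    n_obs, n_tr = len(observers), len(delta)
    noisy = np.tile(delta, (n_obs, 1))
    if params.choice_noise_sd > 0:
        item_noise = rng.normal(0, params.choice_noise_sd, (2, n_obs, n_tr))
        noisy = noisy + item_noise[0] - item_noise[1]
    chosen = np.where(noisy > 0, 1, 2)
    base = pd.DataFrame(
        {
            "task": cue,
            "hue": [a.hue for a in firsts],
            "slant": [a.slant for a in firsts],
            "relief1": [a.relief for a in firsts],
            "roughness1": [a.roughness for a in firsts],
            "relief2": [b.relief for b in seconds],
            "roughness2": [b.roughness for b in seconds],
        }
    )
    df = pd.concat([base] * n_obs, ignore_index=True)
    df.insert(0, "observer", np.repeat(observers, n_tr))
    df["chosen"] = chosen.ravel()
    return df


@dataclass(frozen=True)
class SyntheticDataset:
    """A complete simulated study: responses plus the ground truth record."""

    params: ObserverParams
    matching: pd.DataFrame
    gloss_choices: pd.DataFrame
    coverage_choices: pd.DataFrame
    trial_seeds: dict
    provenance: dict

    def ground_truth(self) -> dict:
        gt = asdict(self.params)
        gt["hue_W_offsets"] = dict(self.params.hue_W_offsets)
        return gt


def make_dataset(
    params: ObserverParams,
    hues,
    slants,
    reliefs,
    roughnesses,
    grid_by_hue: Mapping[float, MatchingGrid],
    n_matching_observers: int = 9,
    n_choice_observers: int = 4,
) -> SyntheticDataset:
    """Simulate the full study design for the given level sets.

    Matching responses cover the full hue x relief x roughness x slant
    crossing; choice responses cover one paired-comparison block per
    hue x slant (all ordered pairs of relief x roughness conditions).
    """
    from .design import build_pc_trials, enumerate_conditions

    hues, slants = list(hues), list(slants)
    ss = np.random.SeedSequence(params.seed)
    match_ss, gloss_ss, cov_ss, trial_ss = ss.spawn(4)
    match_rng = np.random.default_rng(match_ss)
    gloss_rng = np.random.default_rng(gloss_ss)
    cov_rng = np.random.default_rng(cov_ss)

    match_obs = tuple(f"m{i + 1}" for i in range(n_matching_observers))
    choice_obs = tuple(f"c{i + 1}" for i in range(n_choice_observers))

    matching_frames = []
    gloss_frames = []
    cov_frames = []
    trial_seeds = {}
    trial_seed_values = trial_ss.generate_state(len(list(hues)) * len(list(slants)))
    k = 0
    for hue in hues:
        conds_all = enumerate_conditions([hue], reliefs, roughnesses, slants)
        matching_frames.append(
            simulate_matching(params, conds_all, grid_by_hue[hue],
                              observers=match_obs, rng=match_rng)
        )
        for slant in slants:
            block = [c for c in conds_all if c.slant == slant]
            seed = int(trial_seed_values[k] % (2**31)); k += 1
            trials = build_pc_trials(block, seed=seed)
            trial_seeds[(float(hue), float(slant))] = seed
            gloss_frames.append(
                simulate_choices(params, trials, "gloss",
                                 observers=choice_obs, rng=gloss_rng)
            )
            cov_frames.append(
                simulate_choices(params, trials, "coverage",
                                 observers=choice_obs, rng=cov_rng)
            )
    return SyntheticDataset(
        params=params,
        matching=pd.concat(matching_frames, ignore_index=True),
        gloss_choices=pd.concat(gloss_frames, ignore_index=True),
        coverage_choices=pd.concat(cov_frames, ignore_index=True),
        trial_seeds=trial_seeds,
        provenance={"seed": params.seed},
    )
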