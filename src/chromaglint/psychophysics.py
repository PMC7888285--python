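"""From raw responses to perceptual estimates.

Three analyses: per-condition mean matched lightness/chroma/saturation from
the asymmetric-matching task; win-probability estimates of perceived gloss
and specular coverage from the paired-comparison tasks; and a balanced
fully-within-subjects repeated-measures ANOVA in which every effect is
tested against its interaction with subjects (no sphericity correction).

Response tables are plain pandas DataFrames:

matching responses
    columns ``observer, hue, relief, roughness, slant, L, C``
choice responses
    columns ``observer, task, hue, slant, relief1, roughness1,
    relief2, roughness2, chosen`` with ``chosen`` in {1, 2}
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .colorimetry import saturation
from .design import MatchingGrid

__all__ = [
    "aggregate_matches",
    "pc_probability",
    "rm_anova",
    "validate_matches",
]

CONDITION_KEYS = ["hue", "relief", "roughness", "slant"]


def validate_matches(responses: pd.DataFrame, grid: MatchingGrid) -> None:
    """Check every matched (L, C) setting is a cell of the session grid."""
    L_ok = np.isclose(
        responses["L"].to_numpy()[:, None], grid.lightness_levels[None, :]
    ).any(axis=1)
    C_ok = np.isclose(
        responses["C"].to_numpy()[:, None], grid.chroma_levels[None, :]
    ).any(axis=1)
    bad = ~(L_ok & C_ok)
    if bad.any():
        rows = responses.index[bad].tolist()[:5]
        raise ValueError(f"responses not on the matching grid at rows {rows}")


def aggregate_matches(
    responses: pd.DataFrame,
    rule: str = "mean-of-ratios",
    grid: MatchingGrid | None = None,
) -> pd.DataFrame:
    """Per (observer, condition) mean matched L*, C* and saturation.

    ``rule`` controls the saturation aggregate: ``"mean-of-ratios"``
    (default) averages per-trial C/L; ``"ratio-of-means"`` divides the mean
    chroma by the mean lightness.  Conditions with no responses are absent
    from the table (missingness is explicit, never a silent zero).
    """
    if rule not in ("mean-of-ratios", "ratio-of-means"):
        raise ValueError(f"unknown saturation rule: {rule!r}")
    if grid is not None:
        validate_matches(responses, grid)
    df = responses.copy()
    df["S"] = saturation(df["C"].to_numpy(), df["L"].to_numpy())
    g = df.groupby(["observer"] + CONDITION_KEYS, sort=True)
    out = g.agg(
        mean_L=("L", "mean"), mean_C=("C", "mean"), mean_S=("S", "mean"),
        n_trials=("L", "size"),
    ).reset_index()
    if rule == "ratio-of-means":
        out["mean_S"] = saturation(out["mean_C"].to_numpy(), out["mean_L"].to_numpy())
    return out


def pc_probability(choices: pd.DataFrame, trials: pd.DataFrame | None = None) -> pd.DataFrame:
    """Win probabilities from paired-comparison choices.

    For every condition in each (observer, task, hue, slant) block:
    p = times chosen / times presented, with presentations counted from the
    trial structure (both sides of every pair), not from wins.  If
    ``trials`` is given (columns ``hue, slant, relief1, roughness1,
    relief2, roughness2``), presentation counts come from the full trial
    list so conditions that never won — or whose trials are missing from
    ``choices`` — are still denominated correctly; conditions never
    presented are absent (missing, not zero).
    """
    req = {"observer", "task", "hue", "slant",
           "relief1", "roughness1", "relief2", "roughness2", "chosen"}
    missing = req - set(choices.columns)
    if missing:
        raise ValueError(f"choice table missing columns: {sorted(missing)}")
    if not choices["chosen"].isin([1, 2]).all():
        raise ValueError("chosen must be 1 (first/left) or 2 (second/right)")

    def _side(df: pd.DataFrame, side: int) -> pd.DataFrame:
        out = df[["observer", "task", "hue", "slant",
                  f"relief{side}", f"roughness{side}"]].copy()
        out.columns = ["observer", "task", "hue", "slant", "relief", "roughness"]
        return out

    block_keys = ["observer", "task", "hue", "slant", "relief", "roughness"]
    appearances = pd.concat([_side(choices, 1), _side(choices, 2)],
                            ignore_index=True)
    pres = appearances.groupby(block_keys, sort=True).size().rename("n_presentations")

    winners = pd.concat(
        [
            _side(choices[choices["chosen"] == 1], 1),
            _side(choices[choices["chosen"] == 2], 2),
        ],
        ignore_index=True,
    )
    wins = winners.groupby(block_keys, sort=True).size().rename("wins")

    if trials is not None:
        # presentation counts per condition from the designed trial list,
        # replicated for every (observer, task) block present in the choices
        tpres = pd.concat(
            [
                trials[["hue", "slant", f"relief{s}", f"roughness{s}"]].rename(
                    columns={f"relief{s}": "relief", f"roughness{s}": "roughness"}
                )
                for s in (1, 2)
            ],
            ignore_index=True,
        ).groupby(["hue", "slant", "relief", "roughness"], sort=True).size()
        obs_blocks = choices[["observer", "task"]].drop_duplicates()
        full = []
        for _, (obs, task) in obs_blocks.iterrows():
            t = tpres.reset_index()
            t.insert(0, "task", task)
            t.insert(0, "observer", obs)
            full.append(t)
        pres = (
            pd.concat(full, ignore_index=True)
            .set_index(block_keys)[0]
            .rename("n_presentations")
        )

    out = pres.to_frame()
    out["wins"] = wins.reindex(pres.index).fillna(0).astype(int)
    out["p"] = out["wins"] / out["n_presentations"]
    out = out.reset_index()
    return out[["observer", "task", "hue", "slant", "relief", "roughness",
                "p", "n_presentations"]]


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA (balanced, fully within subjects).
# ---------------------------------------------------------------------------

def _effect_ss(data: np.ndarray, centered_axes: tuple[int, ...]) -> float:
    """Sum of squares of one term of the factorial decomposition.

    ``data`` has one axis per design factor (subject included).  The term's
    estimate applies mean-centering along ``centered_axes`` and plain
    averaging along every other axis; its SS is the squared norm of that
    estimate scaled by the count of observations each estimate represents.
    """
    t = data.astype(float)
    mult = 1
    for ax in range(data.ndim):
        if ax in centered_axes:
            t = t - t.mean(axis=ax, keepdims=True)
        else:
            t = t.mean(axis=ax, keepdims=True)
            mult *= data.shape[ax]
    return float(np.sum(t**2) * mult)


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: Sequence[str],
    subject: str = "observer",
) -> pd.DataFrame:
    """Balanced within-subjects ANOVA over fully crossed factors.

    Each main effect and interaction among ``within`` factors is tested
    against its own interaction with subjects, the classical univariate
    partitioning with no sphericity correction.  Replicated cells are first
    averaged within subject; missing cells raise (no imputation).

    Returns a table with columns ``effect, F, df1, df2, p``.
    """
    within = list(within)
    if len(within) == 0:
        raise ValueError("need at least one within factor")
    cols = [subject] + within
    cell = data.groupby(cols, sort=True)[dv].mean()
    levels = [cell.index.get_level_values(c).unique() for c in cols]
    n_subj = len(levels[0])
    if n_subj < 2:
        raise ValueError("repeated-measures ANOVA needs at least 2 subjects")
    expected = np.prod([len(lv) for lv in levels])
    if len(cell) != expected:
        full = pd.MultiIndex.from_product(levels, names=cols)
        absent = full.difference(cell.index)
        raise ValueError(
            f"design not fully crossed: {len(absent)} missing cells, "
            f"first {list(absent[:3])}"
        )
    cube = cell.to_numpy().reshape([len(lv) for lv in levels])

    subj_ax = 0
    factor_axes = {f: i + 1 for i, f in enumerate(within)}
    rows = []
    for k in range(1, len(within) + 1):
        for combo in itertools.combinations(within, k):
            axes = tuple(factor_axes[f] for f in combo)
            ss_eff = _effect_ss(cube, axes)
            ss_err = _effect_ss(cube, axes + (subj_ax,))
            df1 = int(np.prod([cube.shape[a] - 1 for a in axes]))
            df2 = df1 * (n_subj - 1)
            ms_eff = ss_eff / df1
            ms_err = ss_err / df2
            F = ms_eff / ms_err if ms_err > 0 else np.inf
            p = float(stats.f.sf(F, df1, df2))
            rows.append((":".join(combo), F, df1, df2, p))
    return pd.DataFrame(rows, columns=["effect", "F", "df1", "df2", "p"])
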