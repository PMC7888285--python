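"""Stimulus condition enumeration, the asymmetric-matching grid, and trial lists.

The experiments cross three hue angles lying on the sRGB primary axes with
mesoscopic relief height (displacement-map scale), Beckmann specular roughness
and surface slant relative to the overhead light.  The matching task offers a
22 x 22 lightness x chroma lattice of LCH settings at the target hue; the
paired-comparison tasks present every ordered pair of conditions within a
hue x slant block.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .colorimetry import GamutError, LCHColor, WhitePoint, in_gamut

__all__ = [
    "SurfaceCondition",
    "MatchingGrid",
    "TrialList",
    "HUES",
    "RELIEFS",
    "ROUGHNESS_MATCHING",
    "ROUGHNESS_PC",
    "SLANTS",
    "enumerate_conditions",
    "build_matching_grid",
    "build_pc_trials",
    "conditions_to_frame",
]

#: Hue angles (degrees) of the red, green and blue stimulus sets.
HUES = (39.999, 136.016, 306.285)
#: Relief heights: displacement scale as a fraction of tile width.
RELIEFS = (0.025, 0.050, 0.100, 0.200)
#: Beckmann roughness levels of the matching experiment.
ROUGHNESS_MATCHING = (0.010, 0.100, 0.200, 0.300, 0.400)
#: Roughness levels of the paired-comparison experiments (0.200 dropped).
ROUGHNESS_PC = (0.010, 0.100, 0.300, 0.400)
#: Surface slants (degrees) about the horizontal axis.
SLANTS = (15.0, 30.0, 45.0)

#: Matching-grid ranges: lightness 18.750..97.500, chroma 22.500..101.250, step 3.75.
GRID_L_RANGE = (18.750, 97.500)
GRID_C_RANGE = (22.500, 101.250)
GRID_STEP = 3.75


@dataclass(frozen=True, order=True)
class SurfaceCondition:
    """One stimulus cell: (hue angle, relief height, roughness, slant)."""

    hue: float
    relief: float
    roughness: float
    slant: float

    def key(self) -> tuple[float, float, float, float]:
        return (self.hue, self.relief, self.roughness, self.slant)


def enumerate_conditions(hues, reliefs, roughnesses, slants) -> list[SurfaceCondition]:
    """Cartesian product of the level sets in lexicographic (hue, relief,
    roughness, slant) order; empty if any level set is empty."""
    return [
        SurfaceCondition(float(h), float(re), float(ro), float(s))
        for h, re, ro, s in itertools.product(hues, reliefs, roughnesses, slants)
    ]


def conditions_to_frame(conditions) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.hue, c.relief, c.roughness, c.slant) for c in conditions],
        columns=["hue", "relief", "roughness", "slant"],
    )


def _levels(lo: float, hi: float, step: float) -> np.ndarray:
    if step <= 0:
        raise ValueError("step must be positive")
    if hi < lo:
        raise ValueError(f"range inverted: [{lo}, {hi}]")
    n_float = (hi - lo) / step
    n = int(round(n_float))
    if abs(n_float - n) > 1e-9:
        raise ValueError(
            f"range [{lo}, {hi}] is not divisible by step {step}"
        )
    return lo + step * np.arange(n + 1)


@dataclass(frozen=True)
class MatchingGrid:
    """The lattice of LCH settings available in the matching task.

    Indexing convention: ``cell(i, j)`` takes row i as the chroma index and
    column j as the lightness index, both axes ascending (chroma along
    columns of the on-screen matrix, lightness along rows).

    When built in clip-tolerant mode, ``out_of_gamut[i, j]`` marks cells
    whose sRGB conversion leaves [0, 1] (an 8-bit display clips them) and
    ``max_excursion`` records the largest channel overshoot on the lattice.
    """

    hue: float
    lightness_levels: np.ndarray
    chroma_levels: np.ndarray
    white_point: str = "d65"
    out_of_gamut: np.ndarray | None = None
    max_excursion: float = 0.0

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.chroma_levels), len(self.lightness_levels))

    def cell(self, i: int, j: int) -> LCHColor:
        return LCHColor(
            float(self.lightness_levels[j]), float(self.chroma_levels[i]), self.hue
        )

    def to_json_dict(self) -> dict:
        return {
            "hue": self.hue,
            "lightness_levels": [float(v) for v in self.lightness_levels],
            "chroma_levels": [float(v) for v in self.chroma_levels],
            "white_point": self.white_point,
        }


def build_matching_grid(
    hue: float,
    L_min: float = GRID_L_RANGE[0],
    L_max: float = GRID_L_RANGE[1],
    C_min: float = GRID_C_RANGE[0],
    C_max: float = GRID_C_RANGE[1],
    step: float = GRID_STEP,
    white_point: WhitePoint = "d65",
    validate_gamut: bool | str = True,
) -> MatchingGrid:
    """Build the matching grid and check every cell against the sRGB gamut.

    ``validate_gamut`` modes:

    ``True`` (strict, default)
        raise :class:`GamutError` listing the offending (L*, C*) cells if
        any lattice point falls outside sRGB;
    ``"clip"``
        tolerate out-of-gamut cells, recording a per-cell mask and the
        worst channel excursion on the returned grid — this is what an
        8-bit sRGB display does with such settings;
    ``False``
        skip the check entirely.
    """
    Ls = _levels(L_min, L_max, step)
    Cs = _levels(C_min, C_max, step)
    oog = None
    excursion = 0.0
    if validate_gamut:
        from .colorimetry import lch_to_rgb_array

        LL, CC = np.meshgrid(Ls, Cs)
        rgb = lch_to_rgb_array(LL.ravel(), CC.ravel(), hue, white_point)
        over = np.maximum(rgb - 1.0, -rgb).max(axis=-1)
        ok = over <= 1e-9
        if not ok.all():
            if validate_gamut == "clip":
                oog = (~ok).reshape(len(Cs), len(Ls))
                excursion = float(over.max())
            else:
                bad = [
                    (float(l), float(c))
                    for l, c, o in zip(LL.ravel(), CC.ravel(), ok)
                    if not o
                ]
                raise GamutError(
                    f"{len(bad)} matching-grid cells out of gamut at hue {hue}: "
                    f"first offenders {bad[:5]}",
                    channels=(np.nan, np.nan, np.nan),
                )
    return MatchingGrid(
        hue=float(hue),
        lightness_levels=Ls,
        chroma_levels=Cs,
        white_point=white_point,
        out_of_gamut=oog,
        max_excursion=excursion,
    )


@dataclass(frozen=True)
class TrialList:
    """An ordered trial sequence with the seed that produced its shuffle.

    For the paired-comparison design each trial is an ordered pair of
    distinct conditions sharing hue and slant; pair order encodes left/right
    screen position.
    """

    design: str
    trials: tuple
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t_id, tr in enumerate(self.trials):
            if self.design == "paired-comparison":
                a, b = tr
                rows.append(
                    (
                        t_id, self.design, a.hue, a.slant,
                        a.relief, a.roughness, b.relief, b.roughness,
                    )
                )
            else:
                rows.append(
                    (t_id, self.design, tr.hue, tr.slant, tr.relief, tr.roughness,
                     np.nan, np.nan)
                )
        return pd.DataFrame(
            rows,
            columns=[
                "trial_id", "design", "hue", "slant",
                "relief1", "roughness1", "relief2", "roughness2",
            ],
        )


def build_pc_trials(conditions, seed: int) -> TrialList:
    """All ordered pairs of distinct conditions, shuffled reproducibly.

    Requires >= 2 conditions all sharing hue and slant (one experimental
    block); yields n(n-1) trials with each condition appearing 2(n-1) times,
    exactly balanced between first (left) and second (right) position.
    """
    conditions = list(conditions)
    if len(conditions) < 2:
        raise ValueError("paired comparisons need at least two conditions")
    hues = {c.hue for c in conditions}
    slants = {c.slant for c in conditions}
    if len(hues) > 1 or len(slants) > 1:
        raise ValueError(
            f"paired-comparison block must share hue and slant, got hues={sorted(hues)}, "
            f"slants={sorted(slants)}"
        )
    pairs = [
        (a, b) for a, b in itertools.product(conditions, repeat=2) if a != b
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    shuffled = tuple(pairs[k] for k in order)
    return TrialList(design="paired-comparison", trials=shuffled, seed=int(seed))


def build_matching_trials(conditions, seed: int) -> TrialList:
    """One matching trial per condition, shuffled reproducibly (one block)."""
    conditions = list(conditions)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(conditions))
    return TrialList(
        design="matching",
        trials=tuple(conditions[k] for k in order),
        seed=int(seed),
    )
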