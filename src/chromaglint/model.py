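"""Weighted linear combination of perceived gloss and specular coverage.

The model predicts a color percept (saturation or lightness) from the two
paired-comparison probability scales:

    P' = W * P_coverage + (1 - W) * (1 - P_gloss)

W = 1 puts all weight on perceived coverage, W = 0 all weight on perceived
gloss (via its complement).  W is estimated by sweeping a grid from -1 to 1
(default step 0.01) and keeping the weight whose model output correlates
most strongly (largest r^2) with the percepts; the signed Pearson r is
reported, since saturation correlates negatively and lightness positively
with the same machinery.  Correlation p values use the standard t transform
with n - 2 degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelFit",
    "SweepResult",
    "predict",
    "sweep_weight",
    "forced_weight_fit",
    "pooled_fit",
]

_VAR_TOL = 1e-24


@dataclass(frozen=True)
class ModelFit:
    """One correlation between model output and percepts at a fixed weight."""

    W: float
    r: float
    p: float
    n: int
    pooling: str = "per-block"
    dv: str = "saturation"

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("a reported fit needs at least 3 points")
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"invalid correlation {self.r}")


@dataclass(frozen=True)
class SweepResult:
    """The full (W, r) sweep grid and the best-fitting weight.

    ``best`` maximises r^2 on the grid; exact ties break toward the smaller
    |W| (then toward the negative weight) for deterministic output.
    """

    weights: np.ndarray
    correlations: np.ndarray
    best: ModelFit
    tie_note: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"W": self.weights, "r": self.correlations})


def predict(W: float, p_gloss, p_coverage):
    """Model output W * p_coverage + (1 - W) * (1 - p_gloss), elementwise."""
    p_gloss = np.asarray(p_gloss, float)
    p_coverage = np.asarray(p_coverage, float)
    if not (np.all(np.isfinite(p_gloss)) and np.all(np.isfinite(p_coverage))):
        raise ValueError("cue probabilities must be finite")
    return W * p_coverage + (1.0 - W) * (1.0 - p_gloss)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided p value (t transform, n-2 dfs)."""
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return r, p


def _check_inputs(percepts, p_gloss, p_coverage):
    percepts = np.asarray(percepts, float)
    p_gloss = np.asarray(p_gloss, float)
    p_coverage = np.asarray(p_coverage, float)
    if not percepts.shape == p_gloss.shape == p_coverage.shape:
        raise ValueError("percepts and cue arrays must be aligned")
    if percepts.size < 3:
        raise ValueError("need at least 3 aligned conditions")
    if np.var(percepts) <= _VAR_TOL:
        raise ValueError("percepts have zero variance; nothing to correlate")
    return percepts, p_gloss, p_coverage


def weight_grid(step: float = 0.01) -> np.ndarray:
    """Inclusive arithmetic grid from -1 to 1; 201 points at the 0.01 step."""
    n = int(round(2.0 / step))
    return np.linspace(-1.0, 1.0, n + 1)


def sweep_weight(
    percepts,
    p_gloss,
    p_coverage,
    step: float = 0.01,
    pooling: str = "per-block",
    dv: str = "saturation",
) -> SweepResult:
    """Grid-sweep W in [-1, 1] and keep the weight maximising r^2.

    Grid points where the model output is (numerically) constant are
    excluded with a warning; if every point is excluded the sweep fails.
    """
    percepts, p_gloss, p_coverage = _check_inputs(percepts, p_gloss, p_coverage)
    Ws = weight_grid(step)
    rs = np.full_like(Ws, np.nan)
    for i, W in enumerate(Ws):
        out = predict(W, p_gloss, p_coverage)
        if np.var(out) <= _VAR_TOL:
            continue
        rs[i] = np.corrcoef(out, percepts)[0, 1]
    valid = np.isfinite(rs)
    n_excluded = int((~valid).sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} sweep weights excluded (constant model output)",
            stacklevel=2,
        )
    if not valid.any():
        raise ValueError("model output constant at every sweep weight")
    r2 = np.where(valid, rs**2, -np.inf)
    # lexicographic tie-break: max r^2, then min |W|, then the smaller W
    order = np.lexsort((Ws, np.abs(Ws), -r2))
    k = order[0]
    ties = int(np.sum(np.isclose(r2, r2[k], rtol=0, atol=0)))
    r, p = _pearson(predict(Ws[k], p_gloss, p_coverage), percepts)
    best = ModelFit(W=float(Ws[k]), r=r, p=p, n=len(percepts),
                    pooling=pooling, dv=dv)
    note = f"{ties - 1} exact ties broken toward smaller |W|" if ties > 1 else ""
    return SweepResult(weights=Ws, correlations=rs, best=best, tie_note=note)


def forced_weight_fit(
    W_fixed: float,
    percepts,
    p_gloss,
    p_coverage,
    pooling: str = "per-block",
    dv: str = "saturation",
) -> ModelFit:
    """Correlation at one fixed weight (e.g. the pooled-data optimum)."""
    percepts, p_gloss, p_coverage = _check_inputs(percepts, p_gloss, p_coverage)
    out = predict(W_fixed, p_gloss, p_coverage)
    if np.var(out) <= _VAR_TOL:
        raise ValueError(f"model output constant at W = {W_fixed}")
    r, p = _pearson(out, percepts)
    return ModelFit(W=float(W_fixed), r=r, p=p, n=len(percepts),
                    pooling=pooling, dv=dv)


def pooled_fit(
    blocks: pd.DataFrame,
    percept_col: str,
    step: float = 0.01,
    dv: str = "saturation",
) -> tuple[SweepResult, float]:
    """One sweep over points concatenated across hue x slant blocks.

    ``blocks`` needs columns ``p_gloss``, ``p_coverage`` and ``percept_col``.
    Also returns the gloss-coverage inter-correlation on the pooled points.
    """
    req = {"p_gloss", "p_coverage", percept_col}
    if not req <= set(blocks.columns):
        raise ValueError(f"pooled table missing columns: {sorted(req - set(blocks.columns))}")
    sweep = sweep_weight(
        blocks[percept_col].to_numpy(),
        blocks["p_gloss"].to_numpy(),
        blocks["p_coverage"].to_numpy(),
        step=step,
        pooling="pooled",
        dv=dv,
    )
    inter_r = float(
        np.corrcoef(blocks["p_gloss"].to_numpy(), blocks["p_coverage"].to_numpy())[0, 1]
    )
    return sweep, inter_r
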