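"""Construction and use of DLQI TTO value sets.

A value set maps every combination of DLQI severity levels to a predicted TTO
utility: a trader intercept plus, for each item and level, a cumulative
(non-positive) partial effect. Societal ("adjusted") variants re-introduce the
non-trader subpopulation, who value every state at 1, through the weighted
average

    y_adj = w * 1 + (1 - w) * y_trader

which is equivalent to mapping the intercept to w + (1 - w) * intercept and
scaling every partial effect by (1 - w).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import DLQIState, DummyDesign, N_ITEMS, design_matrix

__all__ = [
    "ValueSet",
    "build_value_set",
    "average_models",
    "cumulate",
    "adjust_for_nontraders",
    "predict_utility",
    "enumerate_levels",
    "enumerate_distribution",
    "concavity_summary",
    "lambda_combine",
]


@dataclass(frozen=True)
class ValueSet:
    """Cumulative partial effects (items x levels 0..3) plus an intercept.

    `cumulative[i, l]` is the total disutility of item i+1 at severity level l
    (column 0 is zero by construction). `w` is the non-trader weight already
    applied; `w = 0` denotes the trader-only variant.
    """

    intercept: float
    cumulative: np.ndarray  # shape (10, 4), non-positive, non-increasing in level
    w: float = 0.0
    provenance: str = ""

    def __post_init__(self) -> None:
        cum = np.asarray(self.cumulative, dtype=float)
        if cum.shape != (N_ITEMS, 4):
            raise ValueError("cumulative must have shape (10, 4)")
        if not np.allclose(cum[:, 0], 0.0):
            raise ValueError("level-0 column must be zero")
        if np.any(cum > 1e-12):
            raise ValueError("cumulative effects must be non-positive")
        if np.any(np.diff(cum, axis=1) > 1e-12):
            raise ValueError("cumulative effects must be non-increasing in level")
        object.__setattr__(self, "cumulative", cum)

    def predict(self, levels: np.ndarray) -> np.ndarray:
        """Predicted utilities for an (n, 10) array of severity levels, clipped to [0, 1]."""
        levels = np.atleast_2d(np.asarray(levels, dtype=np.intp))
        u = self.intercept + sum(self.cumulative[i][levels[:, i]] for i in range(N_ITEMS))
        return np.clip(u, 0.0, 1.0)

    def to_frame(self, digits: int | None = None) -> pd.DataFrame:
        """Published-table layout: one row per item, columns Level 1..3, plus intercept."""
        cum = self.cumulative[:, 1:]
        if digits is not None:
            cum = _round_half_up(cum, digits)
        df = pd.DataFrame(cum, columns=["level_1", "level_2", "level_3"],
                          index=[f"Q{i}" for i in range(1, N_ITEMS + 1)])
        df.loc["Intercept"] = [
            _round_half_up(np.array(self.intercept), digits) if digits is not None else self.intercept
        ] + [np.nan, np.nan]
        return df

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "cumulative": self.cumulative.tolist(),
            "w": self.w,
            "provenance": self.provenance,
        }


def _round_half_up(x: np.ndarray, digits: int):
    """Round half away from zero, matching how published tables display values."""
    factor = 10.0**digits
    return np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor


def build_value_set(
    intercept: float,
    incremental: dict[tuple[int, int], float],
    design: DummyDesign,
    w: float = 0.0,
    provenance: str = "",
) -> ValueSet:
    """Assemble a ValueSet from incremental per-dummy effects (thermometer semantics)."""
    return ValueSet(intercept, cumulate(incremental, design), w=w, provenance=provenance)


def average_models(fits: list) -> tuple[float, dict[tuple[int, int], float]]:
    """Element-wise mean of intercepts and incremental coefficients across fits.

    All fits must be on the utility scale and share the same active dummy set.
    """
    if not fits:
        raise ValueError("need at least one fit")
    keys = set(fits[0].beta)
    for f in fits:
        if f.scale != "utility":
            raise ValueError(f"fit for family {f.family!r} is not on the utility scale")
        if set(f.beta) != keys:
            raise ValueError("fits have mismatched active dummy sets")
    alpha = float(np.mean([f.alpha for f in fits]))
    incr = {k: float(np.mean([f.beta[k] for f in fits])) for k in keys}
    return alpha, incr


def cumulate(incremental: dict[tuple[int, int], float], design: DummyDesign) -> np.ndarray:
    """Cumulative effects per item x level: sums of active incremental effects
    at levels <= l; inactive severity steps contribute 0 (merged with the
    previous level)."""
    active = set(design.active)
    unknown = set(incremental) - active
    if unknown:
        raise ValueError(f"incremental effects for inactive dummies: {sorted(unknown)}")
    cum = np.zeros((N_ITEMS, 4))
    for (i, l), v in incremental.items():
        cum[i - 1, l:] += v
    return cum


def adjust_for_nontraders(vs: ValueSet, w: float) -> ValueSet:
    """Apply the non-trader weighting: intercept -> w + (1-w) * intercept,
    effects scaled by (1 - w)."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must be in [0, 1]")
    return replace(
        vs,
        intercept=w + (1.0 - w) * vs.intercept,
        cumulative=(1.0 - w) * vs.cumulative,
        w=w,
    )


def predict_utility(state: DLQIState | np.ndarray, vs: ValueSet) -> float:
    """Predicted TTO utility for one state (clipped to [0, 1])."""
    levels = np.asarray(state.levels if isinstance(state, DLQIState) else state)
    return float(vs.predict(levels[None, :])[0])


def enumerate_levels() -> np.ndarray:
    """All 4^10 = 1,048,576 severity-level combinations as an (n, 10) int8 array."""
    n = 4**N_ITEMS
    idx = np.arange(n)
    out = np.empty((n, N_ITEMS), dtype=np.int8)
    for i in range(N_ITEMS):
        out[:, N_ITEMS - 1 - i] = (idx >> (2 * i)) & 3
    return out


def enumerate_distribution(
    vs: ValueSet,
    total_score: int | None = None,
    percentiles: tuple[float, ...] = (5, 25, 50, 75, 95),
) -> dict:
    """Distribution of predicted utilities over all (equally weighted) level
    combinations, optionally restricted to one DLQI total score.

    Percentiles use linear interpolation between order statistics.
    """
    if total_score is not None and not 0 <= total_score <= 30:
        raise ValueError("total_score must be in 0..30")
    levels = enumerate_levels()
    if total_score is not None:
        levels = levels[levels.sum(axis=1) == total_score]
    u = vs.predict(levels)
    pcts = np.percentile(u, percentiles)
    out = {"count": int(len(u)), "percentiles": dict(zip(percentiles, map(float, pcts)))}
    out["iqr"] = float(np.percentile(u, 75) - np.percentile(u, 25))
    out["p95_minus_p5"] = float(np.percentile(u, 95) - np.percentile(u, 5))
    out["mean"] = float(u.mean())
    return out


def concavity_summary(vs: ValueSet) -> pd.DataFrame:
    """Mean predicted utility per DLQI total score (equally weighted
    combinations) with second differences; predominantly non-positive second
    differences indicate increasing marginal disutility."""
    levels = enumerate_levels()
    scores = levels.sum(axis=1)
    u = vs.predict(levels)
    mean_u = np.array([u[scores == s].mean() for s in range(31)])
    second = np.full(31, np.nan)
    second[1:-1] = np.diff(mean_u, 2)
    return pd.DataFrame({"total_score": np.arange(31), "mean_utility": mean_u,
                         "second_difference": second})


def lambda_combine(
    z_of_levels,
    design: DummyDesign,
    lambdas: np.ndarray,
) -> tuple[float, dict[tuple[int, int], float]]:
    """Combine a relative-disutility predictor with a scale-range distribution.

    `z_of_levels(levels)` returns the predicted relative disutility z for a
    10-vector of severity levels; the utility prediction for a state is the
    mean over `lambdas` of clip(1 - lambda * z, 0, 1). Returns the implied
    utility-scale intercept (prediction at the all-zero state) and incremental
    per-dummy effects (finite differences along single-item severity paths), so
    two-part scalable fits are directly comparable with one-part families.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size == 0:
        raise ValueError("empty lambda sample")

    def predict(levels: np.ndarray) -> float:
        z = z_of_levels(np.asarray(levels, dtype=np.int8))
        return float(np.mean(np.clip(1.0 - lambdas * z, 0.0, 1.0)))

    base = np.zeros(design.n_items, dtype=np.int8)
    alpha_y = predict(base)
    incr: dict[tuple[int, int], float] = {}
    for i in range(1, design.n_items + 1):
        item_levels = sorted(l for (j, l) in design.active if j == i)
        prev_pred, prev_level = alpha_y, 0
        for l in item_levels:
            lv = base.copy()
            lv[i - 1] = l
            p = predict(lv)
            incr[(i, l)] = p - prev_pred
            prev_pred, prev_level = p, l
    return alpha_y, incr
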