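"""Respondent screening: TTO-to-utility conversion and the exclusion cascade.

Each respondent valued five health states, always including the 'worst
possible' (all level 3) state. The cascade classifies every respondent into
exactly one category, in this order:

1. ``non_trader`` -- utility 1 on all five states (kept aside and
   re-introduced when the societal value set is built);
2. ``excluded_identical`` -- the same valuation (< 1) on all five states;
3. ``excluded_time_or_inconsistent`` -- too-fast responding (shortest response
   time <= thr_min AND median response time <= thr_med) OR an inconsistency
   (some other state valued more than |thr_diff| below the worst state);
4. ``excluded_uninformative`` -- exactly two distinct values used, with the
   larger assigned to the worst state;
5. ``trader`` -- everyone else; only traders enter the regression stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScreeningConfig",
    "ScreeningOutcome",
    "CATEGORIES",
    "tto_to_utility",
    "classify_respondent",
    "screen_sample",
    "threshold_grid",
]

CATEGORIES = (
    "trader",
    "non_trader",
    "excluded_identical",
    "excluded_time_or_inconsistent",
    "excluded_uninformative",
)


@dataclass(frozen=True)
class ScreeningConfig:
    """Exclusion thresholds: response-time floor/median (seconds) and the
    minimum tolerated utility difference vs the worst state (non-positive)."""

    thr_min: float = 5.0
    thr_med: float = 10.0
    thr_diff: float = -0.10

    def __post_init__(self) -> None:
        if self.thr_min > self.thr_med:
            raise ValueError("thr_min must be <= thr_med")
        if self.thr_diff > 0:
            raise ValueError("thr_diff must be <= 0")


def tto_to_utility(t) -> np.ndarray | float:
    """Utility y = 1 - t/10 for years traded t on the half-year grid [0, 10]."""
    t_arr = np.asarray(t, dtype=float)
    if np.any((t_arr < 0) | (t_arr > 10)):
        raise ValueError("t must lie in [0, 10]")
    if not np.allclose(t_arr * 2.0, np.round(t_arr * 2.0), atol=1e-9):
        raise ValueError("t must be on the half-year grid {0, 0.5, ..., 10}")
    y = 1.0 - t_arr / 10.0
    return float(y) if np.isscalar(t) else y


def _grid_int(y: np.ndarray) -> np.ndarray:
    """Utilities as exact grid integers (y * 20) to avoid float comparisons."""
    g = np.round(np.asarray(y, dtype=float) * 20.0).astype(int)
    return g


def classify_respondent(
    valuations: np.ndarray,
    response_times: np.ndarray,
    worst_index: int,
    config: ScreeningConfig | None = None,
) -> str:
    """Apply the exclusion cascade to one respondent's five valuations."""
    config = config or ScreeningConfig()
    y = np.asarray(valuations, dtype=float)
    rt = np.asarray(response_times, dtype=float)
    if y.shape != (5,) or rt.shape != (5,):
        raise ValueError("exactly five valuations and response times required")
    if not 0 <= worst_index < 5:
        raise ValueError("worst_index must identify the worst-state valuation")
    g = _grid_int(y)
    if np.all(g == 20):
        return "non_trader"
    if len(np.unique(g)) == 1:
        return "excluded_identical"
    too_fast = (np.min(rt) <= config.thr_min) and (np.median(rt) <= config.thr_med)
    others = np.delete(y, worst_index)
    inconsistent = np.min(others - y[worst_index]) < config.thr_diff - 1e-12
    if too_fast or inconsistent:
        return "excluded_time_or_inconsistent"
    uniq = np.unique(g)
    if len(uniq) == 2 and g[worst_index] == uniq.max():
        return "excluded_uninformative"
    return "trader"


@dataclass
class ScreeningOutcome:
    """Per-respondent categories plus aggregate accounting of the cascade."""

    categories: pd.Series  # respondent_id -> category
    accounting: dict[str, int]
    w_candidates: dict[str, float]

    def counts(self) -> dict[str, int]:
        c = self.categories.value_counts()
        return {k: int(c.get(k, 0)) for k in CATEGORIES}


def _worst_index_per_respondent(df: pd.DataFrame) -> pd.Series:
    qcols = [f"q{i}" for i in range(1, 11)]
    is_worst = (df[qcols] == 3).all(axis=1)
    counts = is_worst.groupby(df["respondent_id"]).sum()
    bad = counts[counts != 1]
    if len(bad):
        raise ValueError(
            f"each respondent needs exactly one worst-state valuation; offending ids: "
            f"{bad.index.tolist()[:5]} ..."
        )
    return is_worst


def screen_sample(
    dataset, config: ScreeningConfig | None = None
) -> tuple[ScreeningOutcome, pd.DataFrame]:
    """Screen a full survey dataset; returns the outcome and the trader subset.

    `dataset` is a :class:`~dlqivalue.simulate.SurveyDataset` or a long-format
    DataFrame with columns respondent_id, q1..q10, y, response_time_s.
    """
    config = config or ScreeningConfig()
    df = dataset if isinstance(dataset, pd.DataFrame) else dataset.data
    if df.empty:
        raise ValueError("empty dataset")
    is_worst = _worst_index_per_respondent(df)
    cats = {}
    for rid, sub in df.groupby("respondent_id", sort=True):
        w_ix = int(np.flatnonzero(is_worst.loc[sub.index].to_numpy())[0])
        cats[rid] = classify_respondent(
            sub["y"].to_numpy(), sub["response_time_s"].to_numpy(), w_ix, config
        )
    categories = pd.Series(cats, name="category")
    n = len(categories)
    c = categories.value_counts()
    n_nt = int(c.get("non_trader", 0))
    n_tr = int(c.get("trader", 0))
    accounting = {
        "initial_full_sample": n,
        "non_traders": n_nt,
        "initial_traders": n - n_nt,
        "excluded_identical": int(c.get("excluded_identical", 0)),
        "excluded_time_or_inconsistent": int(c.get("excluded_time_or_inconsistent", 0)),
        "excluded_uninformative": int(c.get("excluded_uninformative", 0)),
        "final_traders": n_tr,
        "valuers": n_tr + n_nt,  # respondents contributing to the value set
    }
    w_candidates = {
        "nontraders_over_initial": n_nt / n,
        "nontraders_over_valuers": n_nt / (n_nt + n_tr) if (n_nt + n_tr) else float("nan"),
    }
    traders = df[df["respondent_id"].map(categories) == "trader"].copy()
    return ScreeningOutcome(categories, accounting, w_candidates), traders


def threshold_grid(
    dataset,
    min_range=(4, 5, 6, 8, 10, 12),
    med_range=(8, 10, 12, 16, 20, 24),
    diff_range=(-0.40, -0.30, -0.20, -0.10, 0.0),
) -> pd.DataFrame:
    """Evaluate candidate threshold combinations.

    For every (thr_min, thr_med, thr_diff) with thr_min <= thr_med, reports the
    retained trader count, the share of retained traders with any remaining
    inconsistency (some state strictly below the worst state), and the mean
    within-respondent sd of valuations. Selection among candidates is left to
    the user.
    """
    df = dataset if isinstance(dataset, pd.DataFrame) else dataset.data
    rows = []
    for tmin in min_range:
        for tmed in med_range:
            if tmin > tmed:
                continue
            for tdiff in diff_range:
                cfg = ScreeningConfig(float(tmin), float(tmed), float(tdiff))
                outcome, traders = screen_sample(df, cfg)
                if len(traders):
                    is_worst = _worst_index_per_respondent(traders)
                    worst_y = traders.loc[is_worst].set_index("respondent_id")["y"]
                    rel = traders["y"] - traders["respondent_id"].map(worst_y)
                    inconsistent = (
                        rel.lt(-1e-12).groupby(traders["respondent_id"]).any().mean()
                    )
                    within_sd = traders.groupby("respondent_id")["y"].std().mean()
                else:
                    inconsistent, within_sd = float("nan"), float("nan")
                rows.append({
                    "thr_min": tmin, "thr_med": tmed, "thr_diff": tdiff,
                    "retained_n": outcome.accounting["final_traders"],
                    "non_traders": outcome.accounting["non_traders"],
                    "share_inconsistent": float(inconsistent),
                    "mean_within_sd": float(within_sd),
                })
    return pd.DataFrame(rows)
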