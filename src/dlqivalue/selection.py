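"""Sign-constrained variable selection and leave-one-block-out cross-validation.

Selection proceeds in two stages, both enforcing the theoretical prerequisite
that every severity step has a non-positive incremental effect on utility:

1. :func:`backward_eliminate` -- full-sample backward elimination on a
   reference family (default: censored): repeatedly drop the dummy with the
   largest positive coefficient until all remaining coefficients are <= 0.
2. :func:`finalize_model` -- the cross-validated tightening: repeatedly drop
   any dummy whose coefficient turns positive in any leave-one-block-out fold
   of any model family, until every retained coefficient is <= 0 in all folds
   of all families.

Dropping a dummy merges its severity step with the previous level (thermometer
coding), so the model stays interpretable at every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import DummyDesign
from .model import FAMILIES, FitResult, TTORandomIntercept, combine_scalable, fit_indices

__all__ = [
    "SelectionStep",
    "SelectionTrace",
    "CVResult",
    "backward_eliminate",
    "lobo_cv",
    "finalize_model",
]


@dataclass(frozen=True)
class SelectionStep:
    step: int
    removed: tuple[int, int]
    reason: str
    coefficient: float
    p_value: float | None = None


@dataclass
class SelectionTrace:
    stage: str  # initial / intermediate / final
    steps: list[SelectionStep] = field(default_factory=list)

    @property
    def removed(self) -> list[tuple[int, int]]:
        return [s.removed for s in self.steps]


@dataclass
class CVResult:
    """Leave-one-block-out results for one family."""

    family: str
    fold_blocks: list
    fold_fits: list[FitResult]
    coef_min: dict[tuple[int, int], float]
    coef_max: dict[tuple[int, int], float]
    pooled_pred: pd.Series  # out-of-fold predictions aligned to the data index
    indices: dict[str, float]


def _fit_family(df: pd.DataFrame, design: DummyDesign, family: str,
                n_quad: int = 15, start_params=None, compute_se: bool = False,
                maxiter: int = 300):
    model = TTORandomIntercept.from_dataframe(df, design, family=family, n_quad=n_quad)
    return model.fit(start_params=start_params, compute_se=compute_se, maxiter=maxiter)


def _utility_fit_result(results) -> FitResult:
    fr = results.as_fit_result()
    if fr.scale == "z":
        fr = combine_scalable(results)
    return fr


def _tie_key(item_level: tuple[int, int]):
    # ties broken toward the higher item index, then the higher level
    return (item_level[0], item_level[1])


def backward_eliminate(
    df: pd.DataFrame,
    design: DummyDesign,
    families: tuple[str, ...] = ("censored",),
    n_quad: int = 15,
    p_threshold: float = 0.05,
) -> tuple[DummyDesign, SelectionTrace]:
    """Stage-1 backward elimination to the maximal all-non-positive model.

    Coefficients are averaged over `families` (utility scale); the dummy with
    the largest positive average is removed and the models are refitted, until
    none is positive. The recorded p-value is the asymptotic z-test from the
    first (reference) family.
    """
    trace = SelectionTrace(stage="intermediate")
    step = 0
    warm: dict[str, np.ndarray] = {}
    while len(design):
        fits = []
        for fam in families:
            res = _fit_family(df, design, fam, n_quad=n_quad,
                              start_params=warm.get(fam), compute_se=(fam == families[0]))
            warm[fam] = res.params
            fits.append((fam, res, _utility_fit_result(res)))
        mean_coef = {
            d: float(np.mean([fr.beta[d] for _, _, fr in fits])) for d in design.active
        }
        positive = {d: c for d, c in mean_coef.items() if c > 0}
        if not positive:
            break
        worst = max(positive, key=lambda d: (positive[d], _tie_key(d)))
        ref_fr = fits[0][2]
        p_val = None
        if ref_fr.se_beta is not None and ref_fr.se_beta.get(worst):
            z = ref_fr.beta[worst] / ref_fr.se_beta[worst]
            p_val = float(2.0 * norm.sf(abs(z)))
        reason = ("positive_nonsignificant"
                  if p_val is None or p_val > p_threshold else "positive_significant")
        step += 1
        trace.steps.append(SelectionStep(step, worst, reason, positive[worst], p_val))
        warm = {fam: _drop_param(p, design, worst) for fam, p in warm.items()}
        design = design.remove(worst)
    return design, trace


def _drop_param(params: np.ndarray, design: DummyDesign, dummy: tuple[int, int]) -> np.ndarray:
    """Warm start for a design with `dummy` removed: drop its slope entry."""
    j = design.active.index(dummy)
    return np.delete(params, 1 + j)


def lobo_cv(
    df: pd.DataFrame,
    design: DummyDesign,
    family: str,
    n_quad: int = 15,
    full_start: np.ndarray | None = None,
    maxiter: int = 200,
) -> CVResult:
    """Leave-one-block-out cross-validation for one family.

    Fits on the respondents of all blocks but one, extrapolates the held-out
    block's valuations, pools out-of-fold predictions over all folds, and
    reports per-dummy coefficient ranges across folds.
    """
    blocks = np.sort(df["block_id"].unique())
    if len(blocks) < 2:
        raise ValueError("leave-one-block-out requires at least 2 blocks")
    from .design import design_matrix  # local import to avoid cycle at module load

    qcols = [f"q{i}" for i in range(1, design.n_items + 1)]
    pooled = pd.Series(index=df.index, dtype=float)
    fold_fits: list[FitResult] = []
    start = full_start
    for b in blocks:
        train = df[df["block_id"] != b]
        test = df[df["block_id"] == b]
        if train["respondent_id"].nunique() == 0 or test.empty:
            raise ValueError(f"fold {b} has no data")
        res = _fit_family(train, design, family, n_quad=n_quad,
                          start_params=start, compute_se=False, maxiter=maxiter)
        start = res.params  # warm start the next fold
        fold_fits.append(_utility_fit_result(res))
        X_test = design_matrix(test[qcols].to_numpy(dtype=np.int8), design)
        pooled.loc[test.index] = res.predict_utility(X_test)
    coef_min = {d: min(fr.beta[d] for fr in fold_fits) for d in design.active}
    coef_max = {d: max(fr.beta[d] for fr in fold_fits) for d in design.active}
    indices = fit_indices(pooled.to_numpy(), df)
    return CVResult(family, list(blocks), fold_fits, coef_min, coef_max, pooled, indices)


def finalize_model(
    df: pd.DataFrame,
    design: DummyDesign,
    families: tuple[str, ...] = FAMILIES,
    n_quad: int = 15,
    maxiter: int = 200,
) -> tuple[DummyDesign, SelectionTrace, dict[str, CVResult]]:
    """Stage-2 cross-validated selection to the final model.

    Repeatedly removes the dummy with the largest positive coefficient in any
    fold of any family (sequentially, refitting in between) until every
    retained dummy has coefficient <= 0 in all folds of all families. Returns
    the final design, the trace, and the last round of CV results per family.
    """
    trace = SelectionTrace(stage="final")
    step = 0
    cv_results: dict[str, CVResult] = {}
    warm: dict[str, np.ndarray] = {}
    while len(design):
        full_starts = {}
        for fam in families:
            res_full = _fit_family(df, design, fam, n_quad=n_quad, compute_se=False,
                                   maxiter=maxiter, start_params=warm.get(fam))
            full_starts[fam] = res_full.params
        warm = full_starts
        cv_results = {
            fam: lobo_cv(df, design, fam, n_quad=n_quad,
                         full_start=full_starts[fam], maxiter=maxiter)
            for fam in families
        }
        positive = []
        for d in design.active:
            c = max(cv_results[fam].coef_max[d] for fam in families)
            if c > 0:
                positive.append((c, _tie_key(d), d))
        if not positive:
            break
        worst_c, _, worst_d = max(positive)
        step += 1
        trace.steps.append(SelectionStep(step, worst_d, "positive_in_some_fold", worst_c))
        warm = {fam: _drop_param(p, design, worst_d) for fam, p in warm.items()}
        design = design.remove(worst_d)
    return design, trace, cv_results


def overfitting_gap(full_indices: dict[str, float], cv_indices: dict[str, float],
                    key: str = "mad_individual") -> float:
    """Degree of overfitting: cross-validated minus full-sample MAD (positive
    values mean the model predicts held-out valuations worse than it fits)."""
    return cv_indices[key] - full_indices[key]
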