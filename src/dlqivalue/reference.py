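"""Reference estimates from the published Hungarian DLQI TTO valuation survey.

The published study (online survey, 2001 respondents after quota screening,
of whom 525 traders and 317 non-traders entered the value set) reported final
13-dummy coefficient columns for its censored and scalable-censored models in
units of 0.01 utility. They are stored here so the published value set can be
reconstructed and used (e.g. for scoring DLQI states) without refitting, and
so the value-set construction chain can be exercised against known printed
output.
"""

from __future__ import annotations

import numpy as np

from .design import DummyDesign
from .model import FitResult
from .valueset import ValueSet, adjust_for_nontraders, average_models, build_value_set

__all__ = [
    "N_INITIAL_SAMPLE",
    "N_NONTRADERS",
    "N_FINAL_TRADERS",
    "REFERENCE_W",
    "FINAL_DUMMIES",
    "CENSORED_COEFFS",
    "SCALABLE_CENSORED_COEFFS",
    "R2_FINAL_MODEL",
    "R2_BENCHMARK",
    "R2_UNIDIMENSIONAL",
    "reference_design",
    "reference_fit_results",
    "reference_value_set",
]

N_INITIAL_SAMPLE = 2001
N_NONTRADERS = 317
N_FINAL_TRADERS = 525
#: non-trader weight: share of non-traders in the initial full sample
REFERENCE_W = N_NONTRADERS / N_INITIAL_SAMPLE

#: the 13 dummies retained by the cross-validated sign-constrained selection
FINAL_DUMMIES = (
    (1, 3), (2, 3), (3, 1), (4, 3), (5, 3), (6, 3),
    (7, 2), (7, 3), (8, 2), (8, 3), (9, 1), (9, 2), (10, 2),
)

#: published final-model columns, in units of 0.01 utility (intercept last)
CENSORED_COEFFS = {
    (1, 3): -1.69, (2, 3): -4.09, (3, 1): -2.34, (4, 3): -3.21, (5, 3): -3.98,
    (6, 3): -2.82, (7, 2): -2.72, (7, 3): -2.17, (8, 2): -1.72, (8, 3): -3.01,
    (9, 1): -3.73, (9, 2): -2.36, (10, 2): -2.03,
}
CENSORED_INTERCEPT = 84.96
CENSORED_SE = {
    (1, 3): 1.14, (2, 3): 0.91, (3, 1): 0.87, (4, 3): 0.94, (5, 3): 0.93,
    (6, 3): 0.91, (7, 2): 0.96, (7, 3): 1.17, (8, 2): 1.01, (8, 3): 1.18,
    (9, 1): 1.05, (9, 2): 1.01, (10, 2): 0.80,
}

SCALABLE_CENSORED_COEFFS = {
    (1, 3): -2.73, (2, 3): -3.97, (3, 1): -2.68, (4, 3): -3.07, (5, 3): -4.57,
    (6, 3): -2.18, (7, 2): -2.40, (7, 3): -1.64, (8, 2): -1.84, (8, 3): -3.07,
    (9, 1): -2.90, (9, 2): -1.85, (10, 2): -1.70,
}
SCALABLE_CENSORED_INTERCEPT = 84.82
SCALABLE_CENSORED_SE = {
    (1, 3): 0.91, (2, 3): 0.79, (3, 1): 0.76, (4, 3): 0.81, (5, 3): 0.81,
    (6, 3): 0.81, (7, 2): 0.85, (7, 3): 1.02, (8, 2): 0.90, (8, 3): 1.04,
    (9, 1): 0.94, (9, 2): 0.89, (10, 2): 0.71,
}

#: published individual-level explained-variance figures: the final 13-dummy
#: model, the saturated per-state benchmark, and the total-score-only model
R2_FINAL_MODEL = 0.136
R2_BENCHMARK = 0.148
R2_UNIDIMENSIONAL = 0.129


def reference_design() -> DummyDesign:
    return DummyDesign.full().subset(list(FINAL_DUMMIES))


def _as_fit_result(family: str, intercept: float, coeffs: dict, ses: dict) -> FitResult:
    design = reference_design()
    return FitResult(
        family=family,
        alpha=intercept / 100.0,
        beta={d: coeffs[d] / 100.0 for d in design.active},
        se_alpha=None,
        se_beta={d: ses[d] / 100.0 for d in design.active},
        sigma_u=float("nan"), sigma_v=None, phi=None, delta=None,
        scale="utility", loglik=float("nan"),
        n_obs=5 * N_FINAL_TRADERS, n_respondents=N_FINAL_TRADERS,
        converged=True, design=design,
    )


def reference_fit_results() -> list[FitResult]:
    """The two published utility-scale coefficient columns that are averaged
    into the value set (censored and scalable censored)."""
    return [
        _as_fit_result("censored", CENSORED_INTERCEPT, CENSORED_COEFFS, CENSORED_SE),
        _as_fit_result("scalable_censored", SCALABLE_CENSORED_INTERCEPT,
                       SCALABLE_CENSORED_COEFFS, SCALABLE_CENSORED_SE),
    ]


def reference_value_set(w: float = REFERENCE_W) -> tuple[ValueSet, ValueSet]:
    """(trader, adjusted) value sets rebuilt from the published coefficients.

    Carries unrounded averaged coefficients; round only for display.
    """
    alpha, incr = average_models(reference_fit_results())
    trader = build_value_set(alpha, incr, reference_design(),
                             provenance="published final models (censored + scalable censored)")
    return trader, adjust_for_nontraders(trader, w)
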