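"""Synthetic TTO survey cohorts with known ground truth.

The generator emulates the data-generating process the analysis assumes: each
respondent carries an individual effective scale range lambda in (0, 1] (the
width of the utility interval they actually use) and an individual random
intercept u; the relative disutility of a health state is

    z = alpha_z + (incremental disutility of its severity levels) + u + v

and the emitted TTO utility is y = 1 - lambda * z, rounded to the 0.05 response
grid and clipped to [0, 1] (equivalently, years traded t = 10 * (1 - y) on the
half-year grid). Two contaminating subpopulations are mixed in so the screening
stage has true positives to find: non-traders, who value every state at 1 (with
probability increasing in the severity of the mildest state of their block),
and careless responders, who produce constant, near-constant, or random
low-information answers with fast response times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import skewnorm

from .design import Block, Catalogue, DummyDesign, design_matrix
from .valueset import ValueSet, adjust_for_nontraders, build_value_set, lambda_combine

__all__ = [
    "LambdaDist",
    "SimulationParams",
    "SurveyDataset",
    "default_beta_z",
    "simulate_cohort",
    "nontrader_probability",
    "true_value_set",
]


@dataclass(frozen=True)
class LambdaDist:
    """Effective scale range distribution: a location-shifted symmetric Beta.

    lambda = mean + width * (B - 1/2) with B ~ Beta(a, a), where `a` and the
    support width are chosen to match the requested mean and sd within the
    interval (lo, hi]. Defaults reproduce the scale-range moments observed for
    trader respondents (mean 0.504, sd 0.261, range about 0.05-1.00).
    """

    mean: float = 0.504
    sd: float = 0.261
    lo: float = 0.05
    hi: float = 1.0

    def __post_init__(self) -> None:
        if not (self.lo < self.mean < self.hi):
            raise ValueError("lambda mean must lie inside (lo, hi)")
        if self.sd <= 0:
            raise ValueError("lambda sd must be positive")
        width = 2.0 * min(self.mean - self.lo, self.hi - self.mean)
        sd_b = self.sd / width
        if sd_b >= 0.5:
            raise ValueError("lambda sd too large for the requested support")
        a = (0.25 / sd_b**2 - 1.0) / 2.0
        object.__setattr__(self, "_width", width)
        object.__setattr__(self, "_a", a)

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        b = rng.beta(self._a, self._a, size=n)
        return self.mean + self._width * (b - 0.5)

    def quantile_grid(self, n: int = 512) -> np.ndarray:
        """Deterministic quadrature grid (equally spaced quantiles) over lambda."""
        from scipy.stats import beta as beta_dist

        q = (np.arange(n) + 0.5) / n
        return self.mean + self._width * (beta_dist.ppf(q, self._a, self._a) - 0.5)


def default_beta_z(design: DummyDesign | None = None) -> dict[tuple[int, int], float]:
    """Default non-positive incremental effects on the z scale.

    The non-zero support follows the 13-dummy pattern of the published final
    model; magnitudes are the published utility-scale incremental effects
    divided by the mean effective scale range (0.504), so that combining with
    the default lambda distribution reproduces utility effects of realistic
    size and z('worst possible') is approximately 1.
    """
    y_incr = {
        (1, 3): -0.0221, (2, 3): -0.0403, (3, 1): -0.0251, (4, 3): -0.0314,
        (5, 3): -0.0428, (6, 3): -0.0250, (7, 2): -0.0256, (7, 3): -0.0191,
        (8, 2): -0.0178, (8, 3): -0.0304, (9, 1): -0.0332, (9, 2): -0.0211,
        (10, 2): -0.0187,
    }
    design = design or DummyDesign.full()
    return {d: y_incr.get(d, 0.0) / 0.504 for d in design.all_dummies}


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the synthetic data-generating process.

    `beta_z` holds non-positive incremental effects in the utility-direction
    convention used throughout the package (the same sign as reported
    coefficients); the generator applies them as z = alpha_z - x'beta_z, so
    severity raises relative disutility.
    """

    alpha_z: float = 0.30
    beta_z: dict[tuple[int, int], float] = field(default_factory=default_beta_z)
    sigma_u: float = 0.25
    skew_u: float = -0.72
    sigma_v: float = 0.23
    lambda_dist: LambdaDist = field(default_factory=LambdaDist)
    p_nontrader_base: float = -2.6
    p_nontrader_slope: float = 0.134
    p_careless: float = 0.65
    careless_weights: tuple[float, float, float] = (0.30, 0.45, 0.25)  # constant, fast_random, two_value
    rt_careful: tuple[float, float] = (np.log(25.0), 0.55)  # lognormal (meanlog, sdlog), seconds
    rt_careless: tuple[float, float] = (np.log(4.0), 0.45)
    rt_low_info: tuple[float, float] = (np.log(14.0), 0.45)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(v > 0 for v in self.beta_z.values()):
            raise ValueError("beta_z entries must be <= 0 (utility-direction convention)")
        if not 0.0 <= self.p_careless <= 1.0:
            raise ValueError("p_careless must be in [0, 1]")
        if self.sigma_u < 0 or self.sigma_v < 0:
            raise ValueError("variance components must be non-negative")
        if abs(sum(self.careless_weights) - 1.0) > 1e-9:
            raise ValueError("careless subtype weights must sum to 1")


@dataclass
class SurveyDataset:
    """Long-format valuation data plus (optional) per-respondent ground truth.

    `data` columns: respondent_id, block_id, state_id, q1..q10, t, y,
    response_time_s -- one row per valuation, five per respondent.
    `truth` columns: respondent_id, cls (trader/nontrader/careless), lam, u.
    """

    data: pd.DataFrame
    truth: pd.DataFrame | None = None

    def to_csv(self, path, truth_path=None) -> None:
        self.data.to_csv(path, index=False)
        if truth_path is not None and self.truth is not None:
            self.truth.to_csv(truth_path, index=False)

    @classmethod
    def from_csv(cls, path, truth_path=None) -> "SurveyDataset":
        truth = pd.read_csv(truth_path) if truth_path else None
        return cls(pd.read_csv(path), truth)


def nontrader_probability(block_min_score: float, params: SimulationParams) -> float:
    """Probability of non-trader behavior, increasing in the severity of the
    mildest state of the respondent's block (logistic in its total score)."""
    return float(expit(params.p_nontrader_base + params.p_nontrader_slope * block_min_score))


def _skewnorm_params(sd: float, skew: float) -> tuple[float, float, float]:
    """(a, loc, scale) of a skew-normal with mean 0, the given sd and skewness."""
    s = np.clip(skew, -0.95, 0.95)
    c = (2.0 * abs(s) / (4.0 - np.pi)) ** (1.0 / 3.0)
    d = np.sign(s) * c / np.sqrt(1.0 + c**2)  # delta = a / sqrt(1 + a^2)
    a = d / np.sqrt(max(1.0 - d**2, 1e-12))
    scale = sd / np.sqrt(1.0 - 2.0 * d**2 / np.pi)
    loc = -scale * d * np.sqrt(2.0 / np.pi)
    return a, loc, scale


def _round_grid(y: np.ndarray) -> np.ndarray:
    return np.clip(np.round(np.asarray(y) * 20.0) / 20.0, 0.0, 1.0)


def simulate_cohort(
    catalogue: Catalogue,
    blocks: list[Block],
    n_respondents: int,
    params: SimulationParams | None = None,
) -> SurveyDataset:
    """Simulate a survey cohort over the given block design."""
    params = params or SimulationParams()
    if n_respondents < 1:
        raise ValueError("n_respondents must be >= 1")
    rng = np.random.default_rng(params.rng_seed)
    design = DummyDesign.full()
    beta_neg = np.array([params.beta_z[d] for d in design.active])

    block_states = {b.block_id: [catalogue[sid] for sid in b.state_ids] for b in blocks}
    block_min = {b.block_id: min(s.total_score for s in block_states[b.block_id]) for b in blocks}
    block_ids = np.array([b.block_id for b in blocks])

    a_u, loc_u, scale_u = _skewnorm_params(params.sigma_u, params.skew_u) if params.sigma_u > 0 else (0, 0, 0)

    rows, truth_rows = [], []
    grid = np.arange(21) / 20.0
    for rid in range(1, n_respondents + 1):
        bid = int(block_ids[rng.integers(len(block_ids))])
        states = block_states[bid]
        p_nt = nontrader_probability(block_min[bid], params)
        if rng.random() < p_nt:
            cls, sub = "nontrader", None
        elif rng.random() < params.p_careless:
            cls = "careless"
            sub = rng.choice(("constant", "fast_random", "two_value"), p=params.careless_weights)
        else:
            cls, sub = "trader", None

        lam = u = np.nan
        if cls == "nontrader":
            y = np.ones(5)
            rt_mu, rt_sd = params.rt_careful
        elif cls == "trader":
            lam = float(params.lambda_dist.draw(1, rng)[0])
            if params.sigma_u > 0:
                u = float(skewnorm.rvs(a_u, loc=loc_u, scale=scale_u, random_state=rng))
            else:
                u = 0.0
            X = design_matrix(states, design)
            z = params.alpha_z - X @ beta_neg + u + rng.normal(0.0, params.sigma_v, 5)
            y = _round_grid(1.0 - lam * z)
            rt_mu, rt_sd = params.rt_careful
        else:  # careless
            if sub == "constant":
                y = np.full(5, grid[rng.integers(0, 20)])  # any constant below 1
                rt_mu, rt_sd = params.rt_careless
            elif sub == "fast_random":
                y = grid[rng.integers(0, 21, size=5)]
                rt_mu, rt_sd = params.rt_careless
            else:  # two_value: two close values only, the larger on the worst state
                gap = 0.05 * rng.integers(1, 3)  # low within-subject variability
                v2 = grid[rng.integers(int(gap * 20), 21)]
                v1 = v2 - gap
                y = np.where(rng.random(5) < 0.5, v1, v2)
                worst_ix = next(i for i, s in enumerate(states) if s.is_worst)
                y[worst_ix] = v2
                if not (y == v1).any():  # keep two distinct values in use
                    y[(worst_ix + 1) % 5] = v1
                rt_mu, rt_sd = params.rt_low_info
        rt = rng.lognormal(rt_mu, rt_sd, 5)
        for j, s in enumerate(states):
            rows.append(
                (rid, bid, s.state_id) + s.levels + (10.0 * (1.0 - y[j]), y[j], rt[j])
            )
        truth_rows.append((rid, cls if sub is None else f"careless:{sub}", lam, u))

    cols = (["respondent_id", "block_id", "state_id"]
            + [f"q{i}" for i in range(1, 11)] + ["t", "y", "response_time_s"])
    data = pd.DataFrame(rows, columns=cols)
    truth = pd.DataFrame(truth_rows, columns=["respondent_id", "cls", "lam", "u"])
    return SurveyDataset(data, truth)


def true_value_set(
    params: SimulationParams,
    w: float = 0.0,
    design: DummyDesign | None = None,
    n_lambda: int = 2048,
) -> ValueSet:
    """The population value set implied by the simulation parameters.

    Uses the same combination rule as the estimation side: predicted utility is
    the mean over the lambda distribution of clip(1 - lambda * z(x), 0, 1), so
    simulated-vs-recovered comparisons are like-for-like.
    """
    design = design or DummyDesign.full()
    beta_neg = {d: params.beta_z.get(d, 0.0) for d in design.active}
    lambdas = params.lambda_dist.quantile_grid(n_lambda)

    def z_of(levels: np.ndarray) -> float:
        x = design_matrix(levels[None, :], design)[0]
        return params.alpha_z - float(x @ np.array([beta_neg[d] for d in design.active]))

    alpha_y, incr_y = lambda_combine(z_of, design, lambdas)
    vs = build_value_set(alpha_y, incr_y, design, provenance="simulation truth")
    return adjust_for_nontraders(vs, w) if w > 0 else vs
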