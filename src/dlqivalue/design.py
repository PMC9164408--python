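"""DLQI health states, study-design generation, and incremental dummy coding.

The Dermatology Life Quality Index (DLQI) has 10 items, each scored on four
severity levels 0-3 (total score 0-30), giving 4^10 possible health states.
This module provides

* :class:`DLQIState` / :class:`Catalogue` / :class:`Block` -- the health-state
  catalogue used in a valuation survey and its randomized block design;
* :func:`generate_orthogonal_core` -- an orthogonal core subset in which every
  severity level of every item is uniformly represented and all item pairs are
  uncorrelated;
* :class:`DummyDesign` / :func:`design_matrix` -- incremental ("thermometer")
  dummy coding of severity levels, in which the dummy for (item i, level l) is
  active whenever the state's severity on item i is >= l, so each regression
  coefficient measures the extra disutility of moving up one level.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

N_ITEMS = 10
N_LEVELS = 4
MAX_SCORE = N_ITEMS * (N_LEVELS - 1)

__all__ = [
    "DLQIState",
    "Catalogue",
    "Block",
    "DummyDesign",
    "generate_orthogonal_core",
    "build_catalogue",
    "default_extra_states",
    "assign_blocks",
    "design_matrix",
    "pairwise_level_correlations",
]


@dataclass(frozen=True)
class DLQIState:
    """One DLQI health state: an id plus the ordered 10-vector of levels."""

    state_id: str
    levels: tuple[int, ...]

    def __post_init__(self) -> None:
        # reduced designs (fewer items) are allowed for small experiments
        if not 1 <= len(self.levels) <= N_ITEMS:
            raise ValueError("levels must have between 1 and 10 entries")
        if any((not isinstance(l, (int, np.integer))) or l < 0 or l > 3 for l in self.levels):
            raise ValueError(f"levels must be integers in 0..3, got {self.levels!r}")
        object.__setattr__(self, "levels", tuple(int(l) for l in self.levels))

    @property
    def total_score(self) -> int:
        return int(sum(self.levels))

    @property
    def is_worst(self) -> bool:
        """True for the 'worst possible' state (all items at level 3)."""
        return all(l == 3 for l in self.levels)


@dataclass
class Catalogue:
    """Collection of unique health states: an orthogonal core plus extras."""

    states: list[DLQIState]
    core_ids: frozenset[str] = field(default_factory=frozenset)
    extra_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        ids = [s.state_id for s in self.states]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate state ids: {dupes}")
        self._by_id = {s.state_id: s for s in self.states}

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, state_id: str) -> DLQIState:
        return self._by_id[state_id]

    def __contains__(self, state_id: str) -> bool:
        return state_id in self._by_id

    @property
    def worst_state(self) -> DLQIState:
        worst = [s for s in self.states if s.is_worst]
        if len(worst) != 1:
            raise ValueError(f"catalogue must contain exactly one all-level-3 state, found {len(worst)}")
        return worst[0]

    def core_states(self) -> list[DLQIState]:
        return [s for s in self.states if s.state_id in self.core_ids]

    def core_score_summary(self) -> dict[str, float]:
        """Mean/sd of core total scores, excluding the minimal and maximal core states."""
        scores = sorted(s.total_score for s in self.core_states())
        inner = scores[1:-1]
        return {
            "n": len(inner),
            "mean": float(np.mean(inner)),
            "sd": float(np.std(inner, ddof=1)),
        }

    def level_matrix(self, state_ids: list[str] | None = None) -> np.ndarray:
        states = self.states if state_ids is None else [self[i] for i in state_ids]
        return np.array([s.levels for s in states], dtype=np.int8)

    # -- JSON round trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "states": [{"id": s.state_id, "levels": list(s.levels)} for s in self.states],
            "core_ids": sorted(self.core_ids),
            "extra_ids": sorted(self.extra_ids),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Catalogue":
        states = [DLQIState(e["id"], tuple(e["levels"])) for e in d["states"]]
        return cls(states, frozenset(d.get("core_ids", [])), frozenset(d.get("extra_ids", [])))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Catalogue":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class Block:
    """One randomization block: the worst state plus one draw per severity cluster."""

    block_id: int
    state_ids: tuple[str, ...]
    cluster_assignment: dict

    def __post_init__(self) -> None:
        if len(self.state_ids) != 5:
            raise ValueError("a block contains exactly 5 states")
        if len(set(self.state_ids)) != 5:
            raise ValueError("block states must be distinct")


# ---------------------------------------------------------------------------
# Orthogonal core construction
# ---------------------------------------------------------------------------

_GF4_MUL = np.array(
    [[0, 0, 0, 0],
     [0, 1, 2, 3],
     [0, 2, 3, 1],
     [0, 3, 1, 2]], dtype=np.int8
)  # GF(4) as {0, 1, a, a+1} with a^2 = a + 1; addition is XOR


def _gf4_dot(c: np.ndarray, runs: np.ndarray) -> np.ndarray:
    """GF(4) inner products of coefficient vector `c` with each row of `runs`."""
    acc = np.zeros(runs.shape[0], dtype=np.int8)
    for j in range(len(c)):
        acc ^= _GF4_MUL[c[j], runs[:, j]]
    return acc


def pairwise_level_correlations(levels: np.ndarray) -> float:
    """Maximum absolute pairwise correlation between item-level columns."""
    corr = np.corrcoef(np.asarray(levels, dtype=float), rowvar=False)
    corr = np.atleast_2d(corr)
    off = corr[~np.eye(corr.shape[0], dtype=bool)]
    return float(np.max(np.abs(off))) if off.size else 0.0


def _exact_core_levels(n_states: int, n_items: int, rng: np.random.Generator) -> np.ndarray:
    """Strength-2 orthogonal array over GF(4)^k, with an all-3 and an all-0 run.

    Columns are GF(4) linear forms c.x with leading coefficient 1, so any two
    distinct columns are linearly independent and the level pairs of any two
    items are jointly uniform -- hence exactly zero sample correlation for any
    numeric coding of the levels.
    """
    k = round(np.log(n_states) / np.log(4))
    if 4**k != n_states:
        raise ValueError(f"exact construction requires n_states a power of 4, got {n_states}")
    n_cols_avail = 4 ** (k - 1)
    if n_items > n_cols_avail:
        raise ValueError(
            f"n_states={n_states} supports at most {n_cols_avail} pairwise-uncorrelated items, "
            f"need {n_items}"
        )
    runs = np.array(list(itertools.product(range(4), repeat=k)), dtype=np.int8)
    tails = list(itertools.product(range(4), repeat=k - 1))
    chosen = rng.choice(len(tails), size=n_items, replace=False)
    levels = np.empty((n_states, n_items), dtype=np.int8)
    for j, t in enumerate(chosen):
        col = _gf4_dot(np.array((1,) + tails[t], dtype=np.int8), runs)
        # map GF(4) symbols to severity levels: 0 -> 3 (all-3 run at x = 0),
        # 1 -> 0 (all-0 run at x = e1), and {a, a+1} -> {1, 2} at random
        perm = np.empty(4, dtype=np.int8)
        perm[0], perm[1] = 3, 0
        perm[[2, 3]] = rng.permutation([1, 2])
        levels[:, j] = perm[col]
    return levels


def _search_core_levels(
    n_states: int, n_items: int, rng: np.random.Generator,
    tol: float = 0.02, max_tries: int = 400,
) -> np.ndarray:
    """Randomized balanced design with approximately uncorrelated columns.

    Reserves an all-3 and an all-0 run, fills the rest with exactly balanced
    level counts per column, and resamples offending columns until all pairwise
    correlations are within `tol`.
    """
    n = n_states
    per = n // 4
    base = np.repeat(np.arange(4, dtype=float), per - 1)
    free = np.r_[base, 1.0, 2.0]  # level counts per column minus the two reserved runs
    # with exact balance, zero correlation between two columns is equivalent to
    # their dot product hitting the integer target n * 1.5^2
    target = 2.25 * n
    tol_dots = tol * n * 1.25  # |corr| <= tol in dot-product units
    levels = np.empty((n, n_items))
    levels[0, :] = 3.0
    levels[1, :] = 0.0
    levels[2:, 0] = rng.permutation(free)
    for j in range(1, n_items):
        prev = levels[:, :j]
        placed = False
        for _ in range(max(1, max_tries // n_items)):
            v = np.r_[3.0, 0.0, rng.permutation(free)]
            err = v @ prev - target
            # greedy swaps within the free rows until every dot product fits
            for _ in range(2 * n):
                if np.max(np.abs(err)) <= tol_dots:
                    break
                best = None
                for r1 in range(2, n):
                    for r2 in range(r1 + 1, n):
                        if v[r1] == v[r2]:
                            continue
                        delta = (v[r2] - v[r1]) * (prev[r1] - prev[r2])
                        s = float(np.sum((err + delta) ** 2))
                        if best is None or s < best[0]:
                            best = (s, r1, r2, delta)
                if best is None or best[0] >= float(np.sum(err**2)):
                    # stalled in a local minimum: random kick, then keep going
                    for _ in range(3):
                        r1, r2 = 2 + rng.integers(n - 2, size=2)
                        if v[r1] != v[r2]:
                            err = err + (v[r2] - v[r1]) * (prev[r1] - prev[r2])
                            v[r1], v[r2] = v[r2], v[r1]
                    continue
                _, r1, r2, delta = best
                v[r1], v[r2] = v[r2], v[r1]
                err = err + delta
            if np.max(np.abs(err)) <= tol_dots:
                levels[:, j] = v
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not reach pairwise correlation <= {tol} for n_states={n_states}"
            )
    return levels.astype(np.int8)


def generate_orthogonal_core(
    n_states: int = 64,
    rng_seed: int = 0,
    n_items: int = N_ITEMS,
    corr_tol: float = 0.02,
) -> Catalogue:
    """Generate the orthogonal core subset of the health-state catalogue.

    Every severity level of every item appears exactly ``n_states / 4`` times.
    For ``n_states`` a power of 4 the design is a strength-2 orthogonal array
    and all pairwise item correlations are exactly zero; for other multiples of
    4 a randomized balanced search is used with tolerance ``corr_tol``.
    The core always contains the all-level-3 ('worst possible') state and an
    all-level-0 state.
    """
    if n_states % 4 != 0 or n_states < 4:
        raise ValueError(f"n_states must be a positive multiple of 4, got {n_states}")
    rng = np.random.default_rng(rng_seed)
    k = round(np.log(n_states) / np.log(4))
    if 4**k == n_states and n_items <= 4 ** (k - 1):
        levels = _exact_core_levels(n_states, n_items, rng)
    else:
        levels = _search_core_levels(n_states, n_items, rng, tol=corr_tol)
    width = max(2, len(str(n_states)))
    states = [DLQIState(f"H{i + 1:0{width}d}", tuple(row)) for i, row in enumerate(levels)]
    return Catalogue(states, core_ids=frozenset(s.state_id for s in states))


def default_extra_states() -> list[DLQIState]:
    """Nine mild supplementary states (total scores 1-5), ids E01..E09.

    Stand-ins for survey-specific mild states (in the original study these were
    the most frequently observed real patient profiles); replace via
    :func:`build_catalogue` when an empirical catalogue is available.
    """
    rows = [
        (1, 0, 0, 0, 0, 0, 0, 0, 0, 0),  # score 1
        (1, 1, 0, 0, 0, 0, 0, 0, 0, 0),  # score 2
        (0, 1, 0, 1, 0, 0, 0, 0, 0, 0),  # score 2
        (1, 1, 1, 0, 0, 0, 0, 0, 0, 0),  # score 3
        (2, 1, 0, 0, 0, 0, 0, 0, 0, 0),  # score 3
        (1, 1, 0, 1, 1, 0, 0, 0, 0, 0),  # score 4
        (2, 1, 1, 0, 0, 0, 0, 0, 0, 0),  # score 4
        (1, 1, 1, 1, 1, 0, 0, 0, 0, 0),  # score 5
        (2, 2, 1, 0, 0, 0, 0, 0, 0, 0),  # score 5
    ]
    return [DLQIState(f"E{i + 1:02d}", r) for i, r in enumerate(rows)]


def build_catalogue(core: Catalogue, extra_states: list[DLQIState] | None = None) -> Catalogue:
    """Union of the orthogonal core and supplementary states.

    Raises if ids collide or if the worst-possible state is absent from the core.
    """
    if extra_states is None:
        extra_states = default_extra_states()
    if not any(s.is_worst for s in core.states):
        raise ValueError("core must contain the all-level-3 'worst possible' state")
    states = list(core.states) + list(extra_states)
    cat = Catalogue(
        states,
        core_ids=frozenset(s.state_id for s in core.states),
        extra_ids=frozenset(s.state_id for s in extra_states),
    )
    cat.worst_state  # validates uniqueness of the all-3 state
    return cat


def assign_blocks(
    catalogue: Catalogue,
    n_blocks: int = 18,
    cluster_bounds: tuple[float, float, float] | None = None,
    rng_seed: int = 0,
) -> list[Block]:
    """Randomized block design: each block gets the worst state plus one random
    draw from each of four total-score clusters of the remaining states.

    ``cluster_bounds`` are three score cut-points partitioning the non-worst
    states; by default the quartiles of their total scores. Within-block
    presentation order is randomized. States may appear in several blocks or in
    none (sampling with replacement across blocks).
    """
    rng = np.random.default_rng(rng_seed)
    worst = catalogue.worst_state
    others = [s for s in catalogue.states if s.state_id != worst.state_id]
    scores = np.array([s.total_score for s in others], dtype=float)
    if cluster_bounds is None:
        cluster_bounds = tuple(np.quantile(scores, [0.25, 0.5, 0.75]))
    idx = np.searchsorted(np.asarray(cluster_bounds, dtype=float), scores, side="right")
    clusters = [[s for s, c in zip(others, idx) if c == k] for k in range(4)]
    for k, cl in enumerate(clusters):
        if not cl:
            raise ValueError(f"severity cluster {k} is empty; adjust cluster_bounds")
    blocks = []
    for b in range(1, n_blocks + 1):
        picks = [cl[rng.integers(len(cl))] for cl in clusters]
        assignment = {s.state_id: k for k, s in enumerate(picks)}
        ids = [worst.state_id] + [s.state_id for s in picks]
        order = rng.permutation(5)
        blocks.append(Block(b, tuple(ids[i] for i in order), assignment))
    return blocks


# ---------------------------------------------------------------------------
# Incremental (thermometer) dummy coding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DummyDesign:
    """The set of incremental severity dummies currently in the model.

    A dummy is an (item, level) pair with item in 1..10 and level in 1..3; its
    design-matrix entry for a state is 1 iff the state's severity on that item
    is >= level. The full design has all 30 dummies; selection removes dummies,
    which merges the corresponding severity step with the previous level.
    """

    active: tuple[tuple[int, int], ...]
    n_items: int = N_ITEMS

    @classmethod
    def full(cls, n_items: int = N_ITEMS) -> "DummyDesign":
        return cls(tuple((i, l) for i in range(1, n_items + 1) for l in (1, 2, 3)), n_items)

    @property
    def all_dummies(self) -> tuple[tuple[int, int], ...]:
        return tuple((i, l) for i in range(1, self.n_items + 1) for l in (1, 2, 3))

    @property
    def labels(self) -> list[str]:
        return [f"D{i:02d}_L{l}" for i, l in self.active]

    def __len__(self) -> int:
        return len(self.active)

    def remove(self, dummy: tuple[int, int]) -> "DummyDesign":
        if dummy not in self.active:
            raise KeyError(f"dummy {dummy} not active")
        return DummyDesign(tuple(d for d in self.active if d != dummy), self.n_items)

    def subset(self, dummies: list[tuple[int, int]]) -> "DummyDesign":
        keep = set(dummies)
        return DummyDesign(tuple(d for d in self.active if d in keep), self.n_items)


def design_matrix(states: list[DLQIState] | np.ndarray, design: DummyDesign) -> np.ndarray:
    """Thermometer-coded 0/1 matrix: one row per state, one column per active dummy."""
    if isinstance(states, np.ndarray):
        levels = states
    else:
        levels = np.array([s.levels for s in states], dtype=np.int8)
    cols = [(levels[:, i - 1] >= l).astype(np.int8) for i, l in design.active]
    if not cols:
        return np.zeros((levels.shape[0], 0), dtype=np.int8)
    return np.column_stack(cols)
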