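"""Asynchronously tuned ECA (AT-ECA) update dynamics.

Each time step draws a fresh random bijective update order over the
cells: ``order[i]`` is the rank at which cell ``i`` updates (1-based,
smaller updates first). The local order of a cell relative to its two
neighbors selects one of four update cases:

* ``ACTIVE_MIN``   — both neighbors rank later; the cell applies its own
  per-cell *active* rule to the time-t neighborhood.
* ``LEFT_FIRST``   — left neighbor earlier, right later; the shared
  *passive* rule is applied with the left neighbor's already-updated
  state substituted.
* ``RIGHT_FIRST``  — the mirror case.
* ``PASSIVE_MAX``  — both neighbors earlier; the passive rule is applied
  to both updated neighbor states.

After a cell's state update its active rule is tuned: unchanged in
``ACTIVE_MIN``; in ``LEFT_FIRST``/``RIGHT_FIRST`` the entry for the
time-t neighborhood ``m = 4 c_{i-1}(t) + 2 c_i(t) + c_{i+1}(t)`` is
re-initialized from the passive rule; in ``PASSIVE_MAX`` that entry is
overwritten with the freshly computed state ``c_i(t+1)``. At most one
active-rule entry per cell changes per step, and every cell starts with
its active rule equal to the passive rule.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .eca_core import (
    PERIODIC,
    BoundaryPair,
    RuleTable,
    SpaceTimeDiagram,
    as_configuration,
    random_configuration,
)

__all__ = [
    "UpdateCase",
    "ATState",
    "draw_order",
    "validate_order",
    "neighbor_ranks",
    "classify_case",
    "classify_all",
    "at_step",
    "run_at_eca",
]

#: Rank assigned to clamped boundary cells: they never update, so from an
#: interior cell's viewpoint a boundary neighbor always ranks "later".
BOUNDARY_RANK = np.iinfo(np.int64).max


class UpdateCase(enum.IntEnum):
    ACTIVE_MIN = 0
    LEFT_FIRST = 1
    RIGHT_FIRST = 2
    PASSIVE_MAX = 3


def draw_order(n_cells: int, rng: np.random.Generator) -> np.ndarray:
    """A uniformly random update order: ``order[i]`` in {1, ..., N}, bijective."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    return rng.permutation(n_cells).astype(np.int64) + 1


def validate_order(order: np.ndarray) -> np.ndarray:
    order = np.asarray(order, dtype=np.int64)
    n = order.size
    if n < 1 or not np.array_equal(np.sort(order), np.arange(1, n + 1)):
        raise ValueError("order must be a bijection onto {1, ..., N}")
    return order


def neighbor_ranks(order: np.ndarray, i: int, topology: str = "ring") -> tuple[int, int]:
    """Ranks of cell i's left and right neighbors under the topology."""
    n = order.size
    if topology == "ring":
        if n < 2:
            raise ValueError("ring topology needs at least 2 cells")
        return int(order[(i - 1) % n]), int(order[(i + 1) % n])
    if topology == "clamped":
        left = int(order[i - 1]) if i > 0 else BOUNDARY_RANK
        right = int(order[i + 1]) if i < n - 1 else BOUNDARY_RANK
        return left, right
    raise ValueError(f"unknown topology {topology!r}")


def classify_case(order: np.ndarray, i: int, topology: str = "ring") -> UpdateCase:
    """Which of the four update cases holds for cell i under this order."""
    order = validate_order(order)
    lrank, rrank = neighbor_ranks(order, i, topology)
    own = int(order[i])
    if lrank > own < rrank:
        return UpdateCase.ACTIVE_MIN
    if lrank < own < rrank:
        return UpdateCase.LEFT_FIRST
    if lrank > own > rrank:
        return UpdateCase.RIGHT_FIRST
    return UpdateCase.PASSIVE_MAX


def classify_all(order: np.ndarray, topology: str = "ring") -> np.ndarray:
    """Vectorized case classification for every cell (uint8 codes)."""
    order = np.asarray(order, dtype=np.int64)
    n = order.size
    if topology == "ring":
        if n < 2:
            raise ValueError("ring topology needs at least 2 cells")
        lrank = np.roll(order, 1)
        rrank = np.roll(order, -1)
    else:
        lrank = np.empty(n, dtype=np.int64)
        rrank = np.empty(n, dtype=np.int64)
        lrank[1:] = order[:-1]
        rrank[:-1] = order[1:]
        lrank[0] = BOUNDARY_RANK
        rrank[-1] = BOUNDARY_RANK
    cases = np.empty(n, dtype=np.uint8)
    cases[(lrank > order) & (order < rrank)] = UpdateCase.ACTIVE_MIN
    cases[(lrank < order) & (order < rrank)] = UpdateCase.LEFT_FIRST
    cases[(lrank > order) & (order > rrank)] = UpdateCase.RIGHT_FIRST
    cases[(lrank < order) & (order > rrank)] = UpdateCase.PASSIVE_MAX
    return cases


@dataclass
class ATState:
    """Configuration, per-cell active-rule field, and the shared passive rule.

    ``active`` is an N x 8 binary matrix; row i is cell i's active rule
    table (same neighborhood indexing as :class:`RuleTable`). The passive
    rule is immutable for the whole run.
    """

    config: np.ndarray
    active: np.ndarray
    passive: RuleTable
    time: int = 0

    def __post_init__(self) -> None:
        self.config = as_configuration(self.config)
        active = np.asarray(self.active, dtype=np.uint8)
        if active.shape != (self.config.size, 8):
            raise ValueError("active field must be N x 8")
        if not np.isin(active, (0, 1)).all():
            raise ValueError("active-rule entries must be 0 or 1")
        self.active = active

    @classmethod
    def initial(cls, config: np.ndarray, passive: RuleTable) -> "ATState":
        """Fresh state with every cell's active rule equal to the passive rule."""
        config = as_configuration(config)
        active = np.tile(passive.outputs, (config.size, 1))
        return cls(config, active, passive, time=0)

    def active_field_text(self) -> str:
        """The active field as an N x 8 plain-text 0/1 matrix."""
        return "\n".join("".join(map(str, row)) for row in self.active) + "\n"


def at_step(
    state: ATState,
    order: np.ndarray,
    topology: str = "ring",
    boundary: BoundaryPair | None = None,
    eq12_literal_a0: bool = False,
) -> ATState:
    """One asynchronously tuned update under a given order permutation.

    Cells are processed in ascending rank over a single evolving state
    array alongside a frozen snapshot of time t; a neighbor's value is
    therefore read as c(t+1) exactly when its rank is smaller and c(t)
    otherwise, which is what the four update cases prescribe.

    ``eq12_literal_a0`` switches the LEFT_FIRST/RIGHT_FIRST tuning from
    re-initializing entry m to the passive output a_m (the default,
    which restores the entry to its initial value) to overwriting it
    with a_0 regardless of m.
    """
    order = validate_order(order)
    n = state.config.size
    if order.size != n:
        raise ValueError("order length must match configuration length")
    if topology == "clamped" and boundary is None:
        raise ValueError("clamped topology requires a BoundaryPair")

    old = state.config.copy()
    cur = state.config.copy()
    active = state.active.copy()
    passive = state.passive.outputs
    cases = classify_all(order, topology)
    ring = topology == "ring"

    def read(arr: np.ndarray, j: int) -> int:
        if ring:
            return int(arr[j % n])
        if j < 0:
            return boundary.left
        if j >= n:
            return boundary.right
        return int(arr[j])

    for i in np.argsort(order, kind="stable"):
        i = int(i)
        case = cases[i]
        # Neighbors with smaller rank have already been written into
        # `cur`; larger-rank neighbors (and clamped boundaries) still
        # hold their time-t values there.
        s = 4 * read(cur, i - 1) + 2 * int(cur[i]) + read(cur, i + 1)
        if case == UpdateCase.ACTIVE_MIN:
            new = int(active[i, s])
        else:
            new = int(passive[s])
        m = 4 * read(old, i - 1) + 2 * int(old[i]) + read(old, i + 1)
        if case in (UpdateCase.LEFT_FIRST, UpdateCase.RIGHT_FIRST):
            active[i, m] = passive[0] if eq12_literal_a0 else passive[m]
        elif case == UpdateCase.PASSIVE_MAX:
            active[i, m] = new
        cur[i] = new

    return ATState(cur, active, state.passive, state.time + 1)


def run_at_eca(
    passive: RuleTable | int,
    T: int,
    n_cells: int | None = None,
    initial: np.ndarray | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    topology: str = "ring",
    boundary: BoundaryPair | None = None,
    eq12_literal_a0: bool = False,
) -> tuple[SpaceTimeDiagram, ATState]:
    """Run AT-ECA for ``T`` steps with a fresh random order every step.

    Either an explicit ``initial`` configuration or ``n_cells`` (for an
    i.i.d. Bernoulli(0.5) start) must be given. Deterministic per seed.
    """
    from .eca_core import decode_rule

    if isinstance(passive, (int, np.integer)):
        passive = decode_rule(int(passive))
    if T < 0:
        raise ValueError("T must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    if initial is None:
        if n_cells is None:
            raise ValueError("give either an initial configuration or n_cells")
        initial = random_configuration(n_cells, rng)
    state = ATState.initial(initial, passive)
    rows = np.empty((T + 1, state.config.size), dtype=np.uint8)
    rows[0] = state.config
    for t in range(T):
        order = draw_order(state.config.size, rng)
        state = at_step(state, order, topology, boundary, eq12_literal_a0)
        rows[t + 1] = state.config
    meta = {
        "rule": passive.rule_number,
        "regime": "at",
        "seed": seed,
        "boundary": topology if topology == "ring" else f"{boundary.left}{boundary.right}",
    }
    return SpaceTimeDiagram(rows, meta), state
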