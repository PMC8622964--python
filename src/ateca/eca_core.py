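"""Elementary cellular automata: rule tables, synchronous and
probabilistically asynchronous dynamics, and space-time diagrams.

An elementary cellular automaton (ECA) is a one-dimensional array of
binary cells updated by a radius-1 transition rule ``f : B^3 -> B``.
The 256 possible rules are numbered by the Wolfram convention

    r = sum_s 2^s * d_s,    s = 4x + 2y + z,

where ``d_s = f(x, y, z)`` is the output for neighborhood ``(x, y, z)``.

Two closed boundary treatments are supported: a periodic ring, and a
clamped pair of constant boundary cells (the latter is what the
computability measures use).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence, Union

import numpy as np

__all__ = [
    "RuleTable",
    "BoundaryPair",
    "SpaceTimeDiagram",
    "decode_rule",
    "as_configuration",
    "random_configuration",
    "sync_step",
    "async_step",
    "run_trajectory",
]

#: Bit weights of the eight neighborhoods, s = 4x + 2y + z.
_WEIGHTS = np.array([4, 2, 1], dtype=np.int64)


@dataclass(frozen=True)
class RuleTable:
    """An 8-entry binary transition table and its Wolfram rule number.

    ``outputs[s]`` is the next state of a cell whose neighborhood
    ``(left, self, right) = (x, y, z)`` has index ``s = 4x + 2y + z``.
    """

    rule_number: int
    outputs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        out = np.asarray(self.outputs, dtype=np.uint8)
        if out.shape != (8,) or not np.isin(out, (0, 1)).all():
            raise ValueError("outputs must be 8 binary values")
        object.__setattr__(self, "outputs", out)
        if self.encode() != self.rule_number:
            raise ValueError(
                f"outputs encode rule {self.encode()}, not {self.rule_number}"
            )

    def encode(self) -> int:
        return int(np.dot(self.outputs.astype(np.int64), 1 << np.arange(8)))

    def __call__(self, x: int, y: int, z: int) -> int:
        return int(self.outputs[4 * x + 2 * y + z])

    def bitstring(self) -> str:
        """The table as the 8-bit string ``d7 d6 ... d0``."""
        return "".join(str(int(b)) for b in self.outputs[::-1])

    def __str__(self) -> str:
        return f"rule {self.rule_number} [{self.bitstring()}]"


def decode_rule(rule_number: int) -> RuleTable:
    """Expand a Wolfram rule number into its 8-entry lookup table.

    Raises ``ValueError`` unless ``0 <= rule_number <= 255``.
    """
    if not (isinstance(rule_number, (int, np.integer)) and 0 <= rule_number <= 255):
        raise ValueError(f"rule number must be an integer in [0, 255], got {rule_number!r}")
    outputs = (int(rule_number) >> np.arange(8)) & 1
    return RuleTable(int(rule_number), outputs.astype(np.uint8))


@dataclass(frozen=True)
class BoundaryPair:
    """Constant clamped boundary cells ``(c_0, c_{n+1})`` flanking the array."""

    left: int
    right: int

    def __post_init__(self) -> None:
        if self.left not in (0, 1) or self.right not in (0, 1):
            raise ValueError("boundary values must be 0 or 1")


#: A boundary is either the string ``"periodic"`` or a clamped pair.
Boundary = Union[str, BoundaryPair, tuple]

PERIODIC = "periodic"


def _as_boundary(boundary: Boundary) -> Boundary:
    if isinstance(boundary, str):
        if boundary != PERIODIC:
            raise ValueError(f"unknown boundary mode {boundary!r}")
        return PERIODIC
    if isinstance(boundary, BoundaryPair):
        return boundary
    left, right = boundary
    return BoundaryPair(int(left), int(right))


def as_configuration(cells: Sequence[int]) -> np.ndarray:
    """Validate and convert a cell sequence to a uint8 array."""
    arr = np.asarray(cells, dtype=np.uint8)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError("configuration must be a nonempty 1-D sequence")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("configuration cells must be 0 or 1")
    return arr


def random_configuration(
    n_cells: int, rng: np.random.Generator, density: float = 0.5
) -> np.ndarray:
    """I.i.d. Bernoulli(``density``) initial configuration."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    return (rng.random(n_cells) < density).astype(np.uint8)


def _neighbor_views(config: np.ndarray, boundary: Boundary):
    """Left and right neighbor arrays under the given boundary mode."""
    if boundary == PERIODIC:
        return np.roll(config, 1), np.roll(config, -1)
    left = np.empty_like(config)
    right = np.empty_like(config)
    left[1:] = config[:-1]
    right[:-1] = config[1:]
    left[0] = boundary.left
    right[-1] = boundary.right
    return left, right


def sync_step(
    config: np.ndarray, rule: RuleTable, boundary: Boundary = PERIODIC
) -> np.ndarray:
    """One synchronous update: every cell reads its time-t neighborhood."""
    config = as_configuration(config)
    boundary = _as_boundary(boundary)
    left, right = _neighbor_views(config, boundary)
    s = 4 * left.astype(np.int64) + 2 * config + right
    return rule.outputs[s]


def async_step(
    config: np.ndarray,
    rule: RuleTable,
    p: float,
    rng: np.random.Generator,
    boundary: Boundary = PERIODIC,
) -> np.ndarray:
    """One probabilistically asynchronous update.

    Each cell independently keeps its state with probability ``p`` and
    otherwise applies the rule to its time-t neighborhood; all rule
    inputs are read from time t regardless of the coin flips.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    candidate = sync_step(config, rule, boundary)
    keep = rng.random(len(config)) < p
    return np.where(keep, config, candidate).astype(np.uint8)


@dataclass
class SpaceTimeDiagram:
    """A trajectory: row t is the configuration at time t (time downward)."""

    rows: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=np.uint8)
        if rows.ndim != 2:
            raise ValueError("rows must be a 2-D array (time x cells)")
        self.rows = rows

    @property
    def n_steps(self) -> int:
        return self.rows.shape[0] - 1

    @property
    def n_cells(self) -> int:
        return self.rows.shape[1]

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.rows)

    # -- plain-text 0/1 matrix (round-trip exact) --------------------------

    def to_text(self) -> str:
        header = "# " + " ".join(
            f"{k}={self.metadata[k]}" for k in sorted(self.metadata)
        )
        body = "\n".join("".join(map(str, row)) for row in self.rows)
        return (header + "\n" if self.metadata else "") + body + "\n"

    @classmethod
    def from_text(cls, text: str) -> "SpaceTimeDiagram":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        metadata: dict = {}
        if lines and lines[0].startswith("#"):
            for item in lines.pop(0)[1:].split():
                key, _, value = item.partition("=")
                metadata[key] = value
        rows = np.array([[int(ch) for ch in ln.strip()] for ln in lines], dtype=np.uint8)
        return cls(rows, metadata)

    def write_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def read_text(cls, path) -> "SpaceTimeDiagram":
        with open(path) as fh:
            return cls.from_text(fh.read())

    # -- images ------------------------------------------------------------

    def write_pgm(self, path) -> None:
        """Binary PGM, one pixel per cell, state 1 drawn black."""
        h, w = self.rows.shape
        pixels = (255 * (1 - self.rows)).astype(np.uint8)
        with open(path, "wb") as fh:
            fh.write(f"P5\n{w} {h}\n255\n".encode())
            fh.write(pixels.tobytes())

    def write_png(self, path) -> None:
        from . import plotting

        plotting.render_diagram(self, path)


def run_trajectory(
    initial: np.ndarray,
    rule: RuleTable,
    T: int,
    regime: str = "sync",
    p: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    boundary: Boundary = PERIODIC,
) -> SpaceTimeDiagram:
    """Iterate a rule for ``T`` steps and collect the space-time diagram.

    ``regime`` is ``"sync"`` or ``"async"`` (the latter keeps each cell
    with probability ``p`` per step). The run is bit-reproducible given
    ``seed`` (or an explicit ``rng``).
    """
    if T < 0:
        raise ValueError("T must be >= 0")
    if regime not in ("sync", "async"):
        raise ValueError(f"unknown regime {regime!r}")
    initial = as_configuration(initial)
    boundary = _as_boundary(boundary)
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = np.empty((T + 1, len(initial)), dtype=np.uint8)
    rows[0] = initial
    for t in range(T):
        if regime == "sync":
            rows[t + 1] = sync_step(rows[t], rule, boundary)
        else:
            rows[t + 1] = async_step(rows[t], rule, p, rng, boundary)
    meta = {
        "rule": rule.rule_number,
        "regime": regime if regime == "sync" else f"async(p={p})",
        "seed": seed,
        "boundary": boundary if isinstance(boundary, str) else f"{boundary.left}{boundary.right}",
    }
    return SpaceTimeDiagram(rows, meta)
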