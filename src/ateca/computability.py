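"""Computational universality and efficiency measures, the EMIN tradeoff
step function, and tradeoff-break statistics.

For a rule r and an interior width n, all 2^n interior initial states
are enumerated under a clamped random boundary pair and iterated to the
horizon T_max = 2^n. The *reachable states* (possible goals) are the
configurations occupied at the horizon; their count is the
computational universality U(r), and UN(r) = U(r) / 2^n its normalized
form. For a reachable state X the summed first-hitting time is

    tau(X) = sum over initial states Y of T(Y -> X),

where T(Y -> X) is the smallest T >= 1 at which the trajectory from Y
occupies X, or the penalty T_theta if X is not reached within the
horizon. The computational efficiency E(r) is the mean of tau over the
reachable states; smaller E means more efficient computation.

Stochastic regimes (probabilistically asynchronous, asynchronously
tuned) are evaluated over independent replicates — each with a fresh
boundary pair and fresh update orders / coins — and U, E are averaged.

The universality-efficiency tradeoff of the synchronous regime is
summarized by the EMIN step function: UN-space is split into m
half-open intervals Int_k = ((k-1)/m, k/m], EMIN(k) is the minimum
synchronous E over rules whose UN falls in Int_k, and an empty interval
inherits the minimum over all later intervals. A rule run under an
alternative regime *breaks the tradeoff* when its E lies strictly below
EMIN at the interval containing its UN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .at_dynamics import ATState, at_step
from .eca_core import BoundaryPair, RuleTable, decode_rule

__all__ = [
    "MeasureConfig",
    "ComputabilityRecord",
    "TradeoffSummary",
    "evaluate_rule",
    "normalized_universality",
    "sweep_all_rules",
    "emin_curve",
    "interval_index",
    "tradeoff_breaks",
    "async_break_table",
    "records_to_frame",
]

#: Exhaustive enumeration guard: fh matrices are (2^n x 2^n).
MAX_INTERIOR_WIDTH = 12

REGIMES = ("sync", "async", "at")


@dataclass(frozen=True)
class MeasureConfig:
    """Problem size and protocol for the computability measures.

    ``T_max`` (observation/hitting horizon) and ``T_theta`` (penalty
    hitting time for unreached goals) both default to 2^n. ``runs`` is
    the number of stochastic replicates; each redraws the boundary pair.
    """

    n: int
    T_max: int | None = None
    T_theta: int | None = None
    runs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n <= MAX_INTERIOR_WIDTH:
            raise ValueError(f"n must be in [1, {MAX_INTERIOR_WIDTH}]")
        if self.T_max is None:
            object.__setattr__(self, "T_max", 2**self.n)
        if self.T_theta is None:
            object.__setattr__(self, "T_theta", 2**self.n)
        if self.T_max < 1 or self.T_theta < 1 or self.runs < 1:
            raise ValueError("T_max, T_theta and runs must all be >= 1")

    @property
    def n_states(self) -> int:
        return 2**self.n


@dataclass
class ComputabilityRecord:
    """Universality/efficiency measures of one rule under one regime."""

    rule_number: int
    regime: str
    p: float | None
    n: int
    U: float
    UN: float
    E: float
    reachable: frozenset
    tau: Mapping[int, float]
    T_max: int
    T_theta: int
    runs: int
    seed: int
    boundaries: tuple = ()
    per_rep_U: tuple = ()
    per_rep_E: tuple = ()


def normalized_universality(record: ComputabilityRecord) -> float:
    """UN(r) = U(r) / 2^n, in (0, 1]."""
    return record.U / 2**record.n


def _measures(fh: np.ndarray, final: np.ndarray, T_theta: int):
    """Reachable set, per-state tau, and E from one replicate's raw data."""
    reachable = np.unique(final)
    tau = np.where(fh < 0, T_theta, fh).sum(axis=0, dtype=np.int64)
    E = float(tau[reachable].mean())
    return reachable, tau, E


def _sync_transition_table(
    outputs: np.ndarray, n: int, bl: int, br: int
) -> np.ndarray:
    """next-state lookup over all 2^n packed interior states."""
    size = 2**n
    states = np.arange(size)
    bits = (states[:, None] >> np.arange(n - 1, -1, -1)) & 1
    left = np.concatenate([np.full((size, 1), bl), bits[:, :-1]], axis=1)
    right = np.concatenate([bits[:, 1:], np.full((size, 1), br)], axis=1)
    new = outputs[4 * left + 2 * bits + right]
    return new @ (1 << np.arange(n - 1, -1, -1))


def _at_replicate_reference(
    rule: RuleTable,
    cfg: MeasureConfig,
    bl: int,
    br: int,
    seed: int,
):
    """Slow per-cell path through :func:`ateca.at_dynamics.at_step`.

    Mirrors the compiled kernel's random stream exactly — one block of n
    uniform order keys per step, trajectories in increasing initial-state
    order — so the two engines agree trajectory-for-trajectory.
    """
    n, T = cfg.n, cfg.T_max
    size = cfg.n_states
    boundary = BoundaryPair(bl, br)
    fh = np.full((size, size), -1, dtype=np.int32)
    final = np.empty(size, dtype=np.int64)
    weights = 1 << np.arange(n - 1, -1, -1)
    rs = np.random.RandomState(seed)
    for init in range(size):
        bits = (init >> np.arange(n - 1, -1, -1)) & 1
        state = ATState.initial(bits.astype(np.uint8), rule)
        for t in range(T):
            keys = rs.random_sample(n)
            ranks = np.argsort(np.argsort(keys)) + 1
            state = at_step(state, ranks, topology="clamped", boundary=boundary)
            packed = int(state.config @ weights)
            if fh[init, packed] < 0:
                fh[init, packed] = t + 1
        final[init] = packed
    return fh, final


def evaluate_rule(
    rule_number: int,
    cfg: MeasureConfig,
    regime: str = "sync",
    p: float | None = None,
    engine: str = "fast",
    eq12_literal_a0: bool = False,
) -> ComputabilityRecord:
    """Measure U, UN, tau and E of one rule under one update regime.

    One random boundary pair is drawn per replicate and shared by all
    2^n initial interior states of that replicate; replicate streams are
    derived from ``(cfg.seed, rule_number, replicate)`` so sweeps are
    order-independent and reproducible. ``engine="reference"`` routes
    the asynchronously tuned regime through the per-cell step function
    instead of the compiled kernel (identical results, much slower).
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    if regime == "async":
        if p is None or not 0.0 <= p <= 1.0:
            raise ValueError("async regime requires p in [0, 1]")
    rule = decode_rule(rule_number)
    n, T, T_theta = cfg.n, cfg.T_max, cfg.T_theta
    size = cfg.n_states

    reachable_union: set[int] = set()
    tau_sums = np.zeros(size, dtype=np.float64)
    Us, Es, boundaries = [], [], []
    for rep in range(cfg.runs):
        ss = np.random.SeedSequence(entropy=(cfg.seed, rule_number, rep))
        ss_boundary, ss_coins, ss_orders = ss.spawn(3)
        bl, br = (int(v) for v in np.random.default_rng(ss_boundary).integers(0, 2, 2))
        fh = np.full((size, size), -1, dtype=np.int32)
        final = np.empty(size, dtype=np.int64)
        if regime == "sync":
            table = _sync_transition_table(rule.outputs, n, bl, br)
            _kernels.sync_firsthit(table.astype(np.int64), T, fh, final)
        elif regime == "async":
            kseed = int(ss_coins.generate_state(1)[0] % np.uint32(2**31))
            _kernels.async_firsthit(
                rule.outputs, n, T, float(p), np.uint8(bl), np.uint8(br),
                kseed, fh, final,
            )
        else:  # at
            kseed = int(ss_orders.generate_state(1)[0] % np.uint32(2**31))
            if engine == "reference":
                fh, final = _at_replicate_reference(rule, cfg, bl, br, kseed)
            else:
                _kernels.at_firsthit(
                    rule.outputs, n, T, np.uint8(bl), np.uint8(br),
                    kseed, eq12_literal_a0, fh, final,
                )
        reachable, tau, E = _measures(fh, final, T_theta)
        reachable_union.update(int(x) for x in reachable)
        tau_sums += tau
        Us.append(len(reachable))
        Es.append(E)
        boundaries.append((bl, br))

    U = float(np.mean(Us))
    tau_mean = tau_sums / cfg.runs
    return ComputabilityRecord(
        rule_number=rule_number,
        regime=regime,
        p=p,
        n=n,
        U=U,
        UN=U / size,
        E=float(np.mean(Es)),
        reachable=frozenset(reachable_union),
        tau={x: float(tau_mean[x]) for x in sorted(reachable_union)},
        T_max=T,
        T_theta=T_theta,
        runs=cfg.runs,
        seed=cfg.seed,
        boundaries=tuple(boundaries),
        per_rep_U=tuple(Us),
        per_rep_E=tuple(Es),
    )


def sweep_all_rules(
    cfg: MeasureConfig,
    regime: str = "sync",
    p: float | None = None,
    rules: Iterable[int] = range(256),
    progress: bool = False,
) -> list[ComputabilityRecord]:
    """Evaluate a set of rules (all 256 by default) under one regime.

    Per-rule seeds are derived from ``(cfg.seed, rule)``, so results do
    not depend on evaluation order and sweeps may be sharded freely.
    """
    rules = list(rules)
    if not rules:
        raise ValueError("empty rule set")
    records = []
    for r in rules:
        records.append(evaluate_rule(r, cfg, regime=regime, p=p))
        if progress and (r + 1) % 32 == 0:
            print(f"  regime={regime} p={p} rule {r + 1}/{rules[-1] + 1}", flush=True)
    return records


def records_to_frame(records: Sequence[ComputabilityRecord]) -> pd.DataFrame:
    """Serialize sweep records to the flat table written as CSV."""
    return pd.DataFrame(
        {
            "rule": [r.rule_number for r in records],
            "regime": [r.regime for r in records],
            "p": [r.p for r in records],
            "U": [r.U for r in records],
            "UN": [r.UN for r in records],
            "E": [r.E for r in records],
            "seed": [r.seed for r in records],
            "n": [r.n for r in records],
            "T_theta": [r.T_theta for r in records],
            "runs": [r.runs for r in records],
        }
    )


def interval_index(un: float, m: int) -> int:
    """1-based index k with UN in Int_k = ((k-1)/m, k/m]."""
    if not 0.0 < un <= 1.0:
        raise ValueError(f"UN must lie in (0, 1], got {un}")
    return min(m, max(1, math.ceil(un * m - 1e-12)))


def emin_curve(records, m: int) -> np.ndarray:
    """EMIN step function over m universality intervals.

    ``records`` may be ComputabilityRecords or any objects/rows exposing
    ``UN`` and ``E``. Empty intervals inherit the minimum E over all
    later (higher-universality) intervals; trailing empty intervals,
    which have no later interval to inherit from, take the global
    minimum E.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    un, e = _un_e_arrays(records)
    if un.size == 0:
        raise ValueError("no records")
    interval_min = np.full(m + 1, np.inf)
    for u, ev in zip(un, e):
        k = interval_index(u, m)
        interval_min[k] = min(interval_min[k], ev)
    emin = np.empty(m)
    suffix = np.inf  # min E over intervals strictly later than k
    global_min = float(e.min())
    for k in range(m, 0, -1):
        if np.isfinite(interval_min[k]):
            emin[k - 1] = interval_min[k]
        elif np.isfinite(suffix):
            emin[k - 1] = suffix
        else:
            emin[k - 1] = global_min
        suffix = min(suffix, interval_min[k])
    return emin


def _un_e_arrays(records):
    if isinstance(records, pd.DataFrame):
        return records["UN"].to_numpy(float), records["E"].to_numpy(float)
    return (
        np.array([r.UN for r in records], float),
        np.array([r.E for r in records], float),
    )


def _rule_numbers(records):
    if isinstance(records, pd.DataFrame):
        return records["rule"].to_numpy(int)
    return np.array([r.rule_number for r in records], int)


@dataclass
class TradeoffSummary:
    """Per-rule deviations from the synchronous EMIN curve and break flags."""

    m: int
    emin: np.ndarray
    rules: np.ndarray
    un_alt: np.ndarray
    e_alt: np.ndarray
    interval: np.ndarray
    deviation: np.ndarray  # EMIN(k) - E_alt(r); > 0 means the tradeoff broke
    break_flag: np.ndarray
    break_fraction: float
    mean_deviation_by_interval: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": self.rules,
                "UN": self.un_alt,
                "E": self.e_alt,
                "interval": self.interval,
                "emin": self.emin[self.interval - 1],
                "deviation": self.deviation,
                "break": self.break_flag,
            }
        )

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "emin": [float(v) for v in self.emin],
            "break_fraction": self.break_fraction,
            "n_breaks": int(self.break_flag.sum()),
            "n_rules": int(self.rules.size),
            "mean_deviation_by_interval": {
                int(k): float(v) for k, v in self.mean_deviation_by_interval.items()
            },
        }


def tradeoff_breaks(sync_records, alt_records, m: int = 20) -> TradeoffSummary:
    """Compare an alternative regime's (UN, E) cloud against sync EMIN.

    A rule breaks the tradeoff when its alternative-regime E is strictly
    below EMIN at the interval containing its alternative-regime UN.
    """
    sync_rules = _rule_numbers(sync_records)
    alt_rules = _rule_numbers(alt_records)
    if set(sync_rules) != set(alt_rules):
        raise ValueError("sync and alternative sweeps must cover the same rules")
    emin = emin_curve(sync_records, m)
    un_alt, e_alt = _un_e_arrays(alt_records)
    interval = np.array([interval_index(u, m) for u in un_alt])
    deviation = emin[interval - 1] - e_alt
    break_flag = deviation > 0
    mean_dev = {
        int(k): float(deviation[interval == k].mean())
        for k in np.unique(interval)
    }
    return TradeoffSummary(
        m=m,
        emin=emin,
        rules=alt_rules,
        un_alt=un_alt,
        e_alt=e_alt,
        interval=interval,
        deviation=deviation,
        break_flag=break_flag,
        break_fraction=float(break_flag.mean()),
        mean_deviation_by_interval=mean_dev,
    )


def async_break_table(
    cfg: MeasureConfig,
    p_grid: Sequence[float] = tuple(np.round(np.arange(1, 21) * 0.05, 2)),
    sync_records=None,
    m: int = 20,
    progress: bool = False,
) -> pd.DataFrame:
    """Break fraction of the probabilistically asynchronous regime per p.

    The default grid is p = 0.05, 0.10, ..., 1.00.
    """
    if sync_records is None:
        sync_records = sweep_all_rules(cfg, regime="sync", progress=progress)
    rows = []
    for p in p_grid:
        alt = sweep_all_rules(cfg, regime="async", p=float(p), progress=progress)
        summary = tradeoff_breaks(sync_records, alt, m)
        rows.append({"p": float(p), "break_fraction": summary.break_fraction})
    return pd.DataFrame(rows)
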