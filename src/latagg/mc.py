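"""Metropolis Monte Carlo engine: move proposals, acceptance, trajectories.

The move repertoire follows the standard self-avoiding-walk set:

* local moves (probability 1 - p_global, default 0.9): a chain and a bead
  are picked uniformly; end beads attempt a tail rotation to a uniformly
  chosen neighbour of their anchor, interior beads attempt a corner flip
  (the fourth corner of the right-angle plaquette) or a crankshaft of the
  U-segment (i, i+1) about its anchor axis, each branch with probability
  1/2 regardless of geometry so proposal probabilities stay exactly
  symmetric;
* global moves (p_global, default 0.1): a whole chain is rotated 90
  degrees about a coordinate axis through a uniformly chosen pivot bead
  (sense +-90 equiprobable) or translated by one lattice unit in one of
  the 6 directions, each with probability 1/2.

Geometrically impossible picks are null moves that consume the attempt.
Acceptance is standard Metropolis, min(1, exp(-dE/T)) with k_B = 1 and T
in eps_H units.  One MCS is one attempted elementary move by default; a
per-sweep mode (N*M attempts per MCS) is available behind a flag and
recorded in output metadata, since absolute times shift by a constant
factor between the two conventions while comparisons across conditions
do not.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .energy import EnergyBreakdown, InteractionModel
from .lattice import EMPTY, SystemState


class MoveKind(enum.Enum):
    TAIL_ROTATION = "tail_rotation"
    CORNER_FLIP = "corner_flip"
    CRANKSHAFT = "crankshaft"
    RIGID_ROTATION = "rigid_rotation"
    RIGID_TRANSLATION = "rigid_translation"


@dataclass
class MoveProposal:
    chain_index: int
    kind: MoveKind
    bead_indices: np.ndarray
    old_pos: np.ndarray
    new_pos: np.ndarray
    rejected_by_geometry: bool = False

    @classmethod
    def rejected(cls, chain: int, kind: MoveKind) -> "MoveProposal":
        empty = np.zeros((0, 3), dtype=np.int64)
        return cls(chain, kind, np.zeros(0, dtype=np.int64), empty, empty, True)

    def is_null(self) -> bool:
        return self.rejected_by_geometry or np.array_equal(self.old_pos, self.new_pos)


def _surface_aff(state: SystemState, model: InteractionModel) -> np.ndarray:
    if state.surface is None:
        return np.zeros(4)
    return model.affinity_row(state.surface.chemistry)


def metropolis_accept(dE: float, T: float, rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(-dE/T)); k_B = 1."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return dE <= 0 or rng.random() < math.exp(-dE / T)


def _free(state: SystemState, site: tuple[int, int, int]) -> bool:
    return state.occupancy[site] == EMPTY


def _z_ok(state: SystemState, z: int) -> bool:
    box = state.box
    return (not box.z_wall) or (box.z_min <= z <= box.z_max)


def propose_local(state: SystemState, rng: np.random.Generator) -> MoveProposal:
    """Draw one local move proposal (not applied); mirrors the kernel rules."""
    box = state.box
    M = state.chain_length
    c = int(rng.integers(state.n_chains))
    i = int(rng.integers(M))
    chain = state.chains[c]

    if i in (0, M - 1):
        adj = 1 if i == 0 else M - 2
        offs = np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
        )
        raw = chain[adj] + offs[rng.integers(6)]
        if not _z_ok(state, int(raw[2])):
            return MoveProposal.rejected(c, MoveKind.TAIL_ROTATION)
        target = tuple(box.wrap(raw))
        if target == tuple(chain[i]) or not _free(state, target):
            return MoveProposal.rejected(c, MoveKind.TAIL_ROTATION)
        return MoveProposal(
            c, MoveKind.TAIL_ROTATION, np.array([i]),
            chain[i][None].copy(), np.array([target], dtype=np.int64),
        )

    if rng.random() < 0.5:  # corner flip
        a, b = chain[i - 1], chain[i + 1]
        d = np.abs(box.min_image(b - a))
        if d.sum() != 2 or d.max() == 2:
            return MoveProposal.rejected(c, MoveKind.CORNER_FLIP)
        raw = chain[i] + box.min_image(a - chain[i]) + box.min_image(b - chain[i])
        if not _z_ok(state, int(raw[2])):
            return MoveProposal.rejected(c, MoveKind.CORNER_FLIP)
        target = tuple(box.wrap(raw))
        if not _free(state, target):
            return MoveProposal.rejected(c, MoveKind.CORNER_FLIP)
        return MoveProposal(
            c, MoveKind.CORNER_FLIP, np.array([i]),
            chain[i][None].copy(), np.array([target], dtype=np.int64),
        )

    # crankshaft on the pair (i, i+1)
    if i > M - 3:
        return MoveProposal.rejected(c, MoveKind.CRANKSHAFT)
    a, b = chain[i - 1], chain[i + 2]
    e = box.min_image(b - a)
    if np.abs(e).sum() != 1:
        return MoveProposal.rejected(c, MoveKind.CRANKSHAFT)
    u = box.min_image(chain[i] - a)
    k = int(rng.integers(3))
    if k == 0:
        v = np.cross(e, u)
    elif k == 1:
        v = -u
    else:
        v = -np.cross(e, u)
    raw1, raw2 = a + v, b + v
    if not (_z_ok(state, int(raw1[2])) and _z_ok(state, int(raw2[2]))):
        return MoveProposal.rejected(c, MoveKind.CRANKSHAFT)
    t1, t2 = tuple(box.wrap(raw1)), tuple(box.wrap(raw2))
    if not (_free(state, t1) and _free(state, t2)):
        return MoveProposal.rejected(c, MoveKind.CRANKSHAFT)
    return MoveProposal(
        c, MoveKind.CRANKSHAFT, np.array([i, i + 1]),
        chain[i : i + 2].copy(), np.array([t1, t2], dtype=np.int64),
    )


def propose_global(state: SystemState, rng: np.random.Generator) -> MoveProposal:
    """Draw one rigid-chain move proposal (rotation or unit translation)."""
    box = state.box
    c = int(rng.integers(state.n_chains))
    chain = state.chains[c]
    M = state.chain_length
    if rng.random() < 0.5:
        kind = MoveKind.RIGID_ROTATION
        pivot = int(rng.integers(M))
        axis = int(rng.integers(3))
        sign = 1 if rng.random() < 0.5 else -1
        d = box.min_image(chain - chain[pivot])
        rot = np.empty_like(d)
        if axis == 0:
            rot[:, 0], rot[:, 1], rot[:, 2] = d[:, 0], -sign * d[:, 2], sign * d[:, 1]
        elif axis == 1:
            rot[:, 0], rot[:, 1], rot[:, 2] = sign * d[:, 2], d[:, 1], -sign * d[:, 0]
        else:
            rot[:, 0], rot[:, 1], rot[:, 2] = -sign * d[:, 1], sign * d[:, 0], d[:, 2]
        raw = chain[pivot] + rot
    else:
        kind = MoveKind.RIGID_TRANSLATION
        offs = np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
        )
        raw = chain + offs[rng.integers(6)]
    if box.z_wall and (raw[:, 2].min() < box.z_min or raw[:, 2].max() > box.z_max):
        return MoveProposal.rejected(c, kind)
    new = box.wrap(raw)
    occ = state.occupancy
    M_ = state.chain_length
    for site in map(tuple, new):
        code = occ[site]
        if code != EMPTY and code // M_ != c:
            return MoveProposal.rejected(c, kind)
    # moved beads may land on the chain's own old sites, but not on each other
    if len({tuple(s) for s in new}) != M:
        return MoveProposal.rejected(c, kind)
    return MoveProposal(c, kind, np.arange(M), chain.copy(), new)


def apply_proposal(state: SystemState, proposal: MoveProposal) -> None:
    """Commit an accepted proposal to the state and its occupancy index."""
    if proposal.rejected_by_geometry:
        raise ValueError("cannot apply a geometry-rejected proposal")
    M = state.chain_length
    c = proposal.chain_index
    occ = state.occupancy
    for x, y, z in proposal.old_pos:
        occ[x, y, z] = EMPTY
    for (x, y, z), i in zip(proposal.new_pos, proposal.bead_indices):
        occ[x, y, z] = c * M + int(i)
        state.chains[c, i] = (x, y, z)


@dataclass
class MCConfig:
    """Dynamics parameters; temperature in eps_H/k_B with k_B = 1."""

    temperature: float = 0.54
    p_global: float = 0.1
    max_mcs: int = 10_000
    measure_every: int = 100
    seed: int = 0
    sweep_mode: bool = False  # one MCS = N*M attempts instead of 1

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not 0.0 <= self.p_global <= 1.0:
            raise ValueError("p_global must lie in [0, 1]")

    def to_metadata(self) -> dict:
        return {
            "temperature": self.temperature,
            "p_global": self.p_global,
            "max_mcs": self.max_mcs,
            "measure_every": self.measure_every,
            "seed": self.seed,
            "mcs_mode": "sweep" if self.sweep_mode else "single_attempt",
        }


@dataclass
class FibrilStop:
    """Stop condition: >= threshold of the reference inter-chain contacts."""

    q_fib: int
    threshold: float = 0.8


@dataclass
class TrajectoryRecord:
    mcs: np.ndarray
    energies: list[EnergyBreakdown]
    contacts: np.ndarray
    fibril_fraction: np.ndarray  # contacts / q_fib, nan when no reference
    final_state: SystemState
    first_passage: Optional[int]  # None = censored (never reached threshold)
    n_accepted: int
    config: MCConfig = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def acceptance_rate(self) -> float:
        att = int(self.mcs[-1]) if len(self.mcs) else 0
        if self.config is not None and self.config.sweep_mode:
            att *= len(self.final_state.sequence) * self.final_state.n_chains
        return self.n_accepted / att if att else 0.0


def run_trajectory(
    state: SystemState,
    model: InteractionModel,
    config: MCConfig,
    stop_condition: Optional[FibrilStop] = None,
) -> TrajectoryRecord:
    """Run Metropolis dynamics from ``state`` (not mutated); kernel-backed.

    Deterministic for a given seed.  When a stop condition is given the run
    halts at the first measurement meeting it; otherwise it runs max_mcs.
    """
    st = state.copy()
    aff = _surface_aff(st, model)
    q_fib = stop_condition.q_fib if stop_condition else 0
    threshold = stop_condition.threshold if stop_condition else 0.0
    attempts = st.n_chains * st.chain_length if config.sweep_mode else 1
    n, mcs, ei, ee, es, q, fp, n_acc = _kernels.run_dynamics(
        st.chains,
        st.occupancy,
        st.sequence,
        model.table.matrix,
        aff,
        st.box.z_wall,
        st.box.z_min,
        config.temperature,
        config.p_global,
        config.max_mcs,
        max(1, attempts),
        config.measure_every,
        config.seed,
        q_fib,
        threshold,
        stop_condition is not None,
    )
    energies = [
        EnergyBreakdown(float(ei[k]), float(ee[k]), float(es[k])) for k in range(n)
    ]
    frac = (
        q[:n].astype(float) / q_fib if q_fib > 0 else np.full(n, np.nan)
    )
    return TrajectoryRecord(
        mcs=mcs[:n].copy(),
        energies=energies,
        contacts=q[:n].copy(),
        fibril_fraction=frac,
        final_state=st,
        first_passage=None if fp < 0 else int(fp),
        n_accepted=int(n_acc),
        config=config,
    )


@dataclass
class AnnealSchedule:
    """Geometric cooling ladder for ground-state searches."""

    t_high: float = 1.2
    t_low: float = 0.12
    n_temps: int = 24
    steps_per_temp: int = 20_000

    def temperatures(self) -> np.ndarray:
        return np.geomspace(self.t_high, self.t_low, self.n_temps)


def anneal(
    state: SystemState,
    model: InteractionModel,
    schedule: AnnealSchedule,
    seed: int = 0,
    p_global: float = 0.1,
) -> tuple[float, SystemState]:
    """One annealing run; returns (best energy, best state found)."""
    st = state.copy()
    aff = _surface_aff(st, model)
    best_e, best_chains = _kernels.run_anneal(
        st.chains,
        st.occupancy,
        st.sequence,
        model.table.matrix,
        aff,
        st.box.z_wall,
        st.box.z_min,
        schedule.temperatures(),
        schedule.steps_per_temp,
        p_global,
        seed,
    )
    best = SystemState(
        sequence=st.sequence.copy(),
        chains=best_chains,
        box=st.box,
        surface=st.surface,
    )
    return float(best_e), best


__all__ = [
    "MoveKind",
    "MoveProposal",
    "metropolis_accept",
    "propose_local",
    "propose_global",
    "apply_proposal",
    "MCConfig",
    "FibrilStop",
    "TrajectoryRecord",
    "run_trajectory",
    "AnnealSchedule",
    "anneal",
]
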