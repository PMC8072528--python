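"""Contact energies: intra-chain, inter-chain and chain-surface terms.

The total energy of N chains is a sum over nearest-neighbour (distance
a = 1, minimum image) bead pairs:

    E = sum_intra e(s_i, s_j) + sum_inter e(s_i, s_j) + sum_surf e_nu(s_i)

Intra-chain pairs count only beads that are not successive in sequence
(|i - j| >= 2); inter-chain pairs count every distance-1 pair from
different chains; the surface term adds one affinity entry per (chain
bead, surface site) contact, so a bead touching two surface sites accrues
two terms.  Energies are in units of the hydrogen-bond energy eps_H.

The default bead-bead matrix (statistical-potential derived):

          H      P      +      -
    H   -1.0    0.2    0.2    0.2
    P    0.2   -0.2   -0.2   -0.2
    +    0.2   -0.2    0.35  -0.7
    -    0.2   -0.2   -0.7    0.35

Surface affinity rows (one per surface chemistry; the matching-polarity
entry is the tunable adsorption strength, stored as -eps with eps >= 0):

    Ps (hydrophilic):  H 0.2,  P -eps_ps,  + -0.2,  - -0.2
    Hs (hydrophobic):  H -eps_hs,  P 0.2,  + 0.2,  - 0.2

Surface beads are frozen and do not interact with each other; balls carry
the same affinity row as the plane of their surface.

``total_energy`` here is a direct, vectorised full summation and serves
as the exact reference against which the incremental kernel updates are
verified; ``delta_energy`` is the fast local-shell path used by the
Metropolis engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .lattice import BEAD_ALPHABET, BEAD_CODES, SystemState

_DEFAULT_TABLE = np.array(
    [
        [-1.0, 0.2, 0.2, 0.2],
        [0.2, -0.2, -0.2, -0.2],
        [0.2, -0.2, 0.35, -0.7],
        [0.2, -0.2, -0.7, 0.35],
    ]
)


class EnergyError(ValueError):
    pass


@dataclass(frozen=True)
class InteractionTable:
    """Symmetric 4x4 bead-bead contact matrix over (H, P, +, -), in eps_H."""

    matrix: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        m = _DEFAULT_TABLE.copy() if self.matrix is None else np.asarray(
            self.matrix, dtype=float
        )
        if m.shape != (4, 4):
            raise EnergyError("interaction table must be 4x4")
        if not np.allclose(m, m.T):
            raise EnergyError("interaction table must be symmetric")
        object.__setattr__(self, "matrix", m)

    def entry(self, a: str, b: str) -> float:
        return float(self.matrix[BEAD_CODES[a], BEAD_CODES[b]])

    def to_config(self) -> dict:
        return {"beads": list(BEAD_ALPHABET), "matrix": self.matrix.tolist()}

    @classmethod
    def from_config(cls, cfg: dict) -> "InteractionTable":
        order = [BEAD_CODES[b] for b in cfg.get("beads", list(BEAD_ALPHABET))]
        m = np.asarray(cfg["matrix"], dtype=float)
        full = np.empty((4, 4))
        for i, oi in enumerate(order):
            for j, oj in enumerate(order):
                full[oi, oj] = m[i, j]
        return cls(full)


# Fixed (non-tunable) surface affinity entries, by chemistry then bead.
_FIXED_AFFINITY = {
    "Ps": {"H": 0.2, "+": -0.2, "-": -0.2},
    "Hs": {"P": 0.2, "+": 0.2, "-": 0.2},
}
_TUNABLE_BEAD = {"Ps": "P", "Hs": "H"}


def surface_affinity_row(chemistry: str, eps: float) -> np.ndarray:
    """Per-chain-bead affinity row for a surface chemistry, in eps_H.

    ``eps`` is the tunable adsorption strength (>= 0); the row entry for
    the matching bead type equals -eps.
    """
    if chemistry not in _FIXED_AFFINITY:
        raise EnergyError(f"unknown surface chemistry {chemistry!r}")
    if eps < 0:
        raise EnergyError("tunable surface affinity eps must be >= 0")
    row = np.zeros(4)
    for bead, val in _FIXED_AFFINITY[chemistry].items():
        row[BEAD_CODES[bead]] = val
    row[BEAD_CODES[_TUNABLE_BEAD[chemistry]]] = -eps
    return row


@dataclass(frozen=True)
class InteractionModel:
    """Bead-bead table plus the two tunable surface affinities."""

    table: InteractionTable = None  # type: ignore[assignment]
    eps_ps: float = 0.0  # hydrophilic surface <-> P bead strength
    eps_hs: float = 0.0  # hydrophobic surface <-> H bead strength

    def __post_init__(self) -> None:
        if self.table is None:
            object.__setattr__(self, "table", InteractionTable())
        if self.eps_ps < 0 or self.eps_hs < 0:
            raise EnergyError("surface affinities must be >= 0")

    def affinity_row(self, chemistry: str) -> np.ndarray:
        eps = self.eps_ps if chemistry == "Ps" else self.eps_hs
        return surface_affinity_row(chemistry, eps)

    def to_config(self) -> dict:
        return {
            "table": self.table.to_config(),
            "eps_ps": self.eps_ps,
            "eps_hs": self.eps_hs,
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "InteractionModel":
        table = (
            InteractionTable.from_config(cfg["table"])
            if "table" in cfg
            else InteractionTable()
        )
        return cls(table, float(cfg.get("eps_ps", 0.0)), float(cfg.get("eps_hs", 0.0)))


@dataclass(frozen=True)
class EnergyBreakdown:
    e_intra: float
    e_inter: float
    e_surf: float

    @property
    def e_total(self) -> float:
        return self.e_intra + self.e_inter + self.e_surf

    def __iter__(self):
        yield from (self.e_intra, self.e_inter, self.e_surf, self.e_total)


def total_energy(state: SystemState, model: InteractionModel) -> EnergyBreakdown:
    """Full O(n^2) recomputation of the three energy terms.

    Deliberately independent of the occupancy grid and of the incremental
    kernel: pairwise minimum-image distances are evaluated directly from
    the chain coordinates.
    """
    N, M = state.n_chains, state.chain_length
    if N == 0:
        return EnergyBreakdown(0.0, 0.0, 0.0)
    box = state.box
    pos = state.chains.reshape(N * M, 3)
    codes = np.tile(state.sequence, N)
    owner = np.repeat(np.arange(N), M)
    index = np.tile(np.arange(M), N)

    d = pos[:, None, :] - pos[None, :, :]
    for ax, L in ((0, box.Lx), (1, box.Ly)):
        d[..., ax] = (d[..., ax] + L // 2) % L - L // 2
    if not box.z_wall:
        d[..., 2] = (d[..., 2] + box.Lz // 2) % box.Lz - box.Lz // 2
    contact = np.abs(d).sum(axis=2) == 1
    upper = np.triu(np.ones((N * M, N * M), dtype=bool), k=1)
    same_chain = owner[:, None] == owner[None, :]
    nonsucc = np.abs(index[:, None] - index[None, :]) >= 2
    e = model.table.matrix[codes[:, None], codes[None, :]]

    e_intra = float(e[contact & upper & same_chain & nonsucc].sum())
    e_inter = float(e[contact & upper & ~same_chain].sum())

    e_surf = 0.0
    if state.surface is not None:
        aff = model.affinity_row(state.surface.chemistry)
        surf = {tuple(s) for s in state.surface.sites()}
        for k in range(N * M):
            x, y, z = pos[k]
            for nx, ny, nz in (
                ((x + 1) % box.Lx, y, z),
                ((x - 1) % box.Lx, y, z),
                (x, (y + 1) % box.Ly, z),
                (x, (y - 1) % box.Ly, z),
                (x, y, z + 1),
                (x, y, z - 1),
            ):
                if (nx, ny, nz) in surf:
                    e_surf += aff[codes[k]]
    return EnergyBreakdown(e_intra, e_inter, float(e_surf))


def delta_energy(state: SystemState, proposal, model: InteractionModel) -> float:
    """E(after) - E(before) from the affected beads' contact shells only.

    Exact to round-off against ``total_energy(after) - total_energy(before)``
    for every move type; the geometric validity of the proposal (bonds,
    self-avoidance) must already have been established.
    """
    from . import _kernels

    if getattr(proposal, "rejected_by_geometry", False):
        raise EnergyError("delta_energy called on a geometry-rejected proposal")
    idxs = np.asarray(proposal.bead_indices, dtype=np.int64)
    old = np.asarray(proposal.old_pos, dtype=np.int64).reshape(len(idxs), 3)
    new = np.asarray(proposal.new_pos, dtype=np.int64).reshape(len(idxs), 3)
    if np.array_equal(old, new):
        return 0.0
    aff = (
        model.affinity_row(state.surface.chemistry)
        if state.surface is not None
        else np.zeros(4)
    )
    occ = state.occupancy
    chain = int(proposal.chain_index)
    M = state.chain_length
    # Lift the moved beads out of the grid, score both shells, put them back.
    for x, y, z in old:
        occ[x, y, z] = -1
    try:
        before = _kernels.segment_energy(
            occ, state.sequence, model.table.matrix, aff,
            chain, idxs, old, M, state.box.z_wall,
        )
        after = _kernels.segment_energy(
            occ, state.sequence, model.table.matrix, aff,
            chain, idxs, new, M, state.box.z_wall,
        )
    finally:
        for (x, y, z), i in zip(old, idxs):
            occ[x, y, z] = chain * M + int(i)
    return float(after - before)


__all__ = [
    "EnergyError",
    "InteractionTable",
    "surface_affinity_row",
    "InteractionModel",
    "EnergyBreakdown",
    "total_energy",
    "delta_energy",
]
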