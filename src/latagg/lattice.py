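"""Cubic-lattice geometry, chain representation and occupancy bookkeeping.

Polypeptide chains are self-avoiding walks on a simple cubic lattice with
spacing a = 1.  Coordinates are 0-based integers; the simulation box is
periodic on x and y (and on z in bulk), while an attached surface turns the
z axis into a slab: the surface plane sits at z = 0, surface balls at
z = 1 (and 2), and chain beads live in 1 <= z <= Lz-1 with a hard,
non-interacting wall at the top.

The occupancy index is a dense int32 grid over box sites: -1 empty,
-2 surface (plane bead or ball), and ``chain * M + bead`` for chain beads.
It is the single source of truth for site exclusion and is cheap to rebuild
from scratch, which the test suite exploits to cross-check incremental
updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, TextIO, Union

import numpy as np

# Bead alphabet: chain beads H (hydrophobic), P (polar), + / - (charged).
BEAD_ALPHABET = "HP+-"
BEAD_CODES = {c: i for i, c in enumerate(BEAD_ALPHABET)}
DEFAULT_SEQUENCE = "+HHPPHH-"

# Occupancy grid sentinels (shared with the numba kernels).
EMPTY = -1
SURF = -2

# Element labels used by the extended-XYZ writer.
XYZ_ELEMENTS = {"H": "C", "P": "N", "+": "K", "-": "O"}
SURFACE_ELEMENT = "S"


class LatticeError(ValueError):
    """Base class for lattice-state errors."""


class InvalidStateError(LatticeError):
    """A chain or occupancy invariant is violated."""


class PlacementError(LatticeError):
    """Random chain placement exhausted its retry budget."""


def parse_sequence(seq: Union[str, Iterable[int], np.ndarray]) -> np.ndarray:
    """Return integer bead codes for a peptide sequence.

    Accepts a string over the alphabet ``H P + -`` (the unicode minus sign
    is tolerated) or an already-encoded integer array.
    """
    if isinstance(seq, str):
        seq = seq.replace("−", "-")
        try:
            codes = np.array([BEAD_CODES[c] for c in seq], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message path
            raise LatticeError(f"unknown bead type {exc.args[0]!r}") from None
    else:
        codes = np.asarray(seq, dtype=np.int64)
        if codes.ndim != 1 or codes.size and (codes.min() < 0 or codes.max() > 3):
            raise LatticeError("bead codes must be a 1-D array over 0..3")
    if len(codes) < 3:
        raise LatticeError("peptide sequences must have at least 3 beads")
    return codes


def sequence_str(codes: np.ndarray) -> str:
    return "".join(BEAD_ALPHABET[c] for c in codes)


@dataclass(frozen=True)
class SimulationBox:
    """Simulation box: Lx x Ly x Lz sites, periodic laterally.

    ``z_wall`` selects slab geometry (surface attached): z is bounded by
    hard walls instead of wrapping.  Bulk boxes are periodic on all axes.
    """

    Lx: int
    Ly: int
    Lz: int
    z_wall: bool = False

    def __post_init__(self) -> None:
        if min(self.Lx, self.Ly, self.Lz) < 4:
            raise LatticeError("box dimensions must be >= 4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.Lx, self.Ly, self.Lz)

    @property
    def z_min(self) -> int:
        """Lowest z a chain bead may occupy (1 above an attached surface)."""
        return 1 if self.z_wall else 0

    @property
    def z_max(self) -> int:
        return self.Lz - 1

    def wrap(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=np.int64).copy()
        r[..., 0] %= self.Lx
        r[..., 1] %= self.Ly
        if not self.z_wall:
            r[..., 2] %= self.Lz
        return r

    def min_image(self, d: np.ndarray) -> np.ndarray:
        """Minimum-image displacement for a raw coordinate difference."""
        d = np.asarray(d, dtype=np.int64).copy()
        for ax, L in ((0, self.Lx), (1, self.Ly)):
            d[..., ax] = (d[..., ax] + L // 2) % L - L // 2
        if not self.z_wall:
            d[..., 2] = (d[..., 2] + self.Lz // 2) % self.Lz - self.Lz // 2
        return d

    def contains(self, r: np.ndarray) -> bool:
        r = np.asarray(r)
        ok = (r[..., 0] >= 0) & (r[..., 0] < self.Lx)
        ok &= (r[..., 1] >= 0) & (r[..., 1] < self.Ly)
        ok &= (r[..., 2] >= 0) & (r[..., 2] < self.Lz)
        return bool(np.all(ok))


_UNIT_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)


def neighbors(site: np.ndarray, box: SimulationBox) -> list[tuple[int, int, int]]:
    """The <=6 nearest-neighbour sites of ``site`` under box boundaries.

    Periodic axes wrap; on a walled z axis, sites beyond the wall are
    omitted (so corner/edge sites have fewer than 6 neighbours).
    """
    site = np.asarray(site, dtype=np.int64)
    if not box.contains(site):
        raise LatticeError(f"site {tuple(site)} outside box {box.shape}")
    out = []
    for off in _UNIT_OFFSETS:
        n = site + off
        if box.z_wall and not (0 <= n[2] < box.Lz):
            continue
        out.append(tuple(box.wrap(n)))
    return out


def adjacent(r1: np.ndarray, r2: np.ndarray, box: SimulationBox) -> bool:
    """True iff the minimum-image distance between two sites is exactly 1."""
    r1 = np.asarray(r1, dtype=np.int64)
    r2 = np.asarray(r2, dtype=np.int64)
    if not (box.contains(r1) and box.contains(r2)):
        raise LatticeError("sites must lie inside the box")
    d = box.min_image(r2 - r1)
    return int(np.abs(d).sum()) == 1


@dataclass
class SystemState:
    """N chains + optional surface + box; owns the occupancy grid."""

    sequence: np.ndarray  # (M,) bead codes
    chains: np.ndarray  # (N, M, 3) int64 lattice coordinates
    box: SimulationBox
    surface: Optional["SurfaceProfile"] = None  # noqa: F821 - forward ref
    occupancy: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sequence = np.asarray(self.sequence, dtype=np.int64)
        self.chains = np.asarray(self.chains, dtype=np.int64).reshape(
            -1, len(self.sequence), 3
        )
        if self.surface is not None and not self.box.z_wall:
            raise InvalidStateError("a surface requires slab (z_wall) geometry")
        if self.occupancy is None:
            self.occupancy = build_occupancy(self)

    @property
    def n_chains(self) -> int:
        return self.chains.shape[0]

    @property
    def chain_length(self) -> int:
        return self.chains.shape[1]

    def copy(self) -> "SystemState":
        return SystemState(
            sequence=self.sequence.copy(),
            chains=self.chains.copy(),
            box=self.box,
            surface=self.surface,
            occupancy=self.occupancy.copy(),
        )

    def validate(self) -> None:
        """Raise InvalidStateError on any broken invariant."""
        box = self.box
        if not box.contains(self.chains):
            raise InvalidStateError("chain bead outside box")
        if box.z_wall:
            z = self.chains[..., 2]
            if z.size and (z.min() < box.z_min or z.max() > box.z_max):
                raise InvalidStateError("chain bead inside wall/surface layer")
        for c in range(self.n_chains):
            d = box.min_image(np.diff(self.chains[c], axis=0))
            if d.size and not np.all(np.abs(d).sum(axis=1) == 1):
                raise InvalidStateError(f"chain {c} has a bond of length != 1")
        rebuilt = build_occupancy(self)  # raises on any site collision
        if not np.array_equal(rebuilt, self.occupancy):
            raise InvalidStateError("occupancy index inconsistent with chains")

    def rebuild_occupancy(self) -> None:
        self.occupancy = build_occupancy(self)


def build_occupancy(state: SystemState) -> np.ndarray:
    """Dense occupancy grid from scratch; raises on any double occupancy."""
    grid = np.full(state.box.shape, EMPTY, dtype=np.int32)
    if state.surface is not None:
        for x, y, z in state.surface.sites():
            grid[x, y, z] = SURF
    M = state.chain_length
    for c in range(state.n_chains):
        for i in range(M):
            x, y, z = state.chains[c, i]
            prev = grid[x, y, z]
            if prev != EMPTY:
                other = "surface" if prev == SURF else f"chain {prev // M} bead {prev % M}"
                raise InvalidStateError(
                    f"site ({x},{y},{z}) occupied by {other} and chain {c} bead {i}"
                )
            grid[x, y, z] = c * M + i
    return grid


def occupancy_entries(state: SystemState) -> dict[tuple[int, int, int], tuple]:
    """Mapping site -> ('surface',) or (chain index, bead index)."""
    out: dict[tuple[int, int, int], tuple] = {}
    grid = state.occupancy
    M = state.chain_length
    for x, y, z in np.argwhere(grid != EMPTY):
        code = grid[x, y, z]
        out[(int(x), int(y), int(z))] = (
            ("surface",) if code == SURF else (int(code) // M, int(code) % M)
        )
    return out


def default_box(n_chains: int, with_surface: bool = False) -> SimulationBox:
    """Box sizes matching the working chain-bead density convention.

    N = 6 chains of 8 beads in a 14^3 box and N = 12 in 18^3 keep the bead
    number density near 0.017 per site; the mapping of lattice units to a
    molar concentration is a convention recorded in run metadata, not a
    derived quantity.
    """
    L = 14 if n_chains <= 6 else 18
    return SimulationBox(L, L, L, z_wall=with_surface)


def place_random_chains(
    n_chains: int,
    sequence: Union[str, np.ndarray],
    box: SimulationBox,
    surface: Optional["SurfaceProfile"] = None,  # noqa: F821
    rng_seed: int = 0,
    max_attempts_per_chain: int = 2000,
) -> SystemState:
    """Grow N mutually avoiding chains at random sites; deterministic per seed.

    Each chain is grown step by step, choosing uniformly among the free
    neighbour sites of the current head; dead ends restart the chain.  The
    retry budget bounds total work and raises PlacementError (suggesting a
    larger box) when exhausted.
    """
    seq = parse_sequence(sequence)
    M = len(seq)
    rng = np.random.default_rng(rng_seed)
    grid = np.full(box.shape, EMPTY, dtype=np.int32)
    if surface is not None:
        if not box.z_wall:
            raise InvalidStateError("a surface requires slab (z_wall) geometry")
        for x, y, z in surface.sites():
            grid[x, y, z] = SURF
    zmin = box.z_min
    chains = np.zeros((n_chains, M, 3), dtype=np.int64)
    for c in range(n_chains):
        placed = False
        for _ in range(max_attempts_per_chain):
            start = np.array(
                [
                    rng.integers(box.Lx),
                    rng.integers(box.Ly),
                    rng.integers(zmin, box.Lz),
                ],
                dtype=np.int64,
            )
            if grid[tuple(start)] != EMPTY:
                continue
            walk = [start]
            ok = True
            for _step in range(M - 1):
                cands = [
                    np.array(n)
                    for n in neighbors(walk[-1], box)
                    if n[2] >= zmin
                    and grid[n] == EMPTY
                    and not any(np.array_equal(n, w) for w in walk)
                ]
                if not cands:
                    ok = False
                    break
                walk.append(cands[rng.integers(len(cands))])
            if ok:
                for i, site in enumerate(walk):
                    grid[tuple(site)] = c * M + i
                chains[c] = np.stack(walk)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place chain {c} of {n_chains} after "
                f"{max_attempts_per_chain} attempts; try a larger box"
            )
    return SystemState(
        sequence=seq, chains=chains, box=box, surface=surface, occupancy=grid
    )


def write_extxyz(
    fh: TextIO,
    state: SystemState,
    comment_extra: str = "",
    include_surface: bool = True,
) -> None:
    """Append one extended-XYZ frame for a SystemState.

    Bead types map to element labels H->C, P->N, +->K, -->O and surface
    beads/balls (Ps or Hs) to S; lattice coordinates are written as floats.
    """
    rows: list[str] = []
    for c in range(state.n_chains):
        for i in range(state.chain_length):
            el = XYZ_ELEMENTS[BEAD_ALPHABET[state.sequence[i]]]
            x, y, z = state.chains[c, i]
            rows.append(f"{el} {float(x):.1f} {float(y):.1f} {float(z):.1f}")
    if include_surface and state.surface is not None:
        for x, y, z in state.surface.sites():
            rows.append(f"{SURFACE_ELEMENT} {float(x):.1f} {float(y):.1f} {float(z):.1f}")
    box = state.box
    header = (
        f'Lattice="{box.Lx} 0 0 0 {box.Ly} 0 0 0 {box.Lz}" '
        "Properties=species:S:1:pos:R:3"
    )
    if comment_extra:
        header += " " + comment_extra
    fh.write(f"{len(rows)}\n{header}\n")
    fh.write("\n".join(rows) + "\n")


__all__ = [
    "BEAD_ALPHABET",
    "BEAD_CODES",
    "DEFAULT_SEQUENCE",
    "EMPTY",
    "SURF",
    "LatticeError",
    "InvalidStateError",
    "PlacementError",
    "parse_sequence",
    "sequence_str",
    "SimulationBox",
    "neighbors",
    "adjacent",
    "SystemState",
    "build_occupancy",
    "occupancy_entries",
    "default_box",
    "place_random_chains",
    "write_extxyz",
]
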