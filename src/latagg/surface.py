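"""Smooth and rough surfaces and their roughness statistics.

A surface is a plane of fixed beads at z = 0 (hydrophilic Ps or hydrophobic
Hs chemistry) plus, for rough surfaces, balls stacked on randomly chosen
columns: single balls at z = 1 (S style), rigid double balls at z = 1 and
z = 2 (D style), or an equal mix (DS style).  The column height field
h in {0, 1, 2} fully describes the geometry.

Roughness statistics over the Ns = Lx*Ly columns:

    h_bar = sum(h_i) / Ns                 (mean ball height)
    Theta = sqrt(sum((h_i - h_bar)^2)/Ns) (population standard deviation)
    Omega = N_b / Ns                      (fraction of columns with balls)

For exact coverage these reduce to closed forms: Theta = sqrt(Om(1-Om))
for S, 2*sqrt(Om(1-Om)) for D, and sqrt(2.5*Om - 2.25*Om^2) for DS at an
exact equal split, which the Theta-parameterised scans invert.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Optional, TextIO, Union

import numpy as np

STYLES = ("smooth", "S", "D", "DS")
CHEMISTRIES = ("Ps", "Hs")


class SurfaceError(ValueError):
    pass


@dataclass
class SurfaceProfile:
    """2-D height field with ball chemistry; generation seed kept for replay."""

    heights: np.ndarray  # (Lx, Ly) int8, values in {0, 1, 2}
    chemistry: str  # "Ps" (hydrophilic) | "Hs" (hydrophobic)
    style: str  # "smooth" | "S" | "D" | "DS"
    omega: float  # requested ball-column fraction
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=np.int8)
        if self.heights.ndim != 2:
            raise SurfaceError("heights must be a 2-D field")
        if self.chemistry not in CHEMISTRIES:
            raise SurfaceError(f"unknown chemistry {self.chemistry!r}")
        if self.style not in STYLES:
            raise SurfaceError(f"unknown surface style {self.style!r}")
        if self.heights.size and (self.heights.min() < 0 or self.heights.max() > 2):
            raise SurfaceError("heights must lie in {0, 1, 2}")

    @property
    def dims(self) -> tuple[int, int]:
        return self.heights.shape  # type: ignore[return-value]

    @property
    def n_sites(self) -> int:
        return self.heights.size

    @property
    def n_ball_columns(self) -> int:
        return int(np.count_nonzero(self.heights))

    def sites(self) -> np.ndarray:
        """All occupied 3-D sites: the z = 0 plane plus every ball."""
        Lx, Ly = self.dims
        xs, ys = np.meshgrid(np.arange(Lx), np.arange(Ly), indexing="ij")
        plane = np.stack([xs.ravel(), ys.ravel(), np.zeros(Lx * Ly, int)], axis=1)
        parts = [plane]
        for z in (1, 2):
            cols = np.argwhere(self.heights >= z)
            if len(cols):
                parts.append(
                    np.concatenate([cols, np.full((len(cols), 1), z)], axis=1)
                )
        return np.concatenate(parts, axis=0).astype(np.int64)


@dataclass(frozen=True)
class RoughnessStats:
    h_bar: float
    theta: float
    omega: float
    n_ball_columns: int
    n_sites: int


def generate_profile(
    style: str,
    omega: float,
    dims: tuple[int, int],
    chemistry: str = "Ps",
    seed: Optional[int] = 0,
) -> SurfaceProfile:
    """Random surface profile with round(omega * Ns) ball columns.

    Columns are sampled uniformly without replacement.  For DS, the ball
    columns are split equally between single and double balls, an odd
    budget assigning the extra column to the single-ball type.  The same
    seed reproduces the height field bit for bit.
    """
    if style not in STYLES:
        raise SurfaceError(f"unknown surface style {style!r}")
    if not 0.0 <= omega <= 1.0:
        raise SurfaceError("omega must lie in [0, 1]")
    Lx, Ly = int(dims[0]), int(dims[1])
    if Lx <= 0 or Ly <= 0:
        raise SurfaceError("surface dimensions must be positive")
    heights = np.zeros((Lx, Ly), dtype=np.int8)
    n_sites = Lx * Ly
    n_b = int(round(omega * n_sites))
    if style == "smooth" or n_b == 0:
        return SurfaceProfile(heights, chemistry, style, omega, seed)
    rng = np.random.default_rng(seed)
    cols = rng.choice(n_sites, size=n_b, replace=False)
    flat = heights.ravel()
    if style == "S":
        flat[cols] = 1
    elif style == "D":
        flat[cols] = 2
    else:  # DS: first half of the draw order is S-type (gets the odd extra)
        n_d = n_b // 2
        flat[cols[: n_b - n_d]] = 1
        flat[cols[n_b - n_d :]] = 2
    return SurfaceProfile(heights, chemistry, style, omega, seed)


def roughness_stats(profile: SurfaceProfile) -> RoughnessStats:
    h = profile.heights.astype(float).ravel()
    h_bar = float(h.mean())
    theta = float(np.sqrt(np.mean((h - h_bar) ** 2)))
    return RoughnessStats(
        h_bar=h_bar,
        theta=theta,
        omega=profile.n_ball_columns / profile.n_sites,
        n_ball_columns=profile.n_ball_columns,
        n_sites=profile.n_sites,
    )


def theta_closed_form(style: str, omega: float) -> float:
    """Roughness at exact coverage omega for each ball arrangement."""
    if style == "smooth" or omega == 0.0:
        return 0.0
    if style == "S":
        return float(np.sqrt(omega * (1.0 - omega)))
    if style == "D":
        return 2.0 * float(np.sqrt(omega * (1.0 - omega)))
    if style == "DS":
        return float(np.sqrt(2.5 * omega - 2.25 * omega**2))
    raise SurfaceError(f"unknown surface style {style!r}")


# Largest Theta reachable with the smaller-root (Omega <= peak) branch.
_THETA_MAX = {"S": 0.5, "D": 1.0, "DS": 5.0 / 6.0}


def solve_coverage_for_roughness(style: str, theta: float) -> float:
    """Invert the closed form: the smaller coverage root giving ``theta``.

    Used by Theta-parameterised scans; the realised roughness of a generated
    profile then matches ``theta`` up to the round(omega * Ns)
    discretisation.
    """
    if theta < 0:
        raise SurfaceError("theta must be >= 0")
    if theta == 0.0:
        return 0.0
    if style not in _THETA_MAX:
        raise SurfaceError(f"style {style!r} has no roughness to solve for")
    tmax = _THETA_MAX[style]
    if theta > tmax + 1e-12:
        raise SurfaceError(
            f"theta={theta} unattainable for style {style} (max {tmax:.4f})"
        )
    t2 = min(theta, tmax) ** 2
    if style == "S":
        disc = max(0.0, 1.0 - 4.0 * t2)
        return (1.0 - np.sqrt(disc)) / 2.0
    if style == "D":
        disc = max(0.0, 1.0 - t2)
        return (1.0 - np.sqrt(disc)) / 2.0
    disc = max(0.0, 6.25 - 9.0 * t2)
    return (2.5 - np.sqrt(disc)) / 4.5


def write_profile(fh: Union[TextIO, str], profile: SurfaceProfile) -> None:
    """Plain-text profile dump: header line + height grid, for exact replay."""
    own = isinstance(fh, str)
    out = open(fh, "w") if own else fh
    try:
        Lx, Ly = profile.dims
        seed = "none" if profile.seed is None else profile.seed
        out.write(
            f"# latagg-surface dims={Lx}x{Ly} style={profile.style} "
            f"chemistry={profile.chemistry} omega={profile.omega!r} seed={seed}\n"
        )
        for row in profile.heights:
            out.write(" ".join(str(int(v)) for v in row) + "\n")
    finally:
        if own:
            out.close()


def read_profile(fh: Union[TextIO, str]) -> SurfaceProfile:
    own = isinstance(fh, str)
    inp = open(fh) if own else fh
    try:
        header = inp.readline().strip()
        if not header.startswith("# latagg-surface"):
            raise SurfaceError("not a latagg surface profile file")
        fields = dict(tok.split("=", 1) for tok in header.split()[2:])
        heights = np.loadtxt(io.StringIO(inp.read()), dtype=np.int8, ndmin=2)
        seed = None if fields["seed"] == "none" else int(fields["seed"])
        return SurfaceProfile(
            heights=heights,
            chemistry=fields["chemistry"],
            style=fields["style"],
            omega=float(fields["omega"]),
            seed=seed,
        )
    finally:
        if own:
            inp.close()


__all__ = [
    "STYLES",
    "CHEMISTRIES",
    "SurfaceError",
    "SurfaceProfile",
    "RoughnessStats",
    "generate_profile",
    "roughness_stats",
    "theta_closed_form",
    "solve_coverage_for_roughness",
    "write_profile",
    "read_profile",
]
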