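"""Lattice polymer generators: fractal globules and equilibrium globules.

The fractal (crumpled) globule is produced by conformation-dependent
polymerization (CDP): a self-avoiding walk on the cubic lattice whose next
step is biased toward crowded sites, weighting each unoccupied candidate
neighbour by ``1 + A * n`` (``n`` = its number of occupied neighbours) and
each occupied candidate by ``epsilon`` (a rejected attempt).  With the
defaults ``A = 1e4`` and ``epsilon = 1e-4`` this yields compact,
space-filling conformations whose contact probability decays as ``s**-1``
and whose end-to-end distance grows as ``s**(1/3)``.

The equilibrium globule — the reference state — is a self-avoiding walk
confined to a sphere, sampled uniformly by a slithering-snake plus kink-flip
Monte Carlo; it shows ideal-chain ``s**(1/2)`` scaling at short contour
separations and a plateau at the confinement size.

Off-lattice variants for contact registration come from bond-preserving
crankshaft annealing (see :func:`anneal_snapshots`).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels

#: excluded-volume diameter used off-lattice, in units of the bond length
HARD_CORE_FRACTION = 0.8

#: default site-filling fraction for the equilibrium globule's sphere;
#: tighter spheres push the confinement plateau of R(s) into the
#: intermediate-s window, hiding the ideal-chain regime
EG_FILL_FRACTION = 0.25


class GenerationError(RuntimeError):
    """Chain growth or equilibration could not complete."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Conformation:
    """Ordered 3D coordinates of a polymer chain.

    ``coords`` is an (N, 3) float array in lattice units; consecutive rows
    are bonded monomers at distance ``bond_length``.
    """

    coords: np.ndarray
    lattice_flag: bool = True
    bond_length: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.coords, axis=0), axis=1)

    def check(self, tol: float = 1e-6) -> None:
        """Assert bond-length and self-avoidance invariants; raise otherwise."""
        bl = self.bond_lengths()
        if self.n >= 2 and not np.allclose(bl, self.bond_length, atol=tol):
            raise ValueError(
                f"bond lengths deviate from {self.bond_length}: "
                f"range [{bl.min():.6f}, {bl.max():.6f}]"
            )
        if self.lattice_flag:
            sites = np.round(self.coords).astype(np.int64)
            if not np.array_equal(sites, self.coords):
                raise ValueError("lattice_flag set but coordinates not integer")
            uniq = np.unique(sites, axis=0)
            if uniq.shape[0] != self.n:
                raise ValueError("on-lattice conformation is not self-avoiding")
        else:
            min_d = HARD_CORE_FRACTION * self.bond_length
            tree = cKDTree(self.coords)
            pairs = tree.query_pairs(r=min_d - 1e-9)
            if pairs:
                raise ValueError(
                    f"off-lattice self-avoidance violated for {len(pairs)} pairs"
                )


@dataclass
class CdpParams:
    """Parameters of the conformation-dependent polymerization growth."""

    N: int
    A: float = 1e4
    epsilon: float = 1e-4
    seed: int = 0
    box_size: Optional[int] = None  # confining cube side; None = free growth

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.A < 0:
            raise ValueError("A must be >= 0")
        if not 0 < self.epsilon <= 1:
            raise ValueError("epsilon must be in (0, 1]")
        if self.box_size is not None and self.box_size ** 3 < self.N:
            raise ValueError(
                f"lattice capacity {self.box_size ** 3} < N = {self.N}"
            )


@dataclass
class AnnealParams:
    """Parameters of the off-lattice crankshaft randomization."""

    n_snapshots: int = 1000
    displacement_scale: float = 1.0
    n_moves_per_snapshot: Optional[int] = None  # default: one sweep (N moves)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snapshots < 1:
            raise ValueError("n_snapshots must be >= 1")
        if self.displacement_scale < 0:
            raise ValueError("displacement_scale must be >= 0")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_cdp(params: CdpParams) -> Conformation:
    """Grow a fractal globule by conformation-dependent polymerization.

    Returns an on-lattice self-avoiding walk of ``params.N`` monomers.
    Raises :class:`GenerationError` if growth cannot complete within the
    bounded backtrack/restart budget, and ``ValueError`` if the requested
    chain exceeds the lattice capacity.
    """
    if params.box_size is not None:
        side = int(params.box_size)
        random_start = True
    else:
        # free growth stays compact; size the grid generously around the blob
        side = 2 * (int(math.ceil(params.N ** (1.0 / 3.0))) + 10)
        random_start = False
    coords, ok = _kernels.grow_chain(
        params.N, float(params.A), float(params.epsilon), side, -1.0,
        random_start, int(params.seed) & 0x7FFFFFFF,
        10, 100, 200,
    )
    if not ok:
        raise GenerationError(
            f"CDP growth failed for N={params.N} after bounded restarts"
        )
    conf = Conformation(coords.astype(float), lattice_flag=True,
                        bond_length=1.0,
                        meta={"model": "cdp", "N": params.N, "A": params.A,
                              "epsilon": params.epsilon, "seed": params.seed,
                              "box_size": params.box_size})
    return conf


def eg_radius(N: int, fill: float = EG_FILL_FRACTION) -> float:
    """Sphere radius (lattice units) holding ``N`` monomers at site-filling
    fraction ``fill``."""
    return (3.0 * N / (4.0 * math.pi * fill)) ** (1.0 / 3.0)


def radius_from_fg(fg: "Conformation", convention: str = "diameter_rg") -> float:
    """Confinement radius for an equilibrium globule companion to ``fg``.

    ``diameter_rg`` reads "a volume with the same diameter as the fractal
    globule's radius of gyration" literally (sphere diameter = R_g, i.e.
    radius = R_g / 2); ``diameter_2rg`` uses the globule's full extent
    (radius = R_g).  Note that on-lattice both can be too small to host the
    chain at one monomer per site; see :func:`eg_radius` for a
    density-feasible choice.
    """
    from .analysis import radius_of_gyration

    rg = radius_of_gyration(fg)
    if convention == "diameter_rg":
        return rg / 2.0
    if convention == "diameter_2rg":
        return rg
    raise ValueError(f"unknown convention {convention!r}")


def generate_equilibrium_globule(
    N: int,
    radius: Optional[float] = None,
    seed: int = 0,
    n_attempts: Optional[int] = None,
    p_reptation: float = 0.8,
) -> Conformation:
    """Sample an equilibrium globule: a self-avoiding walk confined to a
    sphere, equilibrated by slithering-snake and kink-flip Monte Carlo.

    ``radius`` defaults to the sphere that holds ``N`` monomers at a
    site-filling fraction of 0.25, comparable to the internal density of a
    grown fractal globule.  ``n_attempts`` defaults to ``15 * N**2``
    attempted moves, several reptation renewal times of the chain, after
    which end-to-end statistics are stationary.

    Raises ``ValueError`` when the sphere cannot host the chain.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if radius is None:
        radius = eg_radius(N)
    # count lattice sites inside the sphere
    r_int = int(math.floor(radius))
    side = 2 * r_int + 5
    c = side // 2
    ax = np.arange(side)
    d2 = ((ax - c)[:, None, None] ** 2 + (ax - c)[None, :, None] ** 2
          + (ax - c)[None, None, :] ** 2)
    capacity = int((d2 <= radius ** 2).sum())
    if capacity < N:
        raise ValueError(
            f"sphere of radius {radius:.2f} holds {capacity} lattice sites "
            f"< N = {N}; density too high"
        )
    # initial compact configuration grown inside the sphere
    coords, ok = _kernels.grow_chain(
        N, 1e4, 1e-4, side, float(radius) ** 2, False,
        (int(seed) * 2 + 1) & 0x7FFFFFFF, 10, 100, 400,
    )
    if not ok:
        raise GenerationError(
            f"could not seed an initial chain of N={N} in radius {radius:.2f}"
        )
    if n_attempts is None:
        n_attempts = 15 * N * N
    out, accepted = _kernels.equilibrate_snake(
        coords, side, float(radius) ** 2, int(n_attempts),
        float(p_reptation), int(seed) & 0x7FFFFFFF,
    )
    center = np.array([c, c, c], dtype=float)
    conf = Conformation(out.astype(float) - center, lattice_flag=True,
                        bond_length=1.0,
                        meta={"model": "eg", "N": N, "radius": radius,
                              "seed": seed, "n_attempts": int(n_attempts),
                              "accepted": int(accepted)})
    return conf


def anneal_snapshots(conf: Conformation, params: AnnealParams) -> List[Conformation]:
    """Randomize ``conf`` off-lattice and return annealing snapshots.

    Each snapshot preserves every bond length exactly (crankshaft moves) and
    self-avoidance at the hard-core diameter ``0.8 * bond_length``; monomer
    order is unchanged.  Snapshots are verified before being returned.
    """
    n_moves = params.n_moves_per_snapshot
    if n_moves is None:
        n_moves = conf.n
    hard_core = HARD_CORE_FRACTION * conf.bond_length
    snaps = _kernels.anneal_chain(
        np.ascontiguousarray(conf.coords, dtype=float),
        int(params.n_snapshots), int(n_moves),
        float(params.displacement_scale), float(hard_core),
        int(params.seed) & 0x7FFFFFFF,
    )
    out = []
    for s in range(snaps.shape[0]):
        snap = Conformation(snaps[s], lattice_flag=False,
                            bond_length=conf.bond_length,
                            meta={**conf.meta, "annealed": True,
                                  "snapshot": s, "anneal_seed": params.seed})
        snap.check(tol=1e-6)
        out.append(snap)
    return out


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------

def write_xyz(conf: Conformation, path) -> None:
    """Write a conformation as 3-column text, one monomer per line, with the
    generation metadata in ``#`` header comments."""
    with open(path, "w") as fh:
        fh.write(f"# bond_length={conf.bond_length}\n")
        fh.write(f"# lattice={int(conf.lattice_flag)}\n")
        for key, val in sorted(conf.meta.items()):
            fh.write(f"# {key}={val}\n")
        np.savetxt(fh, conf.coords, fmt="%.10g")


def read_xyz(path) -> Conformation:
    """Read a conformation written by :func:`write_xyz`."""
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, val = body.split("=", 1)
                    meta[key.strip()] = val.strip()
                continue
            rows.append(line)
    coords = np.loadtxt(io.StringIO("\n".join(rows)), ndmin=2)
    bond = float(meta.pop("bond_length", 1.0))
    lattice = bool(int(meta.pop("lattice", 1)))
    return Conformation(coords, lattice_flag=lattice, bond_length=bond,
                        meta=meta)


def ensemble(
    factory,
    n_chains: int,
    seed: int,
) -> List[Conformation]:
    """Generate ``n_chains`` conformations with independent seed streams
    derived from ``seed`` via ``factory(chain_seed)``."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(n_chains)]
    return [factory(s) for s in seeds]
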