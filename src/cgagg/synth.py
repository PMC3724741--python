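"""Synthetic trajectory generation with known ground truth.

Three generators emulate the statistical structure of coarse-grained
membrane-aggregation simulations so that every analysis stage in this
package can be validated without external trajectory data:

* :func:`simulate_sticky_brownian` — membrane-anchored proteins performing
  quasi-2D Brownian motion with irreversible cluster merging and
  size-dependent mobility (cluster D = d_free * size**-alpha),
* :func:`generate_domain_field` — a ternary DPPC/DLiPC/CHOL bead field that
  interpolates between fully mixed and a striped, de-mixed state,
* :func:`make_sasa_fixture` — bead arrangements with analytically known
  solvent-accessible surface area.

All randomness flows from a single integer seed per call; repeated calls
with the same configuration are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np

from .core import (
    BeadRole,
    D_UNIT_NM2_PER_NS,
    DEFAULT_BEAD_RADIUS,
    GeometryError,
    MoleculeType,
    Topology,
    Trajectory,
    TrajectoryFrame,
    wrap_positions,
)
from .sasa import sphere_points

__all__ = [
    "StickySimConfig",
    "DomainFieldConfig",
    "GroundTruth",
    "simulate_sticky_brownian",
    "generate_domain_field",
    "generate_demixing_trajectory",
    "make_sasa_fixture",
    "protein_blob_offsets",
]


# ---------------------------------------------------------------------------
# sticky Brownian aggregation
# ---------------------------------------------------------------------------

@dataclass
class StickySimConfig:
    """Study conditions for the aggregation generator.

    Defaults mirror the reference bilayer system: 32 full-length proteins of
    186 residues in a 44 nm x 46 nm periodic plane, monomer lateral diffusion
    10.5 (units of 1e-8 cm^2/s), frames every 4 ns, sticking at the 0.75 nm
    contact cutoff, and Stokes-like cluster slowdown (alpha = 1).
    """

    n_proteins: int = 32
    n_residues: int = 186
    d_free: float = 10.5          # 1e-8 cm^2/s
    dt: float = 4.0               # ns, frame spacing == step size
    n_steps: int = 250
    box_xy: tuple[float, float] = (44.0, 46.0)
    box_z: float = 14.0
    bind_radius: float = 0.75     # nm; 0 disables sticking
    size_exponent: float = 1.0    # cluster D ~ size**-alpha
    blob_radius: float = 1.0      # nm, protein bead-blob radius
    min_separation: float = 5.0   # nm, initial nearest-neighbor distance
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.d_free < 0:
            raise ValueError("d_free must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.bind_radius < 0:
            raise ValueError("bind_radius must be >= 0")

    @property
    def d_free_nm2ns(self) -> float:
        return self.d_free * D_UNIT_NM2_PER_NS


@dataclass
class GroundTruth:
    """Sidecar record of the generator's true state, kept unwrapped."""

    times: np.ndarray                 # (n_frames,)
    labels: np.ndarray                # (n_frames, n_proteins) canonical labels
    centers_unwrapped: np.ndarray     # (n_frames, n_proteins, 3)
    merge_events: list[tuple[float, int, int]]   # (time, label_a, label_b)
    d_free: float                     # 1e-8 cm^2/s
    config: StickySimConfig

    @property
    def n_clusters(self) -> np.ndarray:
        return np.array([len(np.unique(l)) for l in self.labels])

    def to_json(self, path) -> None:
        payload = {
            "times": self.times.tolist(),
            "labels": self.labels.tolist(),
            "centers_unwrapped": self.centers_unwrapped.tolist(),
            "merge_events": [list(e) for e in self.merge_events],
            "d_free": self.d_free,
            "config": asdict(self.config),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def protein_blob_offsets(n_residues: int, radius: float) -> np.ndarray:
    """Deterministic rigid-blob bead offsets filling a ball of given radius.

    One bead per residue; a single-residue protein collapses to its center.
    """
    if n_residues == 1:
        return np.zeros((1, 3))
    shells = sphere_points(n_residues)
    # cube-root radial spacing fills the ball with near-uniform density
    radial = radius * ((np.arange(n_residues) + 0.5) / n_residues) ** (1.0 / 3.0)
    return shells * radial[:, None]


def _initial_grid(n: int, box_xy, min_separation: float) -> np.ndarray:
    bx, by = box_xy
    nx = int(np.ceil(np.sqrt(n * bx / by)))
    ny = int(np.ceil(n / nx))
    while nx * ny < n:
        ny += 1
    sx, sy = bx / nx, by / ny
    if min(sx, sy) < min_separation:
        raise ValueError(
            f"cannot place {n} proteins with >= {min_separation} nm "
            f"separation in a {bx} x {by} nm box")
    pts = [((i + 0.5) * sx, (j + 0.5) * sy)
           for j in range(ny) for i in range(nx)][:n]
    return np.array(pts)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[max(ri, rj)] = min(ri, rj)
        return True


def _canonical_labels(uf: _UnionFind, n: int) -> np.ndarray:
    roots = np.array([uf.find(i) for i in range(n)])
    # canonical label of a cluster = smallest member id; roots already are
    # minimal because union always keeps the smaller root
    return roots


def simulate_sticky_brownian(
    config: StickySimConfig,
) -> tuple[Trajectory, GroundTruth]:
    """Quasi-2D sticky Brownian aggregation with rigid protein blobs.

    Each protein is a rigid blob of ``n_residues`` backbone beads translated
    with its center.  Clusters move rigidly with D = d_free * size**-alpha;
    two clusters merge irreversibly as soon as any two member centers come
    within ``bind_radius`` (minimum-image, in-plane).  Emitted frames are
    wrapped into the box; the ground-truth record keeps unwrapped centers.
    """
    cfg = config
    n = cfg.n_proteins
    d_nm = cfg.d_free_nm2ns
    sigma_free = np.sqrt(2.0 * d_nm * cfg.dt)
    box3 = np.array([cfg.box_xy[0], cfg.box_xy[1], cfg.box_z])
    if sigma_free > min(cfg.box_xy) / 4:
        raise GeometryError(
            f"per-step rms displacement {sigma_free:.3g} nm exceeds a quarter "
            f"of the box; reduce dt or d_free")

    rng = np.random.default_rng(cfg.seed)
    xy = _initial_grid(n, cfg.box_xy, cfg.min_separation)
    z = np.full(n, cfg.box_z / 2.0)
    centers = np.column_stack([xy, z])       # unwrapped
    offsets = protein_blob_offsets(cfg.n_residues, cfg.blob_radius)

    uf = _UnionFind(n)
    merge_events: list[tuple[float, int, int]] = []
    box_xy_arr = np.asarray(cfg.box_xy, dtype=float)

    def do_merges(t: float) -> None:
        if cfg.bind_radius <= 0:
            return
        # brute-force center pair scan; n is small by construction
        for i in range(n):
            d = centers[i + 1:, :2] - centers[i, :2]
            d -= box_xy_arr * np.round(d / box_xy_arr)
            close = np.nonzero(np.einsum("ij,ij->i", d, d)
                               <= cfg.bind_radius ** 2)[0]
            for k in close:
                j = i + 1 + int(k)
                ri, rj = uf.find(i), uf.find(j)
                if ri != rj:
                    merge_events.append((t, min(ri, rj), max(ri, rj)))
                    uf.union(i, j)

    times = []
    all_labels = []
    all_centers = []
    frames = []

    def emit(t: float) -> None:
        times.append(t)
        labels = _canonical_labels(uf, n)
        all_labels.append(labels.copy())
        all_centers.append(centers.copy())
        beads = (centers[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
        frames.append(TrajectoryFrame(
            time=t, box=box3, positions=wrap_positions(beads, box3)))

    do_merges(0.0)
    emit(0.0)
    for step in range(1, cfg.n_steps + 1):
        t = step * cfg.dt
        labels = _canonical_labels(uf, n)
        uniq, inverse, sizes = np.unique(
            labels, return_inverse=True, return_counts=True)
        d_cluster = d_nm * sizes.astype(float) ** (-cfg.size_exponent)
        step_xy = rng.normal(
            0.0, np.sqrt(2.0 * d_cluster * cfg.dt)[:, None], size=(len(uniq), 2))
        centers[:, :2] += step_xy[inverse]
        do_merges(t)
        emit(t)

    topo = _protein_topology(n, cfg.n_residues)
    traj = Trajectory(frames, topo)
    truth = GroundTruth(
        times=np.array(times),
        labels=np.array(all_labels),
        centers_unwrapped=np.array(all_centers),
        merge_events=merge_events,
        d_free=cfg.d_free,
        config=cfg,
    )
    return traj, truth


def _protein_topology(n_proteins: int, n_residues: int,
                      radius: float = DEFAULT_BEAD_RADIUS) -> Topology:
    n = n_proteins * n_residues
    return Topology(
        molecule_id=np.repeat(np.arange(n_proteins), n_residues),
        molecule_type=np.full(n, MoleculeType.PROTEIN.value),
        residue_index=np.tile(np.arange(1, n_residues + 1), n_proteins),
        bead_role=np.full(n, BeadRole.BACKBONE.value),
        bead_radius=np.full(n, radius),
    )


# ---------------------------------------------------------------------------
# lipid domain field
# ---------------------------------------------------------------------------

@dataclass
class DomainFieldConfig:
    """Ternary lipid field conditions; defaults are the reference bilayer's
    3480 DPPC / 2304 DLiPC / 1536 CHOL beads (5:3:2) in a 44 x 46 nm plane."""

    n_dppc: int = 3480
    n_dlipc: int = 2304
    n_chol: int = 1536
    stripe_fraction: float = 0.3
    mixing_noise: float = 0.3     # nm positional jitter
    box_xy: tuple[float, float] = (44.0, 46.0)
    box_z: float = 14.0
    leaflet_offset: float = 1.0   # nm above/below bilayer midplane
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_dppc, self.n_dlipc, self.n_chol) < 0:
            raise ValueError("lipid counts must be >= 0")
        if not 0.0 <= self.stripe_fraction <= 1.0:
            raise ValueError("stripe_fraction must lie in [0, 1]")


def generate_domain_field(
    config: DomainFieldConfig,
    demix_progress: float,
    first_molecule_id: int = 0,
) -> tuple[TrajectoryFrame, Topology]:
    """One-bead-per-lipid ternary field at a given de-mixing stage.

    At ``demix_progress = 0`` all species are uniformly mixed; at 1 the
    DLiPC beads occupy a stripe of width ``stripe_fraction * box_x`` and
    DPPC/CHOL the remainder, modulo ``mixing_noise`` jitter.  Intermediate
    values set the per-bead probability of domain-respecting placement.
    Beads split evenly between two leaflets at z = mid +/- leaflet_offset.
    """
    if not 0.0 <= demix_progress <= 1.0:
        raise ValueError("demix_progress must lie in [0, 1]")
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    bx, by = cfg.box_xy
    x_edge = cfg.stripe_fraction * bx
    box3 = np.array([bx, by, cfg.box_z])

    species = [
        (MoleculeType.DLIPC.value, cfg.n_dlipc, True),
        (MoleculeType.DPPC.value, cfg.n_dppc, False),
        (MoleculeType.CHOL.value, cfg.n_chol, False),
    ]
    pos_list, type_list = [], []
    for name, count, in_stripe in species:
        if count == 0:
            continue
        demixed = rng.random(count) < demix_progress
        x = rng.uniform(0.0, bx, count)
        if in_stripe:
            x[demixed] = rng.uniform(0.0, x_edge, int(demixed.sum()))
        else:
            x[demixed] = rng.uniform(x_edge, bx, int(demixed.sum()))
        y = rng.uniform(0.0, by, count)
        if cfg.mixing_noise > 0:
            # bounded jitter: a bead never strays more than mixing_noise
            # from its assigned spot, so domain membership stays auditable
            x = x + rng.uniform(-cfg.mixing_noise, cfg.mixing_noise, count)
            y = y + rng.uniform(-cfg.mixing_noise, cfg.mixing_noise, count)
        z_mid = cfg.box_z / 2.0
        leaflet = np.where(np.arange(count) % 2 == 0, 1.0, -1.0)
        z = z_mid + leaflet * cfg.leaflet_offset
        pos_list.append(np.column_stack([x, y, z]))
        type_list.append(np.full(count, name))

    pos = wrap_positions(np.concatenate(pos_list), box3)
    types = np.concatenate(type_list)
    n = len(types)
    topo = Topology(
        molecule_id=first_molecule_id + np.arange(n),
        molecule_type=types,
        residue_index=np.ones(n, dtype=int),
        bead_role=np.full(n, BeadRole.HEADGROUP.value),
        bead_radius=np.full(n, DEFAULT_BEAD_RADIUS),
    )
    frame = TrajectoryFrame(time=0.0, box=box3, positions=pos)
    return frame, topo


def generate_demixing_trajectory(
    config: DomainFieldConfig,
    n_frames: int,
    dt: float = 4.0,
) -> Trajectory:
    """Lipid field de-mixing linearly from mixed (frame 0) to striped."""
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    frames = []
    topo = None
    for k in range(n_frames):
        progress = k / (n_frames - 1)
        cfg = DomainFieldConfig(**{**asdict(config),
                                   "seed": config.seed + k})
        cfg.box_xy = tuple(cfg.box_xy)
        frame, topo = generate_domain_field(cfg, progress)
        frames.append(TrajectoryFrame(time=k * dt, box=frame.box,
                                      positions=frame.positions))
    return Trajectory(frames, topo)


# ---------------------------------------------------------------------------
# SASA fixtures
# ---------------------------------------------------------------------------

def make_sasa_fixture(
    kind: Literal["single_sphere", "two_spheres", "buried_core"],
    radius: float = DEFAULT_BEAD_RADIUS,
    separation: float = 1.0,
    n_shell: int = 60,
    shell_distance: float = 0.5,
    box_edge: float = 30.0,
) -> tuple[TrajectoryFrame, Topology]:
    """Bead arrangements with analytically known SASA.

    ``single_sphere``: one bead (SASA = 4*pi*(r+probe)^2).
    ``two_spheres``: two beads at the given center separation (closed-form
    lens-overlap correction).
    ``buried_core``: one central bead enclosed by ``n_shell`` beads at
    ``shell_distance`` — the core's SASA is exactly zero for any probe not
    smaller than the shell spacing allows.
    """
    c = box_edge / 2.0
    if kind == "single_sphere":
        pos = np.array([[c, c, c]])
    elif kind == "two_spheres":
        if separation < 0:
            raise ValueError("separation must be >= 0")
        pos = np.array([[c - separation / 2, c, c],
                        [c + separation / 2, c, c]])
    elif kind == "buried_core":
        shell = c + sphere_points(n_shell) * shell_distance
        pos = np.vstack([[[c, c, c]], shell])
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")

    n = len(pos)
    topo = Topology(
        molecule_id=np.arange(n),
        molecule_type=np.full(n, MoleculeType.OTHER.value),
        residue_index=np.ones(n, dtype=int),
        bead_role=np.full(n, BeadRole.OTHER.value),
        bead_radius=np.full(n, radius),
    )
    frame = TrajectoryFrame(time=0.0, box=np.full(3, box_edge), positions=pos)
    return frame, topo
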