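"""Lateral diffusion from mean-square displacement (Einstein relation).

The workflow is: unwrap per-molecule center-of-mass tracks from wrapped
periodic coordinates, compute the time-origin-averaged lateral MSD
MSD(t) = <|r_i(tau0 + t) - r_i(tau0)|^2> over molecules i and all origins
tau0, and fit D = slope / (2 d) with d = 2 for in-plane diffusion.
Uncertainties come from block averaging over molecules: the ensemble is
split into blocks, D refit per block, and the spread of block estimates
reported.

Internally lengths are nm and times ns; reported D is in the conventional
1e-8 cm^2/s (1e-3 nm^2/ns per unit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    AnalysisWindow,
    D_UNIT_NM2_PER_NS,
    MoleculeType,
    Topology,
    Trajectory,
    minimum_image,
)

__all__ = [
    "Tracks",
    "MsdProfile",
    "DiffusionEstimate",
    "unwrap_trajectory",
    "msd_profile",
    "fit_diffusion",
]


class UndersamplingError(ValueError):
    """A molecule moved too far between frames for unambiguous unwrapping."""


@dataclass
class Tracks:
    """Continuous (unwrapped) per-molecule center-of-mass tracks."""

    times: np.ndarray          # (n_frames,)
    positions: np.ndarray      # (n_frames, n_molecules, 3), unwrapped
    molecule_ids: np.ndarray   # (n_molecules,)

    @property
    def n_molecules(self) -> int:
        return self.positions.shape[1]

    def window(self, win: AnalysisWindow) -> "Tracks":
        keep = (self.times >= win.t_start - 1e-9) \
            & (self.times <= win.t_end + 1e-9)
        if keep.sum() < 2:
            raise ValueError(f"window {win} contains fewer than two frames")
        return Tracks(self.times[keep], self.positions[keep],
                      self.molecule_ids)


def unwrap_trajectory(
    traj: Trajectory,
    topo: Topology | None = None,
    selection: str | np.ndarray = "protein",
    max_step_fraction: float = 0.45,
) -> Tracks:
    """Remove periodic jumps from per-molecule center-of-mass motion.

    The center of mass of each selected molecule is formed within each
    frame by unwrapping the molecule's beads around its first bead
    (minimum image), then jumps between consecutive frames are removed by
    accumulating minimum-image inter-frame displacements.

    ``selection`` is either a molecule-type name ("protein", "DPPC", ...)
    or an explicit array of molecule ids.  A per-frame center displacement
    whose magnitude exceeds ``max_step_fraction`` of a box edge is rejected
    as undersampled (the minimum-image convention can no longer be trusted
    to identify the true displacement).
    """
    topo = topo if topo is not None else traj.topology
    if topo is None:
        raise ValueError("a topology is required")
    if isinstance(selection, str):
        sel_type = MoleculeType(selection.upper()).value
        mol_ids = np.unique(topo.molecule_id[topo.molecule_type == sel_type])
    else:
        mol_ids = np.asarray(selection)
    if len(mol_ids) == 0:
        raise ValueError(f"selection {selection!r} matches no molecules")

    bead_groups = [np.nonzero(topo.molecule_id == m)[0] for m in mol_ids]
    n_frames = len(traj)
    coms = np.empty((n_frames, len(mol_ids), 3))
    for f, fr in enumerate(traj):
        box = fr.box
        for k, beads in enumerate(bead_groups):
            ref = fr.positions[beads[0]]
            disp = minimum_image(ref, fr.positions[beads], box)
            coms[f, k] = ref + disp.mean(axis=0)

    out = np.empty_like(coms)
    out[0] = coms[0]
    times = traj.times
    for f in range(1, n_frames):
        box = traj[f].box
        step = minimum_image(coms[f - 1], coms[f], box)
        too_far = np.abs(step) > max_step_fraction * box
        if np.any(too_far):
            k = int(np.argwhere(too_far.any(axis=1))[0, 0])
            raise UndersamplingError(
                f"molecule {mol_ids[k]} moved {np.abs(step[k]).max():.2f} nm "
                f"between frames {f - 1} and {f} (t={times[f]:.3f} ns); "
                "frame spacing too coarse for unambiguous unwrapping")
        out[f] = out[f - 1] + step
    return Tracks(times=times, positions=out, molecule_ids=mol_ids)


@dataclass
class MsdProfile:
    """Time-origin-averaged lateral MSD curve."""

    lag_times: np.ndarray     # ns, strictly increasing, starts at 0
    msd: np.ndarray           # nm^2
    n_origins: np.ndarray     # origins averaged per lag
    n_molecules: int
    selection: str = ""

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lag_times) <= 0):
            raise ValueError("lag times must be strictly increasing")
        if np.any(self.msd < 0):
            raise ValueError("MSD cannot be negative")


def msd_profile(
    tracks: Tracks,
    window: AnalysisWindow | None = None,
    max_lag: float | None = None,
) -> MsdProfile:
    """Lateral (xy) MSD averaged over molecules and all time origins.

    ``max_lag`` (ns) defaults to half the window length; it must be shorter
    than the window.
    """
    if window is not None:
        tracks = tracks.window(window)
    t = tracks.times
    if len(t) < 2:
        raise ValueError("MSD needs at least two frames")
    dt = t[1] - t[0]
    span = t[-1] - t[0]
    if max_lag is None:
        max_lag = span / 2
    if max_lag >= span - 1e-9:
        raise ValueError(
            f"max_lag {max_lag} ns must be below the window length {span} ns")
    n_lags = int(np.floor(max_lag / dt + 1e-9))
    xy = tracks.positions[:, :, :2]
    n_frames = xy.shape[0]

    lags = np.arange(n_lags + 1)
    msd = np.zeros(n_lags + 1)
    n_origins = np.zeros(n_lags + 1, dtype=int)
    for k in lags[1:]:
        d = xy[k:] - xy[:-k]
        msd[k] = np.mean(np.einsum("fmi,fmi->fm", d, d))
        n_origins[k] = n_frames - k
    n_origins[0] = n_frames
    return MsdProfile(lag_times=lags * dt, msd=msd, n_origins=n_origins,
                      n_molecules=tracks.n_molecules)


@dataclass
class DiffusionEstimate:
    """Fitted lateral diffusion coefficient in 1e-8 cm^2/s."""

    D: float
    stderr: float                 # std of block estimates; NaN if undefined
    fit_window: tuple[float, float]
    dimensionality: int = 2
    n_blocks: int = 5
    slope_nm2_per_ns: float = 0.0


def _fit_slope(lag: np.ndarray, msd: np.ndarray) -> float:
    return float(np.polyfit(lag, msd, 1)[0])


def fit_diffusion(
    profile: MsdProfile,
    fit_window: tuple[float, float] | None = None,
    d: int = 2,
    tracks: Tracks | None = None,
    window: AnalysisWindow | None = None,
    n_blocks: int = 5,
) -> DiffusionEstimate:
    """Least-squares MSD slope over a lag window; D = slope / (2 d).

    ``fit_window`` is a (lag_min, lag_max) range in ns; the default spans
    10%–50% of the profile's maximum lag, avoiding both the short-lag
    regime and the poorly averaged tail.  When the underlying ``tracks``
    are supplied, a block-averaged uncertainty is attached: molecules are
    split into ``n_blocks`` groups, D refit per group, and the standard
    deviation of the block estimates reported.
    """
    lag = profile.lag_times
    if fit_window is None:
        fit_window = (0.1 * lag[-1], 0.5 * lag[-1])
    lo, hi = fit_window
    keep = (lag >= lo - 1e-9) & (lag <= hi + 1e-9)
    if keep.sum() < 3:
        raise ValueError(
            f"fit window {fit_window} contains fewer than three lag points")
    slope = _fit_slope(lag[keep], profile.msd[keep])
    D_nm = slope / (2.0 * d)
    D_out = D_nm / D_UNIT_NM2_PER_NS

    stderr = float("nan")
    if tracks is not None:
        groups = np.array_split(np.arange(tracks.n_molecules), n_blocks)
        block_Ds = []
        for g in groups:
            if len(g) == 0:
                continue
            sub = Tracks(tracks.times, tracks.positions[:, g],
                         tracks.molecule_ids[g])
            prof = msd_profile(sub, window=window, max_lag=lag[-1])
            k = (prof.lag_times >= lo - 1e-9) & (prof.lag_times <= hi + 1e-9)
            s = _fit_slope(prof.lag_times[k], prof.msd[k])
            block_Ds.append(s / (2.0 * d) / D_UNIT_NM2_PER_NS)
        if len(block_Ds) >= 2:
            stderr = float(np.std(block_Ds, ddof=1))
    return DiffusionEstimate(D=float(D_out), stderr=stderr,
                             fit_window=(float(lo), float(hi)),
                             dimensionality=d, n_blocks=n_blocks,
                             slope_nm2_per_ns=float(slope))
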