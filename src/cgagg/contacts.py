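"""Residue-resolved contact statistics.

Implements the inter-protein contact-probability map P (contact counts
normalized by frames, molecule pairs and the N_r^2 equally likely residue
pairings), high-probability pair extraction, the ensemble contact ratio R,
protein–lipid bead contact counts, lipid-domain preference of proteins, and
the leaflet-resolved DPPC–DLiPC de-mixing contact ratio.

Contacts use backbone-bead distances with a closed cutoff (default 0.75 nm)
under the minimum-image convention.  A residue pair of a molecule pair
counts at most once per frame (binary), since each residue carries exactly
one backbone bead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import ContactCriterion, DEFAULT_CONTACT_CUTOFF_NM
from .core import (
    AnalysisWindow,
    MoleculeType,
    Topology,
    Trajectory,
    TrajectoryFrame,
    periodic_pairs,
)

__all__ = [
    "ContactAccumulator",
    "ContactProbabilityMap",
    "DomainContactStats",
    "accumulate_residue_contacts",
    "contact_probability",
    "high_contact_pairs",
    "contact_ratio_R",
    "protein_lipid_contacts",
    "domain_preference_ratio",
    "demixing_contact_ratio",
    "DEFAULT_HIGH_P_CUTOFF",
]

#: probability threshold used to call a residue pair "high contact"
DEFAULT_HIGH_P_CUTOFF = 10.0e-9

LIPID_TYPES = (MoleculeType.DPPC.value, MoleculeType.DLIPC.value,
               MoleculeType.CHOL.value)


@dataclass
class ContactAccumulator:
    """Symmetric residue-pair contact counts C_ij over a frame window."""

    C: np.ndarray        # (N_r, N_r) symmetric int
    F: int               # frames accumulated
    n_mol: int           # proteins M
    n_residues: int      # N_r

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C)
        if self.C.shape != (self.n_residues, self.n_residues):
            raise ValueError("C must be N_r x N_r")
        if np.any(self.C < 0):
            raise ValueError("contact counts cannot be negative")
        if not np.array_equal(self.C, self.C.T):
            raise ValueError("C must be symmetric")

    @property
    def molecule_pairs(self) -> int:
        return self.n_mol * (self.n_mol - 1) // 2

    def total_per_frame(self) -> float:
        """Total pairwise residue contacts per frame (Eq.-3-style H/F)."""
        if self.F == 0:
            raise ValueError("no frames accumulated")
        upper = np.triu(self.C)          # one physical count per pair
        return float(upper.sum() / self.F)


def accumulate_residue_contacts(
    traj: Trajectory,
    topo: Topology | None = None,
    crit: ContactCriterion = ContactCriterion(),
    window: AnalysisWindow | None = None,
) -> ContactAccumulator:
    """Count inter-protein residue-pair contacts over (a window of) frames.

    For every frame and unordered molecule pair, C_ij gains one count when
    the backbone beads of residue i (one molecule) and residue j (the
    other) are within the cutoff; the count is stored symmetrically.
    Requires every protein to have the same residue count.
    """
    topo = topo if topo is not None else traj.topology
    if topo is None:
        raise ValueError("a topology is required")
    if window is not None:
        traj = traj.window(window)
    sizes = topo.protein_sizes()
    if not sizes:
        raise ValueError("topology contains no proteins")
    n_r = next(iter(sizes.values()))
    if any(s != n_r for s in sizes.values()):
        raise ValueError(
            f"heterogeneous protein sizes {sorted(set(sizes.values()))}; "
            "the residue-pair map is undefined")
    n_mol = len(sizes)

    mask = topo.is_protein & (topo.bead_role == crit.bead_role)
    idx = np.nonzero(mask)[0]
    mol = topo.molecule_id[idx]
    res = topo.residue_index[idx]

    C = np.zeros((n_r, n_r), dtype=np.int64)
    for fr in traj:
        bead_pairs = periodic_pairs(fr.positions, fr.box, crit.cutoff,
                                    subset=idx)
        if len(bead_pairs) == 0:
            continue
        # map bead indices back to (molecule, residue)
        pos_in_sel = np.searchsorted(idx, bead_pairs)
        ma, mb = mol[pos_in_sel[:, 0]], mol[pos_in_sel[:, 1]]
        ra, rb = res[pos_in_sel[:, 0]], res[pos_in_sel[:, 1]]
        keep = ma != mb
        if not np.any(keep):
            continue
        lo_m = np.minimum(ma[keep], mb[keep])
        hi_m = np.maximum(ma[keep], mb[keep])
        lo_r = np.minimum(ra[keep], rb[keep])
        hi_r = np.maximum(ra[keep], rb[keep])
        events = np.unique(
            np.column_stack([lo_m, hi_m, lo_r, hi_r]), axis=0)
        i = events[:, 2] - 1
        j = events[:, 3] - 1
        np.add.at(C, (i, j), 1)
        off = i != j
        np.add.at(C, (j[off], i[off]), 1)
    return ContactAccumulator(C=C, F=len(traj), n_mol=n_mol, n_residues=n_r)


@dataclass
class ContactProbabilityMap:
    """Normalized residue-pair contact probabilities (symmetric)."""

    P: np.ndarray
    n_residues: int
    normalization: float     # F * C(M,2) * N_r^2
    window: AnalysisWindow | None = None
    criterion: ContactCriterion | None = None

    def __post_init__(self) -> None:
        bound = 1.0 / self.n_residues**2
        if np.any(self.P < 0) or np.any(self.P > bound * (1 + 1e-12)):
            raise ValueError(
                f"P must lie in [0, 1/N_r^2] = [0, {bound:.3e}]")


def contact_probability(
    acc: ContactAccumulator,
    window: AnalysisWindow | None = None,
    criterion: ContactCriterion | None = None,
) -> ContactProbabilityMap:
    """P_ij = C_ij / (F * C(M,2) * N_r^2).

    The normalization makes P_ij the probability that a random residue of
    one random molecule and a random residue of a random other molecule are
    the pair (i, j) in contact; a pair in contact in every frame for every
    molecule pair saturates at 1/N_r^2.
    """
    if acc.F == 0:
        raise ValueError("map undefined for zero accumulated frames")
    if acc.n_mol < 2:
        raise ValueError("need at least two molecules")
    norm = acc.F * acc.molecule_pairs * acc.n_residues**2
    return ContactProbabilityMap(P=acc.C / norm, n_residues=acc.n_residues,
                                 normalization=float(norm),
                                 window=window, criterion=criterion)


def high_contact_pairs(
    pmap: ContactProbabilityMap,
    cutoff: float = DEFAULT_HIGH_P_CUTOFF,
) -> list[tuple[int, int, float]]:
    """Residue pairs with P strictly above the cutoff.

    Returns 1-based (i, j, P) with i <= j, sorted by descending P, ties
    broken lexicographically by (i, j).
    """
    n = pmap.n_residues
    iu, ju = np.triu_indices(n)
    vals = pmap.P[iu, ju]
    keep = vals > cutoff
    rows = sorted(
        zip(iu[keep] + 1, ju[keep] + 1, vals[keep]),
        key=lambda t: (-t[2], t[0], t[1]))
    return [(int(i), int(j), float(p)) for i, j, p in rows]


def contact_ratio_R(acc_a: ContactAccumulator,
                    acc_b: ContactAccumulator) -> float:
    """Ratio of total per-frame pairwise residue contacts between ensembles.

    R = (sum_ij C^a_ij / F_a) / (sum_ij C^b_ij / F_b); per-frame totals make
    windows of unequal length comparable.
    """
    if acc_a.n_residues != acc_b.n_residues:
        raise ValueError("accumulators cover different residue counts")
    denom = acc_b.total_per_frame()
    if denom == 0:
        raise ValueError("denominator ensemble has zero contacts; R undefined")
    return acc_a.total_per_frame() / denom


# ---------------------------------------------------------------------------
# protein–lipid contacts and domain statistics
# ---------------------------------------------------------------------------

def protein_lipid_contacts(
    frame: TrajectoryFrame,
    topo: Topology,
    residue_range: tuple[int, int] | None = None,
    cutoff: float = DEFAULT_CONTACT_CUTOFF_NM,
) -> dict[str, int]:
    """Lipid beads (any role) within cutoff of the selected protein residues.

    ``residue_range`` is an inclusive 1-based (first, last) span (default:
    all residues).  A lipid bead touching several proteins is counted once.
    Returns counts per lipid molecule type.
    """
    if residue_range is not None:
        lo, hi = residue_range
        if lo > hi or lo < 1:
            raise ValueError(f"empty or invalid residue range {residue_range}")
        prot = topo.is_protein & (topo.residue_index >= lo) \
            & (topo.residue_index <= hi)
    else:
        prot = topo.is_protein
    if not np.any(prot):
        raise ValueError("no protein beads in the selected residue range")
    lipid = topo.lipid_mask()
    counts = {t: 0 for t in LIPID_TYPES}
    if not np.any(lipid):
        return counts
    both = np.nonzero(prot | lipid)[0]
    pairs = periodic_pairs(frame.positions, frame.box, cutoff, subset=both)
    if len(pairs) == 0:
        return counts
    is_p = prot[pairs]
    is_l = lipid[pairs]
    cross = (is_p[:, 0] & is_l[:, 1]) | (is_p[:, 1] & is_l[:, 0])
    lip_beads = np.where(is_l[cross][:, 0], pairs[cross][:, 0],
                         pairs[cross][:, 1])
    for b in np.unique(lip_beads):
        counts[str(topo.molecule_type[b])] += 1
    return counts


@dataclass
class DomainContactStats:
    """Window-averaged protein–lipid contact counts and the L_o/L_d ratio."""

    mean_counts: dict[str, float]
    ratio_dppc_dlipc: float          # NaN when DLiPC contacts vanish
    stderr: float
    n_frames: int
    per_frame: pd.DataFrame = field(repr=False, default=None)


def domain_preference_ratio(
    traj: Trajectory,
    topo: Topology | None = None,
    window: AnalysisWindow | None = None,
    cutoff: float = DEFAULT_CONTACT_CUTOFF_NM,
    n_blocks: int = 5,
) -> DomainContactStats:
    """DPPC:DLiPC bead-contact ratio of the proteins over a frame window.

    Counts lipid beads within the cutoff of any protein bead per frame,
    averages over the window, and block-averages the per-frame ratios for a
    standard error.  Needs at least two frames.  When no DLiPC bead ever
    touches a protein the ratio is undefined (NaN) but the counts are still
    reported.
    """
    topo = topo if topo is not None else traj.topology
    if topo is None:
        raise ValueError("a topology is required")
    if window is not None:
        traj = traj.window(window)
    if len(traj) < 2:
        raise ValueError("domain ratio needs a window of at least two frames")
    rows = []
    for fr in traj:
        c = protein_lipid_contacts(fr, topo, None, cutoff)
        rows.append((fr.time, c[MoleculeType.DPPC.value],
                     c[MoleculeType.DLIPC.value],
                     c[MoleculeType.CHOL.value]))
    df = pd.DataFrame(rows, columns=["time", "DPPC", "DLIPC", "CHOL"])
    mean_counts = {k: float(df[k].mean()) for k in ("DPPC", "DLIPC", "CHOL")}

    if df["DLIPC"].sum() == 0:
        return DomainContactStats(mean_counts=mean_counts,
                                  ratio_dppc_dlipc=float("nan"),
                                  stderr=float("nan"),
                                  n_frames=len(df), per_frame=df)
    ratio = mean_counts["DPPC"] / mean_counts["DLIPC"]
    nb = max(2, min(n_blocks, len(df)))
    blocks = [df.iloc[ix] for ix in np.array_split(np.arange(len(df)), nb)]
    block_ratios = []
    for b in blocks:
        if b["DLIPC"].sum() > 0:
            block_ratios.append(b["DPPC"].mean() / b["DLIPC"].mean())
    stderr = float(np.std(block_ratios, ddof=1) / np.sqrt(len(block_ratios))) \
        if len(block_ratios) > 1 else float("nan")
    return DomainContactStats(mean_counts=mean_counts,
                              ratio_dppc_dlipc=float(ratio),
                              stderr=stderr, n_frames=len(df), per_frame=df)


def demixing_contact_ratio(
    traj: Trajectory,
    topo: Topology | None = None,
    cutoff: float = DEFAULT_CONTACT_CUTOFF_NM,
) -> pd.DataFrame:
    """Leaflet-resolved DPPC–DLiPC mixing ratio over time.

    Per frame and leaflet: (DPPC–DLiPC hetero contacts) / (all contacts of
    DPPC beads to DPPC or DLiPC beads).  For an ideally mixed field the
    ratio approaches n_DLiPC / (n_DPPC + n_DLiPC - 1); de-mixing drives it
    toward the stripe-boundary floor.  Leaflets are assigned by z relative
    to the median lipid z per frame.

    Returns a DataFrame with columns time, leaflet ("upper"/"lower"), ratio.
    """
    topo = topo if topo is not None else traj.topology
    if topo is None:
        raise ValueError("a topology is required")
    dppc = topo.molecule_type == MoleculeType.DPPC.value
    dlipc = topo.molecule_type == MoleculeType.DLIPC.value
    lipid = topo.lipid_mask()
    if not np.any(lipid):
        raise ValueError("no lipid beads; leaflet assignment impossible")

    rows = []
    for fr in traj:
        z = fr.positions[:, 2]
        mid = np.median(z[lipid])
        for name, leaf in (("upper", z >= mid), ("lower", z < mid)):
            sel = np.nonzero((dppc | dlipc) & leaf)[0]
            if len(sel) < 2:
                rows.append((fr.time, name, float("nan")))
                continue
            pairs = periodic_pairs(fr.positions, fr.box, cutoff, subset=sel)
            if len(pairs) == 0:
                rows.append((fr.time, name, 0.0))
                continue
            a_d = dppc[pairs[:, 0]]
            b_d = dppc[pairs[:, 1]]
            hetero = int(np.sum(a_d != b_d))
            homo_dppc = int(np.sum(a_d & b_d))
            denom = 2 * homo_dppc + hetero   # per-DPPC-bead neighbor count
            ratio = hetero / denom if denom else 0.0
            rows.append((fr.time, name, ratio))
    return pd.DataFrame(rows, columns=["time", "leaflet", "ratio"])
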