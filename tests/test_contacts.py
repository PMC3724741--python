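"""Residue contact maps, ratios and lipid-domain statistics."""

import numpy as np
import pytest

from cgagg.clustering import ContactCriterion
from cgagg.contacts import (
    ContactAccumulator,
    accumulate_residue_contacts,
    contact_probability,
    contact_ratio_R,
    demixing_contact_ratio,
    domain_preference_ratio,
    high_contact_pairs,
    protein_lipid_contacts,
)
from cgagg.core import (
    BeadRole,
    MoleculeType,
    Topology,
    Trajectory,
    minimum_image,
)
from conftest import make_frame, make_protein_topology


# ---------------------------------------------------------------------------
# oracle
# ---------------------------------------------------------------------------

def brute_force_accumulate(frames, topo, cutoff):
    """O(M^2 N_r^2) per-frame scan, binary per (molecule pair, residue pair)."""
    prot = np.unique(topo.molecule_id[topo.is_protein])
    n_r = int(topo.residue_index[topo.is_protein].max())
    C = np.zeros((n_r, n_r), dtype=int)
    for fr in frames:
        for ai in range(len(prot)):
            for bi in range(ai + 1, len(prot)):
                hit = set()
                for i in np.nonzero((topo.molecule_id == prot[ai])
                                    & topo.is_backbone)[0]:
                    for j in np.nonzero((topo.molecule_id == prot[bi])
                                        & topo.is_backbone)[0]:
                        d = minimum_image(fr.positions[i], fr.positions[j],
                                          fr.box)
                        if np.linalg.norm(d) <= cutoff:
                            ri, rj = sorted((topo.residue_index[i],
                                             topo.residue_index[j]))
                            hit.add((int(ri), int(rj)))
                for ri, rj in hit:
                    C[ri - 1, rj - 1] += 1
                    if ri != rj:
                        C[rj - 1, ri - 1] += 1
    return C


def make_accumulator(C, F, n_mol):
    C = np.asarray(C)
    return ContactAccumulator(C=C, F=F, n_mol=n_mol, n_residues=C.shape[0])


# ---------------------------------------------------------------------------
# accumulation
# ---------------------------------------------------------------------------

def test_zero_contact_trajectory_gives_zero_counts():
    topo = make_protein_topology(2, 4)
    frames = [make_frame(np.vstack([np.column_stack([np.arange(4) * 0.4,
                                                     np.zeros(4),
                                                     np.zeros(4)]) + c
                                    for c in ([1, 1, 1], [10, 10, 10])]),
                         time=4.0 * k) for k in range(3)]
    acc = accumulate_residue_contacts(Trajectory(frames, topo))
    assert acc.C.sum() == 0
    assert acc.F == 3


def test_single_touching_pair_counts_once_per_frame():
    # proteins of 25 residues touching only at residues (10, 20)
    n_r, F = 25, 6
    topo = make_protein_topology(2, n_r)
    pos = np.zeros((2 * n_r, 3))
    pos[:n_r] = np.column_stack([np.arange(n_r) * 1.0,
                                 np.zeros(n_r), np.full(n_r, 5.0)])
    pos[n_r:] = pos[:n_r] + np.array([0.0, 30.0, 0.0])
    pos[n_r + 19] = pos[9] + np.array([0.0, 0.5, 0.0])   # b res20 near a res10
    frames = [make_frame(pos, box=(80., 80., 80.), time=4.0 * k)
              for k in range(F)]
    acc = accumulate_residue_contacts(Trajectory(frames, topo))
    assert acc.C[9, 19] == F
    assert acc.C[19, 9] == F
    assert acc.C.sum() == 2 * F


def test_accumulation_matches_brute_force(rng):
    topo = make_protein_topology(4, 6)
    frames = []
    for k in range(5):
        centers = rng.uniform(0, 10, size=(4, 3))
        offs = rng.uniform(-0.8, 0.8, size=(4, 6, 3))
        pos = (centers[:, None, :] + offs).reshape(-1, 3) % 12.0
        frames.append(make_frame(pos, box=(12., 12., 12.), time=4.0 * k))
    traj = Trajectory(frames, topo)
    acc = accumulate_residue_contacts(traj, crit=ContactCriterion(cutoff=1.2))
    ref = brute_force_accumulate(frames, topo, 1.2)
    assert np.array_equal(acc.C, ref)


def test_heterogeneous_protein_sizes_rejected():
    a = make_protein_topology(1, 5)
    b = make_protein_topology(1, 7)
    b.molecule_id[:] = 1
    topo = Topology.concatenate([a, b])
    frames = [make_frame(np.zeros((12, 3)) + np.arange(12)[:, None] * 0.1)]
    with pytest.raises(ValueError, match="heterogeneous"):
        accumulate_residue_contacts(Trajectory(frames, topo))


# ---------------------------------------------------------------------------
# probability map
# ---------------------------------------------------------------------------

def test_zero_counts_give_zero_map():
    acc = make_accumulator(np.zeros((5, 5), int), F=3, n_mol=4)
    assert np.all(contact_probability(acc).P == 0)


def test_saturated_pair_reaches_probability_bound():
    n_r, M, F = 30, 4, 7
    C = np.zeros((n_r, n_r), int)
    C[9, 19] = C[19, 9] = F * (M * (M - 1) // 2)
    pmap = contact_probability(make_accumulator(C, F, M))
    assert pmap.P[9, 19] == pytest.approx(1.0 / n_r**2)


def test_normalization_constant_for_reference_system():
    n_r, M, F = 186, 32, 10
    acc = make_accumulator(np.zeros((n_r, n_r), int), F, M)
    pmap = contact_probability(acc)
    assert acc.molecule_pairs == 496
    assert pmap.normalization == F * 496 * 34596


def test_map_symmetry_and_bound_on_random_accumulators(rng):
    for _ in range(20):
        n_r, M, F = 12, 5, 4
        cap = F * (M * (M - 1) // 2)
        upper = rng.integers(0, cap + 1, size=(n_r, n_r))
        C = np.triu(upper)
        C = C + np.triu(C, 1).T
        pmap = contact_probability(make_accumulator(C, F, M))
        assert np.array_equal(pmap.P, pmap.P.T)
        assert pmap.P.max() <= 1.0 / n_r**2 + 1e-15


def test_zero_frames_rejected():
    acc = make_accumulator(np.zeros((4, 4), int), F=0, n_mol=3)
    with pytest.raises(ValueError, match="zero accumulated frames"):
        contact_probability(acc)


# ---------------------------------------------------------------------------
# high-P extraction
# ---------------------------------------------------------------------------

def test_high_pairs_empty_and_single():
    acc = make_accumulator(np.zeros((6, 6), int), F=2, n_mol=3)
    assert high_contact_pairs(contact_probability(acc)) == []
    C = np.zeros((6, 6), int)
    C[1, 4] = C[4, 1] = 2
    pmap = contact_probability(make_accumulator(C, 2, 3))
    out = high_contact_pairs(pmap, cutoff=1e-9)
    assert len(out) == 1 and out[0][:2] == (2, 5)


def test_high_pairs_match_exhaustive_filter(rng):
    n_r, M, F = 15, 6, 3
    cap = F * (M * (M - 1) // 2)
    C = np.triu(rng.integers(0, cap + 1, size=(n_r, n_r)))
    C = C + np.triu(C, 1).T
    pmap = contact_probability(make_accumulator(C, F, M))
    cutoff = float(np.median(pmap.P[pmap.P > 0]))
    got = high_contact_pairs(pmap, cutoff)
    ref = []
    for i in range(n_r):
        for j in range(i, n_r):
            if pmap.P[i, j] > cutoff:      # strictly greater
                ref.append((i + 1, j + 1, pmap.P[i, j]))
    ref.sort(key=lambda t: (-t[2], t[0], t[1]))
    assert [(i, j) for i, j, _ in got] == [(i, j) for i, j, _ in ref]
    assert np.allclose([p for _, _, p in got], [p for _, _, p in ref])


# ---------------------------------------------------------------------------
# contact ratio R
# ---------------------------------------------------------------------------

def test_ratio_identity_and_hand_arithmetic():
    C = np.zeros((4, 4), int)
    C[0, 1] = C[1, 0] = 59
    a = make_accumulator(C, F=1, n_mol=3)
    C2 = np.zeros((4, 4), int)
    C2[0, 1] = C2[1, 0] = 100
    b = make_accumulator(C2, F=1, n_mol=3)
    assert contact_ratio_R(a, a) == pytest.approx(1.0)
    assert contact_ratio_R(a, b) == pytest.approx(0.59)


def test_ratio_swap_antisymmetry_and_scale_invariance(rng):
    def random_acc(F):
        C = np.triu(rng.integers(0, 5, size=(8, 8)) * F)
        C = C + np.triu(C, 1).T
        return make_accumulator(C, F, 4)
    a, b = random_acc(4), random_acc(6)
    assert contact_ratio_R(a, b) * contact_ratio_R(b, a) == pytest.approx(1.0)
    half = make_accumulator(a.C // 2, a.F // 2, a.n_mol)
    assert contact_ratio_R(half, b) == pytest.approx(contact_ratio_R(a, b))


def test_ratio_zero_denominator_rejected():
    a = make_accumulator(np.zeros((4, 4), int), 2, 3)
    with pytest.raises(ValueError, match="undefined"):
        contact_ratio_R(a, a)


# ---------------------------------------------------------------------------
# protein–lipid contacts
# ---------------------------------------------------------------------------

def lipid_bead_topology(types, first_mol=100):
    n = len(types)
    return Topology(
        molecule_id=first_mol + np.arange(n),
        molecule_type=np.array(types),
        residue_index=np.ones(n, int),
        bead_role=np.full(n, BeadRole.HEADGROUP.value),
        bead_radius=np.full(n, 0.26))


def test_no_lipids_in_range_gives_zero_counts():
    topo = Topology.concatenate([
        make_protein_topology(1, 3),
        lipid_bead_topology(["DPPC", "DLIPC"])])
    pos = np.array([[1, 1, 1], [1.4, 1, 1], [1.8, 1, 1],
                    [10, 10, 10], [12, 12, 12]], float)
    counts = protein_lipid_contacts(make_frame(pos), topo)
    assert counts == {"DPPC": 0, "DLIPC": 0, "CHOL": 0}


def test_hand_placed_counts_and_ratio():
    # 17 DPPC + 20 DLiPC beads in contact -> ratio 17/20 = 0.85
    n_p = 3
    topo = Topology.concatenate([
        make_protein_topology(1, n_p),
        lipid_bead_topology(["DPPC"] * 17 + ["DLIPC"] * 20 + ["CHOL"] * 5)])
    prot = np.array([[10.0, 10.0, 10.0], [10.4, 10.0, 10.0],
                     [10.8, 10.0, 10.0]])
    rng = np.random.default_rng(1)
    ang = rng.uniform(0, 2 * np.pi, 37)
    near = prot[1] + 0.6 * np.column_stack(
        [np.cos(ang), np.sin(ang), np.zeros(37)])
    far = rng.uniform(0, 5, size=(5, 3))
    counts = protein_lipid_contacts(
        make_frame(np.vstack([prot, near, far]), box=(30., 30., 30.)), topo)
    assert counts["DPPC"] == 17 and counts["DLIPC"] == 20
    assert counts["DPPC"] / counts["DLIPC"] == pytest.approx(0.85)


def test_lipid_contact_counts_match_brute_force(rng):
    topo = Topology.concatenate([
        make_protein_topology(2, 4),
        lipid_bead_topology(list(rng.choice(["DPPC", "DLIPC", "CHOL"], 60)))])
    pos = rng.uniform(0, 8, size=(68, 3))
    frame = make_frame(pos, box=(8., 8., 8.))
    counts = protein_lipid_contacts(frame, topo, cutoff=0.75)
    ref = {"DPPC": 0, "DLIPC": 0, "CHOL": 0}
    prot_idx = np.nonzero(topo.is_protein)[0]
    for b in np.nonzero(topo.lipid_mask())[0]:
        touched = any(
            np.linalg.norm(minimum_image(pos[b], pos[p], frame.box)) <= 0.75
            for p in prot_idx)
        if touched:
            ref[str(topo.molecule_type[b])] += 1   # once, globally
    assert counts == ref


def test_residue_range_validation():
    topo = Topology.concatenate([make_protein_topology(1, 5),
                                 lipid_bead_topology(["DPPC"])])
    frame = make_frame(np.zeros((6, 3)) + np.arange(6)[:, None] * 0.3)
    with pytest.raises(ValueError, match="range"):
        protein_lipid_contacts(frame, topo, residue_range=(4, 2))


# ---------------------------------------------------------------------------
# domain preference
# ---------------------------------------------------------------------------

def test_symmetric_boundary_straddle_gives_unit_ratio():
    # mirror-symmetric DPPC/DLiPC placement around a protein on the boundary
    n_lip = 12
    rng = np.random.default_rng(3)
    y = rng.uniform(9, 11, n_lip)
    dx = rng.uniform(0.1, 0.7, n_lip)
    dppc = np.column_stack([10.0 - dx, y, np.full(n_lip, 10.0)])
    dlipc = np.column_stack([10.0 + dx, y, np.full(n_lip, 10.0)])
    topo = Topology.concatenate([
        make_protein_topology(1, 1),
        lipid_bead_topology(["DPPC"] * n_lip + ["DLIPC"] * n_lip)])
    pos = np.vstack([[[10.0, 10.0, 10.0]], dppc, dlipc])
    frames = [make_frame(pos, time=4.0 * k) for k in range(4)]
    stats = domain_preference_ratio(Trajectory(frames, topo))
    assert stats.ratio_dppc_dlipc == pytest.approx(1.0)


def test_dppc_only_environment_reports_undefined_ratio():
    topo = Topology.concatenate([
        make_protein_topology(1, 1), lipid_bead_topology(["DPPC"] * 6)])
    pos = np.vstack([[[5., 5., 5.]],
                     [[5 + 0.1 * k, 5.3, 5.] for k in range(6)]])
    frames = [make_frame(pos, time=4.0 * k) for k in range(3)]
    stats = domain_preference_ratio(Trajectory(frames, topo))
    assert np.isnan(stats.ratio_dppc_dlipc)
    assert stats.mean_counts["DPPC"] == 6.0


def test_single_frame_window_rejected():
    topo = Topology.concatenate([
        make_protein_topology(1, 1), lipid_bead_topology(["DPPC", "DLIPC"])])
    frames = [make_frame(np.zeros((3, 3)) + np.arange(3)[:, None] * 0.3)]
    with pytest.raises(ValueError, match="two frames"):
        domain_preference_ratio(Trajectory(frames, topo))


# ---------------------------------------------------------------------------
# de-mixing ratio
# ---------------------------------------------------------------------------

def test_dppc_only_field_ratio_zero():
    topo = lipid_bead_topology(["DPPC"] * 40, first_mol=0)
    rng = np.random.default_rng(0)
    pos = rng.uniform(0, 6, size=(40, 3))
    df = demixing_contact_ratio(
        Trajectory([make_frame(pos, box=(6., 6., 6.))], topo), topo)
    assert np.all(df["ratio"].to_numpy() == 0.0)


def test_demixed_stripe_ratio_far_below_mixed_expectation():
    from cgagg.synth import DomainFieldConfig, generate_domain_field
    cfg = DomainFieldConfig(seed=5)
    mixed_expect = 2304 / (3480 + 2304 - 1)
    frame, topo = generate_domain_field(cfg, 1.0)
    df = demixing_contact_ratio(Trajectory([frame], topo), topo)
    # only the two stripe boundaries contribute hetero contacts
    assert np.all(df["ratio"].to_numpy() < mixed_expect / 3)
    assert np.all(df["ratio"].to_numpy() > 0)
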