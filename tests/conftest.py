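import numpy as np
import pytest

from cgagg.core import BeadRole, MoleculeType, Topology, TrajectoryFrame


def make_protein_topology(n_proteins: int, n_residues: int,
                          radius: float = 0.26) -> Topology:
    """All-backbone protein topology, one bead per residue."""
    n = n_proteins * n_residues
    return Topology(
        molecule_id=np.repeat(np.arange(n_proteins), n_residues),
        molecule_type=np.full(n, MoleculeType.PROTEIN.value),
        residue_index=np.tile(np.arange(1, n_residues + 1), n_proteins),
        bead_role=np.full(n, BeadRole.BACKBONE.value),
        bead_radius=np.full(n, radius),
    )


def make_frame(positions, box=(20.0, 20.0, 20.0), time=0.0) -> TrajectoryFrame:
    return TrajectoryFrame(time=time, box=np.asarray(box, float),
                           positions=np.asarray(positions, float))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
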