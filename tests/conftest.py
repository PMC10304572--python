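import numpy as np
import pytest
from hypothesis import settings

from dyestack.synthetic import SyntheticConfig, default_dye_template, default_topology, run_aggregation

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=25)
settings.load_profile("ci")

CONTRAST_SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def topology():
    return default_topology()


@pytest.fixture(scope="session")
def dye_template():
    return default_dye_template()


@pytest.fixture(scope="session")
def contrast_runs():
    """Aggregation trajectories for both counterion modes, study-default conditions.

    Computed once per session: 5 seeds x {bulky_hydrophobic, small_ionic}.
    """
    runs = {}
    for mode in ("bulky_hydrophobic", "small_ionic"):
        runs[mode] = [
            run_aggregation(SyntheticConfig(seed=seed, counterion_mode=mode))
            for seed in CONTRAST_SEEDS
        ]
    return runs


def random_pose_frame(rng, n_dyes, box_side=40.0):
    """A frame of randomly posed dye templates in a periodic box (test helper)."""
    from scipy.spatial.transform import Rotation

    from dyestack.trajio import Frame, assign_molecule_ids

    template = default_dye_template()
    atoms = []
    for i in range(n_dyes):
        rot = Rotation.from_quat(_shoemake(rng)).as_matrix()
        pos = rng.random(3) * box_side
        atoms += template.instantiate(pos, rot, residue_id=i + 1)
    assign_molecule_ids(atoms)
    return Frame(time=0.0, atoms=atoms, box=np.full(3, box_side))


def _shoemake(rng):
    u1, u2, u3 = rng.random(3)
    a, b = np.sqrt(1 - u1), np.sqrt(u1)
    return [a * np.sin(2 * np.pi * u2), a * np.cos(2 * np.pi * u2),
            b * np.sin(2 * np.pi * u3), b * np.cos(2 * np.pi * u3)]
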