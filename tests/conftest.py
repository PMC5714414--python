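import numpy as np
import pytest

from vmatplan import CumulativeDVH, DifferentialDVH, StructureInfo


@pytest.fixture
def info():
    return StructureInfo("PTV", 100.0, patient_id="P01", technique="single-arc")


@pytest.fixture
def toy_cumulative(info):
    """Cumulative DVH with a plateau, a shoulder and a steep falloff:
    100% through 40 Gy, 80% at 60 Gy, 30% at 78 Gy, 0% at 80 Gy."""
    return CumulativeDVH(
        info, [0.0, 40.0, 60.0, 78.0, 80.0], [1.0, 1.0, 0.8, 0.3, 0.0]
    )


@pytest.fixture
def uniform_dvh_factory(info):
    """Differential DVH giving a single uniform dose to the whole volume."""

    def make(dose: float, structure=None) -> DifferentialDVH:
        return DifferentialDVH(structure or info, [dose], [1.0])

    return make


@pytest.fixture
def partial_dvh_factory(info):
    """Differential DVH: fraction ``v`` at ``dose``, the rest unirradiated."""

    def make(dose: float, v: float) -> DifferentialDVH:
        return DifferentialDVH(info, [0.0, dose], [1.0 - v, v])

    return make


def random_uniform_cumulative(rng, info, max_bins=60):
    """Random valid cumulative DVH on a uniform dose grid."""
    n = int(rng.integers(2, max_bins))
    width = float(rng.uniform(0.2, 3.0))
    edges = np.arange(n) * width
    drops = rng.random(n - 1)
    vols = np.concatenate([[1.0], 1.0 - np.cumsum(drops) / drops.sum()])
    vols = np.clip(vols, 0.0, 1.0)
    return CumulativeDVH(info, edges, vols)
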