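import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from memjm import HelixSpec, make_hairpin, make_helix


@pytest.fixture
def ideal_helix():
    """18-residue ideal CA helix along +z, one conformer."""
    return make_helix(HelixSpec(18))


@pytest.fixture
def hairpin65():
    """Two 18-residue helices at a 65 degree inter-axis angle."""
    return make_hairpin(65.0)


def gridsearch_superpose_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Independent superposition oracle: coarse rotation-vector grid plus
    derivative-free local refinement; never calls the Kabsch path."""
    a0 = mobile - mobile.mean(axis=0)
    b0 = reference - reference.mean(axis=0)

    def cost(rv):
        R = Rotation.from_rotvec(rv).as_matrix()
        return float(np.sqrt(((a0 @ R.T - b0) ** 2).sum() / len(a0)))

    grid = np.linspace(-np.pi, np.pi, 9)
    best_rv, best = None, np.inf
    for x in grid:
        for y in grid:
            for z in grid:
                c = cost(np.array([x, y, z]))
                if c < best:
                    best, best_rv = c, np.array([x, y, z])
    res = minimize(cost, best_rv, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 5000})
    return float(res.fun)
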