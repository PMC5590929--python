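"""Independent oracles used by the acceptance tests.

The rigid-superposition oracle minimises RMSD by explicit search over
rotations (coarse random-rotation grid followed by simplex refinement of
the rotation vector).  It never touches the SVD-based production path.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def brute_force_min_rmsd(a: np.ndarray, b: np.ndarray, n_grid: int = 3000,
                         seed: int = 0) -> float:
    """Minimum RMSD over proper rotations by direct search."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    n = a.shape[0]

    def rmsd_of(rot: Rotation) -> float:
        diff = ac @ rot.as_matrix().T - bc
        return float(np.sqrt(np.sum(diff * diff) / n))

    grid = Rotation.random(n_grid, random_state=seed)
    values = [rmsd_of(r) for r in grid]
    best = grid[int(np.argmin(values))]

    def objective(rotvec: np.ndarray) -> float:
        return rmsd_of(Rotation.from_rotvec(rotvec))

    result = minimize(objective, best.as_rotvec(), method="Nelder-Mead",
                      options={"xatol": 1e-8, "fatol": 1e-12,
                               "maxiter": 2000})
    return float(result.fun)
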