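"""Independent reference implementations used only as test oracles.

These deliberately avoid the code paths they check: the absolute-orientation
oracle is Horn's closed-form quaternion method (eigenvector of the 4x4 N
matrix), not an SVD; correspondence and subset-selection oracles are
exhaustive searches.
"""

from itertools import combinations

import numpy as np


def horn_quaternion(fixed: np.ndarray, moving: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form absolute orientation (unit-quaternion method): returns
    (R, t) minimizing sum |fixed_i - (R moving_i + t)|^2."""
    p = np.asarray(fixed, float)
    q = np.asarray(moving, float)
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    S = qc.T @ pc  # S[i, j] = sum moving_i * fixed_j
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    N = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    eigvals, eigvecs = np.linalg.eigh(N)
    w, x, y, z = eigvecs[:, np.argmax(eigvals)]
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = p.mean(axis=0) - R @ q.mean(axis=0)
    return R, t


def brute_force_nearest(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """O(n*m) exhaustive nearest-neighbour search."""
    d = np.linalg.norm(moving[:, None, :] - fixed[None, :, :], axis=2)
    idx = d.argmin(axis=1)
    return idx, d[np.arange(len(moving)), idx]

def best_spread_subset(points: np.ndarray, k: int) -> float:
    """Brute-force max-min pairwise distance over all k-subsets of points."""
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    best = 0.0
    for c in combinations(range(len(points)), k):
        m = min(d[a][b] for a, b in combinations(c, 2))
        best = max(best, m)
    return best
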