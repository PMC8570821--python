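"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they verify: the superposition
oracle minimizes RMSD by generic numerical optimization over rotation
vectors, the Hessian oracle evaluates the superelement formula with naive
loops, and the medoid oracle enumerates candidates exhaustively.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def brute_force_min_rmsd(a, b, n_starts=400, seed=0):
    """Minimum RMSD over rigid motions by multi-start rotation-vector search."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)

    def cost(rv):
        rot = Rotation.from_rotvec(rv).as_matrix()
        return np.sqrt(np.mean(np.sum((ac @ rot.T - bc) ** 2, axis=1)))

    starts = Rotation.random(n_starts, random_state=seed).as_rotvec()
    best = min(starts, key=cost)
    res = minimize(cost, best, method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
    return float(res.fun)


def brute_force_hessian(coords, cutoff, gamma):
    """Direct double-loop evaluation of the ANM superelement formula."""
    coords = np.asarray(coords, float)
    n = len(coords)
    h = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = coords[j] - coords[i]
            r = np.linalg.norm(d)
            if r > cutoff:
                continue
            block = -(gamma / r**2) * np.outer(d, d)
            h[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
            h[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
    return h


def exhaustive_medoid(dist, members):
    """Cluster member minimizing summed distance; lowest index on ties."""
    members = list(members)
    best, best_sum = None, np.inf
    for m in members:
        s = sum(dist[m, other] for other in members)
        if s < best_sum - 1e-15:
            best, best_sum = m, s
    return best


def rigid_basis(coords):
    """Orthonormal basis of the six rigid-body displacement fields at coords."""
    c = coords - coords.mean(axis=0)
    n = len(coords)
    fields = []
    for k in range(3):
        t = np.zeros((n, 3))
        t[:, k] = 1.0
        fields.append(t.ravel())
    for ax in np.eye(3):
        fields.append(np.cross(ax, c).ravel())
    q, _ = np.linalg.qr(np.array(fields).T)
    return q.T
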