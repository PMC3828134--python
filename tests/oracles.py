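"""Independent reference implementations used as test oracles.

Deliberately naive: plain loops and brute force, sharing no code with the
package paths they check.
"""

import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def nw_score(seq_a: str, seq_b: str, match=1.0, mismatch=0.0, gap=-1.0) -> float:
    """Needleman-Wunsch optimal global alignment score by full DP."""
    n, m = len(seq_a), len(seq_b)
    dp = np.zeros((n + 1, m + 1))
    dp[:, 0] = gap * np.arange(n + 1)
    dp[0, :] = gap * np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = dp[i - 1, j - 1] + (match if seq_a[i - 1] == seq_b[j - 1]
                                       else mismatch)
            dp[i, j] = max(diag, dp[i - 1, j] + gap, dp[i, j - 1] + gap)
    return float(dp[n, m])


def shrake_rupley_sasa(coords, radii, probe=1.4, n_points=2000):
    """Per-atom SASA by explicit sphere-point counting (golden spiral)."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    k = np.arange(n_points)
    phi = np.pi * (3.0 - np.sqrt(5.0))
    y = 1.0 - 2.0 * (k + 0.5) / n_points
    r = np.sqrt(1.0 - y * y)
    sphere = np.stack([np.cos(phi * k) * r, y, np.sin(phi * k) * r], axis=1)
    out = np.zeros(len(coords))
    for i in range(len(coords)):
        ri = radii[i] + probe
        points = coords[i] + ri * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            rj = radii[j] + probe
            accessible &= np.linalg.norm(points - coords[j], axis=1) >= rj
        out[i] = 4.0 * np.pi * ri ** 2 * accessible.mean()
    return out


def brute_force_max_clique_size(adj: np.ndarray) -> int:
    """Largest clique by enumerating all vertex subsets."""
    n = adj.shape[0]
    best = 0
    for size in range(n, 0, -1):
        if size <= best:
            break
        for subset in itertools.combinations(range(n), size):
            if all(adj[i, j] for i, j in itertools.combinations(subset, 2)):
                best = size
                break
        if best:
            break
    return best


def numeric_superimposition_rmsd(mobile, reference) -> float:
    """Minimum RMSD over rigid transforms by direct numeric optimization."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)

    def objective(x):
        rot = Rotation.from_rotvec(x[:3]).as_matrix()
        moved = mobile @ rot.T + x[3:]
        return np.sqrt(((moved - reference) ** 2).sum(axis=1).mean())

    best = np.inf
    for trial_seed in range(5):
        rng = np.random.default_rng(trial_seed)
        x0 = np.concatenate([rng.normal(0, 1, 3), reference.mean(0) - mobile.mean(0)])
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        best = min(best, res.fun)
    return float(best)


def pairwise_clash_count(coords_a, coords_b, cutoff) -> int:
    """O(n*m) double-loop clash counting."""
    count = 0
    for a in np.asarray(coords_a, dtype=float):
        for b in np.asarray(coords_b, dtype=float):
            if np.linalg.norm(a - b) < cutoff:
                count += 1
    return count
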