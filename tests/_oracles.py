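"""Independent oracles used by the test suite.

These implement the checked quantities by different algorithms than the
package (closed-form quaternion superposition, exhaustive enumeration,
brute-force transitive closure) so agreement is meaningful.
"""

from itertools import combinations

import numpy as np


def horn_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Optimal-superposition RMSD via Horn's closed-form quaternion method."""
    a = np.asarray(a, float) - np.mean(a, axis=0)
    b = np.asarray(b, float) - np.mean(b, axis=0)
    m = b.T @ a
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, szy - syz, sxz - szx, syx - sxy],
        [szy - syz, sxx - syy - szz, sxy + syx, szx + sxz],
        [sxz - szx, sxy + syx, -sxx + syy - szz, syz + szy],
        [syx - sxy, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    e2 = (np.sum(a * a) + np.sum(b * b) - 2.0 * lam) / a.shape[0]
    return float(np.sqrt(max(e2, 0.0)))


def mwu_exact_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all label placements."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)

    def u_of(idx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    u_obs = u_of(range(n))
    mean_u = n * m / 2.0
    dev = abs(u_obs - mean_u)
    count = total = 0
    for idx in combinations(range(n + m), n):
        total += 1
        count += abs(u_of(idx) - mean_u) >= dev - 1e-12
    return count / total


def transitive_clusters(items, linked) -> set[frozenset]:
    """Brute-force transitive closure of a pairwise link predicate."""
    clusters = [{i} for i in items]
    changed = True
    while changed:
        changed = False
        for i, a in enumerate(clusters):
            for b in clusters[i + 1:]:
                if any(linked(x, y) for x in a for y in b):
                    a |= b
                    clusters.remove(b)
                    changed = True
                    break
            if changed:
                break
    return {frozenset(c) for c in clusters}


def helix_ca_trace(n: int, rise: float = 1.5, radius: float = 2.3,
                   turn_deg: float = 100.0) -> np.ndarray:
    """Parametric ideal alpha-helix Calpha trace."""
    k = np.arange(n)
    theta = np.deg2rad(turn_deg) * k
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta), rise * k])


def rg_direct(coords: np.ndarray) -> float:
    """RG by direct double-sum formula: sqrt(mean pairwise sq dist / 2) / sqrt(n) ... ;
    implemented via the pairwise identity RG^2 = (1/2N^2) * sum_ij |ri-rj|^2."""
    c = np.asarray(coords, float)
    n = len(c)
    d2 = np.sum((c[:, None, :] - c[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.sum() / (2.0 * n * n)))
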