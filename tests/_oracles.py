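"""Independent reference implementations used to cross-check the package.

Everything here is deliberately plain (loops, brute force, generic scipy
minimizers) and shares no code path with motifdock itself.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def scan_motif(motif: str, sequence: str) -> list[int]:
    """Window-by-window motif scan; X matches anything."""
    L = len(motif)
    hits = []
    for p in range(len(sequence) - L + 1):
        ok = True
        for k, ch in enumerate(motif):
            if ch != "X" and sequence[p + k] != ch:
                ok = False
                break
        if ok:
            hits.append(p)
    return hits


def nw_identity(a: str, b: str) -> int:
    """Global alignment maximizing (score, identities) lexicographically with
    match +1, mismatch 0, gap -1; returns the identity count.

    Full (n+1)x(m+1) table with explicit cell-by-cell maximization.
    """
    n, m = len(a), len(b)
    score = [[0] * (m + 1) for _ in range(n + 1)]
    ident = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        score[i][0] = -i
    for j in range(1, m + 1):
        score[0][j] = -j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cands = [
                (score[i - 1][j - 1] + (a[i - 1] == b[j - 1]),
                 ident[i - 1][j - 1] + (a[i - 1] == b[j - 1])),
                (score[i - 1][j] - 1, ident[i - 1][j]),
                (score[i][j - 1] - 1, ident[i][j - 1]),
            ]
            score[i][j], ident[i][j] = max(cands)
    return ident[n][m]


def rmsd_after_superposition(A: np.ndarray, B: np.ndarray) -> float:
    """Minimal RMSD over proper rigid motions via generic numeric
    minimization over rotation vectors from a coarse grid of starts."""
    A = np.asarray(A, float).reshape(-1, 3)
    B = np.asarray(B, float).reshape(-1, 3)
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)

    def cost(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        d = Ac @ R.T - Bc
        return float(np.sqrt((d * d).sum(axis=1).mean()))

    best = np.inf
    # coarse start grid over axis-angle space, then local refinement
    for axis in ([1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 0], [1, 0, 1],
                 [0, 1, 1], [1, 1, 1], [-1, 1, 0], [1, -1, 1], [0, 0, 0]):
        axis = np.asarray(axis, float)
        norm = np.linalg.norm(axis)
        for angle in np.arange(0.0, np.pi + 1e-9, np.pi / 6):
            start = np.zeros(3) if norm == 0 else axis / norm * angle
            res = minimize(cost, start, method="Nelder-Mead",
                           options={"xatol": 1e-6, "fatol": 1e-12,
                                    "maxiter": 2000})
            best = min(best, res.fun)
            if norm == 0:
                break
    return best


def direct_correlation(receptor_field: np.ndarray,
                       ligand_field: np.ndarray) -> np.ndarray:
    """S(t) = sum_x R(x) * L(x - t), circular, by explicit shift-and-sum."""
    dims = receptor_field.shape
    out = np.empty(dims)
    for tx in range(dims[0]):
        for ty in range(dims[1]):
            for tz in range(dims[2]):
                shifted = np.roll(ligand_field, (tx, ty, tz), axis=(0, 1, 2))
                out[tx, ty, tz] = float(np.sum(receptor_field * shifted))
    return out


def greedy_cluster_plain(dist: np.ndarray, radius: float):
    """Straightforward greedy radius clustering (formation order)."""
    n = dist.shape[0]
    remaining = list(range(n))
    clusters = []
    while remaining:
        best_center, best_members = None, None
        for i in remaining:
            members = [j for j in remaining if dist[i][j] <= radius]
            if best_members is None or len(members) > len(best_members):
                best_center, best_members = i, members
        clusters.append((best_center, best_members))
        remaining = [j for j in remaining if j not in best_members]
    return clusters


def pairwise_rmsd_plain(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Unsuperposed RMSD by the direct per-atom formula."""
    a = np.asarray(coords_a, float).reshape(-1, 3)
    b = np.asarray(coords_b, float).reshape(-1, 3)
    total = 0.0
    for pa, pb in zip(a, b):
        d = pa - pb
        total += float(d @ d)
    return float(np.sqrt(total / len(a)))
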