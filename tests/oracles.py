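"""Independent reference implementations used only to check tmdock.

These deliberately avoid the code paths they verify: rotations go through
explicit quaternion algebra instead of rotation matrices, superposition uses
Horn's quaternion-eigenvector method instead of Kabsch/scipy, contacts use
an O(n^2) double loop instead of a KD-tree, and the quality-tier ladder is a
literal transcription of the threshold table.
"""

from __future__ import annotations

import numpy as np


def quat_from_axis_angle(axis, theta: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return np.concatenate([[np.cos(theta / 2.0)], np.sin(theta / 2.0) * axis])


def quat_mul(q1, q2) -> np.ndarray:
    w1, x1, y1, z1 = q1
    w2, x2, y2, z2 = q2
    return np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ])


def quat_rotate(q, points: np.ndarray) -> np.ndarray:
    """Rotate points by unit quaternion q via q p q*."""
    qc = q * np.array([1.0, -1.0, -1.0, -1.0])
    out = []
    for p in np.atleast_2d(points):
        pq = np.concatenate([[0.0], p])
        out.append(quat_mul(quat_mul(q, pq), qc)[1:])
    return np.array(out)


def horn_superpose(mobile: np.ndarray, target: np.ndarray):
    """Optimal proper-rotation superposition via Horn's quaternion method.

    Returns (rotation matrix, translation applied after rotation about the
    mobile centroid, rmsd).
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    a, b = mobile - mc, target - tc
    S = a.T @ b
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    w, v = np.linalg.eigh(K)
    q = v[:, np.argmax(w)]  # quaternion (w, x, y, z) of the best rotation
    rotated = quat_rotate(q, a)
    rmsd = np.sqrt(np.mean(np.sum((rotated - b) ** 2, axis=1)))
    ww, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * ww), 2 * (x * z + y * ww)],
        [2 * (x * y + z * ww), 1 - 2 * (x * x + z * z), 2 * (y * z - x * ww)],
        [2 * (x * z - y * ww), 2 * (y * z + x * ww), 1 - 2 * (x * x + y * y)],
    ])
    return R, tc - mc, float(rmsd)


def brute_force_contacts(receptor, ligand, cutoff: float = 5.0) -> set:
    """O(n^2) heavy-atom residue-contact scan."""
    contacts = set()
    rheavy = receptor.heavy_mask()
    lheavy = ligand.heavy_mask()
    rkeys = receptor.residue_keys()
    lkeys = ligand.residue_keys()
    for i in np.flatnonzero(rheavy):
        for j in np.flatnonzero(lheavy):
            if np.linalg.norm(receptor.coords[i] - ligand.coords[j]) <= cutoff:
                contacts.add((rkeys[i], lkeys[j]))
    return contacts


def truth_table_tier(fnat: float, rmsd: float, irmsd: float) -> str:
    """Literal transcription of the quality-tier inequality ladder,
    applied in printed order (incorrect first)."""
    if fnat < 0.1 or (rmsd > 10.0 and irmsd > 4.0):
        return "incorrect"
    high = fnat >= 0.5 and (rmsd <= 1.0 or irmsd <= 1.0)
    intermediate = (
        (0.3 <= fnat < 0.5 and (rmsd <= 5.0 or irmsd <= 2.0))
        or (fnat >= 0.5 and rmsd > 1.0 and irmsd > 1.0
            and (rmsd <= 5.0 or irmsd <= 2.0))
    )
    acceptable = (
        (0.1 <= fnat < 0.3 and (rmsd <= 10.0 or irmsd <= 4.0))
        or (fnat >= 0.3 and rmsd > 5.0 and irmsd > 2.0)
    )
    if high:
        return "high"
    if intermediate:
        return "intermediate"
    if acceptable:
        return "acceptable"
    return "acceptable"  # incorrect ruled out above; ladder is exhaustive


def brute_force_nearest(vertices: np.ndarray, point: np.ndarray):
    """Exact nearest vertex by linear scan; lowest index on ties."""
    d = np.linalg.norm(vertices - point, axis=1)
    best = d.min()
    idx = int(np.flatnonzero(d <= best).min())
    return idx, float(d[idx])


def direct_kernel_density(points: np.ndarray, frames: np.ndarray,
                          weights: np.ndarray, sigma: float) -> np.ndarray:
    """Untruncated frame-averaged Gaussian density at arbitrary points."""
    norm = 1.0 / (2.0 * np.pi * sigma ** 2) ** 1.5
    vals = np.zeros(len(points))
    for f in frames:
        for w, r in zip(weights, f):
            d2 = np.sum((points - r) ** 2, axis=1)
            vals += w * norm * np.exp(-d2 / (2.0 * sigma ** 2))
    return vals / len(frames)
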