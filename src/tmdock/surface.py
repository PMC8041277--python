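"""Isosurface extraction and the surface-complementarity docking score.

A protein's ensemble density map is converted into a triangulated level set
at a fixed cutoff of the max-normalized intensity.  Docking then maximizes
the geometric complementarity of the receptor and ligand level sets: ligand
vertices sitting within one water radius of the receptor surface with
anti-aligned normals are rewarded, ligand vertices that have crossed to the
inside of the receptor surface are penalized.  Working on smooth level sets
rather than atom spheres gives the optimizer a gently varying objective with
no hard steric discontinuities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage import measure

from .densmap import VolumetricMap
from .errors import LevelSetError
from .structio import RigidTransform


@dataclass
class IsoSurface:
    """A triangulated level set with outward per-vertex normals.

    ``vertices``: (n, 3) A, laboratory frame.  ``faces``: (m, 3) indices.
    ``normals``: (n, 3) unit vectors pointing *down* the density gradient,
    i.e. away from the protein interior.  ``isovalue``: the cutoff used.
    """

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray
    isovalue: float

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.normals = np.asarray(self.normals, dtype=np.float64)
        if len(self.vertices) == 0:
            raise LevelSetError("isosurface has no vertices")
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")
        norms = np.linalg.norm(self.normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("normals must be unit length")
        self._tree: cKDTree | None = None

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def kdtree(self) -> cKDTree:
        """Cached KD-tree over the vertices (receptor-side lookups)."""
        if self._tree is None:
            self._tree = cKDTree(self.vertices)
        return self._tree

    def area(self) -> float:
        """Total triangle area, A^2."""
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return float(0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1).sum())

    def transformed(self, t: RigidTransform) -> "IsoSurface":
        return IsoSurface(
            vertices=t.apply(self.vertices),
            faces=self.faces,
            normals=t.apply_vectors(self.normals),
            isovalue=self.isovalue,
        )


@dataclass
class ScoreParams:
    """Knobs of the complementarity score.

    contact_distance : A; ligand vertices within this distance of the
        receptor surface count as in contact.  1.4 A is half a water
        diameter — partners separated by more than one water layer do not
        touch.
    clash_depth : A; penetration beyond this depth counts as a clash
        (0 = any vertex strictly inside the partner surface).
    clash_penalty : weight per clashing vertex.
    """

    contact_distance: float = 1.4
    clash_depth: float = 0.0
    clash_penalty: float = 2.0

    def __post_init__(self) -> None:
        if self.contact_distance <= 0:
            raise ValueError("contact_distance must be > 0")
        if self.clash_penalty < 0:
            raise ValueError("clash_penalty must be >= 0")


def extract_isosurface(m: VolumetricMap, isovalue: float) -> IsoSurface:
    """Marching-cubes triangulation of the level set at ``isovalue``.

    Vertices are mapped to laboratory coordinates (A).  Normals are computed
    from the trilinearly interpolated central-difference gradient of the map
    and oriented down-gradient (outward).
    """
    vmin, vmax = m.values.min(), m.values.max()
    if not vmin < isovalue < vmax:
        raise LevelSetError(
            f"isovalue {isovalue} outside map value range ({vmin:g}, {vmax:g})"
        )
    verts_idx, faces, _, _ = measure.marching_cubes(m.values, level=isovalue)
    vertices = m.origin + verts_idx * m.spacing

    # central-difference gradient, trilinear at the vertices
    grads = np.gradient(m.values, m.spacing)
    axes = m.axes()
    from scipy.interpolate import RegularGridInterpolator
    g = np.stack([
        RegularGridInterpolator(axes, gd, method="linear",
                                bounds_error=False, fill_value=0.0)(vertices)
        for gd in grads
    ], axis=1)
    norms = np.linalg.norm(g, axis=1)
    norms[norms == 0] = 1.0
    normals = -g / norms[:, None]  # outward = down-gradient
    return IsoSurface(vertices=vertices, faces=faces, normals=normals,
                      isovalue=isovalue)


def nearest_surface_point(surf: IsoSurface, point) -> tuple[int, float]:
    """Exact nearest vertex to ``point``; ties broken by lowest index."""
    pt = np.asarray(point, dtype=np.float64)
    dist, idx = surf.kdtree().query(pt)
    # resolve ties deterministically: any vertex within float slack of dist
    cand = surf.kdtree().query_ball_point(pt, dist * (1 + 1e-12) + 1e-12)
    if len(cand) > 1:
        d = np.linalg.norm(surf.vertices[cand] - pt, axis=1)
        best = d.min()
        idx = min(c for c, dd in zip(cand, d) if dd <= best * (1 + 1e-12) + 1e-12)
        dist = best
    return int(idx), float(dist)


def complementarity_score(receptor_surf: IsoSurface, ligand_surf: IsoSurface,
                          pose_transform: RigidTransform | None = None,
                          p: ScoreParams | None = None) -> float:
    """Surface-complementarity score of a ligand placement; higher is better.

    The ligand surface is moved by ``pose_transform`` (identity if None),
    then::

        score =  sum over ligand vertices v with dist(v, receptor) <= contact
                    of max(0, -n_v . n_r(v))
               - clash_penalty * #{ligand vertices strictly inside receptor}

    where ``n_r(v)`` is the outward normal of the nearest receptor vertex and
    "inside" means ``(v - nearest) . n_r(v) < -clash_depth``.  Perfectly
    apposed anti-parallel patches contribute 1 per vertex; well-separated
    surfaces score exactly 0; deep interpenetration is driven negative.  A
    pose is called *positive* iff its score is > 0.
    """
    p = p or ScoreParams()
    if pose_transform is not None:
        lv = pose_transform.apply(ligand_surf.vertices)
        ln = pose_transform.apply_vectors(ligand_surf.normals)
    else:
        lv, ln = ligand_surf.vertices, ligand_surf.normals

    tree = receptor_surf.kdtree()
    dist, idx = tree.query(lv)
    rn = receptor_surf.normals[idx]
    rv = receptor_surf.vertices[idx]

    signed = np.einsum("ij,ij->i", lv - rv, rn)
    inside = signed < -p.clash_depth
    contact = dist <= p.contact_distance
    anti = np.maximum(0.0, -np.einsum("ij,ij->i", ln, rn))
    return float(anti[contact].sum() - p.clash_penalty * inside.sum())


def write_obj(surf: IsoSurface, path) -> None:
    """Dump a surface as Wavefront OBJ for visual inspection."""
    with open(path, "w") as fh:
        for v in surf.vertices:
            fh.write(f"v {v[0]:.4f} {v[1]:.4f} {v[2]:.4f}\n")
        for n in surf.normals:
            fh.write(f"vn {n[0]:.4f} {n[1]:.4f} {n[2]:.4f}\n")
        for f in surf.faces:
            i, j, k = f + 1  # OBJ is 1-based
            fh.write(f"f {i}//{i} {j}//{j} {k}//{k}\n")
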