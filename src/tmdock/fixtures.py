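"""Deterministic synthetic dimers with known bound poses.

Real inputs to the pipeline are membrane proteins preoriented in a bilayer
and simulated with MD.  These fixtures stand in for them with minimal
geometry: C-alpha/C-beta pseudo-atom assemblies spanning the bilayer slab
(z in [-15, 15] A), built so that a *known* rigid pose brings the ligand
into snug, clash-free contact with the receptor.  Ensembles are emulated by
i.i.d. Gaussian coordinate jitter — deliberately simpler than correlated MD
fluctuations, but enough to exercise frame-averaged map building.  Every
fixture is a deterministic function of its seed.

Two styles:

* ``bundle`` — receptor = three parallel pseudo-helical rods arranged to
  leave a groove; ligand = a single rod that fits that groove.
* ``ridge_groove`` — receptor = a block lattice with a vertical groove cut
  into one face; ligand = a block carrying the matching ridge.  The unique
  ridge-in-groove fit makes this the pose-recovery test case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import TmdockError
from .search import Pose, pose_to_transform
from .structio import Ensemble, StructureModel, apply_transform


@dataclass
class ToyDimer:
    """A synthetic receptor/ligand pair with its known bound pose.

    Both partners are origin-centered and preoriented (TM center of mass at
    z = 0); ``true_pose`` moves the ligand into contact: closest heavy-atom
    approach within [2, 6] A and no pair closer than 1.5 A.
    """

    receptor: StructureModel
    ligand: StructureModel
    true_pose: Pose
    description: str = ""

    def bound_ligand(self) -> StructureModel:
        return apply_transform(self.ligand, pose_to_transform(self.true_pose))

    def reference_complex(self) -> tuple[StructureModel, StructureModel]:
        return self.receptor, self.bound_ligand()


def _make_structure(coords: np.ndarray, chain: str) -> StructureModel:
    """Pack pseudo-atom coordinates as alternating CA/CB alanine residues.

    Atoms arrive in pairs (CA then CB); every pair is one residue.  All
    atoms are carbon, so mass weighting is uniform by construction.
    """
    n = len(coords)
    if n % 2:
        raise ValueError("expected an even number of pseudo-atoms")
    n_res = n // 2
    return StructureModel(
        chain_ids=np.full(n, chain),
        residue_numbers=np.repeat(np.arange(1, n_res + 1), 2),
        residue_names=np.full(n, "ALA"),
        atom_names=np.tile(["CA", "CB"], n_res),
        elements=np.full(n, "C"),
        coords=coords,
    )


def _rod(center_xy: tuple[float, float], z_lo: float = -14.25,
         z_hi: float = 14.25, rise: float = 1.5,
         cb_direction: tuple[float, float] = (1.0, 0.0),
         cb_offset: float = 1.5) -> np.ndarray:
    """A straight pseudo-helix: CA every ``rise`` A along z, CB offset
    laterally — 2 atoms per residue."""
    z = np.arange(z_lo, z_hi + 1e-9, rise)
    cx, cy = center_xy
    dx, dy = np.asarray(cb_direction) / np.linalg.norm(cb_direction)
    coords = []
    for zi in z:
        coords.append([cx, cy, zi])
        coords.append([cx + cb_offset * dx, cy + cb_offset * dy, zi])
    return np.array(coords)


def _centered(coords: np.ndarray, xy_only: bool = True) -> np.ndarray:
    """Shift so the centroid is at the origin (x/y always, z by symmetry)."""
    c = coords.mean(axis=0)
    if xy_only:
        c = np.array([c[0], c[1], 0.0])
    return coords - c


def _lattice_block(x_range, y_range, z_range, a: float) -> np.ndarray:
    xs = np.arange(x_range[0], x_range[1] + 1e-9, a)
    ys = np.arange(y_range[0], y_range[1] + 1e-9, a)
    zs = np.arange(z_range[0], z_range[1] + 1e-9, a)
    g = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
    return g.reshape(-1, 3)


def _bundle_dimer() -> tuple[np.ndarray, np.ndarray, Pose]:
    """Three receptor rods on a circle leaving a groove; one ligand rod."""
    radius = 5.5
    angles = np.deg2rad([90.0, 210.0, 330.0])
    rec = []
    for ang in angles:
        cx, cy = radius * np.cos(ang), radius * np.sin(ang)
        rec.append(_rod((cx, cy), cb_direction=(np.cos(ang), np.sin(ang))))
    rec = np.vstack(rec)
    lig = _rod((0.0, 0.0), cb_direction=(0.0, -1.0))
    # dock the ligand rod into the gap between the two lower rods
    true_pose = Pose(tx=0.0, ty=-6.0, tz=0.0, ax=0.0, ay=0.0, az=1.0,
                     theta=0.0)
    return _centered(rec), _centered(lig), true_pose


def _ridge_groove_dimer() -> tuple[np.ndarray, np.ndarray, Pose]:
    """Complementary block lattices: vertical groove on the receptor's +x
    face, matching ridge on the ligand's -x face."""
    a = 2.0  # lattice constant, A
    rec = _lattice_block((-6, 6), (-8, 8), (-14, 14), a)
    # cut the groove: remove the outermost +x layer for |y| <= 2
    groove = (np.isclose(rec[:, 0], 6.0)) & (np.abs(rec[:, 1]) <= 2.0 + 1e-9)
    rec = rec[~groove]
    lig = _lattice_block((-4, 4), (-6, 6), (-14, 14), a)
    ridge = _lattice_block((-6, -6), (-2, 2), (-14, 14), a)
    lig = np.vstack([lig, ridge])
    # pad to an even atom count for CA/CB pairing (duplicate-free)
    true_pose = Pose(tx=12.8, ty=0.0, tz=0.0, ax=0.0, ay=0.0, az=1.0,
                     theta=0.0)
    return rec, _centered(lig), true_pose


def _as_pseudo_residues(coords: np.ndarray) -> np.ndarray:
    """Trim to an even count so coordinates pack into CA/CB residue pairs."""
    if len(coords) % 2:
        coords = coords[:-1]
    return coords


def verify_contact(dimer: ToyDimer, lo: float = 2.0, hi: float = 6.0,
                   clash: float = 1.5) -> float:
    """Closest receptor-ligand approach at the true pose; raises if the
    contact-without-clash invariant is violated."""
    bound = dimer.bound_ligand()
    d, _ = cKDTree(dimer.receptor.coords).query(bound.coords)
    dmin = float(d.min())
    if not lo <= dmin <= hi:
        raise TmdockError(
            f"true pose closest approach {dmin:.2f} A outside [{lo}, {hi}]"
        )
    return dmin


def make_toy_dimer(style: str, seed: int = 0) -> ToyDimer:
    """Build a deterministic toy dimer of the given style.

    ``seed`` perturbs atom positions by a tiny (0.05 A) deterministic
    jitter so distinct seeds give distinct but equivalent geometries; the
    contact invariant is verified on every construction.
    """
    if style == "bundle":
        rec, lig, pose = _bundle_dimer()
    elif style == "ridge_groove":
        rec, lig, pose = _ridge_groove_dimer()
    else:
        raise ValueError(f"unknown dimer style {style!r}")
    rng = np.random.default_rng(seed)
    rec = _as_pseudo_residues(rec)
    lig = _as_pseudo_residues(lig)
    rec = rec + rng.normal(0.0, 0.05, rec.shape)
    lig = lig + rng.normal(0.0, 0.05, lig.shape)
    dimer = ToyDimer(
        receptor=_make_structure(rec, "A"),
        ligand=_make_structure(lig, "B"),
        true_pose=pose,
        description=f"{style} toy dimer, seed {seed}",
    )
    verify_contact(dimer)
    return dimer


def make_jitter_ensemble(s: StructureModel, sigma: float, n_frames: int,
                         seed: int = 0) -> Ensemble:
    """Ensemble of ``n_frames`` i.i.d. Gaussian-jittered copies of ``s``.

    A stand-in for MD production frames: per-atom, per-frame displacements
    of width ``sigma`` (A), with no inter-atom correlation.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    base = s.coords[None, :, :]
    noise = rng.normal(0.0, sigma, (n_frames, s.n_atoms, 3)) if sigma > 0 \
        else np.zeros((n_frames, s.n_atoms, 3))
    return Ensemble(frames=base + noise)


def plant_decoys(dimer: ToyDimer, n: int, seed: int = 0,
                 ) -> list[tuple[Pose, "object"]]:
    """Near-native and far decoy poses, each labeled with its CAPRI tier.

    The first pose is the true pose itself; subsequent near-native decoys
    perturb it with growing translation/rotation magnitude, and the far
    decoys are large in-plane displacements.  Tiers are *computed* by the
    assessment metrics against the true-pose reference, never asserted a
    priori.
    """
    from .assess import assess_model

    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    reference = dimer.reference_complex()
    tp = dimer.true_pose
    out = []
    for i in range(n):
        if i == 0:
            pose = tp
        elif i < max(1, n - n // 3):
            mag = 0.5 * i  # growing perturbation, A / tenths of rad
            direction = rng.normal(size=2)
            direction /= np.linalg.norm(direction)
            pose = Pose(
                tx=tp.tx + mag * direction[0], ty=tp.ty + mag * direction[1],
                tz=tp.tz, ax=tp.ax, ay=tp.ay, az=tp.az,
                theta=(tp.theta + 0.02 * i) % (2 * np.pi),
            )
        else:
            pose = Pose(tx=tp.tx + 50.0 + 5.0 * i, ty=tp.ty - 40.0,
                        tz=tp.tz, ax=tp.ax, ay=tp.ay, az=tp.az,
                        theta=rng.uniform(0, 2 * np.pi))
        posed = apply_transform(dimer.ligand, pose_to_transform(pose))
        report = assess_model((dimer.receptor, posed), reference)
        out.append((pose, report.tier))
    return out
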