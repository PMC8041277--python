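"""CAPRI-style model quality assessment and case difficulty classification.

Three metrics compare a predicted complex with a reference:

* ``fnat`` — the fraction of the reference's residue-residue contacts (any
  heavy-atom pair within 5 A) reproduced by the model;
* ligand RMSD — C-alpha RMSD of the model's ligand after superposing the
  model receptor onto the reference receptor;
* interface RMSD — C-alpha RMSD over interface residues (any heavy atom
  within 10 A of the binding partner, selected on the reference) after
  superposing the interfaces.

The tier ladder (incorrect / acceptable / intermediate / high) applies the
CAPRI threshold inequalities in order, rejecting incorrect models first.
Case difficulty (easy / medium / difficult) is the interface C-alpha RMSD
between a bound and an unbound conformation of the same partners.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    CorrespondenceError,
    DegenerateReferenceError,
    DegenerateSuperpositionError,
)
from .structio import RigidTransform, StructureModel

ComplexPair = tuple[StructureModel, StructureModel]

CONTACT_CUTOFF = 5.0      # A, heavy-atom contact definition
INTERFACE_CUTOFF = 10.0   # A, interface residue selection


class Tier(IntEnum):
    """CAPRI model-quality tiers, ordered worst to best."""

    INCORRECT = 0
    ACCEPTABLE = 1
    INTERMEDIATE = 2
    HIGH = 3

    def __str__(self) -> str:
        return self.name.lower()

    # IntEnum formats as a bare int since Python 3.11; reports want the name
    def __format__(self, spec: str) -> str:
        return format(str(self), spec)


@dataclass
class QualityReport:
    fnat: float
    ligand_rmsd: float
    interface_rmsd: float
    tier: Tier

    def __post_init__(self) -> None:
        if not 0.0 <= self.fnat <= 1.0:
            raise ValueError("fnat outside [0, 1]")
        if self.ligand_rmsd < 0 or self.interface_rmsd < 0:
            raise ValueError("RMSDs must be >= 0")


@dataclass
class DifficultyClass:
    delta_interface_rmsd: float
    label: str

    def __post_init__(self) -> None:
        if self.label not in ("easy", "medium", "difficult"):
            raise ValueError(f"unknown difficulty label {self.label!r}")


# ---------------------------------------------------------------------------
# contacts and fnat
# ---------------------------------------------------------------------------

def native_contacts(complex_pair: ComplexPair,
                    cutoff: float = CONTACT_CUTOFF) -> set[tuple[str, str]]:
    """Residue-residue contacts across the interface.

    Returns the unordered set of ``(receptor "chain:resnum",
    ligand "chain:resnum")`` pairs with *any* heavy-atom pair within
    ``cutoff``.  Hydrogens are ignored so models with and without protons
    compare symmetrically.
    """
    receptor, ligand = complex_pair
    rmask, lmask = receptor.heavy_mask(), ligand.heavy_mask()
    if not rmask.any() or not lmask.any():
        return set()
    rkeys = receptor.residue_keys()[rmask]
    lkeys = ligand.residue_keys()[lmask]
    pairs = cKDTree(receptor.coords[rmask]).query_ball_tree(
        cKDTree(ligand.coords[lmask]), cutoff)
    contacts = set()
    for ri, lis in enumerate(pairs):
        for li in lis:
            contacts.add((rkeys[ri], lkeys[li]))
    return contacts


def fnat(model: ComplexPair, reference: ComplexPair,
         cutoff: float = CONTACT_CUTOFF,
         denominator: str = "reference") -> float:
    """Fraction of reference contacts reproduced by the model.

    ``denominator="reference"`` is the CAPRI convention (native contact
    count); ``"model_residues"`` divides by the number of residues in the
    predicted complex instead, for comparison with the looser literal
    definition.  A contact-free reference is degenerate.
    """
    ref_contacts = native_contacts(reference, cutoff)
    if not ref_contacts:
        raise DegenerateReferenceError("reference complex has no contacts")
    model_contacts = native_contacts(model, cutoff)
    common = len(model_contacts & ref_contacts)
    if denominator == "reference":
        return common / len(ref_contacts)
    if denominator == "model_residues":
        n_res = (len(set(model[0].residue_keys()))
                 + len(set(model[1].residue_keys())))
        return common / n_res
    raise ValueError(f"unknown denominator {denominator!r}")


# ---------------------------------------------------------------------------
# superposition and RMSD metrics
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray,
              target: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Proper rotations only (Kabsch); returns the transform and the minimized
    RMSD.  Fewer than 3 points or collinear sets are degenerate.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if mobile.shape != target.shape:
        raise CorrespondenceError(
            f"point sets differ in shape: {mobile.shape} vs {target.shape}"
        )
    if len(mobile) < 3:
        raise DegenerateSuperpositionError("need at least 3 points")
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    a, b = mobile - mc, target - tc
    if np.linalg.matrix_rank(a, tol=1e-8) < 2 or \
       np.linalg.matrix_rank(b, tol=1e-8) < 2:
        raise DegenerateSuperpositionError("collinear point set")
    # Kabsch: the RMSD is recomputed from the residuals rather than from the
    # singular values, which loses half the digits to cancellation
    H = a.T @ b
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    rmsd = np.sqrt(np.mean(np.sum((a @ R.T - b) ** 2, axis=1)))
    t = RigidTransform(rotation=R, translation=tc - mc, center=mc)
    return t, float(rmsd)


def _matched_calpha(a: StructureModel, b: StructureModel,
                    restrict_to: set[str] | None = None,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Paired C-alpha coordinates of two structures, by (chain, resnum).

    A missing counterpart on either side is a hard correspondence error;
    silent subsetting would corrupt RMSD comparability.
    """
    def ca_map(s: StructureModel) -> dict[str, np.ndarray]:
        mask = s.calpha_mask()
        keys = s.residue_keys()[mask]
        coords = s.coords[mask]
        return dict(zip(keys, coords))

    ma, mb = ca_map(a), ca_map(b)
    if set(ma) != set(mb):
        diff = sorted(set(ma) ^ set(mb))[:5]
        raise CorrespondenceError(
            f"model/reference residue sets differ, e.g. {diff}")
    keys = sorted(mb)
    if restrict_to is not None:
        keys = [k for k in keys if k in restrict_to]
    if not keys:
        raise CorrespondenceError("no corresponding C-alpha atoms")
    return (np.array([ma[k] for k in keys]), np.array([mb[k] for k in keys]))


def ligand_rmsd(model: ComplexPair, reference: ComplexPair) -> float:
    """C-alpha RMSD of the ligand after fitting the receptors.

    The model receptor is superposed onto the reference receptor; the same
    transform is applied to the model ligand, whose C-alpha RMSD to the
    reference ligand is returned without further fitting.
    """
    mrec, mlig = model
    rrec, rlig = reference
    mob, tgt = _matched_calpha(mrec, rrec)
    t, _ = superpose(mob, tgt)
    mlig_ca, rlig_ca = _matched_calpha(mlig, rlig)
    moved = t.apply(mlig_ca)
    return float(np.sqrt(np.mean(np.sum((moved - rlig_ca) ** 2, axis=1))))


def _interface_residues(reference: ComplexPair,
                        cutoff: float) -> tuple[set[str], set[str]]:
    """Interface residue keys (receptor side, ligand side), defined on the
    reference: any heavy atom within ``cutoff`` of the binding partner."""
    contacts = native_contacts(reference, cutoff)
    rec = {r for r, _ in contacts}
    lig = {l for _, l in contacts}
    return rec, lig


def interface_rmsd(model: ComplexPair, reference: ComplexPair,
                   interface_cutoff: float = INTERFACE_CUTOFF) -> float:
    """C-alpha RMSD over reference-defined interface residues after
    superposing the model interface onto the reference interface."""
    rec_if, lig_if = _interface_residues(reference, interface_cutoff)
    if not rec_if and not lig_if:
        raise DegenerateReferenceError("reference complex has no interface")
    mob_r, tgt_r = _matched_calpha(model[0], reference[0], restrict_to=rec_if)
    mob_l, tgt_l = _matched_calpha(model[1], reference[1], restrict_to=lig_if)
    mob = np.vstack([mob_r, mob_l])
    tgt = np.vstack([tgt_r, tgt_l])
    _, rmsd = superpose(mob, tgt)
    return rmsd


# ---------------------------------------------------------------------------
# tier / difficulty classification
# ---------------------------------------------------------------------------

def classify_quality(fnat_value: float, rmsd: float, irmsd: float) -> Tier:
    """CAPRI tier of a model given its three metrics.

    Applied in order, incorrect first:

    * incorrect     fnat < 0.1, or (RMSD > 10 and iRMSD > 4)
    * high          fnat >= 0.5 and (RMSD <= 1 or iRMSD <= 1)
    * intermediate  fnat >= 0.3 and (RMSD <= 5 or iRMSD <= 2)
    * acceptable    otherwise (fnat >= 0.1 and (RMSD <= 10 or iRMSD <= 4)
      necessarily hold once the incorrect test fails)
    """
    if fnat_value < 0.1 or (rmsd > 10.0 and irmsd > 4.0):
        return Tier.INCORRECT
    if fnat_value >= 0.5 and (rmsd <= 1.0 or irmsd <= 1.0):
        return Tier.HIGH
    if fnat_value >= 0.3 and (rmsd <= 5.0 or irmsd <= 2.0):
        return Tier.INTERMEDIATE
    return Tier.ACCEPTABLE


def assess_model(model: ComplexPair, reference: ComplexPair) -> QualityReport:
    """All three metrics plus the tier for one model vs the reference."""
    f = fnat(model, reference)
    r = ligand_rmsd(model, reference)
    ir = interface_rmsd(model, reference)
    return QualityReport(fnat=f, ligand_rmsd=r, interface_rmsd=ir,
                         tier=classify_quality(f, r, ir))


def difficulty_from_delta(delta: float) -> DifficultyClass:
    if delta < 1.0:
        label = "easy"
    elif delta <= 2.5:
        label = "medium"
    else:
        label = "difficult"
    return DifficultyClass(delta_interface_rmsd=float(delta), label=label)


def classify_difficulty(bound: ComplexPair,
                        unbound: ComplexPair) -> DifficultyClass:
    """Case difficulty from the bound-vs-unbound interface flexibility.

    Delta is the interface C-alpha RMSD obtained by superposing the unbound
    interface onto the bound interface (interface defined on the bound
    complex): < 1 A easy, 1-2.5 A medium, > 2.5 A difficult.
    """
    delta = interface_rmsd(unbound, bound)
    return difficulty_from_delta(delta)


# ---------------------------------------------------------------------------
# shortlist assessment
# ---------------------------------------------------------------------------

def report_top_n(result, receptor: StructureModel, ligand: StructureModel,
                 reference: ComplexPair, n: int = 10,
                 ) -> tuple[Tier, int | None, list[QualityReport]]:
    """Assess the top ``n`` ranked models of a docking result.

    Each model is realized by applying its pose to the (origin-centered)
    ligand.  Returns the best tier achieved, the rank of the first model of
    acceptable-or-better quality (None if none), and all reports in rank
    order.
    """
    from .search import pose_to_transform
    from .structio import apply_transform

    reports: list[QualityReport] = []
    best = Tier.INCORRECT
    first_success: int | None = None
    for m in result.models[:n]:
        posed = apply_transform(ligand, pose_to_transform(m.pose))
        rep = assess_model((receptor, posed), reference)
        reports.append(rep)
        if rep.tier > best:
            best = rep.tier
        if first_success is None and rep.tier >= Tier.ACCEPTABLE:
            first_success = m.rank
    return best, first_success, reports


def write_assessment_table(reports: list[QualityReport], path) -> None:
    """Tab-separated per-model assessment: rank, fnat, RMSD, iRMSD, tier."""
    with open(path, "w") as fh:
        fh.write("rank\tfnat\tligand_rmsd\tinterface_rmsd\ttier\n")
        for i, rep in enumerate(reports, start=1):
            fh.write(f"{i}\t{rep.fnat:.4f}\t{rep.ligand_rmsd:.4f}\t"
                     f"{rep.interface_rmsd:.4f}\t{rep.tier}\n")
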