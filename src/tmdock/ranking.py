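"""Representative selection, ranking and model emission.

A docking search evaluates tens of thousands of poses; only those with a
positive complementarity score describe surfaces actually in contact.  To
return a *diverse* shortlist rather than hundreds of near-duplicates of the
best basin, the positive-score pool is clustered with K-means in pose space
and the best-scoring member of each cluster is kept, ranked by raw score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .search import Pose, SearchSpace, SearchTrace, pose_to_transform
from .structio import StructureModel, apply_transform, write_model_pdb

logger = logging.getLogger(__name__)


@dataclass
class ScoredPose:
    pose: Pose
    raw_score: float
    rank: int | None = None


@dataclass
class DockingResult:
    """Ranked shortlist of docked poses (descending raw score)."""

    models: list[ScoredPose]
    n_requested: int = 300
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.models) > self.n_requested:
            raise ValueError("more models than requested")
        scores = [m.raw_score for m in self.models]
        if any(s <= 0 for s in scores):
            raise ValueError("ranked models must all have positive scores")
        if any(scores[i] < scores[i + 1] for i in range(len(scores) - 1)):
            raise ValueError("models must be sorted by descending score")

    def __len__(self) -> int:
        return len(self.models)


def _pose_features(poses: list[Pose],
                   space: SearchSpace | None) -> np.ndarray:
    """Range-normalized clustering features of the 7D pose coordinates.

    Translations are scaled to [0, 1] by the search-space bounds (or the
    observed range when no space is given); the rotation axis components are
    already unit-scale; theta is embedded on the unit circle as
    (cos theta, sin theta) so 0 and 2 pi are neighbours — 8 features total.
    """
    arr = np.array([p.as_array() for p in poses])
    t = arr[:, :3]
    if space is not None:
        lo = np.array([space.tx_bounds[0], space.ty_bounds[0],
                       space.tz_bounds[0]])
        hi = np.array([space.tx_bounds[1], space.ty_bounds[1],
                       space.tz_bounds[1]])
    else:
        lo, hi = t.min(axis=0), t.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    t_norm = (t - lo) / span
    theta = arr[:, 6]
    return np.column_stack([t_norm, arr[:, 3:6],
                            np.cos(theta), np.sin(theta)])


def select_representatives(trace: SearchTrace, k: int = 300, seed: int = 0,
                           space: SearchSpace | None = None) -> DockingResult:
    """Pick up to ``k`` diverse representatives of the positive-score pool.

    Poses with raw score > 0 are clustered with K-means (k-means++ init, 10
    restarts, deterministic via ``seed``) on the normalized pose features;
    each cluster contributes its highest-raw-score member (ties broken by
    earlier evaluation order).  With ``k`` or fewer positive poses all are
    returned.  Zero positive poses yield an empty result with a warning —
    the documented "docking failed" signal.
    """
    if trace.eval_count == 0:
        raise ValueError("empty search trace")
    poses = trace.poses()
    raw = trace.raw_scores()
    pos_idx = np.flatnonzero(raw > 0)
    provenance = {"k": k, "seed": seed, "n_evaluations": trace.eval_count,
                  "n_positive": int(pos_idx.size)}

    if pos_idx.size == 0:
        warnings.warn("no positive-score poses: docking failed to find "
                      "surface contact", stacklevel=2)
        return DockingResult(models=[], n_requested=k, provenance=provenance)

    pos_poses = [poses[i] for i in pos_idx]
    pos_raw = raw[pos_idx]

    if pos_idx.size <= k:
        chosen = np.arange(pos_idx.size)
    else:
        feats = _pose_features(pos_poses, space)
        km = KMeans(n_clusters=k, init="k-means++", n_init=10, max_iter=300,
                    random_state=seed)
        labels = km.fit_predict(feats)
        chosen = []
        for lab in range(k):
            members = np.flatnonzero(labels == lab)
            if members.size == 0:
                continue  # honest shortfall rather than padding
            # argmax returns the first (= earliest-evaluated) maximum
            chosen.append(members[np.argmax(pos_raw[members])])
        chosen = np.asarray(chosen)
        if chosen.size < k:
            logger.warning("%d empty clusters: returning %d models",
                           k - chosen.size, chosen.size)

    # sort by descending score; stable sort keeps evaluation order on ties
    order = chosen[np.argsort(-pos_raw[chosen], kind="stable")]
    models = [
        ScoredPose(pose=pos_poses[i], raw_score=float(pos_raw[i]), rank=r + 1)
        for r, i in enumerate(order)
    ]
    return DockingResult(models=models, n_requested=k, provenance=provenance)


def write_ranking_table(result: DockingResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\ttx\tty\ttz\tax\tay\taz\ttheta\tscore\n")
        for m in result.models:
            p = m.pose
            fh.write(
                f"{m.rank}\t{p.tx:.6f}\t{p.ty:.6f}\t{p.tz:.6f}\t"
                f"{p.ax:.6f}\t{p.ay:.6f}\t{p.az:.6f}\t{p.theta:.6f}\t"
                f"{m.raw_score:.6f}\n"
            )


def emit_models(result: DockingResult, receptor: StructureModel,
                ligand: StructureModel, outdir) -> list[Path]:
    """Write each ranked model as a receptor+posed-ligand PDB plus a table.

    Returns the model file paths (rank order).  An empty result writes the
    table header only.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for m in result.models:
        posed = apply_transform(ligand, pose_to_transform(m.pose))
        path = outdir / f"model_{m.rank:04d}.pdb"
        write_model_pdb(receptor, posed, path)
        paths.append(path)
    write_ranking_table(result, outdir / "ranking.tsv")
    return paths
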