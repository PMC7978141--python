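"""Ground-truth evaluation of montages against individual head models.

The atlas-based estimators GIA^ and GIV^ predict montage quality from
population statistics alone.  This module computes the *actual* group imaging
accuracy (GIA) and group imaging variability (GIV) from individual anatomy:
each participant's channel positions are projected from scalp to cortex, moved
to common space, and summarized per channel as

    GIV_i = sqrt( (1 / (N_p - 1)) * sum_j ||b_ij - mean_j b_ij||^2 )   [mm]
    GIA_i = (1 / N_p) * sum_j 1[label(b_ij) in ROI]

with montage-level GIV and GIA the means over channels.  The gap between the
estimators and the ground truth decomposes exactly into an anatomy term
(epsilon_1: population correspondence standing in for individual anatomy) and
a placement term (epsilon_2: realized optode positions deviating from the
intended ones):

    GIA = GIA^ + eps1A + eps2A        GIV = GIV^ + eps1V + eps2V

where eps1 compares intended-position projections against the atlas estimate
and eps2 compares realized-position against intended-position projections.
Both identities hold to machine precision by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigurationError, TBAMontageError
from .mesh import ScalpMesh
from .cpc import compute_cpc, cpc_to_xyz

#: balloon-style projection: brain vertices within (min distance + delta) of the
#: scalp point form the candidate patch whose centroid picks the output vertex
PROJECTION_DELTA = 3.0  # mm


@dataclass
class HeadModel:
    """One individual: scalp mesh, cortical surface, vertex labels, and the
    affine mapping native mm coordinates into common (MNI-like) space."""

    scalp: ScalpMesh
    brain_vertices: np.ndarray            # (B, 3), native mm
    brain_faces: np.ndarray               # (Fb, 3)
    labels: np.ndarray                    # (B,) str, one label per brain vertex
    to_common: np.ndarray                 # (4, 4) affine
    name: str = "head"
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.brain_vertices = np.asarray(self.brain_vertices, dtype=float)
        self.labels = np.asarray(self.labels)
        self.to_common = np.asarray(self.to_common, dtype=float)
        if len(self.labels) != len(self.brain_vertices):
            raise ConfigurationError("one label required per brain vertex")
        if self.to_common.shape != (4, 4):
            raise ConfigurationError("to_common must be a 4x4 affine")

    @property
    def brain_tree(self) -> cKDTree:
        if "tree" not in self._cache:
            self._cache["tree"] = cKDTree(self.brain_vertices)
        return self._cache["tree"]

    def common(self, points: np.ndarray) -> np.ndarray:
        """Apply the native-to-common affine to native-space points (mm)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = p @ self.to_common[:3, :3].T + self.to_common[:3, 3]
        return out[0] if np.asarray(points).ndim == 1 else out

    def min_clearance(self, n_sample: int = 200, seed: int = 0) -> float:
        """Smallest scalp-to-brain distance (mm) over sampled brain vertices;
        positive when the brain lies strictly inside the scalp."""
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(self.brain_vertices),
                         size=min(n_sample, len(self.brain_vertices)),
                         replace=False)
        _, dist = self.scalp.snap_to_surface(self.brain_vertices[idx])
        return float(np.min(dist))

    # ------------------------------------------------------------------- io
    def save(self, directory: str | Path):
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.scalp.save(d / "scalp.ply", d / "scalp.fiducials.json")
        import trimesh
        trimesh.Trimesh(self.brain_vertices, self.brain_faces,
                        process=False).export(d / "brain.ply")
        pd.DataFrame({"vertex_id": np.arange(len(self.labels)),
                      "label": self.labels}).to_csv(
            d / "labels.tsv", sep="\t", index=False)
        with open(d / "affine.json", "w") as fh:
            json.dump(self.to_common.tolist(), fh)

    @classmethod
    def load(cls, directory: str | Path) -> "HeadModel":
        import trimesh
        d = Path(directory)
        scalp = ScalpMesh.load(d / "scalp.ply", d / "scalp.fiducials.json")
        brain = trimesh.load(d / "brain.ply", force="mesh", process=False)
        lab = pd.read_csv(d / "labels.tsv", sep="\t")
        lab = lab.sort_values("vertex_id")["label"].to_numpy()
        with open(d / "affine.json") as fh:
            affine = np.asarray(json.load(fh), dtype=float)
        return cls(scalp=scalp, brain_vertices=np.asarray(brain.vertices),
                   brain_faces=np.asarray(brain.faces), labels=lab,
                   to_common=affine, name=d.name)


# --------------------------------------------------------------------------
# scalp-to-cortex projection
# --------------------------------------------------------------------------

def project_to_brain(head: HeadModel, scalp_point: np.ndarray,
                     delta: float = PROJECTION_DELTA,
                     return_index: bool = False):
    """Balloon-style scalp-to-cortex projection.

    The candidate patch is the set of brain vertices within ``min distance +
    delta`` of the scalp point; the output is the brain vertex nearest to the
    patch centroid.  Deterministic and idempotent (projecting a brain vertex
    returns that vertex, since its own distance is zero and it is its own
    nearest patch member when the patch collapses).
    """
    if len(head.brain_vertices) == 0:
        raise TBAMontageError("head model has an empty brain mesh")
    p = np.asarray(scalp_point, dtype=float).reshape(3)
    dmin, vi0 = head.brain_tree.query(p)
    if dmin < 1e-9:
        # the point already lies on a brain vertex; the projection fixes it
        vi0 = int(vi0)
        if return_index:
            return head.brain_vertices[vi0].copy(), vi0
        return head.brain_vertices[vi0].copy()
    patch_idx = head.brain_tree.query_ball_point(p, dmin + delta)
    centroid = head.brain_vertices[patch_idx].mean(axis=0)
    _, vi = head.brain_tree.query(centroid)
    vi = int(vi)
    if return_index:
        return head.brain_vertices[vi].copy(), vi
    return head.brain_vertices[vi].copy()


# --------------------------------------------------------------------------
# indices
# --------------------------------------------------------------------------

def compute_giv(points: np.ndarray) -> float:
    """Per-channel group imaging variability (mm).

    ``points`` is the (N_p, 3) array of one channel's common-space brain
    locations, one row per participant.  Returns the root of the pooled
    per-axis sample variances.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ConfigurationError("expected an (N_p, 3) point array")
    if len(pts) < 2:
        raise ConfigurationError("GIV requires at least two participants")
    if np.all(pts == pts[0]):
        return 0.0          # coincident locations: exactly zero dispersion
    dev = pts - pts.mean(axis=0)
    return float(np.sqrt(np.sum(dev * dev) / (len(pts) - 1)))


def montage_giv(channel_givs) -> float:
    """Montage-level GIV: mean of the per-channel values (mm)."""
    return float(np.mean(np.asarray(channel_givs, dtype=float)))


def compute_gia(indicators) -> float:
    """Per-channel group imaging accuracy: fraction of participants whose
    channel projection carries an ROI label (indicators in {0, 1})."""
    ind = np.asarray(indicators, dtype=float)
    if len(ind) < 1:
        raise ConfigurationError("GIA requires at least one participant")
    if not np.all((ind == 0) | (ind == 1)):
        raise ConfigurationError("indicators must be 0/1")
    return float(np.mean(ind))


def montage_gia(channel_gias) -> float:
    """Montage-level GIA: mean of the per-channel values."""
    return float(np.mean(np.asarray(channel_gias, dtype=float)))


def scalp_variability(channel_cpcs: np.ndarray, typical_scalp: ScalpMesh) -> float:
    """Scalp-space location variability of one channel (mm).

    Each participant's channel CPC is mapped to 3D on the typical scalp and
    the same dispersion formula as :func:`compute_giv` is applied.
    """
    cpcs = np.asarray(channel_cpcs, dtype=float)
    if cpcs.ndim != 2 or cpcs.shape[1] != 2:
        raise ConfigurationError("expected an (N_p, 2) CPC array")
    if len(cpcs) < 2:
        raise ConfigurationError("scalp variability requires >= 2 participants")
    pts = np.array([cpc_to_xyz(typical_scalp, c) for c in cpcs])
    return compute_giv(pts)


# --------------------------------------------------------------------------
# full evaluation
# --------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Actual vs estimated montage quality with the error decomposition.

    Per-channel arrays are indexed like the placement's channel list.  NaN
    marks a channel whose GIV is undefined (fewer than two participants).
    """

    gia_hat: np.ndarray        # atlas estimate per channel
    giv_hat: np.ndarray        # atlas estimate per channel, mm
    gia_ideal: np.ndarray      # individual anatomy, intended positions
    giv_ideal: np.ndarray
    gia_actual: np.ndarray     # individual anatomy, realized positions
    giv_actual: np.ndarray
    scalp_var: np.ndarray      # realized scalp-space variability, mm
    effective: np.ndarray      # bool, per channel (from the placement)
    n_p: int
    n_p_per_channel: np.ndarray

    @property
    def n_c(self) -> int:
        return len(self.gia_hat)

    @property
    def n_ce(self) -> int:
        return int(np.sum(self.effective))

    # channel-wise error terms
    @property
    def eps1A(self) -> np.ndarray:
        return self.gia_ideal - self.gia_hat

    @property
    def eps2A(self) -> np.ndarray:
        return self.gia_actual - self.gia_ideal

    @property
    def eps1V(self) -> np.ndarray:
        return self.giv_ideal - self.giv_hat

    @property
    def eps2V(self) -> np.ndarray:
        return self.giv_actual - self.giv_ideal

    def summary(self) -> dict:
        """Montage-level means (over channels) of every quantity."""
        m = lambda a: float(np.nanmean(a))
        return {
            "GIA_hat": m(self.gia_hat), "GIV_hat_mm": m(self.giv_hat),
            "GIA": m(self.gia_actual), "GIV_mm": m(self.giv_actual),
            "GIA_ideal": m(self.gia_ideal), "GIV_ideal_mm": m(self.giv_ideal),
            "eps1A": m(self.eps1A), "eps2A": m(self.eps2A),
            "eps1V_mm": m(self.eps1V), "eps2V_mm": m(self.eps2V),
            "scalp_variability_mm": m(self.scalp_var),
            "N_p": self.n_p, "N_c": self.n_c, "N_ce": self.n_ce,
        }

    def to_json(self, path: str | Path):
        out = self.summary()
        fields = [("gia_hat", "gia_hat"), ("giv_hat", "giv_hat"),
                  ("gia", "gia_actual"), ("giv", "giv_actual"),
                  ("eps1A", "eps1A"), ("eps2A", "eps2A"),
                  ("eps1V", "eps1V"), ("eps2V", "eps2V"),
                  ("scalp_variability", "scalp_var")]
        out["channels"] = [
            {**{k: float(getattr(self, a)[i]) for k, a in fields},
             "effective": bool(self.effective[i]),
             "n_p": int(self.n_p_per_channel[i])}
            for i in range(self.n_c)]
        with open(path, "w") as fh:
            json.dump(out, fh, indent=1)


def evaluate_montage(heads: list[HeadModel], intended, realized_cpc,
                     roi, atlas, typical_scalp: ScalpMesh | None = None,
                     delta: float = PROJECTION_DELTA) -> EvaluationReport:
    """Evaluate a placed montage against individual head models.

    Parameters
    ----------
    heads : participant head models.
    intended : a :class:`~tbamontage.montage.MontagePlacement` with channels,
        or an (N_c, 2) array of intended channel CPCs (then ``effective``
        flags default to all-True).
    realized_cpc : (N_p, N_c, 2) realized channel CPCs per participant; NaN
        rows mark missing participant-channels and shrink that channel's N_p.
    roi : ROISpec giving the ROI label set.
    atlas : TranscranialAtlas providing GIA^ and GIV^ at the intended CPCs.
    typical_scalp : scalp used for the scalp-space variability metric
        (defaults to the first head's scalp).
    """
    from .atlas import gia_hat_map  # local import to avoid a cycle

    if hasattr(intended, "channels"):
        ch_cpc = np.array([ch.midpoint_cpc for ch in intended.channels])
        effective = np.array([ch.effective for ch in intended.channels])
    else:
        ch_cpc = np.asarray(intended, dtype=float)
        effective = np.ones(len(ch_cpc), dtype=bool)
    realized = np.asarray(realized_cpc, dtype=float)
    n_p, n_c = realized.shape[0], len(ch_cpc)
    if realized.shape[1] != n_c:
        raise ConfigurationError("realized CPC count does not match channels")
    if typical_scalp is None:
        typical_scalp = heads[0].scalp

    amap = gia_hat_map(atlas, roi)
    roi_set = set(roi.roi_labels)
    gia_hat_arr = np.array([amap.value_at(c) for c in ch_cpc])
    giv_hat_arr = np.array(
        [atlas.brain_sigma[atlas.grid.nearest_index(c)] for c in ch_cpc])

    gia_ideal = np.empty(n_c)
    giv_ideal = np.empty(n_c)
    gia_act = np.empty(n_c)
    giv_act = np.empty(n_c)
    svar = np.empty(n_c)
    npc = np.empty(n_c, dtype=int)

    def _project(head, cpc):
        xyz = cpc_to_xyz(head.scalp, cpc)
        bpt, bidx = project_to_brain(head, xyz, delta=delta, return_index=True)
        return head.common(bpt), 1.0 if head.labels[bidx] in roi_set else 0.0

    for i in range(n_c):
        pts_i, ind_i, pts_a, ind_a, cpcs_a = [], [], [], [], []
        for j, head in enumerate(heads):
            if np.any(np.isnan(realized[j, i])):
                continue
            b, l = _project(head, ch_cpc[i])
            pts_i.append(b)
            ind_i.append(l)
            b, l = _project(head, realized[j, i])
            pts_a.append(b)
            ind_a.append(l)
            cpcs_a.append(realized[j, i])
        npc[i] = len(pts_i)
        if npc[i] == 0:
            raise ConfigurationError(f"channel {i} has no realized positions")
        gia_ideal[i] = compute_gia(ind_i)
        gia_act[i] = compute_gia(ind_a)
        if npc[i] >= 2:
            giv_ideal[i] = compute_giv(np.array(pts_i))
            giv_act[i] = compute_giv(np.array(pts_a))
            svar[i] = scalp_variability(np.array(cpcs_a), typical_scalp)
        else:
            giv_ideal[i] = giv_act[i] = svar[i] = np.nan

    return EvaluationReport(
        gia_hat=gia_hat_arr, giv_hat=giv_hat_arr,
        gia_ideal=gia_ideal, giv_ideal=giv_ideal,
        gia_actual=gia_act, giv_actual=giv_act,
        scalp_var=svar, effective=effective,
        n_p=n_p, n_p_per_channel=npc)
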