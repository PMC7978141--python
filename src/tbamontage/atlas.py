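"""Probabilistic scalp-brain correspondence atlases on CPC grids.

A transcranial atlas tabulates, for every point ``s`` of a CPC grid measured
on a typical scalp, the population statistics of where that scalp location
"lands" on the cortex:

* ``P(l | s)`` — the probability that the projection of ``s`` carries brain
  label ``l`` (anatomical parcel or functional region), estimated as the label
  frequency across the population;
* the mean common-space brain coordinate and its dispersion ``sigma_B(s)``,
  which is the atlas-based variability estimator GIV^(s).

The accuracy estimator for an ROI (a set of adjacent labels) is
``GIA^(s) = max_{l in ROI} P(l | s)``; scalp locations with ``GIA^(s) > t``
are the *effective* locations from which montage centers are drawn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (ArrangementInfeasibleError, ConfigurationError,
                     VocabularyError)
from .cpc import CPC, CPCGrid, cpc_to_xyz
from .evaluation import HeadModel, compute_giv, project_to_brain

BACKGROUND = "background"


@dataclass
class ROISpec:
    """Region-of-interest specification for montage design.

    ``mode="adjacent"`` treats the labels as one contiguous target covered by
    a single montage; ``mode="separate"`` signals sequential per-ROI runs.
    """

    roi_labels: tuple[str, ...]
    t: float = 0.5
    mode: str = "adjacent"

    def __post_init__(self):
        self.roi_labels = tuple(self.roi_labels)
        if not self.roi_labels:
            raise ConfigurationError("ROI label set must be non-empty")
        if not (0.0 <= self.t < 1.0):
            raise ConfigurationError("threshold t must satisfy 0 <= t < 1")
        if self.mode not in ("adjacent", "separate"):
            raise ConfigurationError("mode must be 'adjacent' or 'separate'")


@dataclass
class TranscranialAtlas:
    """CPC-gridded scalp-brain correspondence statistics.

    ``prob[g, k]`` is P(labels[k] | grid point g); rows sum to one over the
    vocabulary, which always contains an explicit background label absorbing
    non-ROI cortex and projection misses.  ``brain_sigma`` stores a scalar
    dispersion per grid point (same convention as the evaluation-side GIV).
    """

    grid: CPCGrid
    labels: tuple[str, ...]
    prob: np.ndarray               # (G, L)
    brain_mean: np.ndarray         # (G, 3), common-space mm
    brain_sigma: np.ndarray        # (G,), mm
    n_subjects: int
    mask: np.ndarray | None = None             # (G,) True where valid
    brain_points: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.labels = tuple(self.labels)
        self.prob = np.asarray(self.prob, dtype=float)
        self.brain_mean = np.asarray(self.brain_mean, dtype=float)
        self.brain_sigma = np.asarray(self.brain_sigma, dtype=float)
        if self.mask is None:
            self.mask = np.ones(len(self.grid), dtype=bool)
        if BACKGROUND not in self.labels:
            raise ConfigurationError(
                f"vocabulary must include the '{BACKGROUND}' label")
        if self.prob.shape != (len(self.grid), len(self.labels)):
            raise ConfigurationError("prob must be (grid points, labels)")
        valid = self.mask
        if np.any(self.prob < -1e-12) or np.any(self.prob > 1 + 1e-12):
            raise ConfigurationError("probabilities outside [0, 1]")
        sums = self.prob[valid].sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ConfigurationError(
                "probabilities must sum to 1 (+-1e-9) at every valid grid point")
        if np.any(self.brain_sigma[valid] < 0):
            raise ConfigurationError("brain_sigma must be non-negative")

    def label_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise VocabularyError(f"label {label!r} not in atlas vocabulary")

    # ------------------------------------------------------------------- io
    def save(self, directory: str | Path, stem: str = "atlas"):
        """Write the TSV/JSON bundle: points table, long-format probability
        table, and metadata."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        pts = pd.DataFrame(
            np.hstack([self.grid.cpc, self.grid.xyz, self.brain_mean,
                       self.brain_sigma[:, None],
                       self.mask[:, None].astype(float)]),
            columns=["p1", "p2", "x", "y", "z",
                     "mean_x", "mean_y", "mean_z", "sigma", "valid"])
        pts.to_csv(d / f"{stem}_points.tsv", sep="\t", index=False)
        g, l = np.nonzero(self.prob > 0)
        prob = pd.DataFrame({
            "p1": self.grid.cpc[g, 0], "p2": self.grid.cpc[g, 1],
            "label": [self.labels[k] for k in l], "prob": self.prob[g, l]})
        prob.to_csv(d / f"{stem}_probabilities.tsv", sep="\t", index=False)
        meta = {"labels": list(self.labels), "n_subjects": self.n_subjects,
                "grid_resolution": self.grid.n, "mesh_id": self.grid.mesh_name}
        with open(d / f"{stem}_meta.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, directory: str | Path, stem: str = "atlas") -> "TranscranialAtlas":
        d = Path(directory)
        with open(d / f"{stem}_meta.json") as fh:
            meta = json.load(fh)
        pts = pd.read_csv(d / f"{stem}_points.tsv", sep="\t")
        n = int(meta["grid_resolution"])
        grid = CPCGrid(n=n, cpc=pts[["p1", "p2"]].to_numpy(),
                       xyz=pts[["x", "y", "z"]].to_numpy(),
                       mesh_name=meta.get("mesh_id", "scalp"))
        labels = tuple(meta["labels"])
        lut = {lab: k for k, lab in enumerate(labels)}
        prob = np.zeros((len(grid), len(labels)))
        long = pd.read_csv(d / f"{stem}_probabilities.tsv", sep="\t")
        gidx = {(round(r.p1, 9), round(r.p2, 9)): i
                for i, r in enumerate(pts.itertuples())}
        for r in long.itertuples():
            prob[gidx[(round(r.p1, 9), round(r.p2, 9))], lut[r.label]] = r.prob
        return cls(grid=grid, labels=labels, prob=prob,
                   brain_mean=pts[["mean_x", "mean_y", "mean_z"]].to_numpy(),
                   brain_sigma=pts["sigma"].to_numpy(),
                   n_subjects=int(meta["n_subjects"]),
                   mask=pts["valid"].to_numpy() > 0.5)


@dataclass
class GIAHatMap:
    """Per-grid-point GIA^ values for one ROI specification."""

    grid: CPCGrid
    values: np.ndarray            # (G,), in [0, 1]
    roi: ROISpec

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ConfigurationError("GIA^ values must lie in [0, 1]")

    def value_at(self, cpc) -> float:
        """GIA^ at the grid point nearest to ``cpc`` (no interpolation)."""
        return float(self.values[self.grid.nearest_index(cpc)])


# --------------------------------------------------------------------------
# queries
# --------------------------------------------------------------------------

def gia_hat_map(atlas: TranscranialAtlas, roi: ROISpec) -> GIAHatMap:
    """GIA^(s) = max over ROI labels of P(l | s), per grid point."""
    cols = [atlas.label_index(l) for l in roi.roi_labels]
    values = atlas.prob[:, cols].max(axis=1)
    values = np.where(atlas.mask, values, 0.0)
    return GIAHatMap(grid=atlas.grid, values=values, roi=roi)


def giv_hat(atlas: TranscranialAtlas, s) -> float:
    """GIV^(s): the stored brain-location dispersion (mm) at the grid point
    nearest to ``s``."""
    return float(atlas.brain_sigma[atlas.grid.nearest_index(s)])


def effective_locations(amap: GIAHatMap, t: float | None = None) -> np.ndarray:
    """CPCs of grid points with GIA^ strictly above ``t`` (default: the ROI's
    threshold).  May be empty; callers must handle that."""
    if t is None:
        t = amap.roi.t
    if not (0.0 <= t < 1.0):
        raise ConfigurationError("threshold t must satisfy 0 <= t < 1")
    return amap.grid.cpc[amap.values > t]


def weighted_center_of_mass(amap: GIAHatMap, t: float | None = None,
                            snap: bool = True) -> CPC:
    """GIA^-weighted center of mass of the effective locations, componentwise
    in CPC space; snapped to the nearest grid point unless ``snap=False``."""
    if t is None:
        t = amap.roi.t
    sel = amap.values > t
    if not np.any(sel):
        raise ArrangementInfeasibleError(
            f"no effective locations at threshold t={t}")
    w = amap.values[sel]
    com = (amap.grid.cpc[sel] * w[:, None]).sum(axis=0) / w.sum()
    if snap:
        com = amap.grid.cpc[amap.grid.nearest_index(com)]
    return CPC(float(com[0]), float(com[1]))


# --------------------------------------------------------------------------
# construction from a population
# --------------------------------------------------------------------------

def build_atlas_from_population(heads: list[HeadModel], grid: CPCGrid,
                                vocabulary) -> TranscranialAtlas:
    """Build a transcranial atlas from head models.

    Every grid CPC is carried to each individual scalp (CPC is the
    cross-participant correspondence), projected to that individual's cortex,
    and the projected vertex's label and common-space coordinate are pooled:
    label frequencies give P(l | s); the mean and GIV-style dispersion of the
    common-space points give the brain-location statistics.  A grid point
    where any head fails (CPC inversion or projection) is masked out.
    """
    if not heads:
        raise ConfigurationError("need at least one head model")
    labels = list(vocabulary)
    if BACKGROUND not in labels:
        labels.append(BACKGROUND)
    lut = {lab: k for k, lab in enumerate(labels)}

    G, H = len(grid), len(heads)
    prob = np.zeros((G, len(labels)))
    mean = np.zeros((G, 3))
    sigma = np.zeros(G)
    mask = np.ones(G, dtype=bool)
    points = np.full((G, H, 3), np.nan)

    for g in range(G):
        cpc = grid.cpc[g]
        pts = np.empty((H, 3))
        counts = np.zeros(len(labels))
        try:
            for j, head in enumerate(heads):
                xyz = cpc_to_xyz(head.scalp, cpc)
                bpt, bidx = project_to_brain(head, xyz, return_index=True)
                pts[j] = head.common(bpt)
                lab = head.labels[bidx]
                counts[lut.get(lab, lut[BACKGROUND])] += 1
        except Exception:
            mask[g] = False
            continue
        prob[g] = counts / H
        mean[g] = pts.mean(axis=0)
        sigma[g] = compute_giv(pts) if H >= 2 else 0.0
        points[g] = pts

    return TranscranialAtlas(grid=grid, labels=tuple(labels), prob=prob,
                             brain_mean=mean, brain_sigma=sigma,
                             n_subjects=H, mask=mask, brain_points=points)
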