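"""Rigid grid-holder montages on curved scalps.

Commercial topographic fNIRS holders are rigid rows-by-cols grids with a fixed
nominal inter-optode distance (typically 30 mm).  Placing such a holder on a
curved scalp is parameterized by a center (in CPC) and an in-plane orientation
``theta``: the grid is seeded in the tangent plane at the center, rotated by
``theta`` relative to the tangent projection of the increasing-p1 direction,
and then relaxed so that every grid-adjacent node pair sits at the nominal
chord distance while all nodes stay on the surface.  Chord (straight-line)
distance is used because physical holders are rigid straight links.

Channels form at grid-adjacent source-detector pairs; the channel scalp
location is the chord midpoint of the two optodes snapped back onto the mesh
and expressed in CPC, where the atlas GIA^ map is looked up.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import (ConfigurationError, DomainError, NumericalError,
                     PlacementInfeasibleError, PoleDegeneracyError)
from .cpc import CPC, compute_cpc, cpc_to_xyz
from .mesh import ScalpMesh

#: relaxation stops when the largest edge-length error drops below this (mm)
RELAX_TOL = 0.1
#: hard feasibility bound on edge-length error, as a fraction of nominal d
EDGE_TOL_FRACTION = 0.01
_MAX_RELAX = 500


@dataclass(frozen=True)
class MontageSpec:
    """Holder geometry and available optode counts.

    rows x cols grid, nominal inter-optode (source-detector) distance ``d`` in
    mm, and the numbers of sources ``nS`` and detectors ``nD`` to arrange.
    """

    rows: int
    cols: int
    d: float = 30.0
    nS: int = 1
    nD: int = 1

    def __post_init__(self):
        if self.rows * self.cols < 2:
            raise ConfigurationError("holder needs at least two nodes")
        if self.d <= 0:
            raise ConfigurationError("inter-optode distance must be positive")
        if self.nS < 1 or self.nD < 1:
            raise ConfigurationError("need at least one source and one detector")
        if self.nS + self.nD > self.rows * self.cols:
            raise ConfigurationError("more optodes than holder nodes")

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols

    def node_index(self, r: int, c: int) -> int:
        return r * self.cols + c

    def node_rc(self, idx: int) -> tuple[int, int]:
        return divmod(idx, self.cols)

    def edges(self) -> list[tuple[int, int]]:
        """Grid-adjacent node pairs: rows*(cols-1) horizontal plus
        (rows-1)*cols vertical, each as (lower index, higher index)."""
        e = []
        for r in range(self.rows):
            for c in range(self.cols - 1):
                e.append((self.node_index(r, c), self.node_index(r, c + 1)))
        for r in range(self.rows - 1):
            for c in range(self.cols):
                e.append((self.node_index(r, c), self.node_index(r + 1, c)))
        return e

    def neighbors(self, idx: int) -> list[int]:
        r, c = self.node_rc(idx)
        out = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < self.rows and 0 <= cc < self.cols:
                out.append(self.node_index(rr, cc))
        return out

    def central_edge(self) -> tuple[int, int]:
        """The edge whose grid midpoint is nearest the holder centroid; ties
        broken lexicographically on the (low, high) node-index pair."""
        cr, cc = (self.rows - 1) / 2, (self.cols - 1) / 2
        best, best_key = None, None
        for a, b in self.edges():
            ra, ca = self.node_rc(a)
            rb, cb = self.node_rc(b)
            d2 = ((ra + rb) / 2 - cr) ** 2 + ((ca + cb) / 2 - cc) ** 2
            key = (round(d2, 12), a, b)
            if best_key is None or key < best_key:
                best, best_key = (a, b), key
        return best


class Channel(NamedTuple):
    """One source-detector measurement channel."""

    source: int                 # node index
    detector: int               # node index
    midpoint_xyz: np.ndarray    # on-surface scalp position, mm
    midpoint_cpc: tuple         # (p1, p2)
    gia_hat: float
    effective: bool


@dataclass
class MontagePlacement:
    """A holder placed at (center, theta) with optode roles and channels.

    ``roles`` holds 'S' (source), 'D' (detector) or '' (empty) per node.
    ``avg_gia_hat`` averages GIA^ over the effective channels only (0.0 when
    there are none) and ``n_ce`` counts them.
    """

    mesh: ScalpMesh
    spec: MontageSpec
    center: CPC | None
    theta: float
    node_xyz: np.ndarray
    node_cpc: np.ndarray | None
    roles: np.ndarray
    channels: list[Channel] = field(default_factory=list)
    avg_gia_hat: float = float("nan")
    n_ce: int = 0
    #: greedy role-assignment history (role tuples), when produced by greedy
    trajectory: list = field(default_factory=list, repr=False)
    _edge_gia: dict = field(default_factory=dict, repr=False)

    def copy_unassigned(self) -> "MontagePlacement":
        return MontagePlacement(
            mesh=self.mesh, spec=self.spec, center=self.center,
            theta=self.theta, node_xyz=self.node_xyz.copy(),
            node_cpc=None if self.node_cpc is None else self.node_cpc.copy(),
            roles=np.full(self.spec.n_nodes, "", dtype=object),
            _edge_gia=self._edge_gia)

    # ------------------------------------------------------------------- io
    def to_json(self, path: str | Path):
        out = {
            "spec": {"rows": self.spec.rows, "cols": self.spec.cols,
                     "d": self.spec.d, "nS": self.spec.nS, "nD": self.spec.nD},
            "center": None if self.center is None else list(map(float, self.center)),
            "theta": float(self.theta),
            "avg_gia_hat": float(self.avg_gia_hat),
            "n_ce": int(self.n_ce),
            "nodes": [{"index": i, "role": str(self.roles[i]),
                       "xyz": [float(v) for v in self.node_xyz[i]],
                       "cpc": None if self.node_cpc is None
                       else [float(v) for v in self.node_cpc[i]]}
                      for i in range(self.spec.n_nodes)],
            "channels": [{"source": int(ch.source), "detector": int(ch.detector),
                          "midpoint_xyz": [float(v) for v in ch.midpoint_xyz],
                          "midpoint_cpc": [float(v) for v in ch.midpoint_cpc],
                          "gia_hat": float(ch.gia_hat),
                          "effective": bool(ch.effective)}
                         for ch in self.channels],
        }
        with open(path, "w") as fh:
            json.dump(out, fh, indent=1)

    def channel_table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "source": ch.source, "detector": ch.detector,
            "p1": ch.midpoint_cpc[0], "p2": ch.midpoint_cpc[1],
            "x": ch.midpoint_xyz[0], "y": ch.midpoint_xyz[1],
            "z": ch.midpoint_xyz[2],
            "gia_hat": ch.gia_hat, "effective": ch.effective}
            for ch in self.channels])


# --------------------------------------------------------------------------
# placement
# --------------------------------------------------------------------------

def _outward_normal(mesh: ScalpMesh, point: np.ndarray) -> np.ndarray:
    from .cpc import _surface_normal
    n = _surface_normal(mesh, point)
    if np.dot(n, mesh.up) < 0:
        n = -n
    return n


def _p1_direction(mesh: ScalpMesh, center: CPC) -> np.ndarray:
    h = min(0.01, 0.5 * center.p1, 0.5 * (1 - center.p1))
    a = cpc_to_xyz(mesh, (center.p1 - h, center.p2))
    b = cpc_to_xyz(mesh, (center.p1 + h, center.p2))
    return b - a


def _grid_reference_nodes(spec: MontageSpec) -> list[int]:
    """Node(s) whose mean position is pinned to the requested center: the
    central node for odd x odd holders, the central 2 or 4 nodes otherwise."""
    rs = [(spec.rows - 1) // 2] if spec.rows % 2 else [spec.rows // 2 - 1, spec.rows // 2]
    cs = [(spec.cols - 1) // 2] if spec.cols % 2 else [spec.cols // 2 - 1, spec.cols // 2]
    return [spec.node_index(r, c) for r in rs for c in cs]


def place_montage(mesh: ScalpMesh, spec: MontageSpec, center, theta: float,
                  axis_hint: np.ndarray | None = None,
                  compute_node_cpc: bool = True) -> MontagePlacement:
    """Place the holder grid on the scalp at (center, theta); roles unassigned.

    ``center`` is a CPC pair; alternatively a 3D point may be given together
    with ``axis_hint`` (the theta = 0 reference direction), which is the mode
    used for meshes without a CPC frame (e.g., a flat calibration plate).
    After seeding in the tangent plane the grid alternates spring relaxation
    of the edge lengths with re-projection onto the surface until every
    grid-adjacent chord distance is within 1% of nominal.
    """
    center_arr = np.asarray(tuple(center) if isinstance(center, CPC) else center,
                            dtype=float)
    if center_arr.size == 2:
        cen = CPC(float(center_arr[0]), float(center_arr[1]))
        center_xyz = cpc_to_xyz(mesh, cen)
        axis = _p1_direction(mesh, cen)
    elif center_arr.size == 3:
        cen = None
        center_xyz, dist = mesh.snap_to_surface(center_arr)
        center_xyz = center_xyz[0]
        if dist[0] > 1.0:
            raise PlacementInfeasibleError("center is not on the scalp surface")
        axis = np.asarray([0.0, 1.0, 0.0] if axis_hint is None else axis_hint,
                          dtype=float)
    else:
        raise ConfigurationError("center must be a CPC pair or a 3D point")

    n = _outward_normal(mesh, center_xyz)
    a0 = axis - np.dot(axis, n) * n
    if np.linalg.norm(a0) < 1e-9:
        raise PlacementInfeasibleError("reference axis is normal to the surface")
    a0 /= np.linalg.norm(a0)
    u = np.cos(theta) * a0 + np.sin(theta) * np.cross(n, a0)   # row axis
    v = np.cross(n, u)                                         # column axis

    rows, cols, d = spec.rows, spec.cols, spec.d
    nodes = np.empty((spec.n_nodes, 3))
    for r in range(rows):
        for c in range(cols):
            nodes[spec.node_index(r, c)] = (
                center_xyz
                + (c - (cols - 1) / 2) * d * u
                + (r - (rows - 1) / 2) * d * v)
    nodes, _ = mesh.snap_to_surface(nodes)

    edges = np.array(spec.edges())
    ref = _grid_reference_nodes(spec)
    for _ in range(_MAX_RELAX):
        vec = nodes[edges[:, 1]] - nodes[edges[:, 0]]
        lens = np.linalg.norm(vec, axis=1)
        err = lens - d
        if np.max(np.abs(err)) < RELAX_TOL:
            break
        unit = vec / lens[:, None]
        force = np.zeros_like(nodes)
        np.add.at(force, edges[:, 0], 0.5 * err[:, None] * unit)
        np.add.at(force, edges[:, 1], -0.5 * err[:, None] * unit)
        nodes = nodes + 0.5 * force
        # pin: the on-surface projection of the reference node(s) midpoint
        # must stay at the requested center (the raw chord mean of an even
        # grid's central pair lies inside the surface, so compare snapped)
        anchor, _ = mesh.snap_to_surface(nodes[ref].mean(axis=0))
        nodes = nodes + (center_xyz - anchor[0])
        nodes, _ = mesh.snap_to_surface(nodes)
    vec = nodes[edges[:, 1]] - nodes[edges[:, 0]]
    lens = np.linalg.norm(vec, axis=1)
    if np.max(np.abs(lens - d)) > EDGE_TOL_FRACTION * d:
        raise NumericalError(
            f"grid relaxation did not reach the 1% edge-length tolerance "
            f"(worst error {np.max(np.abs(lens - d)):.2f} mm)")

    if np.any(mesh.height_above_band(nodes) < -1e-6 * max(mesh.scale, 1.0)):
        raise PlacementInfeasibleError(
            "montage footprint extends below the fiducial boundary band")

    node_cpc = None
    if cen is not None and compute_node_cpc:
        node_cpc = np.empty((spec.n_nodes, 2))
        try:
            for i in range(spec.n_nodes):
                node_cpc[i] = compute_cpc(mesh, nodes[i], snap=False)
        except (DomainError, PoleDegeneracyError) as exc:
            raise PlacementInfeasibleError(
                f"montage node outside the CPC domain: {exc}")

    return MontagePlacement(
        mesh=mesh, spec=spec, center=cen, theta=float(theta),
        node_xyz=nodes, node_cpc=node_cpc,
        roles=np.full(spec.n_nodes, "", dtype=object))


# --------------------------------------------------------------------------
# channels
# --------------------------------------------------------------------------

def edge_midpoint_cpc(placement: MontagePlacement, a: int, b: int):
    """CPC of the snapped chord midpoint of edge (a, b); cached per placement."""
    key = (a, b) if a < b else (b, a)
    cache = placement._edge_gia
    if key not in cache:
        mid = 0.5 * (placement.node_xyz[a] + placement.node_xyz[b])
        snapped, _ = placement.mesh.snap_to_surface(mid)
        cpc = compute_cpc(placement.mesh, snapped[0], snap=False)
        cache[key] = (snapped[0], tuple(cpc))
    return cache[key]


def enumerate_channels(placement: MontagePlacement, amap, t: float,
                       all_channel_objective: bool = False) -> MontagePlacement:
    """Populate channels at every grid-adjacent source-detector pair.

    ``amap`` is a GIAHatMap; a channel is effective when its midpoint GIA^ is
    strictly above ``t``.  ``avg_gia_hat`` averages over effective channels
    (or over all channels when ``all_channel_objective``).
    """
    channels = []
    for a, b in placement.spec.edges():
        ra, rb = placement.roles[a], placement.roles[b]
        if {ra, rb} != {"S", "D"}:
            continue
        s, dnode = (a, b) if ra == "S" else (b, a)
        mid_xyz, mid_cpc = edge_midpoint_cpc(placement, a, b)
        g = amap.value_at(mid_cpc)
        channels.append(Channel(source=s, detector=dnode,
                                midpoint_xyz=mid_xyz, midpoint_cpc=mid_cpc,
                                gia_hat=g, effective=g > t))
    placement.channels = channels
    placement.n_ce = sum(ch.effective for ch in channels)
    if all_channel_objective:
        vals = [ch.gia_hat for ch in channels]
    else:
        vals = [ch.gia_hat for ch in channels if ch.effective]
    placement.avg_gia_hat = float(np.mean(vals)) if vals else 0.0
    return placement
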