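"""Continuous proportional coordinates (CPC) on scalp meshes.

CPC is a 2D proportional parameterization of the superior scalp anchored at
the four 10/20 fiducials, generalizing the proportional spirit of the 10/20
system to a continuum.  The construction is hierarchical, mirroring how 10/20
landmarks are measured with a tape:

* the *midsagittal curve* is the section of the scalp by the plane containing
  Nz, Iz and the superior direction, parameterized by proportional arc length
  from Nz (0) to Iz (1);
* for a scalp point ``p``, the *coronal curve* through ``p`` is the section of
  the scalp by the plane through (AL, AR, p); ``p2`` is the proportional arc
  length of ``p`` along it, from AL (0) to AR (1);
* ``p1`` is the proportional position, along the midsagittal curve, of the
  point where that coronal curve crosses the midsagittal plane.

Both coordinates are dimensionless in (0, 1) for interior points, invariant
under rigid motion and isotropic scaling, and cover the full open unit
square, so the inverse map is direct: walk the midsagittal curve to ``p1``,
take the coronal curve through that point, walk it to ``p2``.  On a sphere
with fiducials placed antipodally on the equator the curves are great circles
and CPC reduces to arc-angle ratios — the closed-form oracle in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import (ConfigurationError, DomainError, NumericalError,
                     PoleDegeneracyError)
from .mesh import FIDUCIAL_NAMES, SNAP_TOL, ScalpMesh


class CPC(NamedTuple):
    """A continuous proportional coordinate (p1 along Nz->Iz, p2 along AL->AR)."""

    p1: float
    p2: float

    @property
    def is_pole(self) -> bool:
        return bool(np.isnan(self.p1) or np.isnan(self.p2))


# --------------------------------------------------------------------------
# plane-mesh section curves
# --------------------------------------------------------------------------

class SectionCurve:
    """An ordered polyline where a plane cuts the mesh; open or closed."""

    def __init__(self, points: np.ndarray, closed: bool):
        self.points = np.asarray(points, dtype=float)
        self.closed = closed
        seg = np.diff(self.points, axis=0)
        self._seglen = np.linalg.norm(seg, axis=1)
        self.cumlen = np.concatenate([[0.0], np.cumsum(self._seglen)])

    @property
    def length(self) -> float:
        return float(self.cumlen[-1])

    def locate(self, point: np.ndarray) -> tuple[float, float]:
        """Arc-length position of the projection of ``point`` onto the curve;
        returns (arclength, distance-to-curve)."""
        p = np.asarray(point, dtype=float)
        p0 = self.points[:-1]
        d = self.points[1:] - p0
        len2 = np.maximum(np.einsum("ij,ij->i", d, d), 1e-300)
        t = np.clip(np.einsum("ij,ij->i", p - p0, d) / len2, 0.0, 1.0)
        foot = p0 + t[:, None] * d
        dist = np.linalg.norm(foot - p, axis=1)
        k = int(np.argmin(dist))
        return float(self.cumlen[k] + t[k] * self._seglen[k]), float(dist[k])

    def point_at(self, s: float) -> np.ndarray:
        """Point at arc length ``s`` (clamped to [0, length])."""
        s = float(np.clip(s, 0.0, self.length))
        k = int(np.searchsorted(self.cumlen, s, side="right") - 1)
        k = min(k, len(self._seglen) - 1)
        if self._seglen[k] < 1e-300:
            return self.points[k].copy()
        t = (s - self.cumlen[k]) / self._seglen[k]
        return self.points[k] + t * (self.points[k + 1] - self.points[k])


def plane_sections(mesh: ScalpMesh, origin: np.ndarray,
                   normal: np.ndarray) -> list[SectionCurve]:
    """All polyline components of the plane-mesh intersection.

    Crossing points are computed per mesh edge and chained through the faces
    that share them, which yields ordered polylines directly (and detects open
    chains at mesh boundaries by their degree-1 end edges).
    """
    V, F = mesh.vertices, mesh.faces
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    d = (V - np.asarray(origin, dtype=float)) @ n
    # nudge exact-zero vertices off the plane so every crossing face has
    # exactly two crossing edges (fiducials lie exactly on their own planes)
    eps = 1e-12 * max(mesh.scale, 1.0)
    d = np.where(d == 0.0, eps, d)

    pos = d[F] > 0
    crossing = ~(pos.all(axis=1) | (~pos).all(axis=1))
    cf = F[crossing]
    if len(cf) == 0:
        return []

    edge_point: dict[tuple[int, int], np.ndarray] = {}
    adj: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for tri in cf:
        keys = []
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            if (d[a] > 0) != (d[b] > 0):
                key = (a, b) if a < b else (b, a)
                keys.append(key)
                if key not in edge_point:
                    i, j = key
                    t = d[i] / (d[i] - d[j])
                    edge_point[key] = V[i] + t * (V[j] - V[i])
                    adj[key] = []
        if len(keys) == 2:
            adj[keys[0]].append(keys[1])
            adj[keys[1]].append(keys[0])

    seen: set[tuple[int, int]] = set()
    curves: list[SectionCurve] = []
    # open chains first (start from degree-1 edges), then any remaining cycles
    deg1 = [k for k, nb in adj.items() if len(nb) == 1]
    for start in deg1 + list(adj):
        if start in seen:
            continue
        chain = [start]
        seen.add(start)
        while True:
            nxt = [k for k in adj[chain[-1]] if k not in seen]
            if not nxt:
                break
            chain.append(nxt[0])
            seen.add(nxt[0])
        closed = len(chain) > 2 and chain[0] in adj[chain[-1]]
        pts = np.array([edge_point[k] for k in chain])
        if closed:
            pts = np.vstack([pts, pts[:1]])
        if len(pts) >= 2:
            curves.append(SectionCurve(pts, closed))
    return curves


# --------------------------------------------------------------------------
# fiducial arcs
# --------------------------------------------------------------------------

class Arc:
    """An ordered open polyline from one fiducial to another along a section."""

    def __init__(self, points: np.ndarray):
        self.curve = SectionCurve(points, closed=False)

    @property
    def length(self) -> float:
        return self.curve.length

    @property
    def points(self) -> np.ndarray:
        return self.curve.points

    def proportion_of(self, point: np.ndarray) -> float:
        s, _ = self.curve.locate(point)
        return s / self.curve.length

    def point_at(self, proportion: float) -> np.ndarray:
        return self.curve.point_at(proportion * self.curve.length)

    def plane_crossings(self, origin: np.ndarray,
                        normal: np.ndarray) -> list[np.ndarray]:
        """Points where the arc crosses the given plane."""
        s = (self.points - np.asarray(origin)) @ np.asarray(normal)
        out = []
        for k in range(len(s) - 1):
            if s[k] == 0.0:
                out.append(self.points[k].copy())
            elif (s[k] > 0) != (s[k + 1] > 0):
                t = s[k] / (s[k] - s[k + 1])
                out.append(self.points[k] + t * (self.points[k + 1] - self.points[k]))
        if s[-1] == 0.0:
            out.append(self.points[-1].copy())
        return out


def _extract_arc(curve: SectionCurve, t_a: float, t_b: float,
                 t_prefer: float | None) -> np.ndarray:
    """Ordered points from arc position ``t_a`` to ``t_b``.

    On a closed curve two arcs join the ends; the one containing ``t_prefer``
    is taken (``t_prefer`` must be given for closed curves).
    """
    pts, cum = curve.points, curve.cumlen
    if not curve.closed:
        lo, hi = (t_a, t_b) if t_a <= t_b else (t_b, t_a)
        inner = pts[(cum > lo + 1e-12) & (cum < hi - 1e-12)]
        seq = np.vstack([curve.point_at(lo), inner, curve.point_at(hi)])
        if t_a > t_b:
            seq = seq[::-1]
        return seq
    L = curve.length
    fwd = (t_b - t_a) % L
    if fwd < 1e-12 or L - fwd < 1e-12:
        raise PoleDegeneracyError("degenerate fiducial arc")
    off = (t_prefer - t_a) % L if t_prefer is not None else 0.5 * fwd
    forward = off <= fwd
    # walk from t_a in the chosen direction collecting vertices up to t_b
    seq = [curve.point_at(t_a)]
    if forward:
        span = fwd
        rel = (cum[:-1] - t_a) % L
        order = np.argsort(rel)
        for k in order:
            if 1e-12 < rel[k] < span - 1e-12:
                seq.append(pts[k])
    else:
        span = L - fwd
        rel = (t_a - cum[:-1]) % L
        order = np.argsort(rel)
        for k in order:
            if 1e-12 < rel[k] < span - 1e-12:
                seq.append(pts[k])
    seq.append(curve.point_at(t_b))
    return np.array(seq)


def _fiducial_arc(mesh: ScalpMesh, name_a: str, name_b: str,
                  normal: np.ndarray, prefer: np.ndarray | None = None) -> Arc:
    """The section arc running from fiducial ``name_a`` to ``name_b`` in the
    plane with the given normal (through both fiducials); on closed meshes the
    arc passing nearest ``prefer`` (default: the topmost section point)."""
    a, b = mesh.fiducials[name_a], mesh.fiducials[name_b]
    curves = plane_sections(mesh, a, normal)
    if not curves:
        raise DomainError("section plane does not intersect the mesh")
    best, best_cost = None, np.inf
    for c in curves:
        cost = c.locate(a)[1] + c.locate(b)[1]
        if prefer is not None:
            cost += c.locate(prefer)[1]
        if cost < best_cost:
            best, best_cost = c, cost
    t_a = best.locate(a)[0]
    t_b = best.locate(b)[0]
    if best.closed:
        if prefer is None:
            k = int(np.argmax(mesh.height_above_band(best.points)))
            t_prefer = float(best.cumlen[k])
        else:
            t_prefer = best.locate(prefer)[0]
        return Arc(_extract_arc(best, t_a, t_b, t_prefer))
    return Arc(_extract_arc(best, t_a, t_b, None))


def _midsagittal(mesh: ScalpMesh) -> Arc:
    """The Nz->Iz midsagittal arc (cached per mesh): the section by the plane
    containing Nz, Iz and the superior direction, running over the vertex."""
    if "midsagittal" not in mesh._cache:
        nz, iz = mesh.fiducials["Nz"], mesh.fiducials["Iz"]
        normal = np.cross(iz - nz, mesh.up)
        nn = np.linalg.norm(normal)
        if nn < 1e-12:
            raise ConfigurationError("degenerate fiducial configuration")
        mesh._cache["midsagittal"] = _fiducial_arc(mesh, "Nz", "Iz", normal / nn)
    return mesh._cache["midsagittal"]


def _coronal_arc(mesh: ScalpMesh, through: np.ndarray) -> Arc:
    """The AL->AR coronal arc through the given point."""
    al, ar = mesh.fiducials["AL"], mesh.fiducials["AR"]
    normal = np.cross(ar - al, through - al)
    nn = np.linalg.norm(normal)
    if nn < 1e-9 * np.linalg.norm(ar - al) * max(np.linalg.norm(through - al), 1e-12):
        raise PoleDegeneracyError("point is collinear with AL-AR; CPC undefined")
    return _fiducial_arc(mesh, "AL", "AR", normal / nn, prefer=through)


# --------------------------------------------------------------------------
# forward and inverse maps
# --------------------------------------------------------------------------

def compute_cpc(mesh: ScalpMesh, point: np.ndarray, snap: bool = True) -> CPC:
    """CPC of a scalp point.

    The point is snapped to the surface (within ``SNAP_TOL`` = 1 mm) and must
    lie on or above the fiducial boundary band.  Querying a fiducial itself
    returns a pole coordinate: the well-defined component is 0 or 1 and the
    degenerate one is NaN.
    """
    p = np.asarray(point, dtype=float).reshape(3)
    snapped, dist = mesh.snap_to_surface(p)
    if dist[0] > SNAP_TOL:
        raise DomainError(
            f"point is {dist[0]:.2f} mm from the surface (> {SNAP_TOL} mm)")
    if snap:
        p = snapped[0]

    scale = max(mesh.scale, 1.0)
    poles = {"Nz": (0.0, np.nan), "Iz": (1.0, np.nan),
             "AL": (np.nan, 0.0), "AR": (np.nan, 1.0)}
    for name in FIDUCIAL_NAMES:
        if np.linalg.norm(p - mesh.fiducials[name]) < 1e-6 * scale:
            return CPC(*poles[name])
    if mesh.height_above_band(p) < -1e-6 * scale:
        raise DomainError("point lies below the Nz-AL-Iz-AR fiducial band")

    coronal = _coronal_arc(mesh, p)
    p2 = coronal.proportion_of(p)

    sag = _midsagittal(mesh)
    nz = mesh.fiducials["Nz"]
    sag_normal = np.cross(mesh.fiducials["Iz"] - nz, mesh.up)
    crossings = coronal.plane_crossings(nz, sag_normal / np.linalg.norm(sag_normal))
    if not crossings:
        raise NumericalError("coronal curve does not reach the midsagittal plane")
    # the crossing on the superior arc (highest above the fiducial band)
    m = max(crossings, key=lambda q: mesh.height_above_band(q))
    p1 = sag.proportion_of(m)
    return CPC(float(p1), float(p2))


def cpc_to_xyz(mesh: ScalpMesh, cpc) -> np.ndarray:
    """Scalp point whose CPC equals ``cpc``.

    Direct construction: the midsagittal curve is walked to proportion ``p1``,
    the coronal curve through that point is sectioned, and walked to ``p2``.
    The result lies exactly on the mesh surface and round-trips through
    :func:`compute_cpc` to well within 1e-3 CPC units.
    """
    target = np.asarray(tuple(cpc), dtype=float).reshape(2)
    if not (0.0 < target[0] < 1.0 and 0.0 < target[1] < 1.0):
        raise DomainError(f"CPC {tuple(target)} outside the open unit square")
    sag = _midsagittal(mesh)
    m = sag.point_at(float(target[0]))
    coronal = _coronal_arc(mesh, m)
    return coronal.point_at(float(target[1]))


# --------------------------------------------------------------------------
# CPC grids
# --------------------------------------------------------------------------

@dataclass
class CPCGrid:
    """Regular interior CPC grid of resolution ``n``: the (n-1)^2 points at
    CPC values {1/n, ..., (n-1)/n}^2 with their 3D scalp positions.

    Row-major storage: index = (i-1)*(n-1) + (j-1) for p1 = i/n, p2 = j/n.
    """

    n: int
    cpc: np.ndarray      # ((n-1)^2, 2)
    xyz: np.ndarray      # ((n-1)^2, 3), mm
    mesh_name: str = "scalp"

    def __len__(self) -> int:
        return len(self.cpc)

    def nearest_index(self, cpc) -> int:
        """Index of the grid point nearest to ``cpc`` in CPC space.

        Uses the regular-lattice formula when the grid is the full interior
        lattice (O(1)); falls back to a linear scan for partial or custom
        point sets.
        """
        p1, p2 = float(cpc[0]), float(cpc[1])
        if len(self.cpc) == (self.n - 1) ** 2:
            i = int(np.clip(round(p1 * self.n), 1, self.n - 1))
            j = int(np.clip(round(p2 * self.n), 1, self.n - 1))
            k = (i - 1) * (self.n - 1) + (j - 1)
            if (abs(self.cpc[k, 0] - i / self.n) < 1e-9
                    and abs(self.cpc[k, 1] - j / self.n) < 1e-9):
                return k
        d = (self.cpc[:, 0] - p1) ** 2 + (self.cpc[:, 1] - p2) ** 2
        return int(np.argmin(d))

    def to_tsv(self, path: str | Path):
        df = pd.DataFrame(np.hstack([self.cpc, self.xyz]),
                          columns=["p1", "p2", "x", "y", "z"])
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, n: int, mesh_name: str = "scalp") -> "CPCGrid":
        df = pd.read_csv(path, sep="\t")
        return cls(n=n, cpc=df[["p1", "p2"]].to_numpy(),
                   xyz=df[["x", "y", "z"]].to_numpy(), mesh_name=mesh_name)


def build_cpc_grid(mesh: ScalpMesh, n: int) -> CPCGrid:
    """The interior CPC grid of resolution ``n`` measured on ``mesh``.

    ``n = 100`` gives the conventional CPC100 sampling with 99 x 99 = 9801
    interior points.  One coronal section is shared per p1 row, so the cost is
    linear in ``n``.  Deterministic for a fixed mesh.
    """
    if n < 2:
        raise ConfigurationError("grid resolution must be >= 2")
    vals = np.arange(1, n) / n
    sag = _midsagittal(mesh)
    cpcs = np.empty(((n - 1) ** 2, 2))
    xyz = np.empty(((n - 1) ** 2, 3))
    for i, p1 in enumerate(vals):
        coronal = _coronal_arc(mesh, sag.point_at(float(p1)))
        for j, p2 in enumerate(vals):
            k = i * (n - 1) + j
            cpcs[k] = (p1, p2)
            xyz[k] = coronal.point_at(float(p2))
    return CPCGrid(n=n, cpc=cpcs, xyz=xyz, mesh_name=mesh.name)


def _surface_normal(mesh: ScalpMesh, q: np.ndarray) -> np.ndarray:
    from trimesh.proximity import closest_point_naive
    _, _, fidx = closest_point_naive(mesh.trimesh, q[None])
    n = mesh.trimesh.face_normals[int(fidx[0])]
    return n / np.linalg.norm(n)
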