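"""Triangulated scalp surfaces anchored by the four 10/20 fiducials.

A :class:`ScalpMesh` is the geometric substrate for everything else in the
package: continuous proportional coordinates (CPC) are measured on it, montages
are relaxed onto it, and channel midpoints are snapped back to it.  The four
fiducials — nasion (Nz), inion (Iz) and the left/right preauricular points
(AL, AR) — define the coordinate frame: the scalp "up" direction is the
right-handed normal ``cross(AR - AL, Nz - Iz)`` and the fiducial plane bounds
the valid CPC domain from below.  All coordinates are in millimetres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import ConfigurationError

FIDUCIAL_NAMES = ("Nz", "Iz", "AL", "AR")

#: a fiducial must lie within this distance (mm) of the mesh surface
FIDUCIAL_SURFACE_TOL = 1e-6

#: points within this distance (mm) of the surface are snapped onto it
SNAP_TOL = 1.0


def _closest_point(mesh: trimesh.Trimesh, points: np.ndarray):
    """Closest points on the surface; (points, distances, face indices)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    return trimesh.proximity.closest_point_naive(mesh, points)


@dataclass
class ScalpMesh:
    """Triangulated scalp surface with the four 10/20 fiducial anchors.

    Parameters
    ----------
    vertices : (V, 3) float array, mm
    faces : (F, 3) int array of triangle vertex indices
    fiducials : dict mapping "Nz", "Iz", "AL", "AR" to 3-vectors (mm); each must
        lie on the surface to within ``FIDUCIAL_SURFACE_TOL``.
    """

    vertices: np.ndarray
    faces: np.ndarray
    fiducials: dict[str, np.ndarray]
    name: str = "scalp"
    _tm: trimesh.Trimesh | None = field(default=None, repr=False, compare=False)
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ConfigurationError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ConfigurationError("faces must be (F, 3)")
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= len(self.vertices):
            raise ConfigurationError("faces reference out-of-range vertices")
        missing = [k for k in FIDUCIAL_NAMES if k not in self.fiducials]
        if missing:
            raise ConfigurationError(f"missing fiducials: {missing}")
        self.fiducials = {k: np.asarray(self.fiducials[k], dtype=float).reshape(3)
                          for k in FIDUCIAL_NAMES}
        pts = np.array([self.fiducials[k] for k in FIDUCIAL_NAMES])
        if np.min(np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
                  + np.eye(4) * 1e9) < 1e-9:
            raise ConfigurationError("fiducials must be pairwise distinct")
        _, dist, _ = _closest_point(self.trimesh, pts)
        if np.max(dist) > FIDUCIAL_SURFACE_TOL:
            raise ConfigurationError(
                f"fiducials must lie on the mesh surface "
                f"(max deviation {np.max(dist):.3g} mm)")

    # ------------------------------------------------------------------ frame
    @property
    def trimesh(self) -> trimesh.Trimesh:
        if self._tm is None:
            self._tm = trimesh.Trimesh(
                vertices=self.vertices, faces=self.faces, process=False)
        return self._tm

    @property
    def scale(self) -> float:
        """Characteristic size (mm): mean fiducial distance from their centroid."""
        pts = np.array([self.fiducials[k] for k in FIDUCIAL_NAMES])
        return float(np.mean(np.linalg.norm(pts - pts.mean(axis=0), axis=1)))

    @property
    def up(self) -> np.ndarray:
        """Unit superior direction: ``cross(AR - AL, Nz - Iz)`` normalized."""
        v = np.cross(self.fiducials["AR"] - self.fiducials["AL"],
                     self.fiducials["Nz"] - self.fiducials["Iz"])
        n = np.linalg.norm(v)
        if n < 1e-12:
            raise ConfigurationError("fiducials are collinear; no up direction")
        return v / n

    @property
    def fiducial_centroid(self) -> np.ndarray:
        return np.mean([self.fiducials[k] for k in FIDUCIAL_NAMES], axis=0)

    def height_above_band(self, points: np.ndarray) -> np.ndarray:
        """Signed distance (mm) of points above the Nz-AL-Iz-AR fiducial plane."""
        points = np.asarray(points, dtype=float)
        return (points - self.fiducial_centroid) @ self.up

    def snap_to_surface(self, points: np.ndarray):
        """Project points onto the surface; returns (snapped, distances)."""
        snapped, dist, _ = _closest_point(self.trimesh, points)
        return snapped, dist

    def is_connected(self) -> bool:
        """True when the face graph forms a single connected component."""
        return self.trimesh.body_count == 1

    # --------------------------------------------------------------------- io
    def save(self, mesh_path: str | Path, fiducials_path: str | Path | None = None):
        """Write the mesh (format from the extension: .ply/.obj/.stl) and the
        fiducial sidecar JSON ``{"Nz": [x,y,z], ...}`` in mm."""
        mesh_path = Path(mesh_path)
        self.trimesh.export(mesh_path)
        if fiducials_path is None:
            fiducials_path = mesh_path.with_suffix(".fiducials.json")
        with open(fiducials_path, "w") as fh:
            json.dump({k: list(map(float, v)) for k, v in self.fiducials.items()},
                      fh, indent=1)

    @classmethod
    def load(cls, mesh_path: str | Path,
             fiducials_path: str | Path | None = None) -> "ScalpMesh":
        """Read a PLY/OBJ/STL mesh plus its fiducial sidecar JSON.

        Fiducials are snapped to the loaded surface (tolerance ``SNAP_TOL``) to
        absorb format round-off.
        """
        mesh_path = Path(mesh_path)
        tm = trimesh.load(mesh_path, force="mesh", process=False)
        # STL stores unshared triangle soup; restore vertex sharing so the
        # section-curve chaining sees a connected edge graph
        tm.merge_vertices()
        if fiducials_path is None:
            fiducials_path = mesh_path.with_suffix(".fiducials.json")
        with open(fiducials_path) as fh:
            raw = json.load(fh)
        fid = {k: np.asarray(v, dtype=float) for k, v in raw.items()}
        snapped, dist, _ = _closest_point(
            tm, np.array([fid[k] for k in FIDUCIAL_NAMES]))
        if np.max(dist) > SNAP_TOL:
            raise ConfigurationError(
                f"fiducials farther than {SNAP_TOL} mm from the surface")
        fid = dict(zip(FIDUCIAL_NAMES, snapped))
        return cls(vertices=np.asarray(tm.vertices, dtype=float),
                   faces=np.asarray(tm.faces), fiducials=fid,
                   name=mesh_path.stem)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None,
                    scale: float = 1.0) -> "ScalpMesh":
        """Rigidly transformed (plus isotropic scaling) copy; fiducials follow."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        verts = scale * (self.vertices @ R.T) + t
        fid = {k: scale * (R @ v) + t for k, v in self.fiducials.items()}
        return ScalpMesh(vertices=verts, faces=self.faces.copy(),
                         fiducials=fid, name=self.name)
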