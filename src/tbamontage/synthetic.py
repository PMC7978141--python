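"""Synthetic head populations with controlled scalp-brain correspondence.

The whole montage-design pipeline — CPC measurement, atlas construction,
greedy arrangement, ground-truth evaluation — depends only on meshes,
fiducials and labels, so the simplest controllable geometry maximizes
testability: each synthetic individual is an upper-half ellipsoid scalp
(semi-axes drawn around population means), a cortical surface obtained by
shrinking the scalp inward with a smooth radial perturbation, and a cortical
parcellation of K angular sectors whose boundaries are rotated per individual
(the anatomical jitter that makes scalp-brain correspondence probabilistic).
Fiducials sit at the ends of the left-right and anterior-posterior equatorial
axes and are exact mesh vertices.

The lat-long (UV) meshing is used instead of icospheres so that fiducials and
the apex are exact vertices, which the CPC invariants rely on.

Realized-placement noise emulates imperfect physical montage placement: an
isotropic 2D Gaussian displacement (in mm) in each participant's tangent
plane, re-expressed in CPC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, TBAMontageError
from .cpc import compute_cpc, cpc_to_xyz, _surface_normal
from .evaluation import HeadModel
from .mesh import ScalpMesh


# --------------------------------------------------------------------------
# mesh primitives
# --------------------------------------------------------------------------

def uv_hemisphere(axes=(1.0, 1.0, 1.0), n_az: int = 48, n_rings: int = 20,
                  name: str = "scalp") -> ScalpMesh:
    """Upper-half ellipsoid scalp mesh with exact fiducial vertices.

    Axes are (left-right, posterior-anterior, inferior-superior) semi-axes in
    the caller's units.  ``n_az`` must be a multiple of 4 so that AR (+x),
    Nz (+y), AL (-x) and Iz (-y) land exactly on equatorial vertices.
    """
    verts, faces = _uv_vertices_faces(axes, n_az, n_rings)
    ax, ay, _ = axes
    fid = {"AR": np.array([ax, 0.0, 0.0]), "Nz": np.array([0.0, ay, 0.0]),
           "AL": np.array([-ax, 0.0, 0.0]), "Iz": np.array([0.0, -ay, 0.0])}
    return ScalpMesh(vertices=verts, faces=faces, fiducials=fid, name=name)


def _uv_vertices_faces(axes, n_az: int, n_rings: int,
                       radial_fn=None) -> tuple[np.ndarray, np.ndarray]:
    if n_az % 4 != 0 or n_az < 8:
        raise ConfigurationError("n_az must be a multiple of 4, >= 8")
    if n_rings < 2:
        raise ConfigurationError("need at least two latitude rings")
    ax, ay, az = (float(a) for a in axes)
    if min(ax, ay, az) <= 0:
        raise ConfigurationError("semi-axes must be positive")
    theta = 2 * np.pi * np.arange(n_az) / n_az
    phi = (np.pi / 2) * np.arange(n_rings) / n_rings
    tt, pp = np.meshgrid(theta, phi, indexing="xy")
    x = np.cos(pp) * np.cos(tt)
    y = np.cos(pp) * np.sin(tt)
    z = np.sin(pp)
    unit = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
    unit = np.vstack([unit, [0.0, 0.0, 1.0]])                    # apex
    scale = np.array([ax, ay, az])
    verts = unit * scale
    if radial_fn is not None:
        tt_flat = np.concatenate([tt.ravel(), [0.0]])
        pp_flat = np.concatenate([pp.ravel(), [np.pi / 2]])
        verts = verts * radial_fn(tt_flat, pp_flat)[:, None]
    apex = len(verts) - 1
    faces = []
    for k in range(n_rings - 1):
        for i in range(n_az):
            a = k * n_az + i
            b = k * n_az + (i + 1) % n_az
            c = (k + 1) * n_az + (i + 1) % n_az
            d = (k + 1) * n_az + i
            faces.append((a, b, c))
            faces.append((a, c, d))
    top = (n_rings - 1) * n_az
    for i in range(n_az):
        faces.append((top + i, top + (i + 1) % n_az, apex))
    return verts, np.asarray(faces, dtype=np.int64)


def flat_plate(half_size: float = 100.0, n: int = 21) -> ScalpMesh:
    """Flat square calibration plate (zero-curvature limit for placement
    tests); fiducials at the edge midpoints."""
    g = np.linspace(-half_size, half_size, n)
    xx, yy = np.meshgrid(g, g, indexing="xy")
    verts = np.stack([xx.ravel(), yy.ravel(), np.zeros(n * n)], axis=1)
    faces = []
    for r in range(n - 1):
        for c in range(n - 1):
            a = r * n + c
            faces.append((a, a + 1, a + n + 1))
            faces.append((a, a + n + 1, a + n))
    fid = {"Nz": np.array([0.0, half_size, 0.0]),
           "Iz": np.array([0.0, -half_size, 0.0]),
           "AL": np.array([-half_size, 0.0, 0.0]),
           "AR": np.array([half_size, 0.0, 0.0])}
    return ScalpMesh(vertices=verts, faces=np.asarray(faces, dtype=np.int64),
                     fiducials=fid, name="flat_plate")


# --------------------------------------------------------------------------
# population generator
# --------------------------------------------------------------------------

@dataclass
class PopulationConfig:
    """Study conditions for a synthetic head population.

    Defaults describe an adult-head-sized cohort: scalp semi-axes around
    (75, 92, 80) mm with 3 mm between-subject SD, a cortical surface at 85% of
    the scalp radius, six azimuthal parcels with 5 degrees of between-subject
    boundary jitter, and 5 mm of tangential placement noise.
    """

    n: int = 20
    scalp_axes_mean: tuple[float, float, float] = (75.0, 92.0, 80.0)
    scalp_axes_sd: float = 3.0
    brain_scale: float = 0.85
    parcellation: tuple[str, ...] = ("S1", "S2", "S3", "S4", "S5", "S6")
    jitter_sigma: float = 5.0            # degrees
    placement_noise_sigma: float = 5.0   # mm
    seed: int = 0
    n_az: int = 40                       # mesh azimuthal resolution
    n_rings: int = 16                    # mesh latitude rings
    brain_bumpiness: float = 0.02        # relative radial perturbation

    def __post_init__(self):
        if self.n < 1:
            raise ConfigurationError("population size must be >= 1")
        if not (0.0 < self.brain_scale < 1.0):
            raise ConfigurationError("brain_scale must be in (0, 1)")
        if self.jitter_sigma < 0 or self.placement_noise_sigma < 0:
            raise ConfigurationError("noise parameters must be non-negative")
        if len(set(self.parcellation)) != len(self.parcellation):
            raise ConfigurationError("parcellation labels must be distinct")
        if min(self.scalp_axes_mean) - 5 * self.scalp_axes_sd <= 0:
            raise ConfigurationError("degenerate scalp axes distribution")


def _sector_labels(theta: np.ndarray, labels: tuple[str, ...],
                   rotation_rad: float) -> np.ndarray:
    K = len(labels)
    sector = np.floor(((theta - rotation_rad) % (2 * np.pi))
                      / (2 * np.pi / K)).astype(int) % K
    return np.asarray(labels, dtype=object)[sector]


def _uv_vertex_azimuth(n_az: int, n_rings: int) -> np.ndarray:
    """Exact parameterization azimuth per UV-mesh vertex (apex gets 0)."""
    theta = 2 * np.pi * np.arange(n_az) / n_az
    return np.concatenate([np.tile(theta, n_rings), [0.0]])


def make_population(config: PopulationConfig) -> tuple[list[HeadModel], dict]:
    """Generate ``config.n`` head models plus the generating ground truth.

    Per individual: scalp semi-axes ~ Normal(mean, sd); the brain is the scalp
    shrunk by ``brain_scale`` with a smooth low-order radial perturbation;
    cortical labels are K azimuthal sectors rotated by Normal(0, jitter_sigma)
    degrees; ``to_common`` is the diagonal affine normalizing the individual
    ellipsoid onto the population-mean (template) ellipsoid.  Bit-identical
    for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    template = np.asarray(config.scalp_axes_mean, dtype=float)
    # the cortical radial relief is a population-level trait: with zero
    # axis SD and zero boundary jitter, all individuals are identical
    phase = rng.uniform(0, 2 * np.pi, size=2)
    amp = config.brain_bumpiness

    def radial(tt, pp, _phase=phase, _amp=amp):
        return 1.0 + _amp * np.sin(3 * tt + _phase[0]) * np.cos(
            2 * pp + _phase[1])

    vertex_azimuth = _uv_vertex_azimuth(config.n_az, config.n_rings)
    heads: list[HeadModel] = []
    rotations = np.empty(config.n)
    axes_all = np.empty((config.n, 3))
    for j in range(config.n):
        axes = rng.normal(template, config.scalp_axes_sd)
        axes = np.maximum(axes, 10.0)
        rot_deg = rng.normal(0.0, config.jitter_sigma)
        axes_all[j] = axes
        rotations[j] = rot_deg

        scalp = uv_hemisphere(axes, n_az=config.n_az, n_rings=config.n_rings,
                              name=f"head{j:03d}")
        bverts, bfaces = _uv_vertices_faces(
            axes * config.brain_scale, config.n_az, config.n_rings,
            radial_fn=radial)
        labels = _sector_labels(vertex_azimuth, tuple(config.parcellation),
                                np.deg2rad(rot_deg))
        affine = np.eye(4)
        affine[:3, :3] = np.diag(template / axes)
        heads.append(HeadModel(scalp=scalp, brain_vertices=bverts,
                               brain_faces=bfaces, labels=labels,
                               to_common=affine, name=f"head{j:03d}"))
    truth = {"template_axes": template,
             "axes": axes_all,
             "boundary_rotation_deg": rotations,
             "labels": tuple(config.parcellation),
             "config": config}
    return heads, truth


def template_scalp(config: PopulationConfig) -> ScalpMesh:
    """The typical (template) scalp of a population: the mean ellipsoid."""
    return uv_hemisphere(tuple(config.scalp_axes_mean), n_az=config.n_az,
                         n_rings=config.n_rings, name="template")


# --------------------------------------------------------------------------
# realized placement
# --------------------------------------------------------------------------

def simulate_realized_placement(intended, heads: list[HeadModel],
                                placement_noise_sigma: float,
                                seed: int = 0) -> np.ndarray:
    """Realized channel CPCs per participant under tangential placement noise.

    ``intended`` is a MontagePlacement (its channel CPCs are used) or an
    (N_c, 2) array of channel CPCs.  Each participant's channel is carried to
    their scalp via CPC, displaced by an isotropic 2D Gaussian of SD
    ``placement_noise_sigma`` mm in the local tangent plane, re-projected to
    the scalp, and re-expressed in CPC.  Returns (N_p, N_c, 2); deterministic
    per seed; ``sigma = 0`` reproduces the intended CPCs exactly.
    """
    if placement_noise_sigma < 0:
        raise ConfigurationError("placement noise sigma must be >= 0")
    if hasattr(intended, "channels"):
        ch_cpc = np.array([ch.midpoint_cpc for ch in intended.channels])
    else:
        ch_cpc = np.asarray(intended, dtype=float)
    rng = np.random.default_rng(seed)
    out = np.empty((len(heads), len(ch_cpc), 2))
    for j, head in enumerate(heads):
        for i, cpc in enumerate(ch_cpc):
            if placement_noise_sigma == 0:
                out[j, i] = cpc
                continue
            q = cpc_to_xyz(head.scalp, cpc)
            nrm = _surface_normal(head.scalp, q)
            t1 = np.cross(nrm, [1.0, 0.0, 0.0])
            if np.linalg.norm(t1) < 1e-6:
                t1 = np.cross(nrm, [0.0, 1.0, 0.0])
            t1 /= np.linalg.norm(t1)
            t2 = np.cross(nrm, t1)
            # noise is truncated to the CPC domain: draws landing below the
            # fiducial band (where CPC is undefined) are rejected and redrawn
            out[j, i] = cpc
            for _ in range(20):
                d1, d2 = rng.normal(0.0, placement_noise_sigma, size=2)
                q2, _ = head.scalp.snap_to_surface(q + d1 * t1 + d2 * t2)
                try:
                    out[j, i] = compute_cpc(head.scalp, q2[0], snap=False)
                    break
                except TBAMontageError:
                    continue
    return out
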