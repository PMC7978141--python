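"""Continuous proportional coordinates (CPC) on a scalp surface.

Builds a head-sized ellipsoid scalp anchored at the four 10/20 fiducials
(Nz, Iz, AL, AR), measures the CPC of a scalp point, inverts it back to 3D,
and samples a coarse CPC grid.  CPC generalizes the 10/20 system: p1 is the
proportional position front-to-back, p2 left-to-right, both in (0, 1), so
the same (p1, p2) names corresponding scalp locations on differently sized
and shaped heads.
"""

import numpy as np

from tbamontage import build_cpc_grid, compute_cpc, cpc_to_xyz, uv_hemisphere

scalp = uv_hemisphere((75.0, 92.0, 80.0), n_az=40, n_rings=16)
print(f"scalp mesh: {len(scalp.vertices)} vertices, "
      f"{len(scalp.faces)} faces, semi-axes 75 x 92 x 80 mm")

apex = np.array([0.0, 0.0, 80.0])
c = compute_cpc(scalp, apex)
print(f"CPC of the vertex (apex): p1={c.p1:.4f}, p2={c.p2:.4f} "
      "(the apex halves both fiducial arcs, so (0.5, 0.5))")

target = (0.30, 0.65)
xyz = cpc_to_xyz(scalp, target)
back = compute_cpc(scalp, xyz, snap=False)
print(f"cpc_to_xyz{target} = [{xyz[0]:.1f}, {xyz[1]:.1f}, {xyz[2]:.1f}] mm; "
      f"round trip -> ({back.p1:.6f}, {back.p2:.6f})")

grid = build_cpc_grid(scalp, 10)
print(f"CPC grid n=10: {len(grid)} interior points "
      "(CPC100 would give 99 x 99 = 9801)")
d = np.linalg.norm(grid.xyz - scalp.snap_to_surface(grid.xyz)[0], axis=1)
print(f"all grid points lie on the surface (max deviation {d.max():.2e} mm)")
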