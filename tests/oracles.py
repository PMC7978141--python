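"""Independent oracles used by the unit and acceptance tests.

These deliberately avoid the greedy machinery: role assignments are found by
exhaustive enumeration and single-channel placements by a direct scan.
"""

import itertools

import numpy as np

from tbamontage import GIAHatMap, MontageSpec, ROISpec, place_montage
from tbamontage.montage import edge_midpoint_cpc, enumerate_channels


def brute_force_best(placement, amap, spec, t):
    """Maximum avg GIA^ over *all* role assignments of nS sources and nD
    detectors to distinct holder nodes (not just greedy-reachable ones)."""
    best = 0.0
    nodes = range(spec.n_nodes)
    for occupied in itertools.combinations(nodes, spec.nS + spec.nD):
        for sources in itertools.combinations(occupied, spec.nS):
            p = placement.copy_unassigned()
            for i in occupied:
                p.roles[i] = "S" if i in sources else "D"
            enumerate_channels(p, amap, t)
            best = max(best, p.avg_gia_hat)
    return best


def exhaustive_single_channel_argmax(mesh, amap, spec, centers, thetas, t):
    """Best (center index, theta index) for a 1-source-1-detector holder by
    directly scanning the seed-channel GIA^ over the sampled space."""
    best_val, best_idx = -1.0, None
    for i, x in enumerate(centers):
        for j, theta in enumerate(thetas):
            try:
                p = place_montage(mesh, spec, tuple(x), theta,
                                  compute_node_cpc=False)
            except Exception:
                continue
            a, b = spec.central_edge()
            _, cpc = edge_midpoint_cpc(p, a, b)
            g = amap.value_at(cpc)
            if g > t and g > best_val:
                best_val, best_idx = g, (i, j)
    return best_idx, best_val


def hotspot_map(grid, hot_cpc, hot=0.9, background=0.1, roi_t=0.5):
    """Single-hotspot GIA^ map: one grid cell high, the rest low."""
    vals = np.full(len(grid), background)
    vals[grid.nearest_index(hot_cpc)] = hot
    return GIAHatMap(grid=grid, values=vals,
                     roi=ROISpec(roi_labels=("x",), t=roi_t))
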