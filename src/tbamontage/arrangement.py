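"""Two-level optimization of optode arrangements.

Level one: at a fixed holder placement (center ``x``, orientation ``theta``),
optode roles are assigned greedily to maximize the average channel GIA^ — a
seed source-detector pair occupies the central grid edge, then sources and
detectors are added alternately at the free node creating the channel with
the highest GIA^, until no candidate would create an effective channel; any
excess optodes are placed randomly adjacent to the existing ones (they form
control channels).

Level two: the greedy solution is evaluated over a sampled search space
Omega(x, theta) — by default only effective scalp locations, optionally
restricted to a radius around the GIA^-weighted ROI center — and, because the
number of effective channels N_ce trades off against their average GIA^, the
best placement is retained *per value of N_ce*, leaving the final pick to the
user.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (ArrangementInfeasibleError, ConfigurationError,
                     NumericalError, PlacementInfeasibleError)
from .atlas import GIAHatMap, effective_locations, weighted_center_of_mass
from .cpc import CPC
from .mesh import ScalpMesh
from .montage import (MontagePlacement, MontageSpec, edge_midpoint_cpc,
                      enumerate_channels, place_montage)

#: 1 CPC unit = 0.01 in (p1, p2); radius restrictions are stated in CPC units
CPC_UNIT = 0.01


@dataclass
class SearchSpace:
    """Sampled placement space Omega(x, theta)."""

    centers: np.ndarray          # (M, 2) CPC
    n_theta: int = 30

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if len(self.centers) == 0:
            raise ArrangementInfeasibleError("empty center set")
        if self.n_theta < 1:
            raise ConfigurationError("n_theta must be >= 1")

    @property
    def thetas(self) -> np.ndarray:
        """Orientations {0, pi/n_theta, ...} in [0, pi); the undirected grid
        is symmetric under a half turn, so [pi, 2pi) would be redundant."""
        return np.pi * np.arange(self.n_theta) / self.n_theta


def restrict_search(amap: GIAHatMap, t: float | None = None,
                    mode: str = "effective-only",
                    r: float = np.inf) -> np.ndarray:
    """Candidate montage centers.

    ``mode="effective-only"``: every effective location.  ``mode="radius"``:
    effective locations within ``r`` CPC units (Euclidean in (p1, p2) scaled
    by 100) of the GIA^-weighted center of mass.
    """
    if t is None:
        t = amap.roi.t
    eff = effective_locations(amap, t)
    if len(eff) == 0:
        raise ArrangementInfeasibleError(
            f"no effective locations at threshold t={t}")
    if mode == "effective-only":
        return eff
    if mode != "radius":
        raise ConfigurationError("mode must be 'effective-only' or 'radius'")
    com = np.asarray(weighted_center_of_mass(amap, t), dtype=float)
    dist = np.linalg.norm(eff - com, axis=1) / CPC_UNIT
    centers = eff[dist < r] if np.isfinite(r) else eff
    if r == 0:
        centers = eff[dist <= 0]
    if len(centers) == 0:
        raise ArrangementInfeasibleError(
            f"no effective locations within {r} CPC units of the ROI center")
    return centers


# --------------------------------------------------------------------------
# level 1: greedy role assignment
# --------------------------------------------------------------------------

def _edge_gia(placement: MontagePlacement, amap: GIAHatMap,
              a: int, b: int) -> float:
    _, cpc = edge_midpoint_cpc(placement, a, b)
    return amap.value_at(cpc)


def greedy_assign(placement: MontagePlacement, amap: GIAHatMap,
                  spec: MontageSpec | None = None, t: float | None = None,
                  seed: int = 0, deterministic_fill: bool = False,
                  all_channel_objective: bool = False) -> MontagePlacement:
    """Assign source/detector roles greedily at a fixed placement.

    Ties are broken by lowest node index throughout.  ``deterministic_fill``
    replaces the seeded random placement of excess optodes with
    "lowest-index adjacent free node" (useful for exact reproducibility in
    analyses that compare arrangements).

    The returned placement carries a ``trajectory`` attribute: the role
    vector after the seed pair and after every scored addition, each a
    candidate arrangement for its own number of effective channels (the
    per-N_ce selection in :func:`optimize` draws on these intermediate
    states as well as the final one).
    """
    if spec is None:
        spec = placement.spec
    if t is None:
        t = amap.roi.t
    if spec.nS + spec.nD > spec.n_nodes:
        raise ConfigurationError("more optodes than holder nodes")
    p = placement.copy_unassigned()
    roles = p.roles
    trajectory: list[tuple] = []

    def snapshot():
        trajectory.append(tuple(roles))

    a, b = spec.central_edge()
    roles[a], roles[b] = "S", "D"          # source on the lower-index node
    snapshot()
    ns_left, nd_left = spec.nS - 1, spec.nD - 1

    def candidates(typ: str):
        opp = "D" if typ == "S" else "S"
        cand = []
        for i in range(spec.n_nodes):
            if roles[i]:
                continue
            scores = [_edge_gia(p, amap, i, j) for j in spec.neighbors(i)
                      if roles[j] == opp]
            if scores:
                cand.append((max(scores), i))
        return cand

    next_type = "S"
    while ns_left + nd_left > 0:
        typ = next_type
        if (typ == "S" and ns_left == 0) or (typ == "D" and nd_left == 0):
            typ = "D" if typ == "S" else "S"
        cand = candidates(typ)
        if not cand:
            other = "D" if typ == "S" else "S"
            if (other == "S" and ns_left > 0) or (other == "D" and nd_left > 0):
                typ = other
                cand = candidates(typ)
        if not cand:
            break
        best_score = max(s for s, _ in cand)
        if best_score <= t:
            break                        # nothing effective left to create
        node = min(i for s, i in cand if s == best_score)
        roles[node] = typ
        snapshot()
        if typ == "S":
            ns_left -= 1
        else:
            nd_left -= 1
        next_type = "D" if typ == "S" else "S"

    # excess optodes: random (or lowest-index) free nodes adjacent to occupied
    rng = np.random.default_rng(seed)
    next_type = "S"
    while ns_left + nd_left > 0:
        typ = next_type
        if (typ == "S" and ns_left == 0) or (typ == "D" and nd_left == 0):
            typ = "D" if typ == "S" else "S"
        free = [i for i in range(spec.n_nodes) if not roles[i]
                and any(roles[j] for j in spec.neighbors(i))]
        if not free:
            free = [i for i in range(spec.n_nodes) if not roles[i]]
        node = free[0] if deterministic_fill else int(rng.choice(free))
        roles[node] = typ
        if typ == "S":
            ns_left -= 1
        else:
            nd_left -= 1
        next_type = "D" if typ == "S" else "S"
    snapshot()                              # full assignment incl. controls

    out = enumerate_channels(p, amap, t,
                             all_channel_objective=all_channel_objective)
    out.trajectory = trajectory
    return out


def _pruning_chain(placement: MontagePlacement, amap: GIAHatMap, t: float,
                   all_channel_objective: bool = False) -> list[tuple]:
    """Role states obtained by discarding optodes one at a time from the full
    arrangement, each time removing the optode whose removal maximizes the
    average GIA^ of the remaining channels (ties: lowest node index).

    These supply competitive low-N_ce candidates for the per-N_ce selection:
    the greedy growth path alone can skip N_ce values when one optode creates
    several effective channels at once.
    """
    scratch = placement.copy_unassigned()
    roles = list(placement.roles)
    chain: list[tuple] = []
    while sum(1 for r in roles if r) > 2:
        best_score, best_node = None, None
        for i, r in enumerate(roles):
            if not r:
                continue
            scratch.roles[:] = roles
            scratch.roles[i] = ""
            enumerate_channels(scratch, amap, t,
                               all_channel_objective=all_channel_objective)
            score = (scratch.avg_gia_hat, -scratch.n_ce)
            if best_score is None or score > best_score:
                best_score, best_node = score, i
        roles[best_node] = ""
        chain.append(tuple(roles))
    return chain


# --------------------------------------------------------------------------
# level 2: search over Omega(x, theta)
# --------------------------------------------------------------------------

@dataclass
class ArrangementResult:
    """Best placement per number of effective channels, plus the full
    objective map f(x_i, theta_j) over the sampled space."""

    best: dict[int, MontagePlacement]
    objective: np.ndarray        # (M, n_theta); NaN where placement infeasible
    n_ce_map: np.ndarray         # (M, n_theta) int; -1 where infeasible
    centers: np.ndarray
    thetas: np.ndarray
    best_index: dict[int, tuple[int, int]]
    metadata: dict = field(default_factory=dict)

    def pareto(self) -> pd.DataFrame:
        """(n_ce, avg_gia_hat) of the retained best placements, sorted."""
        rows = [{"n_ce": k, "avg_gia_hat": v.avg_gia_hat}
                for k, v in sorted(self.best.items())]
        return pd.DataFrame(rows)

    def save(self, directory: str | Path):
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        M, T = self.objective.shape
        rows = []
        for i in range(M):
            for j in range(T):
                rows.append({"p1": self.centers[i, 0], "p2": self.centers[i, 1],
                             "theta": self.thetas[j],
                             "f": self.objective[i, j],
                             "n_ce": int(self.n_ce_map[i, j])})
        pd.DataFrame(rows).to_csv(d / "objective_map.tsv", sep="\t", index=False)
        summary = {"metadata": self.metadata,
                   "pareto": self.pareto().to_dict(orient="records"),
                   "best_index": {str(k): list(v)
                                  for k, v in self.best_index.items()}}
        with open(d / "result.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        for k, placement in self.best.items():
            placement.to_json(d / f"placement_nce{k}.json")
            placement.channel_table().to_csv(
                d / f"channels_nce{k}.tsv", sep="\t", index=False)


def optimize(mesh: ScalpMesh, amap: GIAHatMap, spec: MontageSpec,
             space: SearchSpace, t: float | None = None, seed: int = 0,
             deterministic_fill: bool = False,
             all_channel_objective: bool = False) -> ArrangementResult:
    """Exhaustive scan of Omega(x, theta) with greedy role assignment.

    For every sampled (x_i, theta_j) the holder is placed, roles are assigned
    greedily, and f(x_i, theta_j) = avg GIA^ of the greedy solution is
    recorded; per observed N_ce the placement with maximal f is retained
    (ties: smaller center index, then smaller theta index).  Deterministic for
    a fixed seed; per-placement RNG streams are derived from (seed, i, j).
    """
    if t is None:
        t = amap.roi.t
    thetas = space.thetas
    M, T = len(space.centers), len(thetas)
    objective = np.full((M, T), np.nan)
    n_ce_map = np.full((M, T), -1, dtype=int)
    best: dict[int, MontagePlacement] = {}
    best_index: dict[int, tuple[int, int]] = {}
    any_feasible = False

    for i, x in enumerate(space.centers):
        for j, theta in enumerate(thetas):
            try:
                placement = place_montage(mesh, spec, CPC(*x), theta,
                                          compute_node_cpc=False)
            except (PlacementInfeasibleError, NumericalError):
                continue
            child = int(np.random.SeedSequence(
                [seed, i, j]).generate_state(1)[0] % (2 ** 31))
            assigned = greedy_assign(
                placement, amap, spec, t, seed=child,
                deterministic_fill=deterministic_fill,
                all_channel_objective=all_channel_objective)
            any_feasible = True
            objective[i, j] = assigned.avg_gia_hat
            n_ce_map[i, j] = assigned.n_ce
            # per-N_ce selection over the whole greedy trajectory plus a
            # pruning chain (optodes discarded weakest-first from the full
            # arrangement): each state competes at its own N_ce
            candidates = [assigned]
            states = list(dict.fromkeys(assigned.trajectory[:-1]))
            states += _pruning_chain(assigned, amap, t,
                                     all_channel_objective)
            for roles in dict.fromkeys(states):
                partial = assigned.copy_unassigned()
                partial.roles[:] = roles
                enumerate_channels(partial, amap, t,
                                   all_channel_objective=all_channel_objective)
                candidates.append(partial)
            for cand in candidates:
                k = cand.n_ce
                if k not in best or cand.avg_gia_hat > best[k].avg_gia_hat:
                    best[k] = cand
                    best_index[k] = (i, j)

    if not any_feasible:
        raise ArrangementInfeasibleError("every sampled placement was infeasible")
    meta = {"seed": seed, "t": t,
            "spec": {"rows": spec.rows, "cols": spec.cols, "d": spec.d,
                     "nS": spec.nS, "nD": spec.nD},
            "roi_labels": list(amap.roi.roi_labels),
            "n_centers": M, "n_theta": T}
    return ArrangementResult(best=best, objective=objective, n_ce_map=n_ce_map,
                             centers=space.centers, thetas=thetas,
                             best_index=best_index, metadata=meta)
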