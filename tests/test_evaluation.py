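"""Ground-truth indices, projection, and the error decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from tbamontage import (CPC, ConfigurationError, HeadModel, MontageSpec,
                        ROISpec, compute_gia, compute_giv, evaluate_montage,
                        montage_gia, montage_giv, place_montage,
                        project_to_brain, scalp_variability,
                        simulate_realized_placement, uv_hemisphere)
from tbamontage.cpc import cpc_to_xyz
from tbamontage.montage import enumerate_channels
from tbamontage.atlas import gia_hat_map


class TestGiv:
    def test_identical_points_give_zero(self):
        assert compute_giv(np.tile([3.0, -1.0, 2.0], (5, 1))) == 0.0

    def test_two_points_hand_value(self):
        assert compute_giv(np.array([[0, 0, 0], [2.0, 0, 0]])) == \
            pytest.approx(np.sqrt(2.0))

    def test_montage_mean(self):
        assert montage_giv([1.0, 3.0]) == 2.0

    def test_requires_two_participants(self):
        with pytest.raises(ConfigurationError):
            compute_giv(np.array([[1.0, 2.0, 3.0]]))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_invariant_under_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(6, 3)) * 10
        R = Rotation.random(random_state=seed).as_matrix()
        moved = pts @ R.T + rng.normal(size=3) * 100
        assert compute_giv(moved) == pytest.approx(compute_giv(pts), rel=1e-9)


class TestGia:
    def test_hand_value(self):
        assert compute_gia([1, 1, 0, 1]) == pytest.approx(0.75)

    def test_all_inside(self):
        assert compute_gia([1, 1, 1]) == 1.0

    def test_montage_mean(self):
        assert montage_gia([0.5, 1.0]) == pytest.approx(0.75)

    def test_rejects_non_indicator(self):
        with pytest.raises(ConfigurationError):
            compute_gia([0.5, 1.0])


class TestScalpVariability:
    def test_identical_cpcs_give_zero(self, template):
        cpcs = np.tile([0.45, 0.55], (4, 1))
        assert scalp_variability(cpcs, template) == 0.0

    def test_two_participants_hand_value(self, template):
        c1 = np.array([0.5, 0.5])
        c2 = np.array([0.5, 0.52])
        d = np.linalg.norm(cpc_to_xyz(template, c1) - cpc_to_xyz(template, c2))
        expected = d / np.sqrt(2.0)   # two-point dispersion
        assert scalp_variability(np.array([c1, c2]), template) == \
            pytest.approx(expected, rel=1e-9)

    def test_monotone_under_noise(self, population, pop_template):
        heads, _ = population
        ch = np.array([[0.45, 0.5]])
        vals = []
        for k, sigma in enumerate((0.0, 3.0, 8.0)):
            realized = simulate_realized_placement(ch, heads, sigma,
                                                   seed=50 + k)
            vals.append(scalp_variability(realized[:, 0, :], pop_template))
        assert vals[0] == 0.0
        assert vals[0] < vals[1] < vals[2]


class TestProjection:
    def test_concentric_spheres_project_radially(self):
        import trimesh
        scalp = uv_hemisphere((90.0, 90.0, 90.0), n_az=40, n_rings=16)
        brain = trimesh.creation.icosphere(subdivisions=7, radius=75.0)
        head = HeadModel(scalp=scalp, brain_vertices=np.asarray(brain.vertices),
                         brain_faces=np.asarray(brain.faces),
                         labels=np.array(["a"] * len(brain.vertices)),
                         to_common=np.eye(4))
        for direction in ([0, 0, 1.0], [0.6, 0.2, 0.78], [-0.3, 0.5, 0.81]):
            u = np.asarray(direction) / np.linalg.norm(direction)
            b = project_to_brain(head, 90.0 * u)
            assert np.linalg.norm(b - 75.0 * u) < 1.0

    def test_point_on_brain_vertex_is_fixed(self):
        scalp = uv_hemisphere((90.0, 90.0, 90.0), n_az=24, n_rings=8)
        brain = uv_hemisphere((75.0, 75.0, 75.0), n_az=24, n_rings=8)
        head = HeadModel(scalp=scalp, brain_vertices=brain.vertices,
                         brain_faces=brain.faces,
                         labels=np.array(["a"] * len(brain.vertices)),
                         to_common=np.eye(4))
        v = brain.vertices[37]
        assert np.array_equal(project_to_brain(head, v), v)

    def test_idempotent(self, population):
        heads, _ = population
        head = heads[0]
        rng = np.random.default_rng(2)
        for _ in range(10):
            s = head.scalp.vertices[rng.integers(len(head.scalp.vertices))]
            b1 = project_to_brain(head, s)
            b2 = project_to_brain(head, b1)
            assert np.array_equal(b1, b2)

    def test_matches_dense_mesh_refinement(self):
        """The same projection rule evaluated on a much denser cortical mesh
        moves the answer by at most 2 mm (ellipsoid head)."""
        axes = (80.0, 95.0, 85.0)
        scalp = uv_hemisphere(axes, n_az=40, n_rings=16)
        coarse = uv_hemisphere(tuple(0.85 * a for a in axes), n_az=120, n_rings=48)
        dense = uv_hemisphere(tuple(0.85 * a for a in axes), n_az=360, n_rings=144)
        mk = lambda b: HeadModel(
            scalp=scalp, brain_vertices=b.vertices, brain_faces=b.faces,
            labels=np.array(["a"] * len(b.vertices)), to_common=np.eye(4))
        hc, hd = mk(coarse), mk(dense)
        rng = np.random.default_rng(4)
        for _ in range(10):
            c = rng.uniform(0.2, 0.8, size=2)
            s = cpc_to_xyz(scalp, c)
            assert np.linalg.norm(project_to_brain(hc, s)
                                  - project_to_brain(hd, s)) < 2.0


class TestEvaluateMontage:
    @pytest.fixture()
    def setting(self, population, pop_template, pop_atlas, pop_roi, pop_map):
        heads, _ = population
        spec = MontageSpec(rows=2, cols=2, d=30.0, nS=2, nD=2)
        placement = place_montage(pop_template, spec, CPC(0.3, 0.55), 0.2)
        placement.roles[:] = ["S", "D", "D", "S"]
        enumerate_channels(placement, pop_map, t=0.5)
        return heads, placement

    def test_decomposition_identities_exact(self, setting, pop_roi, pop_atlas,
                                            pop_template, population):
        heads, placement = setting
        realized = simulate_realized_placement(placement, heads, 4.0, seed=9)
        rep = evaluate_montage(heads, placement, realized, pop_roi, pop_atlas,
                               typical_scalp=pop_template)
        assert np.allclose(rep.gia_hat + rep.eps1A + rep.eps2A,
                           rep.gia_actual, atol=1e-12)
        assert np.allclose(rep.giv_hat + rep.eps1V + rep.eps2V,
                           rep.giv_actual, atol=1e-12)

    def test_perfect_placement_kills_eps2(self, setting, pop_roi, pop_atlas,
                                          pop_template):
        heads, placement = setting
        realized = simulate_realized_placement(placement, heads, 0.0, seed=9)
        rep = evaluate_montage(heads, placement, realized, pop_roi, pop_atlas,
                               typical_scalp=pop_template)
        assert np.all(rep.eps2A == 0.0)
        assert np.all(rep.eps2V == 0.0)
        assert np.all(rep.scalp_var == 0.0)

    def test_eps1_vanishes_at_grid_points_with_matched_atlas(
            self, population, pop_atlas, pop_roi, pop_template):
        """Channels placed exactly at atlas grid points, atlas built from the
        same heads, single-label ROI: the atlas estimate equals the ideal
        individual-anatomy accuracy, so eps1A is zero."""
        heads, _ = population
        ch = pop_atlas.grid.cpc[[57, 120, 200]]
        realized = np.tile(ch, (len(heads), 1, 1))
        rep = evaluate_montage(heads, ch, realized, pop_roi, pop_atlas,
                               typical_scalp=pop_template)
        assert np.max(np.abs(rep.eps1A)) < 1.0 / len(heads)

    def test_missing_participants_are_masked(self, setting, pop_roi,
                                             pop_atlas, pop_template):
        heads, placement = setting
        realized = simulate_realized_placement(placement, heads, 2.0, seed=9)
        realized[1, 0] = np.nan
        realized[3, 0] = np.nan
        rep = evaluate_montage(heads, placement, realized, pop_roi, pop_atlas,
                               typical_scalp=pop_template)
        assert rep.n_p_per_channel[0] == len(heads) - 2
        assert rep.n_p_per_channel[1] == len(heads)

    def test_report_json(self, tmp_path, setting, pop_roi, pop_atlas,
                         pop_template):
        import json
        heads, placement = setting
        realized = simulate_realized_placement(placement, heads, 2.0, seed=9)
        rep = evaluate_montage(heads, placement, realized, pop_roi, pop_atlas,
                               typical_scalp=pop_template)
        rep.to_json(tmp_path / "report.json")
        with open(tmp_path / "report.json") as fh:
            data = json.load(fh)
        assert data["N_c"] == len(placement.channels)
        assert len(data["channels"]) == data["N_c"]


def test_headmodel_round_trip(tmp_path, population):
    heads, _ = population
    heads[0].save(tmp_path / "h0")
    loaded = HeadModel.load(tmp_path / "h0")
    assert np.allclose(loaded.brain_vertices, heads[0].brain_vertices, atol=1e-4)
    assert np.array_equal(loaded.labels, heads[0].labels)
    assert np.allclose(loaded.to_common, heads[0].to_common)
    assert loaded.min_clearance() > 0
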