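"""Thin-plate splines, bending energy, template projection, sliding."""

import numpy as np
import pytest

from morphonorm.io import LandmarkSample, Mesh
from morphonorm.superimposition import gpa
from morphonorm.templating import (
    bending_energy_matrix,
    closest_point_on_mesh,
    project_template,
    render_deformation,
    slide_semilandmarks,
    tps_fit,
    warp_points,
)


class TestTPS:
    def test_interpolates_exactly(self, rng):
        src = rng.normal(size=(8, 3))
        tgt = rng.normal(size=(8, 3))
        model = tps_fit(src, tgt)
        np.testing.assert_allclose(warp_points(model, src), tgt, atol=1e-8)

    def test_identity_map_has_zero_energy(self, rng):
        src = rng.normal(size=(6, 3))
        model = tps_fit(src, src)
        assert model.bending_energy == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(model.weights, 0.0, atol=1e-10)

    def test_affine_target_zero_energy_and_affine_warp(self, rng):
        src = rng.normal(size=(7, 3))
        a = rng.normal(size=(3, 3))
        b = rng.normal(size=3)
        model = tps_fit(src, src @ a + b)
        assert model.bending_energy == pytest.approx(0.0, abs=1e-10)
        probe = rng.normal(size=(10, 3))
        np.testing.assert_allclose(warp_points(model, probe), probe @ a + b,
                                   atol=1e-8)

    def test_energy_equals_quadratic_form(self, rng):
        """Model energy must equal target' B target with B the
        bending-energy matrix (the independent quadratic-form route)."""
        src = rng.normal(size=(8, 3))
        tgt = rng.normal(size=(8, 3))
        model = tps_fit(src, tgt)
        b = bending_energy_matrix(src)
        qf = sum(tgt[:, c] @ b @ tgt[:, c] for c in range(3))
        assert model.bending_energy == pytest.approx(qf, abs=1e-8)

    def test_kernel_weights_orthogonal_to_affine_space(self, rng):
        src = rng.normal(size=(9, 3))
        model = tps_fit(src, rng.normal(size=(9, 3)))
        np.testing.assert_allclose(model.weights.sum(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(src.T @ model.weights, 0.0, atol=1e-7)

    def test_midpoint_matches_direct_kernel_summation(self, rng):
        src = rng.normal(size=(8, 3))
        model = tps_fit(src, rng.normal(size=(8, 3)))
        p = 0.5 * (src[0] + src[1])
        direct = (-np.linalg.norm(p - src, axis=1)) @ model.weights \
            + np.concatenate([[1.0], p]) @ model.affine
        np.testing.assert_allclose(warp_points(model, p[None])[0], direct,
                                   atol=1e-10)

    def test_bending_energy_matrix_psd_with_affine_null_space(self, rng):
        src = rng.normal(size=(10, 3))
        b = bending_energy_matrix(src)
        np.testing.assert_allclose(b, b.T, atol=1e-12)
        w, v = np.linalg.eigh(b)
        assert w.min() > -1e-9 * max(w.max(), 1.0)
        # exactly 4 zero eigenvalues, spanned by [1, x, y, z]
        null = (np.abs(w) < 1e-9 * w.max()).sum()
        assert null == 4
        affine = np.hstack([np.ones((10, 1)), src])
        np.testing.assert_allclose(b @ affine, 0.0, atol=1e-8)


class TestProjection:
    def test_self_projection_identity(self, small_template):
        t = small_template
        anchors = t.config[t.role_indices("fixed", "curve")]
        out = project_template(t, t.mesh, anchors)
        np.testing.assert_allclose(out, t.config, atol=1e-9)

    def test_affine_specimen_exact(self, small_template):
        t = small_template
        a = np.diag([1.3, 0.8, 1.1])
        anchors = t.config[t.role_indices("fixed", "curve")] @ a
        out = project_template(t, Mesh(t.mesh.vertices @ a, t.mesh.faces), anchors)
        np.testing.assert_allclose(out, t.config @ a, atol=1e-6)

    def test_equivariant_under_rigid_motion(self, small_template, rng):
        t = small_template
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q = q * np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        shift = rng.normal(size=3) * 50
        anchors = t.config[t.role_indices("fixed", "curve")]
        out0 = project_template(t, t.mesh, anchors)
        out1 = project_template(
            t, Mesh(t.mesh.vertices @ q + shift, t.mesh.faces), anchors @ q + shift
        )
        np.testing.assert_allclose(out1, out0 @ q + shift, atol=1e-6)

    def test_projection_recovers_synthetic_truth(self, small_template, rng):
        """A warped specimen built from the template by a known smooth
        deformation is recovered within the mesh-facet tolerance."""
        t = small_template
        truth_model = tps_fit(
            t.config[t.role_indices("fixed", "curve")],
            t.config[t.role_indices("fixed", "curve")]
            + rng.normal(0, 6.0, (len(t.role_indices("fixed", "curve")), 3)),
        )
        warped_mesh = Mesh(warp_points(truth_model, t.mesh.vertices), t.mesh.faces)
        warped_anchors = warp_points(
            truth_model, t.config[t.role_indices("fixed", "curve")]
        )
        out = project_template(t, warped_mesh, warped_anchors)
        truth_surface = warp_points(truth_model, t.config[t.role_indices("surface")])
        err = np.linalg.norm(out[t.role_indices("surface")] - truth_surface, axis=1)
        assert np.median(err) < 5.0  # µm, vs a ~500 µm structure


class TestClosestPoint:
    def test_on_surface_points_project_to_themselves(self, small_template, rng):
        t = small_template
        tri = t.mesh.vertices[t.mesh.faces]
        bary = rng.dirichlet([1, 1, 1], size=20)
        pts = np.einsum("fvc,fv->fc", tri[:20], bary)
        proj, d = closest_point_on_mesh(t.mesh, pts)
        np.testing.assert_allclose(proj, pts, atol=1e-9)
        assert d.max() < 1e-9

    def test_off_surface_distance_correct_for_plane(self):
        mesh = Mesh(
            np.array([[0.0, 0, 0], [4, 0, 0], [0, 4, 0], [4, 4, 0]]),
            np.array([[0, 1, 2], [1, 3, 2]]),
        )
        pts = np.array([[1.0, 1.0, 2.5], [10.0, 1.0, 0.0]])
        proj, d = closest_point_on_mesh(mesh, pts)
        np.testing.assert_allclose(proj[0], [1, 1, 0], atol=1e-12)
        assert d[0] == pytest.approx(2.5, abs=1e-12)
        np.testing.assert_allclose(proj[1], [4, 1, 0], atol=1e-12)  # edge clamp
        assert d[1] == pytest.approx(6.0, abs=1e-12)


class TestSliding:
    def test_fixed_point_no_movement(self, small_template):
        """If every specimen already equals the consensus there is
        nothing to slide."""
        t = small_template
        coords = np.stack([t.config, t.config])
        sample = LandmarkSample(coords, ["a", "b"], list(t.roles),
                                list(t.pairing), list(t.midline))
        out = slide_semilandmarks(sample, outer_iterations=2)
        res = gpa(sample)
        np.testing.assert_allclose(out.sample.coords, res.aligned, atol=1e-8)

    def test_irregular_circle_becomes_more_regular(self):
        """Curve points irregularly spaced on a circle, reference regular:
        sliding must regularize the spacing and strictly reduce energy."""
        from morphonorm.io import PointRole

        k = 12
        reg = np.linspace(0, 1.5 * np.pi, k)
        irr = reg + 0.12 * np.sin(5 * reg)

        def ring(angles, radius=1.0):
            # a gentle out-of-plane wave keeps the 3D TPS system regular
            return np.column_stack([
                radius * np.cos(angles), radius * np.sin(angles),
                0.2 * np.sin(angles),
            ])

        anchor_roles = [PointRole("fixed"), PointRole("fixed")]
        roles = anchor_roles + [PointRole("curve", 0, i) for i in range(k)]

        def with_anchors(pts):
            return np.vstack([[[1.6, 0, 0.4]], [[-1.6, 0, -0.4]], pts])

        coords = np.stack([
            with_anchors(ring(reg)),       # the regular reference shape
            with_anchors(ring(irr)),       # irregular specimen
        ])
        sample = LandmarkSample(coords, ["ref", "irr"], roles)
        out = slide_semilandmarks(sample, outer_iterations=3, symmetric=False)
        assert out.energy_trace[-1] < out.energy_trace[0]
        assert all(b <= a * (1 + 1e-12)
                   for a, b in zip(out.energy_trace, out.energy_trace[1:]))
        # spacing of the slid irregular curve is more even than before
        slid = out.sample.coords[1][2:]
        gaps = np.linalg.norm(np.diff(slid, axis=0), axis=1)
        gaps0 = np.linalg.norm(np.diff(ring(irr), axis=0), axis=1)
        assert gaps.std() / gaps.mean() < gaps0.std() / gaps0.mean()

    def test_energy_never_increases_on_synthetic_sample(self, small_sample):
        sample, _ = small_sample
        out = slide_semilandmarks(sample.subset(range(24)), outer_iterations=3)
        trace = out.energy_trace
        assert all(b <= a * (1 + 1e-12) for a, b in zip(trace, trace[1:]))

    def test_downstream_effects_survive_sliding(self, small_sample):
        """Sliding must not wash out or invert the simulated temperature
        effect."""
        from morphonorm.shapestats import procrustes_anova_rrpp
        from morphonorm.superimposition import symmetrize, tangent_coordinates

        sample, _ = small_sample
        out = slide_semilandmarks(sample, outer_iterations=2)
        res = symmetrize(gpa(out.sample))
        y = tangent_coordinates(res)
        table = procrustes_anova_rrpp(
            y,
            {"population": sample.factor("population"),
             "temperature": sample.factor("temperature").astype(str)},
            "population*temperature", n_perm=199, seed=5,
        )
        assert table.p["temperature"] <= 0.05
        assert table.z["temperature"] > 2


class TestRenderDeformation:
    def test_zero_multiplier_is_identity(self, small_template):
        t = small_template
        out = render_deformation(t.config, np.ones_like(t.config), 0.0, t.mesh)
        np.testing.assert_array_equal(out.vertices, t.mesh.vertices)

    def test_plus_minus_are_mirror_deformations(self, small_template, rng):
        t = small_template
        vec = rng.normal(0, 0.01, t.config.shape)
        plus = render_deformation(t.config, vec, 3.0, t.mesh)
        minus = render_deformation(t.config, vec, -3.0, t.mesh)
        mid = 0.5 * (plus.vertices + minus.vertices)
        # linear in the multiplier: the average of +k and -k is the identity
        np.testing.assert_allclose(mid, t.mesh.vertices, atol=1e-6)

    def test_vertex_displacement_matches_direct_tps(self, small_template, rng):
        t = small_template
        vec = rng.normal(0, 0.01, t.config.shape)
        out = render_deformation(t.config, vec, 5.0, t.mesh)
        model = tps_fit(t.config, t.config + 5.0 * vec)
        np.testing.assert_allclose(out.vertices, warp_points(model, t.mesh.vertices),
                                   atol=1e-9)
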