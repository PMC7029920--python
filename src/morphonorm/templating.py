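"""Thin-plate-spline machinery: warps, bending energy, template projection,
and sliding semilandmarks.

The 3D kernel is the biharmonic U(r) = -r, whose bending-energy quadratic
form is positive semi-definite with the affine maps as null space; 2D
configurations use the classical U(r) = r^2 log r.  Curve semilandmarks
slide along the local curve tangent (one degree of freedom) and surface
semilandmarks in the local tangent plane (two degrees of freedom), the
displacements chosen to minimize total bending energy relative to the
current Procrustes consensus, after which points are snapped back to
their curve or to the specimen mesh surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import LandmarkSample, Mesh, PointRole, ValidationError
from .superimposition import GPAResult, gpa

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# thin-plate splines
# ---------------------------------------------------------------------------


def _kernel(r: np.ndarray, d: int) -> np.ndarray:
    if d == 3:
        return -r
    if d == 2:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = r * r * np.log(r)
        return np.where(r > 0, out, 0.0)
    raise ValidationError("TPS defined for 2D and 3D only")


def _kernel_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    r = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))
    return _kernel(r, a.shape[1])


@dataclass
class TPSModel:
    """A fitted thin-plate-spline interpolant from ``source`` to a target.

    ``weights`` (k x d) are the kernel coefficients, orthogonal to the
    affine space (columns sum to zero and are orthogonal to the source
    coordinates); ``affine`` ((d+1) x d) holds the affine part as
    [translation; linear].
    """

    source: np.ndarray
    weights: np.ndarray
    affine: np.ndarray
    bending_energy: float = 0.0

    @property
    def n_dim(self) -> int:
        return self.source.shape[1]


def _tps_system(source: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    k, d = source.shape
    kk = _kernel_matrix(source, source)
    if ridge:
        kk = kk + ridge * np.eye(k)
    p = np.hstack([np.ones((k, 1)), source])
    top = np.hstack([kk, p])
    bottom = np.hstack([p.T, np.zeros((d + 1, d + 1))])
    return np.vstack([top, bottom])


def bending_energy_matrix(source: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """The k x k bending-energy matrix of a source configuration.

    Symmetric positive semi-definite; its null space is spanned by the
    affine functions of the source coordinates (per coordinate), so any
    affine deformation has zero bending energy.  The bending energy of a
    map sending ``source`` to ``target`` is ``sum_c target[:,c] @ B @
    target[:,c]``.
    """
    source = np.asarray(source, dtype=float)
    k = source.shape[0]
    l_mat = _tps_system(source, ridge)
    try:
        l_inv = np.linalg.inv(l_mat)
    except np.linalg.LinAlgError:
        eps = 1e-8 * np.abs(l_mat).max()
        logger.warning("singular TPS system; ridge-regularizing with eps=%g", eps)
        l_inv = np.linalg.pinv(_tps_system(source, eps))
    b = l_inv[:k, :k]
    return 0.5 * (b + b.T)


def tps_fit(source: np.ndarray, target: np.ndarray) -> TPSModel:
    """Fit the interpolating thin-plate spline sending source to target."""
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape:
        raise ValidationError("source/target shape mismatch")
    k, d = source.shape
    l_mat = _tps_system(source)
    rhs = np.vstack([target, np.zeros((d + 1, d))])
    try:
        sol = np.linalg.solve(l_mat, rhs)
    except np.linalg.LinAlgError:
        eps = 1e-8 * np.abs(l_mat).max()
        logger.warning("singular TPS system; ridge-regularizing with eps=%g", eps)
        sol, *_ = np.linalg.lstsq(_tps_system(source, eps), rhs, rcond=None)
    weights, affine = sol[:k], sol[k:]
    kk = _kernel_matrix(source, source)
    energy = float(np.einsum("ic,ij,jc->", weights, kk, weights))
    return TPSModel(source, weights, affine, bending_energy=energy)


def warp_points(model: TPSModel, points: np.ndarray) -> np.ndarray:
    """Evaluate a fitted TPS at arbitrary points (exact at the source)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    kk = _kernel_matrix(points, model.source)
    p = np.hstack([np.ones((len(points), 1)), points])
    return kk @ model.weights + p @ model.affine


# ---------------------------------------------------------------------------
# mesh projection
# ---------------------------------------------------------------------------


def closest_point_on_mesh(mesh: Mesh, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest point on the triangle soup for each query point.

    Exact point-triangle projection (not nearest vertex), so the result
    is independent of mesh resolution.  Candidate triangles are culled
    with a KD-tree on triangle centroids: the true nearest triangle's
    centroid lies within (distance to nearest centroid + max triangle
    radius) of the query, so the search stays exact.  Returns (projected
    points, distances).
    """
    from scipy.spatial import cKDTree

    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.vertices[mesh.faces]  # (m, 3, 3)
    centers = tri.mean(axis=1)
    radius = float(np.sqrt(((tri - centers[:, None, :]) ** 2).sum(-1)).max())
    tree = cKDTree(centers)
    d1, _ = tree.query(points)
    cand = tree.query_ball_point(points, d1 + radius + 1e-9)
    rows = np.repeat(np.arange(len(points)), [len(c) for c in cand])
    cols = np.concatenate([np.asarray(c, dtype=int) for c in cand]) \
        if len(rows) else np.empty(0, dtype=int)
    pp = _project_point_triangle_pairs(points[rows], tri[cols])
    d2 = ((pp - points[rows]) ** 2).sum(-1)
    order = np.lexsort((d2, rows))
    first = np.searchsorted(rows[order], np.arange(len(points)))
    pick = order[first]
    return pp[pick], np.sqrt(d2[pick])


def _project_point_triangle_pairs(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on triangle i for query i (Ericson's region method)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = (ab * ap).sum(-1)
    d2 = (ac * ap).sum(-1)
    bp = p - b
    d3 = (ab * bp).sum(-1)
    d4 = (ac * bp).sum(-1)
    cp = p - c
    d5 = (ab * cp).sum(-1)
    d6 = (ac * cp).sum(-1)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
    out = a + v[:, None] * ab + w[:, None] * ac

    with np.errstate(divide="ignore", invalid="ignore"):
        wq = np.where((d2 - d6) != 0, d2 / (d2 - d6), 0.0)
    cond = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    out = np.where(cond[:, None], a + wq[:, None] * ac, out)
    with np.errstate(divide="ignore", invalid="ignore"):
        wq = np.where(((d4 - d3) + (d5 - d6)) != 0,
                      (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)
    cond = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    out = np.where(cond[:, None], b + wq[:, None] * (c - b), out)
    with np.errstate(divide="ignore", invalid="ignore"):
        vq = np.where((d1 - d3) != 0, d1 / (d1 - d3), 0.0)
    cond = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    out = np.where(cond[:, None], a + vq[:, None] * ab, out)
    out = np.where(((d1 <= 0) & (d2 <= 0))[:, None], a, out)
    out = np.where(((d3 >= 0) & (d4 <= d3))[:, None], b, out)
    out = np.where(((d6 >= 0) & (d5 <= d6))[:, None], c, out)
    return out


# ---------------------------------------------------------------------------
# template projection
# ---------------------------------------------------------------------------


@dataclass
class Template:
    """Reference configuration + simplified mesh carrying surface points.

    ``config`` is the k x 3 reference configuration whose point roles
    identify which entries are fixed landmarks, curve semilandmarks, and
    surface semilandmarks; ``mesh`` is the simplified reference surface.
    """

    config: np.ndarray
    roles: list[PointRole]
    mesh: Mesh | None = None
    pairing: list[tuple[int, int]] = field(default_factory=list)
    midline: list[int] = field(default_factory=list)

    def role_indices(self, *roles: str) -> np.ndarray:
        return np.array(
            [i for i, r in enumerate(self.roles) if r.role in roles], dtype=int
        )

    def counts(self) -> dict[str, int]:
        out = {"fixed": 0, "curve": 0, "surface": 0}
        for r in self.roles:
            out[r.role] += 1
        return out


def project_template(
    template: Template,
    specimen_mesh: Mesh,
    specimen_fixed_and_curves: np.ndarray,
    snap: bool = True,
    max_snap_distance: float | None = None,
) -> np.ndarray:
    """Transfer template surface semilandmarks onto one specimen.

    A TPS is fitted from the template's fixed + curve points to the
    specimen's homologous points; the template surface points are warped
    through it and snapped to the nearest point on the specimen mesh.
    Returns the full k-point configuration in template point order.
    """
    anchor_idx = template.role_indices("fixed", "curve")
    surf_idx = template.role_indices("surface")
    spec_anchors = np.asarray(specimen_fixed_and_curves, dtype=float)
    if spec_anchors.shape != (len(anchor_idx), template.config.shape[1]):
        raise ValidationError(
            f"expected {len(anchor_idx)} specimen anchor points, got {spec_anchors.shape}"
        )
    model = tps_fit(template.config[anchor_idx], spec_anchors)
    warped = warp_points(model, template.config[surf_idx])
    if snap and len(surf_idx):
        snapped, dist = closest_point_on_mesh(specimen_mesh, warped)
        if max_snap_distance is not None:
            n_far = int((dist > max_snap_distance).sum())
            if n_far:
                logger.warning(
                    "%d surface points farther than %g from the mesh", n_far,
                    max_snap_distance,
                )
        warped = snapped
    out = np.empty_like(template.config)
    out[anchor_idx] = spec_anchors
    out[surf_idx] = warped
    return out


# ---------------------------------------------------------------------------
# sliding semilandmarks
# ---------------------------------------------------------------------------


@dataclass
class SlideResult:
    sample: LandmarkSample
    gpa: GPAResult
    energy_trace: list[float]
    iterations: int
    converged: bool


def _curve_groups(roles: list[PointRole]) -> dict[int, list[int]]:
    curves: dict[int, list[int]] = {}
    for i, r in enumerate(roles):
        if r.role == "curve":
            curves.setdefault(r.curve_id, []).append(i)
    for cid in curves:
        curves[cid].sort(key=lambda i: roles[i].order_in_curve)
    return curves


def _tangent_frames(
    config: np.ndarray,
    roles: list[PointRole],
    mesh: Mesh | None,
    n_neighbors: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding directions: (param point index, param direction vectors).

    Curve points get the unit tangent from central differences along the
    curve order; surface points get two orthonormal tangent-plane
    vectors, from the mesh normal at the nearest surface point when a
    mesh is available and from local neighbour PCA otherwise.
    """
    d = config.shape[1]
    idx: list[int] = []
    dirs: list[np.ndarray] = []
    for cid, members in _curve_groups(roles).items():
        pts = config[members]
        for j, i in enumerate(members):
            lo = max(j - 1, 0)
            hi = min(j + 1, len(members) - 1)
            t = pts[hi] - pts[lo]
            norm = np.linalg.norm(t)
            if norm == 0:
                continue
            idx.append(i)
            dirs.append(t / norm)
    surf = [i for i, r in enumerate(roles) if r.role == "surface"]
    if surf:
        if mesh is not None and d == 3:
            normals = _mesh_normals_at(mesh, config[surf])
        else:
            normals = _pca_normals(config, np.array(surf), n_neighbors)
        for i, n in zip(surf, normals):
            t1, t2 = _plane_basis(n)
            idx.extend([i, i])
            dirs.extend([t1, t2])
    return np.array(idx, dtype=int), np.array(dirs, dtype=float)


def _mesh_normals_at(mesh: Mesh, points: np.ndarray) -> np.ndarray:
    tri = mesh.vertices[mesh.faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = normals / np.where(norms > 0, norms, 1.0)
    centers = tri.mean(axis=1)
    out = np.empty_like(points)
    for q, p in enumerate(points):
        j = ((centers - p) ** 2).sum(1).argmin()
        out[q] = normals[j]
    return out


def _pca_normals(config: np.ndarray, surf_idx: np.ndarray, n_neighbors: int) -> np.ndarray:
    d = config.shape[1]
    out = np.empty((len(surf_idx), d))
    for q, i in enumerate(surf_idx):
        d2 = ((config - config[i]) ** 2).sum(1)
        nn = np.argsort(d2)[: n_neighbors + 1]
        local = config[nn] - config[nn].mean(0)
        _, _, vt = np.linalg.svd(local, full_matrices=False)
        out[q] = vt[-1]
    return out


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = normal / np.linalg.norm(normal)
    ref = np.zeros_like(n)
    ref[np.abs(n).argmin()] = 1.0
    t1 = np.cross(n, ref) if len(n) == 3 else np.array([-n[1], n[0]])
    t1 = t1 / np.linalg.norm(t1)
    if len(n) == 3:
        t2 = np.cross(n, t1)
        return t1, t2
    return t1, t1  # 2D: degenerate, surface points need 3D


def _slide_one(
    config: np.ndarray,
    bemat: np.ndarray,
    roles: list[PointRole],
    mesh: Mesh | None,
) -> np.ndarray:
    """Minimum-bending-energy tangent displacement for one specimen.

    Minimizes (x + U t)' (I_d (x) B) (x + U t) over the sliding
    parameters t; the normal equations collapse to dense k-indexed
    algebra: A[j,j'] = (v_j . v_j') B[i_j, i_j'].
    """
    idx, dirs = _tangent_frames(config, roles, mesh)
    if len(idx) == 0:
        return config
    a = bemat[np.ix_(idx, idx)] * (dirs @ dirs.T)
    bx = bemat @ config  # (k, d)
    rhs = -(dirs * bx[idx]).sum(axis=1)
    a = a + 1e-10 * np.trace(a) / len(a) * np.eye(len(a))
    t = np.linalg.solve(a, rhs)
    delta = np.zeros_like(config)
    np.add.at(delta, idx, dirs * t[:, None])
    return config + delta


def _snap_to_curves(
    config: np.ndarray, original: np.ndarray, roles: list[PointRole]
) -> np.ndarray:
    """Project slid curve points back onto the original curve polyline."""
    out = config.copy()
    for cid, members in _curve_groups(roles).items():
        poly = original[members]
        seg_a = poly[:-1]
        seg_b = poly[1:]
        ab = seg_b - seg_a
        ab2 = (ab**2).sum(1)
        for i in members:
            p = config[i]
            with np.errstate(divide="ignore", invalid="ignore"):
                s = ((p - seg_a) * ab).sum(1) / np.where(ab2 > 0, ab2, 1.0)
            s = np.clip(s, 0.0, 1.0)
            cand = seg_a + s[:, None] * ab
            j = ((cand - p) ** 2).sum(1).argmin()
            out[i] = cand[j]
    return out


def _total_energy(shapes: np.ndarray, bemat: np.ndarray) -> float:
    return float(np.einsum("nic,ij,njc->", shapes, bemat, shapes))


def slide_semilandmarks(
    sample: LandmarkSample,
    meshes: dict[str, Mesh] | None = None,
    mode: str = "bending_energy",
    outer_iterations: int = 3,
    snap: bool = True,
    symmetric: bool | None = None,
) -> SlideResult:
    """Slide curve and surface semilandmarks to minimize bending energy.

    Outer loop: GPA, tangent-restricted bending-energy minimization of
    every specimen against the consensus, snap back to curves (and to
    the specimen mesh when provided), repeat.  Total bending energy is
    monitored against the initial consensus; an iteration that fails to
    decrease it is rejected and sliding stops with ``converged=False``.

    When ``symmetric`` is true (default when the sample declares a
    pairing) the tangent displacement field is averaged with its
    reflection-relabelled mirror before being applied, so paired points
    slide jointly.
    """
    if mode != "bending_energy":
        raise ValidationError(f"unknown sliding mode {mode!r}")
    if not sample.roles:
        raise ValidationError("sample carries no point roles")
    if symmetric is None:
        symmetric = bool(sample.pairing)

    res = gpa(sample)
    aligned = res.aligned.copy()
    bemat0 = bending_energy_matrix(res.consensus)
    trace = [_total_energy(aligned, bemat0)]
    converged = True
    it = 0
    for it in range(1, outer_iterations + 1):
        bemat = bending_energy_matrix(res.consensus)
        new = np.empty_like(aligned)
        for i in range(len(aligned)):
            mesh = None
            if meshes is not None:
                mesh = meshes.get(sample.specimen_ids[i])
            cfg = _slide_one(aligned[i], bemat, sample.roles, mesh)
            if symmetric and sample.pairing:
                delta = cfg - aligned[i]
                mirror = _mirror_field(delta, aligned[i], res.consensus,
                                       sample.pairing)
                cfg = aligned[i] + 0.5 * (delta + mirror)
            if snap:
                cfg = _snap_to_curves(cfg, aligned[i], sample.roles)
                if mesh is not None:
                    surf = [j for j, r in enumerate(sample.roles) if r.role == "surface"]
                    if surf:
                        cfg[surf], _ = closest_point_on_mesh(mesh, cfg[surf])
            new[i] = cfg
        energy = _total_energy(new, bemat0)
        if energy > trace[-1] * (1 + 1e-12):
            logger.warning(
                "sliding iteration %d would increase bending energy "
                "(%.6g -> %.6g); stopping", it, trace[-1], energy,
            )
            converged = False
            it -= 1
            break
        aligned = new
        trace.append(energy)
        res = gpa(aligned)
        aligned = res.aligned
    out_sample = LandmarkSample(
        aligned, list(sample.specimen_ids), list(sample.roles),
        list(sample.pairing), list(sample.midline), sample.factors,
    )
    return SlideResult(out_sample, res, trace, it, converged)


def _mirror_field(
    delta: np.ndarray,
    config: np.ndarray,
    consensus: np.ndarray,
    pairing: list[tuple[int, int]],
) -> np.ndarray:
    """Reflection-relabelled copy of a displacement field.

    The mirror transform is estimated from the configuration itself: the
    orthogonal map best sending the relabelled reflection back onto the
    configuration, applied to the relabelled, reflected displacements.
    """
    from .superimposition import _reflect_relabel, optimal_rotation

    mirrored_cfg = _reflect_relabel(config, pairing)
    rot = optimal_rotation(mirrored_cfg, config)
    mirrored_delta = _reflect_relabel(delta, pairing) @ rot
    return mirrored_delta


def render_deformation(
    consensus: np.ndarray,
    effect_vector: np.ndarray,
    sd_units: float,
    mesh: Mesh,
) -> Mesh:
    """Warp a mesh by an exaggerated shape effect.

    Fits the TPS sending the consensus to ``consensus + sd_units *
    effect_vector`` (the effect vector scaled to one standard deviation
    of the shape scores it illustrates) and applies it to the mesh
    vertices, for the classic exaggerated-deformation figures.
    """
    consensus = np.asarray(consensus, dtype=float)
    target = consensus + sd_units * np.asarray(effect_vector, dtype=float)
    if sd_units == 0.0:
        return mesh.copy()
    model = tps_fit(consensus, target)
    return Mesh(warp_points(model, mesh.vertices), mesh.faces.copy(), mesh.scale_unit)
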