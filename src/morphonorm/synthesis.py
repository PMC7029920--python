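"""Synthetic shape data with known truth.

Generates a bilaterally symmetric half-ellipsoid "valve-pair" surface
standing in for an ovipositor, with the standard point design (5 fixed
landmarks, two 60-point lateral curves, one 10-point proximal curve, 394
surface semilandmarks; 529 points in total), plus a 2D 15-point
wing-like control structure.  Specimens are drawn under a population x
developmental-temperature design with additive zero-mean shape effects,
log-size allometry, iid landmark noise, and random rigid motion and
scale, so the whole superimposition pipeline is genuinely exercised and
every downstream statistic can be checked against the simulated truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    DEFAULT_GROUP_SIZES,
    FactorDesign,
    LandmarkSample,
    Mesh,
    PointRole,
    ValidationError,
)
from .templating import Template, closest_point_on_mesh

# ---------------------------------------------------------------------------
# base geometry
# ---------------------------------------------------------------------------

# semi-axes of the half-ellipsoid valve pair, micrometres
_AX, _AY, _AZ = 150.0, 250.0, 80.0


def _dome(theta: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Points on the half-ellipsoid: theta in [0, pi] sweeps right to left."""
    shrink = np.sqrt(np.clip(1.0 - (y / _AY) ** 2, 0.0, None))
    x = _AX * np.cos(theta) * shrink
    z = _AZ * np.sin(theta) * shrink
    return np.column_stack([x, np.broadcast_to(y, np.shape(x)), z])


def _base_mesh(n_theta: int = 40, n_y: int = 60) -> Mesh:
    theta = np.linspace(0.0, np.pi, n_theta)
    y = np.linspace(-0.97 * _AY, 0.97 * _AY, n_y)
    tt, yy = np.meshgrid(theta, y)
    verts = _dome(tt.ravel(), yy.ravel())
    faces = []
    for i in range(n_y - 1):
        for j in range(n_theta - 1):
            a = i * n_theta + j
            b = a + 1
            c = a + n_theta
            d = c + 1
            faces.append([a, b, d])
            faces.append([a, d, c])
    return Mesh(verts, np.array(faces)).drop_degenerate_faces()


_PHI = (np.sqrt(5.0) - 1.0) / 2.0  # golden-ratio lattice increment


def make_base_shape(
    k_fixed: int = 5,
    k_curve: tuple[int, ...] = (60, 60, 10),
    k_surface: int = 394,
) -> Template:
    """Build the bilaterally symmetric reference configuration and mesh.

    Point order is fixed landmarks, then curves in declared order, then
    surface semilandmarks.  The defaults give the standard 529-point
    design; the left/right pairing table and midline list are emitted
    exactly, and reflecting the configuration through the x=0 plane and
    relabelling paired points reproduces it.
    """
    if k_fixed < 0 or k_surface < 0 or any(c < 0 for c in k_curve):
        raise ValidationError("point counts must be non-negative")
    pts: list[np.ndarray] = []
    roles: list[PointRole] = []
    pairing: list[tuple[int, int]] = []
    midline: list[int] = []

    def add(point, role: PointRole):
        pts.append(np.asarray(point, dtype=float))
        roles.append(role)
        return len(pts) - 1

    # fixed landmarks: distal pair, proximal pair, dorsal midline point, ...
    fixed_sites = [
        (_dome(np.array([0.0]), np.array([0.93 * _AY]))[0],
         _dome(np.array([np.pi]), np.array([0.93 * _AY]))[0]),   # distal pair
        (_dome(np.array([0.0]), np.array([-0.93 * _AY]))[0],
         _dome(np.array([np.pi]), np.array([-0.93 * _AY]))[0]),  # proximal pair
    ]
    mid_sites = [_dome(np.array([np.pi / 2]), np.array([-0.3 * _AY]))[0],
                 _dome(np.array([np.pi / 2]), np.array([0.5 * _AY]))[0]]
    n_pairs = k_fixed // 2
    for p in range(n_pairs):
        right, left = fixed_sites[p % len(fixed_sites)]
        jitter = 1.0 - 0.04 * (p // len(fixed_sites))
        i = add(right * jitter, PointRole("fixed"))
        j = add(left * jitter, PointRole("fixed"))
        pairing.append((j, i))
    if k_fixed % 2:
        midline.append(add(mid_sites[0], PointRole("fixed")))

    # curves: the first two, if equally sized, form the lateral mirror pair;
    # any other curve is self-symmetric across the midline
    lateral_pair = len(k_curve) >= 2 and k_curve[0] == k_curve[1] and k_curve[0] > 0
    curve_start: dict[int, int] = {}
    for cid, count in enumerate(k_curve):
        if count == 0:
            continue
        curve_start[cid] = len(pts)
        if lateral_pair and cid in (0, 1):
            yy = np.linspace(-0.9 * _AY, 0.9 * _AY, count)
            theta = np.pi if cid == 0 else 0.0  # 0: left rim, 1: right rim
            for order, y in enumerate(yy):
                add(_dome(np.array([theta]), np.array([y]))[0],
                    PointRole("curve", cid, order))
        else:
            theta = np.pi * (np.arange(count) + 0.5) / count
            y = -0.95 * _AY
            for order, th in enumerate(theta):
                add(_dome(np.array([th]), np.array([y]))[0],
                    PointRole("curve", cid, order))
            base = curve_start[cid]
            for order in range(count // 2):
                pairing.append((base + count - 1 - order, base + order))
            if count % 2:
                midline.append(base + count // 2)
    if lateral_pair:
        a, b = curve_start.get(0), curve_start.get(1)
        for order in range(k_curve[0]):
            pairing.append((a + order, b + order))

    # surface semilandmarks: golden-ratio lattice on the x>0 quarter, mirrored;
    # snapped onto the simplified mesh so template self-projection is exact
    mesh = _base_mesh()
    m = k_surface // 2
    surf_right = []
    for i in range(m):
        y = 0.88 * _AY * (2.0 * (i + 0.5) / m - 1.0)
        th = (0.08 + ((i * _PHI) % 1.0) * 0.84) * (np.pi / 2.0)
        surf_right.append(_dome(np.array([th]), np.array([y]))[0])
    if surf_right:
        surf_right, _ = closest_point_on_mesh(mesh, np.vstack(surf_right))
    for p in surf_right:
        i = add(p, PointRole("surface"))
        j = add(p * np.array([-1.0, 1.0, 1.0]), PointRole("surface"))
        pairing.append((j, i))
    if k_surface % 2:
        mid_pt, _ = closest_point_on_mesh(
            mesh, _dome(np.array([np.pi / 2]), np.array([0.0]))
        )
        midline.append(add(mid_pt[0], PointRole("surface")))

    config = np.vstack(pts) if pts else np.zeros((0, 3))
    return Template(config, roles, mesh, pairing, midline)


def make_wing_shape(k: int = 15) -> np.ndarray:
    """A planar wing-like configuration: k 2D landmark positions (µm)."""
    # vein-junction-like positions along a 2.5 mm wing
    t = np.linspace(0.0, 2.0 * np.pi, k, endpoint=False)
    r = 1250.0 * (1.0 + 0.35 * np.cos(2 * t) + 0.1 * np.sin(3 * t))
    return np.column_stack([r * np.cos(t) * 1.0, r * np.sin(t) * 0.45])


# ---------------------------------------------------------------------------
# effect specification
# ---------------------------------------------------------------------------


@dataclass
class EffectSpec:
    """True effect structure for the generator.

    All deformation fields are k x d arrays in shape units (displacements
    of a unit-centroid-size configuration) with zero mean across points
    per coordinate, so they are pure shape effects.  ``allometry_vector``
    is the shape displacement per unit log centroid size.
    """

    population_vectors: dict[str, np.ndarray]
    temperature_vectors: dict[int, np.ndarray]
    allometry_vector: np.ndarray
    interaction_vectors: dict[tuple[str, int], np.ndarray] | None = None
    individual_fields: np.ndarray | None = None   # (j, k, d) smooth basis
    individual_sds: np.ndarray | None = None      # (j,) per-field sd
    noise_sd: float = 0.0
    size_means: dict[tuple[str, int], float] = field(default_factory=dict)
    size_cv: float = 0.037
    measurement_error_sd: float = 0.0
    line_effect_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.measurement_error_sd < 0:
            raise ValidationError("noise standard deviations must be >= 0")
        for label, vec in self._all_fields():
            if np.abs(vec.mean(axis=0)).max() > 1e-9:
                raise ValidationError(f"deformation field {label} is not zero-mean")
        if any(v <= 0 for v in self.size_means.values()):
            raise ValidationError("size means must be positive")

    def _all_fields(self):
        for p, v in self.population_vectors.items():
            yield f"population[{p}]", v
        for t, v in self.temperature_vectors.items():
            yield f"temperature[{t}]", v
        yield "allometry", self.allometry_vector
        if self.interaction_vectors:
            for key, v in self.interaction_vectors.items():
                yield f"interaction[{key}]", v
        if self.individual_fields is not None:
            for j, v in enumerate(self.individual_fields):
                yield f"individual[{j}]", v


def _zero_mean(v: np.ndarray) -> np.ndarray:
    return v - v.mean(axis=0)


def smooth_field(
    config: np.ndarray,
    rng: np.random.Generator,
    norm: float,
    pairing: list[tuple[int, int]] | None = None,
    n_centers: int = 5,
) -> np.ndarray:
    """A smooth, zero-mean deformation field of given Frobenius norm.

    Built from a few Gaussian radial bumps with random centres and
    directions; when a pairing is given the field is symmetrized by
    averaging with its mirror image, so it respects object symmetry.
    """
    k, d = config.shape
    if norm == 0.0:
        return np.zeros((k, d))
    scale = np.sqrt(((config - config.mean(0)) ** 2).sum() / k)
    centers = config[rng.integers(0, k, size=n_centers)]
    centers = centers + rng.normal(0, 0.2 * scale, centers.shape)
    width = 0.8 * scale
    f = np.zeros((k, d))
    for c in centers:
        w = np.exp(-((config - c) ** 2).sum(1) / (2 * width**2))
        f += np.outer(w, rng.normal(size=d))
    if pairing and d == 3:
        mirror = f * np.array([-1.0, 1.0, 1.0])
        g = f.copy()
        for a, b in pairing:
            g[a] = 0.5 * (f[a] + mirror[b])
            g[b] = 0.5 * (f[b] + mirror[a])
        rest = set(range(k)) - {i for p in pairing for i in p}
        for i in rest:
            g[i] = 0.5 * (f[i] + mirror[i])
        f = g
    f = _zero_mean(f)
    fn = np.sqrt((f**2).sum())
    return f * (norm / fn) if fn > 0 else f


def default_effects(
    config: np.ndarray,
    seed: int = 0,
    pairing: list[tuple[int, int]] | None = None,
    temperature_norm: float = 0.05,
    population_norm: float = 0.03,
    allometry_norm: float = 0.2,
    within_group_sd: float = 0.07,
    landmark_noise: float = 0.01,
    n_individual_fields: int = 8,
    interaction_norm: float = 0.0,
    size_means: dict[int, float] | None = None,
    populations: tuple[str, ...] = ("Paris", "Sapporo", "Dayton"),
    temperatures: tuple[int, ...] = (16, 22, 28),
    size_cv: float = 0.037,
) -> EffectSpec:
    """Study-condition defaults: small conserved thermal reaction norms.

    Effect magnitudes are Frobenius norms in shape units.  The defaults
    give group-mean separations of ~0.05 (so reaction-norm path lengths
    near 0.1), within-group shape scatter of ~0.04, sizes decreasing
    with developmental temperature around 500 µm with a ~3.7% CV, and a
    shared allometric vector; the middle temperature and the second
    population are the reference (zero) levels.

    Within-group individual variation is low-rank and smooth (a few
    random smooth deformation fields with decaying standard deviations
    totalling ``within_group_sd``), as biological shape variation is,
    plus a small isotropic landmark-noise floor (``landmark_noise``,
    Frobenius norm).  This matters for any statistic standardized by the
    within-group covariance: effects compete with smooth individual
    variation in the same few directions, not with the vanishingly small
    per-direction noise an isotropic model would imply.
    """
    rng = np.random.default_rng(seed)
    k, d = config.shape
    temp_vecs = {}
    for i, t in enumerate(temperatures):
        is_ref = i == len(temperatures) // 2
        temp_vecs[t] = (
            np.zeros((k, d)) if is_ref
            else smooth_field(config, rng, temperature_norm, pairing)
        )
    pop_vecs = {}
    for i, p in enumerate(populations):
        is_ref = i == 1
        pop_vecs[p] = (
            np.zeros((k, d)) if is_ref
            else smooth_field(config, rng, population_norm, pairing)
        )
    allo = smooth_field(config, rng, allometry_norm, pairing)
    inter = None
    if interaction_norm > 0:
        inter = {
            (p, t): smooth_field(config, rng, interaction_norm, pairing)
            for p in populations for t in temperatures
        }
        inter = {key: _zero_mean(v) for key, v in inter.items()}
    if size_means is None:
        size_means = {16: 522.0, 22: 500.0, 28: 478.0}
        size_means = {t: size_means.get(t, 500.0) for t in temperatures}
    sizes = {}
    for p in populations:
        bump = 1.05 if p == "Dayton" else 1.0
        for t in temperatures:
            sizes[(p, t)] = size_means[t] * bump
    fields = np.stack([
        smooth_field(config, rng, 1.0, pairing) for _ in range(n_individual_fields)
    ]) if n_individual_fields else None
    decay = 0.8 ** np.arange(n_individual_fields)
    sds = within_group_sd * decay / np.sqrt((decay**2).sum()) \
        if n_individual_fields else None
    noise_sd = landmark_noise / np.sqrt(k * d)
    # replicate-measurement noise sized so that a 5-replicate repeatability
    # study sees individual variation ~4x the reconstruction variation
    within_total = np.sqrt(within_group_sd**2 + landmark_noise**2)
    return EffectSpec(
        population_vectors=pop_vecs,
        temperature_vectors=temp_vecs,
        allometry_vector=allo,
        interaction_vectors=inter,
        individual_fields=fields,
        individual_sds=sds,
        noise_sd=noise_sd,
        size_means=sizes,
        size_cv=size_cv,
        measurement_error_sd=1.3 * within_total / np.sqrt(k * d),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


@dataclass
class TruthRecord:
    """Per-specimen ground truth, reproducible from the seed."""

    group_means: dict[tuple[str, int], np.ndarray]
    table: pd.DataFrame  # specimen id -> population, temperature, true size
    seed: int


def _random_rotation(rng: np.random.Generator, d: int) -> np.ndarray:
    """Uniform (Haar) random proper rotation."""
    a = rng.normal(size=(d, d))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def simulate_sample(
    effects: EffectSpec,
    design: FactorDesign | None = None,
    base: np.ndarray | Template | None = None,
    id_prefix: str = "spec",
    structure: str = "ovipositor",
    rigid_motion: bool = True,
) -> tuple[LandmarkSample, TruthRecord]:
    """Draw a sample of specimens under the factorial design.

    Each specimen's true shape is base + population + temperature
    (+ optional interaction) + allometry * (log size - mean log size)
    + iid Gaussian landmark noise, on the unit-centroid-size scale; it is
    then scaled to its drawn size and given a uniform random rotation
    and translation, so superimposition is genuinely exercised.
    Deterministic given ``effects.seed``.
    """
    if design is None:
        design = FactorDesign()
    if base is None:
        base = make_base_shape()
    if isinstance(base, Template):
        template = base
        base_config = template.config
        pairing, midline = template.pairing, template.midline
        roles = template.roles
    else:
        base_config = np.asarray(base, dtype=float)
        pairing, midline, roles = [], [], []
    centred = base_config - base_config.mean(0)
    cs = np.sqrt((centred**2).sum())
    base_unit = centred / cs
    k, d = base_unit.shape

    sizes_by_group = design.sizes()
    rng = np.random.default_rng(effects.seed)
    for (p, t) in sizes_by_group:
        if p not in effects.population_vectors:
            raise ValidationError(f"unknown population label {p!r}")
        if t not in effects.temperature_vectors:
            raise ValidationError(f"unknown temperature level {t!r}")
    mean_log_size = np.mean(
        [np.log(effects.size_means.get(g, 1.0)) for g in sizes_by_group]
    ) if effects.size_means else 0.0

    group_means: dict[tuple[str, int], np.ndarray] = {}
    for (p, t) in sizes_by_group:
        mean = base_unit + effects.population_vectors[p] + effects.temperature_vectors[t]
        if effects.interaction_vectors:
            mean = mean + effects.interaction_vectors.get((p, t), 0.0)
        group_means[(p, t)] = mean

    line_offsets: dict[tuple[str, int], np.ndarray] = {}
    if effects.line_effect_sd > 0:
        for p in design.populations:
            for li in range(design.lines_per_population):
                line_offsets[(p, li)] = _zero_mean(
                    rng.normal(0.0, effects.line_effect_sd, size=(k, d))
                )

    coords, ids, rows = [], [], []
    counter = 0
    for (p, t), n_g in sizes_by_group.items():
        for j in range(n_g):
            size_mean = effects.size_means.get((p, t), 1.0)
            size = size_mean * np.exp(rng.normal(0.0, effects.size_cv))
            shape = group_means[(p, t)] + effects.allometry_vector * (
                np.log(size) - mean_log_size
            )
            line = j % design.lines_per_population
            if line_offsets:
                shape = shape + line_offsets[(p, line)]
            if effects.individual_fields is not None:
                z = rng.normal(size=len(effects.individual_fields))
                shape = shape + np.tensordot(
                    z * effects.individual_sds, effects.individual_fields, axes=1
                )
            shape = shape + rng.normal(0.0, effects.noise_sd, size=(k, d))
            placed = shape * size
            if rigid_motion:
                placed = placed @ _random_rotation(rng, d)
                placed = placed + rng.normal(0.0, 2.0 * size, size=d)
            sid = f"{id_prefix}{counter:03d}"
            coords.append(placed)
            ids.append(sid)
            rows.append(
                {"specimen": sid, "population": p, "temperature": t,
                 "line": f"{p}_L{line}", "structure": structure,
                 "replicate_id": 0, "true_size": size}
            )
            counter += 1
    factors = pd.DataFrame(rows).drop(columns=["true_size"])
    truth_table = pd.DataFrame(rows).set_index("specimen")[
        ["population", "temperature", "true_size"]
    ]
    sample = LandmarkSample(
        np.stack(coords), ids, list(roles), list(pairing), list(midline), factors
    )
    return sample, TruthRecord(group_means, truth_table, effects.seed)


def simulate_replicates(
    sample: LandmarkSample,
    n_rep: int,
    measurement_error_sd: float,
    seed: int = 0,
) -> LandmarkSample:
    """Duplicate each specimen n_rep times with iid measurement noise.

    Measurement error is expressed in shape units and scaled by each
    configuration's centroid size, emulating replicate reconstruction
    plus landmarking noise.
    """
    if n_rep < 2:
        raise ValidationError("need at least 2 replicates")
    rng = np.random.default_rng(seed)
    coords, ids, rows = [], [], []
    for i, sid in enumerate(sample.specimen_ids):
        base = sample.coords[i]
        cs = np.sqrt(((base - base.mean(0)) ** 2).sum())
        meta = (
            sample.factors.loc[sid].to_dict() if sample.factors is not None else {}
        )
        for r in range(n_rep):
            noise = rng.normal(0.0, measurement_error_sd * cs, size=base.shape)
            coords.append(base + noise)
            rid = f"{sid}_r{r}"
            ids.append(rid)
            rows.append({"specimen": rid, **meta, "replicate_id": r,
                         "individual": sid})
    factors = pd.DataFrame(rows)
    return LandmarkSample(
        np.stack(coords), ids, list(sample.roles), list(sample.pairing),
        list(sample.midline), factors,
    )


def simulate_two_structures(
    effects_ovip: EffectSpec,
    effects_wing: EffectSpec,
    design: FactorDesign | None = None,
    base_ovip: Template | np.ndarray | None = None,
    base_wing: np.ndarray | None = None,
) -> tuple[LandmarkSample, LandmarkSample]:
    """Paired ovipositor-like (3D) and wing-like (2D) samples, one design.

    Both structures are phenotyped on the same specimens (shared ids and
    factor levels); by convention the wing carries larger thermal
    plasticity, which the default wing effects express as temperature
    vectors ~3x the ovipositor magnitude.
    """
    if design is None:
        design = FactorDesign()
    if base_wing is None:
        base_wing = make_wing_shape()
    ovip, _ = simulate_sample(effects_ovip, design, base_ovip, structure="ovipositor")
    wing, _ = simulate_sample(effects_wing, design, base_wing, structure="wing")
    # same specimens: share ids and factor rows apart from the structure label
    wing = LandmarkSample(
        wing.coords, list(ovip.specimen_ids), wing.roles, wing.pairing,
        wing.midline,
        ovip.factors.assign(structure="wing"),
    )
    return ovip, wing


def default_wing_effects(
    config: np.ndarray | None = None,
    seed: int = 1,
    temperature_norm: float = 0.15,
    population_norm: float = 0.03,
    within_group_sd: float = 0.07,
) -> EffectSpec:
    """Wing control defaults: ~3x the ovipositor's thermal effect."""
    if config is None:
        config = make_wing_shape()
    return default_effects(
        config, seed=seed, pairing=None,
        temperature_norm=temperature_norm,
        population_norm=population_norm,
        allometry_norm=0.2, within_group_sd=within_group_sd,
        size_means={16: 2850.0, 22: 2500.0, 28: 2175.0},
        size_cv=0.037,
    )
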