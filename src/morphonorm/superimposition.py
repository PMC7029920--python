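"""Ordinary and generalized Procrustes analysis with object symmetry.

Superimposition follows the partial-Procrustes convention: configurations
are centred, scaled to unit centroid size and rotated (never reflected)
to a consensus; size is carried separately as centroid size.  Bilateral
object symmetry is handled by reflection-relabelling: the symmetric
component of a configuration is the average of the shape and its
optimally re-superimposed mirror image, the asymmetric component the
remainder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import LandmarkSample, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class GPAResult:
    """Output of generalized Procrustes analysis.

    ``aligned`` holds unit-centroid-size shapes with centroid at the
    origin; ``centroid_sizes`` the pre-scaling sizes in the input units.
    ``symmetric``/``asymmetric`` are filled by :func:`symmetrize` and
    satisfy ``symmetric + asymmetric == aligned`` exactly.
    """

    aligned: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    symmetric: np.ndarray | None = None
    asymmetric: np.ndarray | None = None
    iterations: int = 0
    converged: bool = True
    sample: LandmarkSample | None = None

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]


def centroid_size(config: np.ndarray) -> float:
    """Centroid size: root summed squared distances of points to their centroid."""
    config = np.asarray(config, dtype=float)
    if config.ndim != 2 or config.shape[0] < 2:
        raise ValidationError("config must be (k >= 2, d)")
    centred = config - config.mean(axis=0)
    cs = float(np.sqrt((centred**2).sum()))
    if cs == 0.0:
        raise ValidationError("all points coincide; centroid size undefined")
    return cs


def _centre_scale(config: np.ndarray) -> tuple[np.ndarray, float]:
    centred = config - config.mean(axis=0)
    cs = np.sqrt((centred**2).sum())
    if cs == 0.0:
        raise ValidationError("degenerate configuration (zero centroid size)")
    return centred / cs, float(cs)


def optimal_rotation(
    moving: np.ndarray, target: np.ndarray, allow_reflection: bool = False
) -> np.ndarray:
    """Least-squares orthogonal map: R minimizing ``||moving @ R - target||``.

    Both configurations must already be centred.  By default the result
    is a proper rotation (det +1); reflections are resolved away, with a
    log note when the unconstrained optimum would have been improper.
    """
    moving = np.asarray(moving, dtype=float)
    target = np.asarray(target, dtype=float)
    if moving.shape != target.shape:
        raise ValidationError("shape mismatch in optimal_rotation")
    m = moving.T @ target
    u, s, vt = np.linalg.svd(m)
    r = u @ vt
    if not allow_reflection and np.linalg.det(r) < 0:
        if s[-1] > 1e-12 * s[0]:
            logger.debug("unconstrained optimum is a reflection; forcing det=+1")
        d = np.ones(len(s))
        d[-1] = -1.0
        r = (u * d) @ vt
    return r


def procrustes_distance(a: np.ndarray, b: np.ndarray, align: bool = True) -> float:
    """Partial Procrustes distance between two configurations.

    With ``align=True`` (default) the shapes are centred, scaled to unit
    centroid size and optimally rotated before taking the root summed
    squared coordinate difference; with ``align=False`` they are assumed
    to live in a common superimposition frame already.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("mismatched configurations")
    if align:
        a, _ = _centre_scale(a)
        b, _ = _centre_scale(b)
        b = b @ optimal_rotation(b, a)
    return float(np.sqrt(((a - b) ** 2).sum()))


def gpa(
    sample: LandmarkSample | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> GPAResult:
    """Generalized Procrustes analysis (partial Procrustes).

    Iteratively centres, scales to unit centroid size and rotates every
    configuration to the running consensus until the relative consensus
    change falls below ``tol``.
    """
    if isinstance(sample, LandmarkSample):
        coords = sample.coords
        src = sample
    else:
        coords = np.asarray(sample, dtype=float)
        src = None
    if coords.ndim != 3 or coords.shape[0] < 2:
        raise ValidationError("need an (n >= 2, k, d) coordinate array")
    n = coords.shape[0]

    aligned = np.empty_like(coords, dtype=float)
    sizes = np.empty(n)
    for i in range(n):
        aligned[i], sizes[i] = _centre_scale(coords[i])

    consensus = aligned[0].copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(n):
            aligned[i] = aligned[i] @ optimal_rotation(aligned[i], consensus)
        new_consensus, _ = _centre_scale(aligned.mean(axis=0))
        change = np.sqrt(((new_consensus - consensus) ** 2).sum())
        consensus = new_consensus
        if change < tol:
            converged = True
            break
    if not converged:
        logger.warning("GPA did not converge in %d iterations", max_iter)
    # final pass so every shape is aligned to the reported consensus
    for i in range(n):
        aligned[i] = aligned[i] @ optimal_rotation(aligned[i], consensus)
    consensus = aligned.mean(axis=0)
    return GPAResult(aligned, consensus, sizes, iterations=it,
                     converged=converged, sample=src)


def _reflect_relabel(
    config: np.ndarray, pairing: list[tuple[int, int]]
) -> np.ndarray:
    """Mirror a configuration and swap paired points (midline points stay)."""
    reflect = np.ones(config.shape[1])
    reflect[0] = -1.0  # the mirror plane is arbitrary: re-superimposition follows
    out = config * reflect
    for left, right in pairing:
        out[[left, right]] = out[[right, left]]
    return out


def symmetrize(
    result: GPAResult,
    pairing: list[tuple[int, int]] | None = None,
    midline: list[int] | None = None,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> GPAResult:
    """Decompose aligned shapes into symmetric and asymmetric components.

    For each specimen the configuration is mirrored, paired points are
    relabelled, and the mirror image is rotated back onto the original;
    the symmetric component is the fixed point of averaging the shape
    with its re-superimposed mirror image (iterated to ``tol``, so
    symmetrizing is idempotent), the asymmetric component the remainder.
    """
    if pairing is None:
        if result.sample is None or not result.sample.pairing:
            raise ValidationError("no symmetry pairing available")
        pairing = result.sample.pairing
        midline = result.sample.midline
    k = result.aligned.shape[1]
    touched = {i for pair in pairing for i in pair} | set(midline or [])
    if touched != set(range(k)):
        raise ValidationError("pairing + midline must cover all points")

    sym = np.empty_like(result.aligned)
    for i, shape in enumerate(result.aligned):
        s = shape.copy()
        for _ in range(max_iter):
            mirrored = _reflect_relabel(s, pairing)
            mirrored = mirrored @ optimal_rotation(mirrored, s)
            new = 0.5 * (s + mirrored)
            if np.sqrt(((new - s) ** 2).sum()) < tol:
                s = new
                break
            s = new
        sym[i] = s
    asym = result.aligned - sym
    return GPAResult(
        result.aligned, result.consensus, result.centroid_sizes,
        symmetric=sym, asymmetric=asym,
        iterations=result.iterations, converged=result.converged,
        sample=result.sample,
    )


def tangent_coordinates(result: GPAResult, use_symmetric: bool = True) -> np.ndarray:
    """Flattened shape coordinates projected into the tangent space.

    Shapes are orthogonally projected onto the tangent plane to the unit
    sphere at the consensus, the standard linearization before fitting
    linear models in shape space.  Returns an (n, k*d) matrix.
    """
    shapes = result.symmetric if (use_symmetric and result.symmetric is not None) \
        else result.aligned
    n = shapes.shape[0]
    x = shapes.reshape(n, -1)
    c = result.consensus.reshape(-1)
    c = c / np.linalg.norm(c)
    return x - np.outer(x @ c - 1.0, c)
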