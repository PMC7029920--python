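"""Permutation-based statistics for superimposed shape data.

Implements the analysis battery for factorial shape studies: between-group
PCA, the permutation test on pairwise Procrustes distances among group
means, multivariate Procrustes ANOVA with residual-randomization
permutation (RRPP) and log-F effect sizes, phenotypic trajectory analysis
of reaction norms (path length, direction, trajectory shape), allometric
regression on log centroid size with a slope-homogeneity test, the
modified signed-likelihood-ratio test for equality of coefficients of
variation, canonical-variate (Mahalanobis) distances on a fixed number of
principal components, and a permutation comparison of thermal plasticity
between two structures.

All permutation p-values follow the (1 + count) / (1 + n_perm)
convention and are reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import cdist, pdist, squareform

from .io import LandmarkSample, ValidationError
from .superimposition import GPAResult


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def as_shape_matrix(y) -> np.ndarray:
    """Coerce a GPAResult / (n,k,d) array / (n,p) matrix to (n,p)."""
    if isinstance(y, GPAResult):
        from .superimposition import tangent_coordinates

        return tangent_coordinates(y)
    y = np.asarray(y, dtype=float)
    if y.ndim == 3:
        return y.reshape(y.shape[0], -1)
    if y.ndim != 2:
        raise ValidationError("expected (n, p) or (n, k, d) data")
    return y


def _reduce(y: np.ndarray) -> np.ndarray:
    """Rotate the variable space to at most n dimensions.

    Right-multiplication by an orthonormal basis of the row space keeps
    all inter-row Euclidean geometry and every sum of squares used here,
    while making permutation loops cheap when p >> n.
    """
    n, p = y.shape
    if p <= n:
        return y
    mu = y.mean(axis=0)
    yc = y - mu
    _, s, vt = np.linalg.svd(yc, full_matrices=False)
    rank = max(int((s > s[0] * 1e-12).sum()), 1)
    return yc @ vt[:rank].T


def _perm_p(obs: float, null: np.ndarray) -> float:
    return float((1 + (null >= obs - 1e-12).sum()) / (1 + len(null)))


def _effect_size(obs: float, dist: np.ndarray, log: bool = False) -> float:
    """Standardized position of the observed statistic in its permutation
    distribution (which includes the observed value)."""
    d = np.asarray(dist, dtype=float)
    o = obs
    if log:
        d = np.log(np.maximum(d, 1e-300))
        o = np.log(max(obs, 1e-300))
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0
    return float((o - d.mean()) / sd)


def _orth_basis(x: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing)."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if len(s) else 0
    return u[:, :rank]


def _dummy(values: np.ndarray) -> tuple[np.ndarray, list]:
    levels = sorted(pd.unique(values), key=str)
    cols = np.column_stack([(values == lev).astype(float) for lev in levels[1:]]) \
        if len(levels) > 1 else np.zeros((len(values), 0))
    return cols, levels


def _term_columns(factors: pd.DataFrame, term: str) -> np.ndarray:
    parts = term.split(":")
    blocks = []
    for part in parts:
        v = factors[part].to_numpy()
        if np.issubdtype(np.asarray(v).dtype, np.number) and len(pd.unique(v)) > 8:
            blocks.append((np.asarray(v, dtype=float) - np.mean(v))[:, None])
        else:
            blocks.append(_dummy(v)[0])
    cols = blocks[0]
    for b in blocks[1:]:
        cols = np.einsum("ni,nj->nij", cols, b).reshape(len(cols), -1)
    return cols


def expand_terms(formula: str | list[str]) -> list[str]:
    """Expand 'a*b' into ['a', 'b', 'a:b']; pass lists through."""
    if isinstance(formula, list):
        return formula
    terms: list[str] = []
    for piece in formula.replace(" ", "").split("+"):
        if "*" in piece:
            a, b = piece.split("*", 1)
            for t in (a, b, f"{a}:{b}"):
                if t not in terms:
                    terms.append(t)
        elif piece and piece not in terms:
            terms.append(piece)
    return terms


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class AnovaTable:
    """Sequential (type-I) multivariate ANOVA table with RRPP inference."""

    terms: list[str]
    ss: dict[str, float]
    df: dict[str, int]
    f: dict[str, float]
    z: dict[str, float]
    p: dict[str, float]
    ss_residual: float
    df_residual: int
    ss_total: float
    n_perm: int

    def ms(self, term: str) -> float:
        return self.ss[term] / self.df[term]

    @property
    def ms_residual(self) -> float:
        return self.ss_residual / self.df_residual if self.df_residual else np.nan

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"term": t, "df": self.df[t], "SS": self.ss[t], "MS": self.ms(t),
             "F": self.f[t], "Z": self.z[t], "p": self.p[t]}
            for t in self.terms
        ]
        rows.append({"term": "residual", "df": self.df_residual,
                     "SS": self.ss_residual, "MS": self.ms_residual,
                     "F": np.nan, "Z": np.nan, "p": np.nan})
        rows.append({"term": "total", "df": self.df_residual + sum(self.df.values()),
                     "SS": self.ss_total, "MS": np.nan, "F": np.nan,
                     "Z": np.nan, "p": np.nan})
        return pd.DataFrame(rows)


@dataclass
class BgPCAResult:
    axes: np.ndarray            # (p, n_axes) eigenvectors of group-mean covariance
    scores: np.ndarray          # (n, n_axes) individual projections
    group_labels: list
    group_mean_scores: np.ndarray
    explained_variance: np.ndarray


@dataclass
class GroupMeanPermTest:
    labels: list
    distances: np.ndarray
    p_values: np.ndarray
    n_perm: int


@dataclass
class TrajectoryResult:
    populations: list
    path_lengths: dict
    pairwise: pd.DataFrame      # stat in {path_length_diff, angle, shape_distance}
    n_perm: int


@dataclass
class CVResult:
    cvs: dict
    statistic: float
    df: int
    p: float


@dataclass
class AllometryResult:
    anova: AnovaTable
    slope: np.ndarray
    homogeneity: AnovaTable | None = None


@dataclass
class RepeatabilityResult:
    ms_individual: float
    ms_residual: float
    ratio: float
    p: float
    infinite: bool
    table: AnovaTable


@dataclass
class PlasticityComparison:
    structures: tuple[str, str]
    mahalanobis: dict           # structure -> {(t1, t2): distance}
    n_pcs: int
    mean_distance: dict         # structure -> mean among-temperature distance
    observed: float
    p: float
    n_perm: int
    per_pair_p: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# between-group PCA and the group-mean permutation test
# ---------------------------------------------------------------------------


def _group_means(y: np.ndarray, groups: np.ndarray):
    labels = sorted(pd.unique(groups), key=str)
    idx = {lab: np.flatnonzero(groups == lab) for lab in labels}
    for lab, ii in idx.items():
        if len(ii) == 0:
            raise ValidationError(f"group {lab!r} has no members")
    means = np.stack([y[idx[lab]].mean(axis=0) for lab in labels])
    return labels, means, idx


def bgpca(y, groups) -> BgPCAResult:
    """Between-group PCA: project individuals onto the principal axes of
    the (unweighted) covariance of group means."""
    y = as_shape_matrix(y)
    groups = np.asarray(groups)
    labels, means, _ = _group_means(y, groups)
    if len(labels) < 2:
        raise ValidationError("need at least 2 groups")
    grand = means.mean(axis=0)
    mc = means - grand
    u, s, vt = np.linalg.svd(mc, full_matrices=False)
    n_axes = min(len(labels) - 1, (s > s[0] * 1e-12).sum() if s.size else 0)
    axes = vt[:n_axes].T
    scores = (y - grand) @ axes
    return BgPCAResult(
        axes=axes,
        scores=scores,
        group_labels=labels,
        group_mean_scores=mc @ axes,
        explained_variance=(s[:n_axes] ** 2) / max(len(labels) - 1, 1),
    )


def perm_test_group_means(
    y, groups, n_perm: int = 10000, seed: int = 0
) -> GroupMeanPermTest:
    """Permutation test on pairwise Procrustes distances among group means.

    Individuals are shuffled across all groups jointly; each pair's p is
    the proportion of permuted distances at least as extreme.  Because
    every permutation re-labels the whole sample at once, the pairwise
    tests share one null and need no multiplicity correction.
    """
    if n_perm < 100:
        import logging

        logging.getLogger(__name__).warning("n_perm=%d is very small", n_perm)
    y = _reduce(as_shape_matrix(y))
    groups = np.asarray(groups)
    labels, means, idx = _group_means(y, groups)
    g = len(labels)
    if g < 2:
        raise ValidationError("need at least 2 groups")
    weights = np.zeros((g, len(y)))
    for a, lab in enumerate(labels):
        weights[a, idx[lab]] = 1.0 / len(idx[lab])
    obs = squareform(pdist(weights @ y))
    rng = np.random.default_rng(seed)
    count = np.zeros((g, g))
    for _ in range(n_perm):
        perm = rng.permutation(len(y))
        d = squareform(pdist(weights @ y[perm]))
        count += d >= obs - 1e-12
    p = (1.0 + count) / (1.0 + n_perm)
    np.fill_diagonal(p, 1.0)
    return GroupMeanPermTest(labels, obs, p, n_perm)


# ---------------------------------------------------------------------------
# RRPP Procrustes ANOVA
# ---------------------------------------------------------------------------


def _nested_bases(factors: pd.DataFrame, terms: list[str]):
    n = len(factors)
    x = np.ones((n, 1))
    bases = [_orth_basis(x)]
    dfs = []
    for term in terms:
        cols = _term_columns(factors, term)
        x = np.hstack([x, cols])
        q = _orth_basis(x)
        df_t = q.shape[1] - bases[-1].shape[1]
        if df_t == 0:
            raise ValidationError(f"term {term!r} is aliased with earlier terms")
        dfs.append(df_t)
        bases.append(q)
    return bases, dfs


def procrustes_anova_rrpp(
    y,
    factors: pd.DataFrame | dict,
    terms: str | list[str],
    n_perm: int = 999,
    seed: int = 0,
) -> AnovaTable:
    """Sequential multivariate ANOVA on shape data with RRPP inference.

    Sums of squares are type-I from multivariate least squares on the
    flattened shape matrix.  For each term the null distribution of its
    F statistic comes from randomizing the residuals of the reduced
    model (the model with all preceding terms); the effect size Z is the
    standardized position of log F in that distribution.
    """
    y = _reduce(as_shape_matrix(y))
    if isinstance(factors, dict):
        factors = pd.DataFrame(factors)
    terms = expand_terms(terms)
    n = len(y)
    if len(factors) != n:
        raise ValidationError("factor table does not match sample size")
    bases, dfs = _nested_bases(factors, terms)
    ss_total = float(((y - y.mean(0)) ** 2).sum())

    def rss(mat: np.ndarray, q: np.ndarray) -> float:
        return float((mat**2).sum() - ((q.T @ mat) ** 2).sum())

    q_full = bases[-1]
    df_res = n - q_full.shape[1]
    if df_res <= 0:
        raise ValidationError("no residual degrees of freedom")
    rng = np.random.default_rng(seed)
    perms = [np.arange(n)] + [rng.permutation(n) for _ in range(n_perm)]

    ss_obs, f_all, z_all, p_all = {}, {}, {}, {}
    for i, term in enumerate(terms):
        q_red, q_fit = bases[i], bases[i + 1]
        fitted_red = q_red @ (q_red.T @ y)
        resid_red = y - fitted_red
        f_dist = np.empty(len(perms))
        for j, perm in enumerate(perms):
            yp = fitted_red + resid_red[perm]
            ss_t = rss(yp, q_red) - rss(yp, q_fit)
            ss_e = rss(yp, q_full)
            f_dist[j] = (ss_t / dfs[i]) / max(ss_e / df_res, 1e-300)
            if j == 0:
                ss_obs[term] = ss_t
        f_all[term] = f_dist[0]
        z_all[term] = _effect_size(f_dist[0], f_dist, log=True)
        p_all[term] = _perm_p(f_dist[0], f_dist[1:])
    ss_res = rss(y, q_full)
    return AnovaTable(
        terms=terms, ss=ss_obs, df=dict(zip(terms, dfs)), f=f_all,
        z=z_all, p=p_all, ss_residual=ss_res, df_residual=df_res,
        ss_total=ss_total, n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# trajectory analysis
# ---------------------------------------------------------------------------


def _trajectory_attributes(means: np.ndarray):
    """Path length, oriented first principal direction, and the
    centred/scaled trajectory configuration for one (levels x p) matrix."""
    steps = np.diff(means, axis=0)
    path_length = float(np.sqrt((steps**2).sum(axis=1)).sum())
    mc = means - means.mean(axis=0)
    _, _, vt = np.linalg.svd(mc, full_matrices=False)
    direction = vt[0]
    span = means[-1] - means[0]
    if direction @ span < 0:
        direction = -direction
    size = np.sqrt((mc**2).sum())
    traj_shape = mc / size if size > 0 else mc
    return path_length, direction, traj_shape


def _trajectory_pair_stats(attrs_a, attrs_b):
    pl_a, dir_a, shp_a = attrs_a
    pl_b, dir_b, shp_b = attrs_b
    dl = abs(pl_a - pl_b)
    cosang = float(np.clip(dir_a @ dir_b, -1.0, 1.0))
    angle = float(np.degrees(np.arccos(cosang)))
    # orthogonal Procrustes between the two trajectory configurations
    u, _, vt = np.linalg.svd(shp_b.T @ shp_a)
    rot = u @ vt
    shape_dist = float(np.sqrt(((shp_a - shp_b @ rot) ** 2).sum()))
    return dl, angle, shape_dist


def trajectory_analysis(
    y,
    group_factor,
    level_factor,
    level_order: list | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> TrajectoryResult:
    """Phenotypic trajectory analysis of reaction norms.

    Each group's trajectory is its sequence of cell means across the
    ordered levels (here developmental temperatures).  Pairwise groups
    are compared on path length (amount of shape change), angle between
    oriented first principal directions in [0, 180] degrees (pattern),
    and Procrustes distance between size-standardized trajectory shapes.
    Inference is by RRPP under the additive reduced model
    group + level.
    """
    y = _reduce(as_shape_matrix(y))
    groups = np.asarray(group_factor)
    levels = np.asarray(level_factor)
    if level_order is None:
        level_order = sorted(pd.unique(levels))
    pops = sorted(pd.unique(groups), key=str)
    cells = {}
    for p in pops:
        for lev in level_order:
            ii = np.flatnonzero((groups == p) & (levels == lev))
            if len(ii) == 0:
                raise ValidationError(f"empty design cell ({p}, {lev})")
            cells[(p, lev)] = ii

    def cell_means(mat):
        return {
            p: np.stack([mat[cells[(p, lev)]].mean(axis=0) for lev in level_order])
            for p in pops
        }

    def all_attrs(mat):
        means = cell_means(mat)
        return {p: _trajectory_attributes(means[p]) for p in pops}

    obs_attrs = all_attrs(y)
    path_lengths = {p: obs_attrs[p][0] for p in pops}
    pairs = [(a, b) for i, a in enumerate(pops) for b in pops[i + 1:]]
    obs_stats = {pr: _trajectory_pair_stats(obs_attrs[pr[0]], obs_attrs[pr[1]])
                 for pr in pairs}

    # RRPP under the additive model (group + level): interaction signal
    # lives in the residuals being permuted
    factors = pd.DataFrame({"g": groups.astype(str), "l": levels.astype(str)})
    bases, _ = _nested_bases(factors, ["g", "l"])
    q_red = bases[-1]
    fitted = q_red @ (q_red.T @ y)
    resid = y - fitted
    rng = np.random.default_rng(seed)
    null = {pr: np.empty((n_perm, 3)) for pr in pairs}
    for j in range(n_perm):
        yp = fitted + resid[rng.permutation(len(y))]
        attrs = all_attrs(yp)
        for pr in pairs:
            null[pr][j] = _trajectory_pair_stats(attrs[pr[0]], attrs[pr[1]])

    rows = []
    stat_names = ["path_length_diff", "angle", "shape_distance"]
    for pr in pairs:
        for s_i, name in enumerate(stat_names):
            obs = obs_stats[pr][s_i]
            dist = null[pr][:, s_i]
            full = np.concatenate([[obs], dist])
            rows.append({
                "group_a": pr[0], "group_b": pr[1], "stat": name,
                "value": obs,
                "Z": _effect_size(obs, full),
                "p": _perm_p(obs, dist),
            })
    return TrajectoryResult(pops, path_lengths, pd.DataFrame(rows), n_perm)


# ---------------------------------------------------------------------------
# allometry
# ---------------------------------------------------------------------------


def allometry_fit(
    y,
    log_cs: np.ndarray,
    groups: np.ndarray | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> AllometryResult:
    """Multivariate regression of shape on log centroid size.

    Returns the RRPP ANOVA for the size term, the common allometric
    slope vector (shape change per unit log size), and, when groups are
    supplied, a slope-homogeneity test: the significance of the
    size-by-group interaction after size and group main effects.
    """
    ymat = as_shape_matrix(y)
    log_cs = np.asarray(log_cs, dtype=float)
    if np.ptp(log_cs) == 0:
        raise ValidationError("zero size variance; allometry undefined")
    factors = pd.DataFrame({"log_cs": log_cs})
    anova = procrustes_anova_rrpp(ymat, factors, ["log_cs"], n_perm, seed)
    xc = log_cs - log_cs.mean()
    slope = (xc @ (ymat - ymat.mean(0))) / (xc @ xc)
    homogeneity = None
    if groups is not None:
        factors2 = pd.DataFrame({"log_cs": log_cs, "group": np.asarray(groups).astype(str)})
        homogeneity = procrustes_anova_rrpp(
            ymat, factors2, ["log_cs", "group", "log_cs:group"], n_perm, seed + 1
        )
    return AllometryResult(anova, slope, homogeneity)


# ---------------------------------------------------------------------------
# coefficients of variation
# ---------------------------------------------------------------------------


def _mslrt_statistic(n: np.ndarray, xbar: np.ndarray, s2: np.ndarray) -> float:
    """Modified signed-likelihood-ratio statistic for equality of CVs.

    Small-sample modification in the Krishnamoorthy & Lee spirit: the
    variance weights use n_i - 1 and the unbiased variances, with the
    common-CV maximum found by alternating the stationarity equations
    for the group means and the common CV.
    """
    m = n - 1.0
    tau2 = float(np.sum(m * s2 / xbar**2) / m.sum())  # start from plug-in CV
    mu = xbar.copy()
    for _ in range(200):
        a = m * s2 + n * xbar**2
        mu_new = (-n * xbar + np.sqrt((n * xbar) ** 2 + 4.0 * m * tau2 * a)) / (
            2.0 * m * tau2
        )
        resid = m * s2 + n * (xbar - mu_new) ** 2
        tau2_new = float(np.sum(resid / mu_new**2) / m.sum())
        if np.abs(mu_new - mu).max() < 1e-12 * np.abs(xbar).max() and abs(
            tau2_new - tau2
        ) < 1e-15:
            mu, tau2 = mu_new, tau2_new
            break
        mu, tau2 = mu_new, tau2_new
    stat = float(np.sum(m * np.log(tau2 * mu**2 / s2)))
    return max(stat, 0.0)


def cv_compare(values_by_group: dict) -> CVResult:
    """Coefficients of variation per group and the test of their equality.

    CV = 100 * sd / mean (%).  Equality across groups is tested with the
    modified signed-likelihood-ratio test, asymptotically chi-square
    with (groups - 1) degrees of freedom.
    """
    labels = list(values_by_group)
    if len(labels) < 2:
        raise ValidationError("need at least 2 groups")
    n, xbar, s2, cvs = [], [], [], {}
    for lab in labels:
        v = np.asarray(values_by_group[lab], dtype=float)
        if len(v) < 2:
            raise ValidationError(f"group {lab!r} needs at least 2 values")
        mean = v.mean()
        if abs(mean) < 1e-12 * max(v.std(), 1e-300):
            raise ValidationError(f"group {lab!r} mean ~ 0; CV undefined")
        n.append(len(v))
        xbar.append(mean)
        s2.append(v.var(ddof=1))
        cvs[lab] = 100.0 * np.sqrt(s2[-1]) / abs(mean)
    stat = _mslrt_statistic(np.array(n, float), np.array(xbar), np.array(s2))
    df = len(labels) - 1
    p = float(sps.chi2.sf(stat, df))
    return CVResult(cvs, stat, df, p)


# ---------------------------------------------------------------------------
# CVA / Mahalanobis and the plasticity comparison
# ---------------------------------------------------------------------------


def pca_scores(y, n_pcs: int | None = None) -> np.ndarray:
    """Principal-component scores of the (flattened) shape data."""
    y = as_shape_matrix(y)
    yc = y - y.mean(axis=0)
    u, s, _ = np.linalg.svd(yc, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if n_pcs is None:
        n_pcs = rank
    if n_pcs > rank:
        raise ValidationError(f"only {rank} PCs available, requested {n_pcs}")
    return u[:, :n_pcs] * s[:n_pcs]


def _pooled_within_cov(scores: np.ndarray, groups: np.ndarray):
    labels, means, idx = _group_means(scores, groups)
    n, g = len(scores), len(labels)
    if n - g <= scores.shape[1]:
        raise ValidationError(
            f"pooled covariance singular: n - groups = {n - g} <= {scores.shape[1]} "
            "variables; use fewer PCs"
        )
    w = np.zeros((scores.shape[1], scores.shape[1]))
    for a, lab in enumerate(labels):
        dev = scores[idx[lab]] - means[a]
        w += dev.T @ dev
    return labels, means, idx, w / (n - g)


def cva_mahalanobis(scores, groups, n_pcs: int | None = None):
    """Pairwise Mahalanobis distances between group means.

    Distances are computed in the metric of the pooled within-group
    covariance on the first ``n_pcs`` principal-component scores (pass
    raw scores and a count, or pre-truncated scores).
    Returns (labels, distance matrix).
    """
    scores = as_shape_matrix(scores)
    if n_pcs is not None:
        if n_pcs > scores.shape[1]:
            raise ValidationError("n_pcs exceeds available components")
        scores = scores[:, :n_pcs]
    groups = np.asarray(groups)
    labels, means, _, w = _pooled_within_cov(scores, groups)
    try:
        w_inv = np.linalg.inv(w)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("singular pooled covariance; use fewer PCs") from exc
    g = len(labels)
    d = np.zeros((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            diff = means[i] - means[j]
            d[i, j] = d[j, i] = np.sqrt(diff @ w_inv @ diff)
    return labels, d


def _whitened(scores: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Sphere the scores by the pooled within-group covariance, so
    Euclidean distances become Mahalanobis distances."""
    _, _, _, w = _pooled_within_cov(scores, groups)
    chol = np.linalg.cholesky(w)
    return np.linalg.solve(chol, scores.T).T


def plasticity_permutation_test(
    scores_a,
    groups_a,
    scores_b,
    groups_b,
    n_perm: int = 1000,
    seed: int = 0,
    n_pcs: int | None = None,
    metric: str = "mahalanobis",
    names: tuple[str, str] = ("ovipositor", "wing"),
) -> PlasticityComparison:
    """Permutation comparison of thermal plasticity between two structures.

    For each structure independently, every individual-to-individual
    distance across each pair of temperature groups is computed (in the
    Mahalanobis-sphered space of the first ``n_pcs`` PCs by default,
    Euclidean PC space with ``metric='euclidean'``).  The observed
    statistic is the difference between the two structures' mean
    among-temperature distances; its null comes from randomly
    re-assigning the pooled distances to two groups of the original
    sizes.  Two-sided p with the +1 convention.
    """
    scores_a = as_shape_matrix(scores_a)
    scores_b = as_shape_matrix(scores_b)
    groups_a = np.asarray(groups_a)
    groups_b = np.asarray(groups_b)
    if len(scores_a) != len(scores_b):
        raise ValidationError("structures must be phenotyped on the same specimens")
    full_a = pca_scores(scores_a)
    full_b = pca_scores(scores_b)
    max_valid = min(
        full_a.shape[1], full_b.shape[1],
        len(scores_a) - len(np.unique(groups_a)) - 1,
        len(scores_b) - len(np.unique(groups_b)) - 1,
    )
    if n_pcs is None:
        n_pcs = max_valid
    elif n_pcs > max_valid:
        raise ValidationError(
            f"n_pcs={n_pcs} exceeds the largest count valid for both "
            f"structures ({max_valid})"
        )
    sa = full_a[:, :n_pcs]
    sb = full_b[:, :n_pcs]

    maha = {}
    for name, s, g in ((names[0], sa, groups_a), (names[1], sb, groups_b)):
        labels, dmat = cva_mahalanobis(s, g)
        maha[name] = {
            (labels[i], labels[j]): float(dmat[i, j])
            for i in range(len(labels)) for j in range(i + 1, len(labels))
        }

    def among_temp_distances(s, g):
        if metric == "mahalanobis":
            s = _whitened(s, g)
        elif metric != "euclidean":
            raise ValidationError(f"unknown metric {metric!r}")
        labels = sorted(pd.unique(g))
        out = []
        for i, la in enumerate(labels):
            for lb in labels[i + 1:]:
                out.append(cdist(s[g == la], s[g == lb]).ravel())
        return np.concatenate(out)

    da = among_temp_distances(sa, groups_a)
    db = among_temp_distances(sb, groups_b)
    observed = float(da.mean() - db.mean())
    pooled = np.concatenate([da, db])
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for j in range(n_perm):
        perm = rng.permutation(len(pooled))
        null[j] = pooled[perm[: len(da)]].mean() - pooled[perm[len(da):]].mean()
    p = float((1 + (np.abs(null) >= abs(observed) - 1e-12).sum()) / (1 + n_perm))
    return PlasticityComparison(
        structures=names,
        mahalanobis=maha,
        n_pcs=n_pcs,
        mean_distance={names[0]: float(da.mean()), names[1]: float(db.mean())},
        observed=observed,
        p=p,
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# repeatability
# ---------------------------------------------------------------------------


def repeatability_anova(
    sample_or_y,
    individuals: np.ndarray | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> RepeatabilityResult:
    """Procrustes ANOVA of replicated configurations: individual vs residual.

    Accepts a replicated LandmarkSample (with an ``individual`` factor
    column; GPA is run internally) or a pre-aligned shape matrix plus
    individual labels.  Returns MS_individual / MS_residual and the
    RRPP p for the individual effect; a ~zero residual MS is flagged as
    an infinite ratio rather than reported as a number.
    """
    if isinstance(sample_or_y, LandmarkSample):
        from .superimposition import gpa, tangent_coordinates

        sample = sample_or_y
        if sample.factors is None or "individual" not in sample.factors.columns:
            raise ValidationError("replicated sample needs an 'individual' factor")
        individuals = sample.factors["individual"].to_numpy()
        y = tangent_coordinates(gpa(sample), use_symmetric=False)
    else:
        y = as_shape_matrix(sample_or_y)
        if individuals is None:
            raise ValidationError("individual labels required")
        individuals = np.asarray(individuals)
    counts = pd.Series(individuals).value_counts()
    if counts.min() < 2 or len(counts) < 2:
        raise ValidationError("need >= 2 individuals with >= 2 replicates each")
    table = procrustes_anova_rrpp(
        y, pd.DataFrame({"individual": individuals.astype(str)}),
        ["individual"], n_perm, seed,
    )
    ms_ind = table.ms("individual")
    ms_res = table.ms_residual
    infinite = ms_res <= 1e-12 * max(ms_ind, 1e-300)
    ratio = np.inf if infinite else ms_ind / ms_res
    return RepeatabilityResult(ms_ind, ms_res, ratio, table.p["individual"],
                               bool(infinite), table)
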