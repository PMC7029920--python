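"""End-to-end orchestration: synthesis/phenotyping -> superimposition ->
statistics -> report bundle.

A single :class:`RunConfig` drives the whole analysis; one master seed is
expanded into independent child seeds per stage, so the run is
deterministic and the stages are statistically independent.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import shapestats as st
from .io import FactorDesign, LandmarkSample, Mesh, write_landmarks, write_mesh
from .superimposition import gpa, symmetrize, tangent_coordinates
from .synthesis import (
    default_effects,
    default_wing_effects,
    make_base_shape,
    simulate_replicates,
    simulate_two_structures,
)
from .templating import render_deformation, slide_semilandmarks

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML round-trippable)."""

    seed: int = 0
    outdir: str = "morphonorm_run"
    # synthesis
    k_fixed: int = 5
    k_curve: tuple[int, ...] = (60, 60, 10)
    k_surface: int = 394
    temperature_norm: float = 0.05
    population_norm: float = 0.03
    interaction_norm: float = 0.0
    allometry_norm: float = 0.2
    within_group_sd: float = 0.07
    wing_temperature_norm: float = 0.15
    shared_reaction_norms: bool = True
    # sliding
    slide: bool = True
    slide_iterations: int = 3
    # statistics
    use_symmetric: bool = True
    n_perm_group_means: int = 10000
    n_perm_anova: int = 999
    n_perm_trajectory: int = 999
    n_perm_plasticity: int = 1000
    n_pcs: int | None = None
    # repeatability sub-study
    n_replicates: int = 5
    n_replicated_individuals: int = 2
    # outputs
    figures: bool = True
    deformation_sd_units: float = 5.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "k_curve" in data:
            data["k_curve"] = tuple(data["k_curve"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["k_curve"] = list(data["k_curve"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds below 2^31 from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _anova_dict(table: st.AnovaTable) -> dict:
    return {
        "terms": {
            t: {"df": table.df[t], "SS": table.ss[t], "MS": table.ms(t),
                "F": table.f[t], "Z": table.z[t], "p": table.p[t]}
            for t in table.terms
        },
        "df_residual": table.df_residual,
        "SS_residual": table.ss_residual,
        "SS_total": table.ss_total,
        "n_perm": table.n_perm,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write a report bundle.

    Returns the bundle: a dict with the machine-readable ``summary``
    and the paths of every written artifact.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 12)
    summary: dict = {"config": dataclasses.asdict(config)}
    summary["config"]["k_curve"] = list(config.k_curve)
    artifacts: dict[str, str] = {}

    # --- synthesis ---------------------------------------------------------
    template = make_base_shape(config.k_fixed, config.k_curve, config.k_surface)
    design = FactorDesign()
    effects = default_effects(
        template.config, seed=seeds[0], pairing=template.pairing,
        temperature_norm=config.temperature_norm,
        population_norm=config.population_norm,
        interaction_norm=config.interaction_norm,
        allometry_norm=config.allometry_norm,
        within_group_sd=config.within_group_sd,
    )
    wing_effects = default_wing_effects(
        seed=seeds[1], temperature_norm=config.wing_temperature_norm,
        population_norm=config.population_norm,
        within_group_sd=config.within_group_sd,
    )
    ovip, wing = simulate_two_structures(effects, wing_effects, design,
                                         base_ovip=template)
    summary["design"] = {
        "n_specimens": ovip.n_specimens,
        "n_points_ovipositor": ovip.n_points,
        "n_points_wing": wing.n_points,
        "point_counts": template.counts(),
        "groups": sorted(f"{p}_{t}" for (p, t) in design.sizes()),
    }
    write_landmarks(ovip, outdir / "ovipositor_landmarks.csv",
                    outdir / "ovipositor_landmarks.yaml",
                    outdir / "factors.csv")
    artifacts["landmarks"] = str(outdir / "ovipositor_landmarks.csv")

    # --- sliding + superimposition ----------------------------------------
    try:
        if config.slide:
            slid = slide_semilandmarks(
                ovip, outer_iterations=config.slide_iterations
            )
            summary["sliding"] = {
                "energy_trace": slid.energy_trace,
                "iterations": slid.iterations,
                "converged": slid.converged,
            }
            ovip_for_stats = slid.sample
        else:
            ovip_for_stats = ovip
        res = symmetrize(gpa(ovip_for_stats))
        y = tangent_coordinates(res, use_symmetric=config.use_symmetric)
        sizes = _sizes_of(ovip)  # pre-superimposition sizes in µm
        res_w = gpa(wing)
        yw = tangent_coordinates(res_w, use_symmetric=False)
        sizes_w = res_w.centroid_sizes
    except Exception as exc:
        raise RuntimeError(f"superimposition stage failed: {exc}") from exc

    pop = ovip.factor("population")
    temp = ovip.factor("temperature").astype(int)
    group9 = np.array([f"{p}_{t}" for p, t in zip(pop, temp)])

    # --- statistics ---------------------------------------------------------
    try:
        gm = st.perm_test_group_means(y, group9, config.n_perm_group_means, seeds[2])
        summary["group_mean_test"] = {
            "labels": gm.labels,
            "n_comparisons": int(len(gm.labels) * (len(gm.labels) - 1) / 2),
            "distances": gm.distances,
            "p_values": gm.p_values,
            "n_perm": gm.n_perm,
        }

        factors = {"population": pop, "temperature": temp.astype(str)}
        shape_anova = st.procrustes_anova_rrpp(
            y, factors, "population*temperature", config.n_perm_anova, seeds[3]
        )
        summary["shape_anova"] = _anova_dict(shape_anova)

        pairwise_interaction = {}
        pops = sorted(set(pop))
        for i, a in enumerate(pops):
            for b in pops[i + 1:]:
                sel = np.isin(pop, [a, b])
                sub = st.procrustes_anova_rrpp(
                    y[sel],
                    {"population": pop[sel], "temperature": temp[sel].astype(str)},
                    "population*temperature", config.n_perm_anova, seeds[4],
                )
                key = f"{a}-{b}"
                pairwise_interaction[key] = {
                    "Z": sub.z["population:temperature"],
                    "p": sub.p["population:temperature"],
                }
        summary["pairwise_interaction"] = pairwise_interaction

        size_anova = st.procrustes_anova_rrpp(
            sizes[:, None], factors, "population*temperature",
            config.n_perm_anova, seeds[5],
        )
        summary["size_anova"] = _anova_dict(size_anova)

        traj = st.trajectory_analysis(
            y, pop, temp, level_order=[16, 22, 28],
            n_perm=config.n_perm_trajectory, seed=seeds[6],
        )
        summary["trajectory"] = {
            "path_lengths": traj.path_lengths,
            "pairwise": traj.pairwise.to_dict(orient="records"),
            "n_perm": traj.n_perm,
        }

        allo = st.allometry_fit(y, np.log(sizes), pop, config.n_perm_anova, seeds[7])
        summary["allometry"] = {
            "anova": _anova_dict(allo.anova),
            "slope_norm": float(np.linalg.norm(allo.slope)),
            "homogeneity": _anova_dict(allo.homogeneity),
        }

        cv_within, mslrt_within = {}, {}
        for t in sorted(set(temp)):
            r = st.cv_compare({
                "ovipositor": sizes[temp == t], "wing": sizes_w[temp == t],
            })
            cv_within[str(t)] = r.cvs
            mslrt_within[str(t)] = {"MSLRT": r.statistic, "p": r.p}
        cv_among = st.cv_compare({"ovipositor": sizes, "wing": sizes_w})
        summary["cv"] = {
            "within_temperature": cv_within,
            "within_temperature_tests": mslrt_within,
            "among_temperature": {
                "cvs": cv_among.cvs, "MSLRT": cv_among.statistic, "p": cv_among.p,
            },
        }

        plast = st.plasticity_permutation_test(
            y, temp, yw, temp,
            n_perm=config.n_perm_plasticity, seed=seeds[8], n_pcs=config.n_pcs,
        )
        summary["plasticity"] = {
            "n_pcs": plast.n_pcs,
            "mahalanobis": {
                s: {f"{a}-{b}": v for (a, b), v in d.items()}
                for s, d in plast.mahalanobis.items()
            },
            "mean_distance": plast.mean_distance,
            "observed_difference": plast.observed,
            "p": plast.p,
            "n_perm": plast.n_perm,
        }

        rep_sample = simulate_replicates(
            ovip.subset(range(config.n_replicated_individuals)),
            config.n_replicates, effects.measurement_error_sd, seed=seeds[9],
        )
        rep = st.repeatability_anova(rep_sample, n_perm=config.n_perm_anova,
                                     seed=seeds[10])
        summary["repeatability"] = {
            "MS_individual": rep.ms_individual,
            "MS_residual": rep.ms_residual,
            "ratio": (None if rep.infinite else rep.ratio),
            "infinite": rep.infinite,
            "p": rep.p,
        }
    except Exception as exc:
        _write_summary(summary, outdir, artifacts)
        raise RuntimeError(f"statistics stage failed: {exc}") from exc

    # --- figures and deformation meshes ------------------------------------
    if config.figures:
        try:
            bg = st.bgpca(y, group9)
            _fig_reaction_norms(bg, pop, temp, outdir / "fig_bgpca.png")
            artifacts["fig_bgpca"] = str(outdir / "fig_bgpca.png")
            _fig_sizes(sizes, pop, temp, outdir / "fig_sizes.png")
            artifacts["fig_sizes"] = str(outdir / "fig_sizes.png")
        except Exception as exc:  # plotting must not kill the analysis
            logger.warning("figure generation failed: %s", exc)
    try:
        consensus = res.consensus
        unit_mesh = _unit_mesh(template)
        v16 = effects.temperature_vectors[16]
        v28 = effects.temperature_vectors[28]
        for name, vec in (("deformation_16C", v16), ("deformation_28C", v28)):
            warped = render_deformation(
                _unit_config(template), vec, config.deformation_sd_units, unit_mesh
            )
            write_mesh(warped, outdir / f"{name}.ply")
            artifacts[name] = str(outdir / f"{name}.ply")
        summary["deformation"] = {
            "sd_units": config.deformation_sd_units,
            "consensus_points": int(consensus.shape[0]),
        }
    except Exception as exc:
        logger.warning("deformation rendering failed: %s", exc)

    _write_summary(summary, outdir, artifacts)
    return {"summary": summary, "artifacts": artifacts, "outdir": str(outdir)}


def _sizes_of(sample: LandmarkSample) -> np.ndarray:
    c = sample.coords - sample.coords.mean(axis=1, keepdims=True)
    return np.sqrt((c**2).sum(axis=(1, 2)))


def _unit_config(template) -> np.ndarray:
    c = template.config - template.config.mean(0)
    return c / np.sqrt((c**2).sum())


def _unit_mesh(template) -> Mesh:
    c = template.config - template.config.mean(0)
    cs = np.sqrt((c**2).sum())
    v = (template.mesh.vertices - template.config.mean(0)) / cs
    return Mesh(v, template.mesh.faces.copy(), "shape units")


def _write_summary(summary: dict, outdir: Path, artifacts: dict) -> None:
    path = outdir / "summary.json"
    path.write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_json_default)
    )
    artifacts["summary"] = str(path)


def _fig_reaction_norms(bg, pop, temp, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"Paris": "tab:red", "Sapporo": "tab:green", "Dayton": "tab:blue"}
    markers = {16: "s", 22: "^", 28: "o"}
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(bg.scores[:, 0], bg.scores[:, 1], c="0.8", s=12, label=None)
    for p in sorted(set(pop)):
        pts = []
        for t in (16, 22, 28):
            lab = f"{p}_{t}"
            i = bg.group_labels.index(lab)
            pts.append(bg.group_mean_scores[i, :2])
            ax.scatter(*bg.group_mean_scores[i, :2], c="k",
                       marker=markers[t], zorder=3)
        pts = np.array(pts)
        ax.plot(pts[:, 0], pts[:, 1], color=colors.get(p, "k"), label=p)
    ax.set_xlabel("bgPC1")
    ax.set_ylabel("bgPC2")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _fig_sizes(sizes, pop, temp, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"Paris": "tab:red", "Sapporo": "tab:green", "Dayton": "tab:blue"}
    fig, ax = plt.subplots(figsize=(7, 4))
    pos = 0
    ticks, ticklabels = [], []
    for t in (16, 22, 28):
        for p in sorted(set(pop)):
            vals = sizes[(pop == p) & (temp == t)]
            ax.boxplot([vals], positions=[pos], widths=0.7,
                       patch_artist=True,
                       boxprops=dict(facecolor=colors.get(p, "0.7")))
            ticks.append(pos)
            ticklabels.append(f"{p[:3]}\n{t}°")
            pos += 1
        pos += 1
    ax.set_xticks(ticks)
    ax.set_xticklabels(ticklabels, fontsize=7)
    ax.set_ylabel("centroid size (µm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


def report(bundle: dict, path: str | Path | None = None) -> str:
    """Render a markdown report from a bundle.

    Every number is taken verbatim from the bundle's summary, so the
    report and ``summary.json`` cannot disagree; missing artifacts are
    listed as absent rather than failing.
    """
    s = bundle.get("summary", {})
    artifacts = bundle.get("artifacts", {})
    lines = ["# Shape plasticity analysis report", ""]

    def fmt(x, nd=6):
        if x is None:
            return "absent"
        if isinstance(x, float):
            return f"{x:.{nd}g}"
        return str(x)

    def section(title):
        lines.extend(["", f"## {title}", ""])

    section("Design")
    d = s.get("design")
    if d:
        lines.append(f"- specimens: {d['n_specimens']}")
        lines.append(f"- ovipositor points: {d['n_points_ovipositor']} "
                     f"({d['point_counts']})")
        lines.append(f"- wing points: {d['n_points_wing']}")
    else:
        lines.append("absent")

    section("Group-mean permutation test")
    gm = s.get("group_mean_test")
    if gm:
        lines.append(f"- groups: {len(gm['labels'])}, pairwise comparisons: "
                     f"{gm['n_comparisons']}, permutations: {gm['n_perm']}")
    else:
        lines.append("absent")

    section("Procrustes ANOVA (shape)")
    an = s.get("shape_anova")
    if an:
        lines.append("| term | df | F | Z | p |")
        lines.append("|---|---|---|---|---|")
        for t, row in an["terms"].items():
            lines.append(
                f"| {t} | {row['df']} | {fmt(row['F'])} | {fmt(row['Z'])} "
                f"| {fmt(row['p'])} |"
            )
        lines.append(f"| residual | {an['df_residual']} | | | |")
    else:
        lines.append("absent")

    section("Centroid-size ANOVA")
    an = s.get("size_anova")
    if an:
        lines.append("| term | df | F | p |")
        lines.append("|---|---|---|---|")
        for t, row in an["terms"].items():
            lines.append(f"| {t} | {row['df']} | {fmt(row['F'])} | {fmt(row['p'])} |")
        lines.append(f"| residual | {an['df_residual']} | | |")
    else:
        lines.append("absent")

    section("Trajectory analysis (reaction norms)")
    tr = s.get("trajectory")
    if tr:
        for p, v in tr["path_lengths"].items():
            lines.append(f"- path length {p}: {fmt(v)}")
        lines.append("")
        lines.append("| pair | stat | value | Z | p |")
        lines.append("|---|---|---|---|---|")
        for row in tr["pairwise"]:
            lines.append(
                f"| {row['group_a']}-{row['group_b']} | {row['stat']} "
                f"| {fmt(row['value'])} | {fmt(row['Z'])} | {fmt(row['p'])} |"
            )
    else:
        lines.append("absent")

    section("Allometry")
    al = s.get("allometry")
    if al:
        r = al["anova"]["terms"]["log_cs"]
        lines.append(f"- shape ~ log(CS): Z = {fmt(r['Z'])}, p = {fmt(r['p'])}")
        h = al["homogeneity"]["terms"].get("log_cs:group")
        if h:
            lines.append(f"- slope homogeneity (size x group): Z = {fmt(h['Z'])}, "
                         f"p = {fmt(h['p'])}")
    else:
        lines.append("absent")

    section("Coefficients of variation (size)")
    cv = s.get("cv")
    if cv:
        for t, d2 in cv["within_temperature"].items():
            test = cv["within_temperature_tests"][t]
            lines.append(
                f"- {t}°C: ovipositor {fmt(d2['ovipositor'], 4)}%, wing "
                f"{fmt(d2['wing'], 4)}%, MSLRT = {fmt(test['MSLRT'], 4)}, "
                f"p = {fmt(test['p'], 4)}"
            )
        am = cv["among_temperature"]
        lines.append(
            f"- among temperatures: ovipositor {fmt(am['cvs']['ovipositor'], 4)}%, "
            f"wing {fmt(am['cvs']['wing'], 4)}%, MSLRT = {fmt(am['MSLRT'], 4)}, "
            f"p = {fmt(am['p'], 4)}"
        )
    else:
        lines.append("absent")

    section("Plasticity comparison (ovipositor vs wing)")
    pl = s.get("plasticity")
    if pl:
        lines.append(f"- PCs used: {pl['n_pcs']}")
        for sname, dd in pl["mahalanobis"].items():
            pairs = ", ".join(f"{k}: {fmt(v, 4)}" for k, v in dd.items())
            lines.append(f"- Mahalanobis distances ({sname}): {pairs}")
        lines.append(
            f"- mean among-temperature distance difference: "
            f"{fmt(pl['observed_difference'])}, p = {fmt(pl['p'])}"
        )
    else:
        lines.append("absent")

    section("Measurement error (repeatability)")
    rep = s.get("repeatability")
    if rep:
        ratio = "infinite" if rep["infinite"] else fmt(rep["ratio"], 4)
        lines.append(f"- MS_individual / MS_residual = {ratio}, p = {fmt(rep['p'], 4)}")
    else:
        lines.append("absent")

    section("Artifacts")
    for name in sorted(artifacts):
        lines.append(f"- {name}: {artifacts[name]}")

    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
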