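"""End-to-end drivers: study -> endpoints -> statistics -> phenomics -> trees.

These functions connect the per-assay endpoint extractors to the statistics
and clustering layers; the numbered scripts under ``analysis/`` and the
command-line interface are thin wrappers over them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import circadian as circ
from . import kinematics as kin
from . import phenomics, phylo, shoaling, stats, zones
from .trajio import ArenaSpec
from .zones import (
    novel_tank_endpoints,
    side_preference_endpoints,
    single_bin_schedule,
    wall_strip_zone,
)

#: contact-strip widths (cm) per assay; roughly one body length, configurable
STRIP_WIDTHS = {"mirror": 1.0, "predator": 3.0, "social": 3.0}


def _side_zones(arena: ArenaSpec, assay: str):
    """Contact strip on the stimulus wall plus the near-side half region."""
    from .synthdata import default_stim_segment
    seg = default_stim_segment(arena)
    strip = wall_strip_zone(f"{assay}_contact", seg, STRIP_WIDTHS[assay],
                            inward=(1.0, 0.0))
    poly = np.asarray(arena.polygon, dtype=float)
    xs = poly[:, 0]
    x_mid = (xs.min() + xs.max()) / 2.0
    y_top = arena.water_level_cm
    half = zones.ZoneSpec(f"{assay}_side",
                          ((xs.min(), 0.0), (x_mid, 0.0),
                           (x_mid, y_top), (xs.min() - 3.0, y_top)),
                          kind="region")
    return strip, half


def session_endpoints(traj, assay: str, arena: ArenaSpec,
                      thresholds: kin.MovementThresholds = kin.MovementThresholds(),
                      light=None) -> dict:
    """Named endpoint values for one session of one assay."""
    fps = arena.fps
    if assay == "novel_tank":
        per_bin = novel_tank_endpoints(traj, arena, thresholds)
        means = per_bin.drop(columns=["bin", "bin_start_s", "bin_missing",
                                      "latency_censored"]).mean()
        return {f"novel_{k}": v for k, v in means.items()}
    if assay in ("mirror", "predator", "social"):
        strip, half = _side_zones(arena, assay)
        out = side_preference_endpoints(traj, strip, half, fps)
        series = kin.kinematic_series(traj, thresholds, fps=fps)
        out["average_speed_cm_s"] = kin.locomotor_endpoints(series)[
            "average_speed_cm_s"]
        return {f"{assay}_{k}": v for k, v in out.items()}
    if assay == "shoaling":
        out = shoaling.shoal_endpoints(traj)
        out.pop("n_frames_used")
        return {f"shoal_{k}": v for k, v in out.items()}
    if assay == "circadian":
        schedule = light or circ.LightSchedule()
        hourly, summary = circ.circadian_profile(traj, schedule,
                                                 thresholds, fps=fps)
        out = {}
        for _, row in summary.iterrows():
            for ep in circ.CIRCADIAN_ENDPOINTS:
                out[f"circadian_{row['phase']}_{ep}"] = row[ep]
        return out
    raise ValueError(f"unknown assay {assay!r}")


def study_endpoints(study: dict,
                    thresholds: kin.MovementThresholds = kin.MovementThresholds()
                    ) -> pd.DataFrame:
    """Tidy endpoint table (group, assay, session, endpoint, value)."""
    rows = []
    for (group, assay, session), traj in study["trajectories"].items():
        arena = (study["circadian_arena"] if assay == "circadian"
                 else study["arena"])
        eps = session_endpoints(traj, assay, arena, thresholds)
        for name, value in eps.items():
            rows.append({"group": group, "assay": assay, "session_id": session,
                         "endpoint": name, "value": value})
    return pd.DataFrame(rows)


def endpoint_statistics(tidy: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Kruskal-Wallis + uncorrected Dunn + compact letters per endpoint."""
    out = []
    for ep, sub in tidy.groupby("endpoint"):
        groups = {g: s["value"].dropna().to_numpy()
                  for g, s in sub.groupby("group")}
        groups = {g: v for g, v in groups.items() if len(v) > 0}
        if len(groups) < 2:
            continue
        kw = stats.kruskal_wallis(groups)
        dunn = stats.dunn_uncorrected(groups)
        # letters assigned in mean-rank order for stable output
        from scipy.stats import rankdata
        pooled = np.concatenate([groups[g] for g in groups])
        ranks = rankdata(pooled)
        mean_ranks, i = {}, 0
        for g in groups:
            mean_ranks[g] = ranks[i:i + len(groups[g])].mean()
            i += len(groups[g])
        order = sorted(groups, key=mean_ranks.get)
        lets = stats.letters(dunn, alpha=alpha, order=order)
        out.append({"endpoint": ep, "H": kw["H"], "df": kw["df"],
                    "p": kw["p"],
                    "letters": ";".join(f"{g}={l}" for g, l in lets.items())})
    return pd.DataFrame(out)


def phenomic_analysis(tidy: pd.DataFrame, distance: str = "correlation",
                      linkage: str = "average") -> dict:
    """Group-mean matrix -> scaled matrix, PCA, two-axis clustering."""
    mat = phenomics.build_endpoint_matrix(tidy)
    scaled = phenomics.scale_rows_unit_variance(mat)
    pca = phenomics.pca_svd(scaled)
    col = phenomics.hcluster(scaled, axis="columns", distance=distance,
                             linkage=linkage)
    row = phenomics.hcluster(scaled, axis="rows", distance=distance,
                             linkage=linkage)
    return {"matrix": mat, "scaled": scaled, "pca": pca,
            "column_clustering": col, "row_clustering": row,
            "phenogram_newick": col["newick"]}


def gene_tree_analysis(sequences: dict, n_bootstrap: int = 200,
                       seed: int | None = None) -> dict:
    """Alignment -> JC distances -> NJ tree with bootstrap supports."""
    msa = phylo.reference_msa(sequences)
    boot = phylo.bootstrap_support(msa, n_replicates=n_bootstrap, seed=seed)
    return {"tree": boot["tree"], "support": boot["support"],
            "newick": phylo.write_newick(boot["tree"]),
            "distance_matrix": phylo.jc_distance_matrix(msa, aligned=True)}


def phenome_genome_concordance(phenogram_newick: str, gene_tree) -> dict:
    """Concordance between the phenomic dendrogram and the gene tree."""
    t1 = phylo.read_newick(phenogram_newick)
    t2 = gene_tree if not isinstance(gene_tree, str) else phylo.read_newick(
        gene_tree)
    return phylo.tree_concordance(t1, t2)
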