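"""End-to-end orchestration: simulate/load -> QC -> threshold -> communities
-> MD/MV -> group statistics -> report, behind a single config object.

Stage order mirrors the analysis design: framewise-displacement exclusion,
matrix loading, optimal-density selection (or a fixed density), local and
global thresholding, best-of-N Louvain, per-participant modular dissociation,
balanced bootstrapped group modular variability with per-iteration consensus
and permutation tests, meta-consensus, meta-aggregated nodal comparisons with
BH-FDR, MD/OA referencing against the reference group, and summary tables.

A single master seed spawns per-stage child seeds so any stage can be re-run
in isolation; a fixed config + seed reproduces every CSV output byte for
byte on one machine.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from ._seeds import child_seeds
from .community import (
    louvain_best_of,
    meta_consensus,
    optimal_density_search,
)
from .io import load_connectome, load_motion_params, load_node_metadata, save_partition
from .metrics import bootstrap_group_mv, md_referenced, nodal_mv
from .networks import global_threshold, local_threshold, weighted_mask
from .stats import (
    distance_strength_fit,
    framewise_displacement,
    global_md_tests,
    meta_aggregate,
    permutation_test,
    residualize,
    viz_transform,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "report"]

_FLOAT_FMT = "%.10g"

# paper-scale defaults and the scaled-down CI profile
_DEFAULTS = dict(n_runs=1000, n_null=40, n_boot=500, n_perm=5000, eq2_n_boot=10000)
_FAST = dict(n_runs=50, n_null=10, n_boot=50, n_perm=500, eq2_n_boot=500)


@dataclass
class RunConfig:
    matrix_dir: str
    covariates: str
    output_dir: str
    nodes: Optional[str] = None
    motion_dir: Optional[str] = None
    density: object = "optimal"  # percent, or "optimal" for the Q-Q_rand scan
    method: str = "local"  # construction used for MV/communities
    grid: Optional[dict] = None  # {"min":…, "max":…, "points":…}
    n_runs: Optional[int] = None
    n_null: Optional[int] = None
    n_boot: Optional[int] = None
    n_perm: Optional[int] = None
    eq2_n_boot: Optional[int] = None
    alpha: float = 0.05
    seed: int = 0
    groups: tuple = ("YA", "OA")  # (group of interest, reference)
    reference_group: str = "OA"
    fd_threshold: float = 0.5
    apply_fd_exclusion: bool = True
    demean_age_within_group: bool = True
    fast: bool = False

    def __post_init__(self):
        profile = _FAST if self.fast else _DEFAULTS
        for key, default in profile.items():
            if getattr(self, key) is None:
                setattr(self, key, default)
        if self.reference_group not in self.groups:
            raise ValueError("reference_group must be one of the group labels")
        if len(self.groups) != 2:
            raise ValueError("exactly two group labels are compared per run")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        paths = raw.get("paths", {})
        analysis = raw.get("analysis", {})
        groups = raw.get("groups", {})
        qc = raw.get("qc", {})
        return cls(
            matrix_dir=paths["matrix_dir"],
            covariates=paths["covariates"],
            output_dir=paths["output_dir"],
            nodes=paths.get("nodes"),
            motion_dir=paths.get("motion_dir"),
            density=analysis.get("density", "optimal"),
            method=analysis.get("method", "local"),
            grid=analysis.get("grid"),
            n_runs=analysis.get("n_runs"),
            n_null=analysis.get("n_null"),
            n_boot=analysis.get("n_boot"),
            n_perm=analysis.get("n_perm"),
            eq2_n_boot=analysis.get("eq2_n_boot"),
            alpha=analysis.get("alpha", 0.05),
            seed=analysis.get("seed", 0),
            groups=tuple(groups.get("labels", ("YA", "OA"))),
            reference_group=groups.get("reference", "OA"),
            fd_threshold=qc.get("fd_threshold", 0.5),
            apply_fd_exclusion=qc.get("apply", True),
            fast=raw.get("fast", False),
        )

    def echo(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}


@dataclass
class RunManifest:
    config: dict
    version: str = "0.1.0"
    seeds: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)
    exclusions: list = field(default_factory=list)
    stages: dict = field(default_factory=dict)  # stage -> "ok" | error message
    outputs: list = field(default_factory=list)

    def write(self, path) -> None:
        path = Path(path)
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(self.__dict__, indent=1, sort_keys=True, default=str))
        tmp.replace(path)  # atomic on POSIX


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _edge_table(conn, binary, dist, row) -> pd.DataFrame:
    i, j = np.nonzero(np.triu(binary.adjacency, 1))
    table = pd.DataFrame(
        {"strength": conn.weights[i, j], "distance": dist[i, j], "age": row["age"], "sex": row["sex"]}
    )
    if "study" in row:
        table["study"] = row["study"]
    return table


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full modular-connectivity analysis described by ``config``.

    Any stage failure is recorded in the manifest under the stage name and
    downstream stages are skipped; the manifest is always written.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.echo())
    stage_names = [
        "qc_fd",
        "load",
        "density",
        "threshold_communities",
        "md",
        "mv_bootstrap",
        "meta_consensus",
        "md_compare",
        "md_oa",
        "distance_strength",
        "report",
    ]
    seeds = dict(zip(stage_names, child_seeds(config.seed, len(stage_names))))
    manifest.seeds = seeds
    state: dict = {}
    failed = False
    for stage in stage_names:
        if failed:
            manifest.stages[stage] = "skipped (upstream failure)"
            continue
        t0 = time.perf_counter()
        try:
            _STAGES[stage](config, state, manifest, seeds[stage])
            manifest.stages.setdefault(stage, "ok")
        except Exception as exc:  # noqa: BLE001 - recorded, not swallowed silently
            logger.exception("stage %s failed", stage)
            manifest.stages[stage] = f"error: {exc}"
            failed = True
        manifest.timings[stage] = round(time.perf_counter() - t0, 3)
    manifest.write(out / "manifest.json")
    return manifest


# --------------------------------------------------------------------------
# stages


def _stage_qc_fd(config, state, manifest, seed):
    cov = pd.read_csv(config.covariates)
    if "id" not in cov.columns:
        raise ValueError("covariate table needs an 'id' column")
    if config.motion_dir is not None:
        fds = []
        for pid in cov["id"]:
            trace = load_motion_params(Path(config.motion_dir) / f"{pid}.par")
            fds.append(framewise_displacement(trace).mean_fd)
        cov["mean_fd"] = fds
    if config.apply_fd_exclusion and "mean_fd" in cov.columns:
        bad = cov["mean_fd"] > config.fd_threshold
        manifest.exclusions = [
            {"id": str(r["id"]), "mean_fd": float(r["mean_fd"])}
            for _, r in cov[bad].iterrows()
        ]
        cov = cov[~bad].reset_index(drop=True)
    state["covariates"] = cov


def _stage_load(config, state, manifest, seed):
    cov = state["covariates"]
    coords = None
    if config.nodes is not None:
        coords = load_node_metadata(config.nodes)[["x", "y", "z"]].to_numpy(dtype=float)
    matrix_dir = Path(config.matrix_dir)
    connectomes = {}
    for pid in cov["id"]:
        path = matrix_dir / f"{pid}.csv"
        manifest.checksums[path.name] = _sha256(path)
        connectomes[pid] = load_connectome(path, coordinates=coords)
    state["connectomes"] = connectomes
    if coords is not None:
        from scipy.spatial.distance import pdist, squareform

        state["distances"] = squareform(pdist(coords))


def _stage_density(config, state, manifest, seed):
    if config.density != "optimal":
        state["density"] = float(config.density)
        return
    conns = list(state["connectomes"].values())
    grid = None
    if config.grid is not None:
        grid = np.linspace(config.grid["min"], config.grid["max"], int(config.grid["points"]))
    curve = optimal_density_search(
        conns,
        density_grid=grid,
        method=config.method,
        seed=seed,
        n_runs=max(10, config.n_runs // 100),
        n_null=config.n_null,
    )
    state["density"] = curve.optimal_density
    pd.DataFrame(
        {
            "density": curve.densities,
            "Q_mean": curve.Q_mean,
            "Q_rand_mean": curve.Q_rand_mean,
            "Q_minus_Qrand": curve.Q_minus_Qrand,
        }
    ).to_csv(Path(config.output_dir) / "density_curve.csv", index=False, float_format=_FLOAT_FMT)
    manifest.outputs.append("density_curve.csv")


def _stage_threshold_communities(config, state, manifest, seed):
    density = state["density"]
    cov = state["covariates"]
    seeds = child_seeds(seed, 2 * len(cov))
    locals_, globals_, parts_local, parts_global = {}, {}, {}, {}
    for k, pid in enumerate(cov["id"]):
        conn = state["connectomes"][pid]
        loc = local_threshold(conn, density)
        glo = global_threshold(conn, density)
        locals_[pid], globals_[pid] = loc, glo
        # same seed stream for both constructions isolates the thresholding effect
        parts_local[pid] = louvain_best_of(weighted_mask(conn, loc), config.n_runs, seeds[2 * k])
        parts_global[pid] = louvain_best_of(weighted_mask(conn, glo), config.n_runs, seeds[2 * k])
    state.update(
        binary_local=locals_, binary_global=globals_,
        partitions_local=parts_local, partitions_global=parts_global,
    )


def _stage_md(config, state, manifest, seed):
    cov = state["covariates"]
    rows = []
    for pid in cov["id"]:
        md = nodal_mv(state["partitions_local"][pid], state["partitions_global"][pid])
        rows.append(md)
    md_matrix = np.vstack(rows)
    state["md_matrix"] = md_matrix
    table = pd.DataFrame(md_matrix, index=cov["id"])
    table.insert(0, "group", cov["group"].to_numpy())
    table.to_csv(Path(config.output_dir) / "md_nodal.csv", float_format=_FLOAT_FMT)
    manifest.outputs.append("md_nodal.csv")


def _stage_mv_bootstrap(config, state, manifest, seed):
    cov = state["covariates"]
    ga, gb = config.groups
    idx_a = cov.index[cov["group"] == ga].tolist()
    idx_b = cov.index[cov["group"] == gb].tolist()
    parts = state["partitions_local"]
    parts_a = [parts[cov.loc[i, "id"]] for i in idx_a]
    parts_b = [parts[cov.loc[i, "id"]] for i in idx_b]
    s_boot, s_perm = child_seeds(seed, 2)
    mv_table, consensus_list = bootstrap_group_mv(
        parts_a,
        parts_b,
        n_boot=config.n_boot,
        seed=s_boot,
        ids_a=[cov.loc[i, "id"] for i in idx_a],
        ids_b=[cov.loc[i, "id"] for i in idx_b],
        group_labels=(ga, gb),
    )
    state["mv_table"], state["consensus_list"] = mv_table, consensus_list
    mv_table.table.to_csv(Path(config.output_dir) / "mv_bootstrap.csv", index=False,
                          float_format=_FLOAT_FMT)
    manifest.outputs.append("mv_bootstrap.csv")

    # per-iteration residualised permutation tests, then meta-aggregation
    cov_cols = [c for c in ("group", "age", "sex", "study", "mean_fd") if c in cov.columns]
    perm_seeds = child_seeds(s_perm, config.n_boot)
    p_iters, z_iters = [], []
    id_to_row = {cov.loc[i, "id"]: i for i in cov.index}
    for it in range(config.n_boot):
        sub = mv_table.table[mv_table.table["iteration"] == it]
        mat = sub.pivot_table(index=["group", "participant"], columns="node", values="value")
        rows = [id_to_row[pid] for _, pid in mat.index]
        covariates = cov.loc[rows, cov_cols].reset_index(drop=True)
        resid = residualize(
            mat.to_numpy(), covariates, demean_age_within_group=config.demean_age_within_group
        )
        is_a = np.asarray([g == ga for g, _ in mat.index])
        res = permutation_test(resid[is_a], resid[~is_a], n_perm=config.n_perm, seed=perm_seeds[it])
        p_iters.append(res.p)
        z_iters.append(res.z)
    comparison = meta_aggregate(np.vstack(p_iters), np.vstack(z_iters), alpha=config.alpha)
    state["mv_comparison"] = comparison
    comparison.to_frame().to_csv(Path(config.output_dir) / "mv_compare.csv", index=False,
                                 float_format=_FLOAT_FMT)
    manifest.outputs.append("mv_compare.csv")


def _stage_meta_consensus(config, state, manifest, seed):
    meta = meta_consensus(state["consensus_list"], seed=seed)
    state["meta_consensus"] = meta
    save_partition(meta, Path(config.output_dir) / "meta_consensus.csv")
    manifest.outputs.append("meta_consensus.csv")


def _stage_md_compare(config, state, manifest, seed):
    cov = state["covariates"]
    ga, gb = config.groups
    cov_cols = [c for c in ("group", "age", "sex", "study", "mean_fd") if c in cov.columns]
    resid = residualize(
        state["md_matrix"], cov[cov_cols], demean_age_within_group=config.demean_age_within_group
    )
    is_a = (cov["group"] == ga).to_numpy()
    is_b = (cov["group"] == gb).to_numpy()
    res = permutation_test(resid[is_a], resid[is_b], n_perm=config.n_perm, seed=seed)
    comparison = meta_aggregate(res.p[None, :], res.z[None, :], alpha=config.alpha)
    state["md_comparison"] = comparison
    comparison.to_frame().to_csv(Path(config.output_dir) / "md_compare.csv", index=False,
                                 float_format=_FLOAT_FMT)
    manifest.outputs.append("md_compare.csv")


def _stage_md_oa(config, state, manifest, seed):
    cov = state["covariates"]
    ref = config.reference_group
    other = [g for g in config.groups if g != ref][0]
    is_ref = (cov["group"] == ref).to_numpy()
    is_other = (cov["group"] == other).to_numpy()
    md = state["md_matrix"]
    cov_cols = [c for c in ("age", "sex", "study", "mean_fd") if c in cov.columns]
    covariates = pd.concat([cov[is_ref], cov[is_other]], ignore_index=True)[cov_cols + ["group"]]
    referenced = md_referenced(
        md[is_other], md[is_ref], covariates, group=other,
        demean_age_within_group=config.demean_age_within_group,
    )
    state["md_oa"] = {other: referenced}
    pd.DataFrame({"node_label": np.arange(md.shape[1]), "md_oa": referenced.md_oa_index}).to_csv(
        Path(config.output_dir) / f"md_oa_{other}.csv", index=False, float_format=_FLOAT_FMT
    )
    modules = state.get("meta_consensus").labels if "meta_consensus" in state else None
    tests = global_md_tests(state["md_oa"], module_labels=None, alpha=config.alpha)
    if modules is not None:
        per_module = pd.DataFrame(
            {
                "module": np.unique(modules),
                "mean_md_oa": [
                    referenced.md_oa_index[modules == m].mean() for m in np.unique(modules)
                ],
            }
        )
        per_module.to_csv(Path(config.output_dir) / f"md_oa_{other}_modules.csv", index=False,
                          float_format=_FLOAT_FMT)
        manifest.outputs.append(f"md_oa_{other}_modules.csv")
    tests.to_csv(Path(config.output_dir) / "md_oa_tests.csv", index=False, float_format=_FLOAT_FMT)
    manifest.outputs += [f"md_oa_{other}.csv", "md_oa_tests.csv"]


def _stage_distance_strength(config, state, manifest, seed):
    if "distances" not in state:
        manifest.stages["distance_strength"] = "skipped (no node coordinates)"
        return
    cov = state["covariates"]
    dist = state["distances"]
    ga, gb = config.groups
    tables = {ga: [], gb: []}
    for _, row in cov.iterrows():
        if row["group"] not in tables:
            continue
        pid = row["id"]
        tables[row["group"]].append(
            _edge_table(state["connectomes"][pid], state["binary_local"][pid], dist, row)
        )
    model = distance_strength_fit(
        pd.concat(tables[ga], ignore_index=True),
        pd.concat(tables[gb], ignore_index=True),
        n_boot=config.eq2_n_boot,
        seed=seed,
    )
    state["distance_strength"] = model
    summary = pd.DataFrame(
        {
            "coefficient": model.coef_names,
            "mean": model.mean().to_numpy(),
            "ci_low": [model.ci95[c][0] for c in model.coef_names],
            "ci_high": [model.ci95[c][1] for c in model.coef_names],
            "p": [model.pvalues[c] for c in model.coef_names],
            "significant": [model.significance[c] for c in model.coef_names],
        }
    )
    summary.to_csv(Path(config.output_dir) / "distance_strength.csv", index=False,
                   float_format=_FLOAT_FMT)
    manifest.outputs.append("distance_strength.csv")


def _stage_report(config, state, manifest, seed):
    report(state, Path(config.output_dir))
    manifest.outputs.append("report_modules.csv")


_STAGES = {
    "qc_fd": _stage_qc_fd,
    "load": _stage_load,
    "density": _stage_density,
    "threshold_communities": _stage_threshold_communities,
    "md": _stage_md,
    "mv_bootstrap": _stage_mv_bootstrap,
    "meta_consensus": _stage_meta_consensus,
    "md_compare": _stage_md_compare,
    "md_oa": _stage_md_oa,
    "distance_strength": _stage_distance_strength,
    "report": _stage_report,
}


def report(state: dict, outdir) -> pd.DataFrame:
    """Per-module mean MV/MD summary with display-transformed values.

    Module means are the averages of nodal values over each meta-consensus
    module; the display columns carry the nonlinear 1-100 visualisation
    mapping and must not be used for statistics.
    """
    required = [k for k in ("meta_consensus", "md_matrix", "mv_table") if k not in state]
    if required:
        raise ValueError(f"missing pipeline outputs: {required}")
    modules = state["meta_consensus"].labels
    md_mean = state["md_matrix"].mean(axis=0)
    mv_mean = (
        state["mv_table"].table.groupby("node")["value"].mean().to_numpy()
    )
    rows = []
    for m in np.unique(modules):
        sel = modules == m
        rows.append(
            {
                "module": int(m),
                "n_nodes": int(sel.sum()),
                "mean_mv": mv_mean[sel].mean(),
                "mean_md": md_mean[sel].mean(),
                "mean_mv_display": viz_transform(np.clip(mv_mean[sel].mean(), 0, 1), "mv"),
                "mean_md_display": viz_transform(np.clip(md_mean[sel].mean(), 0, 1), "md"),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(Path(outdir) / "report_modules.csv", index=False, float_format=_FLOAT_FMT)
    return table
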