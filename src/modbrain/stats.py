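"""Group statistics: bootstrapped distance-strength models, residualisation,
permutation tests with meta-aggregation, FDR, rank-based global tests, and
framewise-displacement motion QC."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "MotionTrace",
    "FDResult",
    "DistanceStrengthModel",
    "PermutationResult",
    "GroupComparison",
    "distance_strength_fit",
    "residualize",
    "permutation_test",
    "meta_aggregate",
    "fdr_bh",
    "global_md_tests",
    "framewise_displacement",
    "viz_transform",
]

FD_EXCLUSION_MM = 0.5
FD_SPHERE_RADIUS_MM = 65.0


@dataclass
class MotionTrace:
    """Six rigid-body motion parameters per fMRI volume.

    ``translations`` are (n_volumes, 3) in mm; ``rotations`` (n_volumes, 3)
    in radians.  Rotational displacement is converted to arc length on a
    65-mm-radius sphere when framewise displacement is computed.
    """

    translations: np.ndarray
    rotations: np.ndarray

    def __post_init__(self):
        self.translations = np.atleast_2d(np.asarray(self.translations, dtype=float))
        self.rotations = np.atleast_2d(np.asarray(self.rotations, dtype=float))
        if self.translations.shape[1] != 3 or self.rotations.shape[1] != 3:
            raise ValueError("expected three translation and three rotation parameters")
        if self.translations.shape[0] != self.rotations.shape[0]:
            raise ValueError("translation and rotation series lengths differ")

    @property
    def n_volumes(self) -> int:
        return self.translations.shape[0]


@dataclass
class FDResult:
    fd: np.ndarray  # per-transition FD (mm), length n_volumes - 1
    mean_fd: float
    exclude: bool  # True iff mean FD exceeds the 0.5 mm cutoff


def framewise_displacement(trace: MotionTrace, radius: float = FD_SPHERE_RADIUS_MM) -> FDResult:
    """Framewise displacement: sum of absolute rigid-body parameter deltas.

    FD_i = |dx| + |dy| + |dz| + |da| + |db| + |dc| with the rotational deltas
    expressed as arc length (radians x ``radius``).  Participants whose mean
    FD exceeds 0.5 mm are flagged for exclusion.
    """
    if trace.n_volumes < 2:
        raise ValueError("need at least two volumes to compute FD")
    d_trans = np.abs(np.diff(trace.translations, axis=0)).sum(axis=1)
    d_rot = np.abs(np.diff(trace.rotations, axis=0)).sum(axis=1) * radius
    fd = d_trans + d_rot
    mean_fd = float(fd.mean())
    return FDResult(fd=fd, mean_fd=mean_fd, exclude=mean_fd > FD_EXCLUSION_MM)


# ---------------------------------------------------------------------------
# covariate residualisation


def _build_design(covariates: pd.DataFrame, demean_age_within_group: bool) -> pd.DataFrame:
    cov = covariates.copy()
    group = cov.pop("group") if "group" in cov.columns else None
    cov = cov.drop(columns=["participant", "id"], errors="ignore")
    if demean_age_within_group:
        if "age" not in cov.columns or group is None:
            raise ValueError("within-group age demeaning needs 'age' and 'group' columns")
        cov["age"] = cov["age"] - cov.groupby(group.values)["age"].transform("mean")
    design = pd.get_dummies(cov, drop_first=True, dtype=float)
    design = design.astype(float)
    # constant columns duplicate the intercept; drop them silently
    keep = [c for c in design.columns if design[c].nunique() > 1]
    dropped = sorted(set(design.columns) - set(keep))
    if dropped:
        logger.debug("dropping zero-variance covariate columns: %s", dropped)
    design = design[keep]
    design.insert(0, "intercept", 1.0)
    x = design.to_numpy()
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        redundant = [
            c
            for i, c in enumerate(design.columns)
            if np.linalg.matrix_rank(np.delete(x, i, axis=1)) == rank
        ]
        raise ValueError(f"collinear covariate design; redundant columns: {redundant}")
    return design


def residualize(
    values: np.ndarray,
    covariates: pd.DataFrame,
    demean_age_within_group: bool = False,
) -> np.ndarray:
    """Least-squares residuals of per-participant values on a covariate design.

    ``values`` is (participants,) or (participants, nodes); ``covariates`` a
    per-participant table whose numeric columns enter directly and whose
    categorical columns are dummy-coded.  A ``group`` column is never used as
    a regressor: it only drives within-group age centring when
    ``demean_age_within_group`` is set, which removes age variance without
    absorbing the group effect.
    """
    v = np.asarray(values, dtype=float)
    squeeze = v.ndim == 1
    v = np.atleast_2d(v.T).T if squeeze else v
    if v.ndim == 1:
        v = v[:, None]
    if len(covariates) != v.shape[0]:
        raise ValueError("covariate rows must match participants")
    x = _build_design(covariates, demean_age_within_group).to_numpy()
    beta, *_ = np.linalg.lstsq(x, v, rcond=None)
    resid = v - x @ beta
    return resid[:, 0] if squeeze else resid


# ---------------------------------------------------------------------------
# distance-strength linear model (bootstrapped)


@dataclass
class DistanceStrengthModel:
    """Bootstrap distributions of the distance-strength model coefficients.

    The model is ``strength ~ b1*distance + b2*group + b3*group*distance +
    b4*age + b5*sex + b6*study + intercept``; b2 and b3 carry the group
    differences in intercept and slope.  Each iteration refits the model by
    OLS on ``sample_fraction`` of the pooled edge population sampled without
    replacement; a coefficient is significant when 0 lies outside the central
    95% of its bootstrap distribution.
    """

    draws: pd.DataFrame  # n_boot x coefficients
    n_boot: int
    sample_fraction: float
    significance: dict = field(default_factory=dict)
    ci95: dict = field(default_factory=dict)
    pvalues: dict = field(default_factory=dict)

    @property
    def coef_names(self) -> list:
        return list(self.draws.columns)

    def mean(self) -> pd.Series:
        return self.draws.mean()


def _edge_design(pooled: pd.DataFrame) -> pd.DataFrame:
    design = pd.DataFrame(
        {
            "intercept": 1.0,
            "distance": pooled["distance"].to_numpy(dtype=float),
            "group": pooled["group"].to_numpy(dtype=float),
        }
    )
    design["group_x_distance"] = design["group"] * design["distance"]
    for col in pooled.columns:
        if col in ("strength", "distance", "group"):
            continue
        series = pooled[col]
        if series.dtype.kind in "biufc":
            vals = series.to_numpy(dtype=float)
            if np.ptp(vals) > 0:
                design[col] = vals
            else:
                warnings.warn(f"constant covariate column '{col}' dropped from Eq. model")
        else:
            dummies = pd.get_dummies(series, prefix=col, drop_first=True, dtype=float)
            for dcol in dummies.columns:
                if dummies[dcol].nunique() > 1:
                    design[dcol] = dummies[dcol].to_numpy()
                else:
                    warnings.warn(f"constant covariate column '{dcol}' dropped from Eq. model")
    return design


def distance_strength_fit(
    edges_a: pd.DataFrame,
    edges_b: pd.DataFrame,
    n_boot: int = 10000,
    fraction: float = 0.2,
    seed: int = 0,
    max_redraws: int = 20,
) -> DistanceStrengthModel:
    """Bootstrapped OLS of edge strength on Euclidean edge distance and group.

    ``edges_a``/``edges_b`` hold one row per surviving network edge of each
    group with at least ``strength`` and ``distance`` (mm) columns plus any
    participant covariates (age, sex, study).  Group is coded 0 for
    ``edges_a`` and 1 for ``edges_b``.
    """
    if len(edges_a) < 10 or len(edges_b) < 10:
        raise ValueError("need at least 10 edges per group")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    pooled = pd.concat(
        [edges_a.assign(group=0), edges_b.assign(group=1)], ignore_index=True
    )
    y = pooled["strength"].to_numpy(dtype=float)
    design = _edge_design(pooled)
    x = design.to_numpy(dtype=float)
    n, p = x.shape
    m = int(np.floor(fraction * n))
    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, p))
    for it in range(n_boot):
        for attempt in range(max_redraws):
            idx = rng.choice(n, size=m, replace=False)
            beta, _, rank, _ = np.linalg.lstsq(x[idx], y[idx], rcond=None)
            if rank == p:
                draws[it] = beta
                break
            logger.warning("bootstrap iteration %d: singular fit, redrawing", it)
        else:
            raise RuntimeError(f"iteration {it}: singular fits in {max_redraws} redraws")
    table = pd.DataFrame(draws, columns=design.columns)
    model = DistanceStrengthModel(table, n_boot=n_boot, sample_fraction=fraction)
    for name in table.columns:
        d = table[name].to_numpy()
        lo, hi = np.percentile(d, [2.5, 97.5])
        model.ci95[name] = (float(lo), float(hi))
        model.significance[name] = bool(lo > 0 or hi < 0)
        tail = min((d <= 0).mean(), (d >= 0).mean())
        model.pvalues[name] = float(min(1.0, 2.0 * tail))
    return model


# ---------------------------------------------------------------------------
# nodal permutation tests


@dataclass
class PermutationResult:
    p: np.ndarray
    z: np.ndarray
    direction: np.ndarray  # sign of (mean_a - mean_b) per node


def permutation_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
) -> PermutationResult:
    """Two-sided nodal permutation test of the difference of group means.

    Group labels are shuffled ``n_perm`` times; the permutation-null mean and
    pooled SD normalise the observed statistic into a Z-score, and the
    two-sided p-value is the (add-one corrected) fraction of null statistics
    at least as extreme as observed.  Nodes with a degenerate (zero-variance)
    null get p = 1, z = 0.
    """
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    b = np.atleast_2d(np.asarray(values_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 participants per group")
    if a.shape[1] != b.shape[1]:
        raise ValueError("node dimensions differ")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very low; p-value resolution will be poor")
    na = a.shape[0]
    pooled = np.vstack([a, b])
    observed = a.mean(axis=0) - b.mean(axis=0)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, pooled.shape[1]))
    for i in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        null[i] = pooled[perm[:na]].mean(axis=0) - pooled[perm[na:]].mean(axis=0)
    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=0)
    degenerate = null_sd == 0
    z = np.zeros_like(observed)
    ok = ~degenerate
    z[ok] = (observed[ok] - null_mean[ok]) / null_sd[ok]
    p = (1.0 + (np.abs(null) >= np.abs(observed)).sum(axis=0)) / (n_perm + 1.0)
    p[degenerate] = 1.0
    return PermutationResult(p=p, z=z, direction=np.sign(observed))


@dataclass
class GroupComparison:
    """Meta-aggregated nodal comparison across bootstrap iterations."""

    p_meta: np.ndarray
    z_meta: np.ndarray
    direction: np.ndarray
    flip_flag: np.ndarray  # True where the difference direction varied across iterations
    fdr_mask: np.ndarray
    alpha: float
    n_iter: int

    def to_frame(self, node_labels=None) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_label": node_labels if node_labels is not None else np.arange(self.p_meta.size),
                "z_meta": self.z_meta,
                "p_meta": self.p_meta,
                "fdr_pass": self.fdr_mask,
                "direction": self.direction,
                "flip_flag": self.flip_flag,
            }
        )


def meta_aggregate(
    pvalues: np.ndarray, zscores: np.ndarray, alpha: float = 0.05
) -> GroupComparison:
    """Average per-iteration nodal p and Z into meta-results.

    ``pvalues`` and ``zscores`` are (iterations, nodes).  The direction of the
    meta difference is the sign of the mean Z; nodes whose per-iteration Z
    changed sign are flagged, since a significant meta-p with a flipping
    direction marks an unstable difference.
    """
    p = np.atleast_2d(np.asarray(pvalues, dtype=float))
    z = np.atleast_2d(np.asarray(zscores, dtype=float))
    if p.shape != z.shape:
        raise ValueError("p-value and z-score arrays must have the same shape")
    p_meta = p.mean(axis=0)
    z_meta = z.mean(axis=0)
    flips = (z > 0).any(axis=0) & (z < 0).any(axis=0)
    return GroupComparison(
        p_meta=p_meta,
        z_meta=z_meta,
        direction=np.sign(z_meta),
        flip_flag=flips,
        fdr_mask=fdr_bh(p_meta, alpha=alpha),
        alpha=alpha,
        n_iter=p.shape[0],
    )


def fdr_bh(pvalues: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level ``alpha``."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject


# ---------------------------------------------------------------------------
# global/module-level MD/OA tests


def _signed_rank_vs_zero(values: np.ndarray) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    if np.all(v == 0):
        return 0.0, 1.0
    res = sps.wilcoxon(v, zero_method="wilcox", alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def global_md_tests(
    referenced: dict,
    module_labels: Optional[np.ndarray] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank-based tests of the MD/OA index, treating nodes as observations.

    Per group: Wilcoxon signed-rank of nodal MD/OA against zero (is the group
    globally more/less dissociated than the OA reference?).  If consensus
    ``module_labels`` are given and there are at least two groups: two-sided
    rank-sum tests between each pair of groups within each module.  BH-FDR
    is applied separately within the global and the module family.
    """
    groups = list(referenced)
    rows = []
    for g in groups:
        ref = referenced[g]
        vals = np.asarray(ref.md_oa_index, dtype=float)
        if vals.size < 10:
            raise ValueError("need at least 10 nodes for rank-based tests")
        stat, p = _signed_rank_vs_zero(vals)
        rows.append(
            {
                "family": "global",
                "group_a": g,
                "group_b": "zero",
                "module": "all",
                "statistic": stat,
                "p": p,
                "mean_md_oa": float(vals.mean()),
            }
        )
    if module_labels is not None and len(groups) >= 2:
        module_labels = np.asarray(module_labels)
        for i, ga in enumerate(groups):
            for gb in groups[i + 1 :]:
                va = np.asarray(referenced[ga].md_oa_index, dtype=float)
                vb = np.asarray(referenced[gb].md_oa_index, dtype=float)
                for mod in np.unique(module_labels):
                    sel = module_labels == mod
                    res = sps.ranksums(va[sel], vb[sel])
                    rows.append(
                        {
                            "family": "module",
                            "group_a": ga,
                            "group_b": gb,
                            "module": str(mod),
                            "statistic": float(res.statistic),
                            "p": float(res.pvalue),
                            "mean_md_oa": float(va[sel].mean() - vb[sel].mean()),
                        }
                    )
    out = pd.DataFrame(rows)
    out["significant"] = False
    for fam in out["family"].unique():
        sel = out["family"] == fam
        out.loc[sel, "significant"] = fdr_bh(out.loc[sel, "p"].to_numpy(), alpha=alpha)
    return out


def viz_transform(values: np.ndarray, kind: str) -> np.ndarray:
    """Nonlinear display mapping from the 0-1 scale to a 1-100 scale.

    MV and MD map as ``100**v``; p-values map as ``100**(1 - p)`` so that
    small p-values display large.  Visualisation-only: never feed these back
    into statistics.
    """
    v = np.asarray(values, dtype=float)
    if np.any((v < 0) | (v > 1)):
        raise ValueError("viz_transform inputs must lie in [0, 1]")
    if kind in ("mv", "md"):
        return 100.0**v
    if kind == "p":
        return 100.0 ** (1.0 - v)
    raise ValueError("kind must be 'mv', 'md' or 'p'")
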