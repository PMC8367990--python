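"""Modular variability (MV) and modular dissociation (MD).

For a node *s* and two partitions *i*, *j*, let X_s(i) be the node-set of the
community containing *s* in partition *i*.  The nodal variability is

    MV_s(i, j) = 1 - (|X_s(i) & X_s(j)| / |X_s(i)|) * (|X_s(i) & X_s(j)| / |X_s(j)|)

which ranges from 0 (identical node-sets) to 1 (no overlap).  MV compares a
participant against a group consensus; MD applies the same formula to the
partitions of one participant's locally vs globally thresholded networks at
equal edge density, measuring how far the network sits from the
nearest-neighbour (segregated) connectivity regime.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._seeds import child_seeds
from .community import ConsensusError, Partition, consensus_partition, louvain_best_of
from .networks import WeightedConnectome, global_threshold, local_threshold, weighted_mask
from .stats import residualize

logger = logging.getLogger(__name__)

__all__ = [
    "NodalMetricTable",
    "ReferencedMD",
    "modular_variability",
    "nodal_mv",
    "modular_dissociation",
    "bootstrap_group_mv",
    "md_referenced",
]


@dataclass
class NodalMetricTable:
    """Long-format per-node metric values with bootstrap provenance.

    ``table`` columns: participant, group, node, value, iteration (NaN when
    the metric is not bootstrapped).
    """

    table: pd.DataFrame
    metric: str  # "mv" | "md"

    def values_matrix(self, group: Optional[str] = None) -> pd.DataFrame:
        """Participant x node matrix, averaging over bootstrap iterations.

        A participant's value at a node is the mean over the iterations in
        which that participant was sampled.
        """
        t = self.table if group is None else self.table[self.table["group"] == group]
        return t.pivot_table(index="participant", columns="node", values="value", aggfunc="mean")


@dataclass
class ReferencedMD:
    """Nodal MD referenced to the covariate-adjusted older-adult mean (MD/OA)."""

    md_oa_index: np.ndarray  # per-node MD/OA of the group of interest
    global_md_oa: float
    group: str
    reference_residual_mean: np.ndarray  # per-node E(R1), for bookkeeping
    referenced_reference_residuals: np.ndarray  # R1 - E(R1): zero mean per node


def modular_variability(community_i, community_j) -> float:
    """Nodal community-change score between two node-sets (0..1)."""
    xi, xj = set(community_i), set(community_j)
    if not xi or not xj:
        raise ValueError("community node-sets must be nonempty")
    inter = len(xi & xj)
    return 1.0 - (inter / len(xi)) * (inter / len(xj))


def nodal_mv(partition_a: Partition, partition_b: Partition) -> np.ndarray:
    """Per-node MV between two partitions of the same node set.

    Computed from the label contingency table: for node s with modules
    (a, b), MV_s = 1 - (n_ab / n_a) * (n_ab / n_b) where n_ab counts nodes
    sharing both assignments.
    """
    la, lb = partition_a.labels, partition_b.labels
    if la.size != lb.size:
        raise ValueError("partitions cover different node sets")
    ua, ia = np.unique(la, return_inverse=True)
    ub, ib = np.unique(lb, return_inverse=True)
    contingency = np.zeros((ua.size, ub.size))
    np.add.at(contingency, (ia, ib), 1)
    size_a = contingency.sum(axis=1)
    size_b = contingency.sum(axis=0)
    n_ab = contingency[ia, ib]
    return 1.0 - (n_ab / size_a[ia]) * (n_ab / size_b[ib])


def modular_dissociation(
    connectome: WeightedConnectome,
    density: float,
    seed: int = 0,
    n_runs: int = 1000,
) -> np.ndarray:
    """Per-node MD of one participant at one edge density.

    Thresholds the connectome both locally and globally at the same density,
    masks the weights, runs best-of-``n_runs`` Louvain on each (with the same
    seed stream, isolating the thresholding effect from optimiser noise), and
    returns the nodal MV between the two partitions.
    """
    local_net = local_threshold(connectome, density)
    global_net = global_threshold(connectome, density)
    part_local = louvain_best_of(weighted_mask(connectome, local_net), n_runs=n_runs, seed=seed)
    part_global = louvain_best_of(weighted_mask(connectome, global_net), n_runs=n_runs, seed=seed)
    return nodal_mv(part_local, part_global)


def bootstrap_group_mv(
    partitions_a: Sequence[Partition],
    partitions_b: Sequence[Partition],
    n_boot: int = 500,
    seed: int = 0,
    ids_a: Optional[Sequence] = None,
    ids_b: Optional[Sequence] = None,
    group_labels: tuple = ("A", "B"),
    max_retries: int = 5,
) -> tuple[NodalMetricTable, list[Partition]]:
    """Balanced bootstrapped group MV against per-iteration consensus partitions.

    At each of ``n_boot`` iterations, B participants (B = the smaller group
    size) are sampled *without replacement* from each group, the joint
    consensus of their Louvain partitions is estimated, and each sampled
    participant's nodal MV against that consensus is recorded.  The consensus
    partitions are returned for meta-consensus estimation.  Iterations whose
    consensus fails to converge are redrawn (up to ``max_retries``, logged).
    """
    b = min(len(partitions_a), len(partitions_b))
    if b < 2:
        raise ValueError("each group needs at least 2 participants")
    ids_a = list(ids_a) if ids_a is not None else [f"{group_labels[0]}{i}" for i in range(len(partitions_a))]
    ids_b = list(ids_b) if ids_b is not None else [f"{group_labels[1]}{i}" for i in range(len(partitions_b))]
    seeds = child_seeds(seed, 2 * n_boot * (max_retries + 1))
    seed_iter = iter(seeds)
    rows = []
    consensus_list: list[Partition] = []
    for it in range(n_boot):
        for attempt in range(max_retries + 1):
            s_draw, s_cons = next(seed_iter), next(seed_iter)
            rng = np.random.default_rng(s_draw)
            sel_a = rng.choice(len(partitions_a), size=b, replace=False)
            sel_b = rng.choice(len(partitions_b), size=b, replace=False)
            sample = [partitions_a[i] for i in sel_a] + [partitions_b[i] for i in sel_b]
            try:
                cons = consensus_partition(sample, seed=s_cons)
                break
            except ConsensusError:
                logger.warning("bootstrap iteration %d: consensus did not converge "
                               "(attempt %d); redrawing", it, attempt + 1)
        else:
            raise ConsensusError(f"iteration {it}: consensus failed after {max_retries} redraws")
        consensus_list.append(cons)
        for grp, sel, ids, parts in (
            (group_labels[0], sel_a, ids_a, partitions_a),
            (group_labels[1], sel_b, ids_b, partitions_b),
        ):
            for p_idx in sel:
                mv = nodal_mv(parts[p_idx], cons)
                rows.append(
                    pd.DataFrame(
                        {
                            "participant": ids[p_idx],
                            "group": grp,
                            "node": np.arange(mv.size),
                            "value": mv,
                            "iteration": it,
                        }
                    )
                )
    table = pd.concat(rows, ignore_index=True)
    return NodalMetricTable(table, metric="mv"), consensus_list


def md_referenced(
    md_group: np.ndarray,
    md_oa: np.ndarray,
    covariates: pd.DataFrame,
    group: str = "G2",
    demean_age_within_group: bool = False,
) -> ReferencedMD:
    """Reference a group's nodal MD to the covariate-adjusted OA mean.

    Per node, the OA participants' MD values (rows of ``md_oa``) and the
    group-of-interest values (rows of ``md_group``) are concatenated
    (``[G1 G2]`` with G1 = OA), residualised on the covariates of no interest
    (which must not encode group membership), and referenced by subtracting
    the OA residual mean: ``[R1 R2] - E(R1)``.  The per-node MD/OA index is
    the group mean of the referenced values, i.e. mean(R2) - mean(R1).

    ``covariates`` rows must correspond to the concatenated participants
    (OA first); a ``group`` column, if present, is used only for within-group
    age demeaning, never as a regressor.
    """
    md_oa = np.atleast_2d(np.asarray(md_oa, dtype=float))
    md_group = np.atleast_2d(np.asarray(md_group, dtype=float))
    if md_oa.shape[1] != md_group.shape[1]:
        raise ValueError("node counts differ between groups")
    n1 = md_oa.shape[0]
    if len(covariates) != n1 + md_group.shape[0]:
        raise ValueError("covariate rows must match concatenated participants")
    values = np.vstack([md_oa, md_group])
    resid = residualize(values, covariates, demean_age_within_group=demean_age_within_group)
    r1, r2 = resid[:n1], resid[n1:]
    e_r1 = r1.mean(axis=0)
    index = r2.mean(axis=0) - e_r1
    return ReferencedMD(
        md_oa_index=index,
        global_md_oa=float(index.mean()),
        group=group,
        reference_residual_mean=e_r1,
        referenced_reference_residuals=r1 - e_r1,
    )
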