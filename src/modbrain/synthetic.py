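"""Synthetic cohorts with planted modular structure and distance decay.

The generator emulates the statistical structure the analysis assumes in
real resting-state |r| matrices: symmetric nonnegative weights with zero
diagonal, a planted block-modular community structure (7-9 communities over
~100-451 nodes), monotone decay of edge weight with Euclidean inter-node
distance with group-specific slope and intercept, participant-level
partition heterogeneity (jitter), and six-parameter rigid-body motion
traces with a controllable mean framewise displacement.

The weight model is additive: ``w_ij = base(block) + intercept_g -
slope_g * d_ij + noise``, clipped to [0, 1], where ``base`` is the
within- or between-module level under the participant's own (jittered)
partition.  This is the simplest model that exhibits both the distance-decay
and the modular structure the pipeline measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.distance import squareform, pdist

from ._seeds import child_seeds
from .networks import WeightedConnectome
from .stats import MotionTrace, framewise_displacement

__all__ = [
    "SpatialEmbedding",
    "CohortSpec",
    "Participant",
    "SyntheticCohort",
    "generate_embedding",
    "generate_cohort",
    "generate_motion_trace",
    "write_cohort",
]

BRAIN_RADIUS_MM = 70.0  # nodes sampled in a ball of brain-scale radius


@dataclass
class SpatialEmbedding:
    """3-D node positions (mm) and their Euclidean distance matrix."""

    coordinates: np.ndarray
    pairwise_distance: np.ndarray = field(init=False)

    def __post_init__(self):
        c = np.asarray(self.coordinates, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3:
            raise ValueError("coordinates must be (n_nodes, 3)")
        self.coordinates = c
        self.pairwise_distance = squareform(pdist(c))


def generate_embedding(n_nodes: int, seed: int, radius: float = BRAIN_RADIUS_MM) -> SpatialEmbedding:
    """Sample node coordinates uniformly inside a ball of the given radius."""
    if n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    rng = np.random.default_rng(seed)
    pts = np.empty((0, 3))
    while pts.shape[0] < n_nodes:
        cand = rng.uniform(-1.0, 1.0, size=(4 * n_nodes, 3))
        cand = cand[np.linalg.norm(cand, axis=1) <= 1.0]
        pts = np.vstack([pts, cand])
    return SpatialEmbedding(pts[:n_nodes] * radius)


@dataclass
class CohortSpec:
    """Study conditions for a synthetic two-group (or multi-group) cohort.

    Defaults emulate a young-adult (YA) vs older-adult (OA) comparison: equal
    block levels for both groups, a steeper distance-decay slope and slightly
    higher partition jitter in OA, ages drawn 20-40 (YA) and 60-80 (OA),
    and a higher in-scanner motion level in OA.  Slopes are in strength per
    mm (positive slope = decay with distance).
    """

    n_nodes: int = 100
    n_modules: int = 8
    planted_partition: Optional[np.ndarray] = None
    group_sizes: dict = field(default_factory=lambda: {"YA": 15, "OA": 15})
    within_module_mean: float = 0.6
    between_module_mean: float = 0.1
    distance_decay_slope: dict = field(default_factory=lambda: {"YA": 0.0015, "OA": 0.0020})
    distance_decay_intercept: dict = field(default_factory=lambda: {"YA": 0.2, "OA": 0.2})
    partition_jitter: dict = field(default_factory=lambda: {"YA": 0.05, "OA": 0.08})
    noise_sd: float = 0.05
    age_range: dict = field(default_factory=lambda: {"YA": (20, 40), "OA": (60, 80)})
    sex_proportion: float = 0.5  # probability of 'F'
    study_labels: tuple = ("study1",)
    motion_level: dict = field(default_factory=lambda: {"YA": 0.15, "OA": 0.25})
    n_volumes: int = 128
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.between_module_mean <= 1.0 and 0.0 <= self.within_module_mean <= 1.0):
            raise ValueError("weight levels must lie in [0, 1]")
        if self.within_module_mean <= self.between_module_mean:
            raise ValueError("within_module_mean must exceed between_module_mean")
        if not 0.0 <= self.sex_proportion <= 1.0:
            raise ValueError("sex_proportion must be a probability")
        for g, size in self.group_sizes.items():
            if size < 2:
                raise ValueError(f"group {g!r} must have at least 2 participants")
        for g, j in self.partition_jitter.items():
            if not 0.0 <= j <= 1.0:
                raise ValueError(f"partition_jitter[{g!r}] must be a probability")
        for g in self.group_sizes:
            cap = abs(self.distance_decay_intercept[g]) + self.within_module_mean
            if cap > 0.95:
                raise ValueError(
                    "|intercept| + within_module_mean must be <= 0.95 "
                    "(clipping would distort the planted means)"
                )
        if self.planted_partition is None:
            self.planted_partition = np.arange(self.n_nodes) % self.n_modules
        else:
            self.planted_partition = np.asarray(self.planted_partition, dtype=int)
            if self.planted_partition.size != self.n_nodes:
                raise ValueError("planted_partition must label every node")
            self.n_modules = np.unique(self.planted_partition).size


@dataclass
class Participant:
    id: str
    group: str
    connectome: WeightedConnectome
    age: float
    sex: str
    study: str
    motion: MotionTrace
    mean_fd: float
    partition: np.ndarray  # the participant's own (jittered) planted partition


@dataclass
class SyntheticCohort:
    participants: list
    embedding: SpatialEmbedding
    spec: CohortSpec

    @property
    def truth_partition(self) -> np.ndarray:
        return self.spec.planted_partition

    def group(self, label: str) -> list:
        return [p for p in self.participants if p.group == label]

    def covariate_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [p.id for p in self.participants],
                "group": [p.group for p in self.participants],
                "age": [p.age for p in self.participants],
                "sex": [p.sex for p in self.participants],
                "study": [p.study for p in self.participants],
                "mean_fd": [p.mean_fd for p in self.participants],
            }
        )


def _jitter_partition(partition: np.ndarray, jitter: float, rng: np.random.Generator) -> np.ndarray:
    """Reassign each node to a uniformly random *other* module w.p. ``jitter``."""
    out = partition.copy()
    modules = np.unique(partition)
    if modules.size < 2 or jitter == 0:
        return out
    flips = rng.random(out.size) < jitter
    for idx in np.nonzero(flips)[0]:
        others = modules[modules != out[idx]]
        out[idx] = rng.choice(others)
    return out


def generate_motion_trace(n_volumes: int, target_mean_fd: float, seed: int) -> MotionTrace:
    """Random-walk rigid-body parameters with an exact target mean FD.

    Gaussian per-volume increments (rotations scaled to contribute comparable
    arc length on the 65-mm sphere) are rescaled so that the realised mean
    framewise displacement equals ``target_mean_fd`` exactly; a target of 0
    yields constant parameters.
    """
    if n_volumes < 2:
        raise ValueError("need at least 2 volumes")
    if target_mean_fd < 0:
        raise ValueError("target_mean_fd must be nonnegative")
    if target_mean_fd == 0:
        zeros = np.zeros((n_volumes, 3))
        return MotionTrace(translations=zeros, rotations=zeros.copy())
    rng = np.random.default_rng(seed)
    d_trans = rng.normal(0.0, 1.0, size=(n_volumes - 1, 3))
    d_rot = rng.normal(0.0, 1.0 / 65.0, size=(n_volumes - 1, 3))
    trace = MotionTrace(
        translations=np.vstack([np.zeros(3), np.cumsum(d_trans, axis=0)]),
        rotations=np.vstack([np.zeros(3), np.cumsum(d_rot, axis=0)]),
    )
    realized = framewise_displacement(trace).mean_fd
    scale = target_mean_fd / realized  # FD is linear in the parameter deltas
    return MotionTrace(translations=trace.translations * scale, rotations=trace.rotations * scale)


def _participant_connectome(
    spec: CohortSpec,
    embedding: SpatialEmbedding,
    partition: np.ndarray,
    group: str,
    rng: np.random.Generator,
) -> WeightedConnectome:
    same = np.equal.outer(partition, partition)
    base = np.where(same, spec.within_module_mean, spec.between_module_mean)
    slope = spec.distance_decay_slope[group]
    intercept = spec.distance_decay_intercept[group]
    w = base + intercept - slope * embedding.pairwise_distance
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=w.shape)
        noise = np.triu(noise, 1)
        w = w + noise + noise.T
    w = np.clip(w, 0.0, 1.0)
    np.fill_diagonal(w, 0.0)
    w = (w + w.T) / 2.0
    return WeightedConnectome(w, coordinates=embedding.coordinates)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a deterministic synthetic cohort from a :class:`CohortSpec`.

    Every participant gets a jittered copy of the planted partition, a
    connectome built from the additive block + distance-decay + noise model
    under that partition, covariates drawn from the spec distributions, and a
    motion trace at the group's mean-FD level (uniformly varied by +/-50%
    between participants).
    """
    master, embed_seed = child_seeds(spec.seed, 2)
    embedding = generate_embedding(spec.n_nodes, embed_seed)
    n_total = sum(spec.group_sizes.values())
    seeds = child_seeds(master, 2 * n_total)
    participants = []
    idx = 0
    for group, size in spec.group_sizes.items():
        for k in range(size):
            rng = np.random.default_rng(seeds[2 * idx])
            partition = _jitter_partition(spec.planted_partition, spec.partition_jitter[group], rng)
            conn = _participant_connectome(spec, embedding, partition, group, rng)
            lo, hi = spec.age_range[group]
            age = float(rng.uniform(lo, hi))
            sex = "F" if rng.random() < spec.sex_proportion else "M"
            study = str(spec.study_labels[rng.integers(len(spec.study_labels))])
            target_fd = spec.motion_level[group] * float(rng.uniform(0.5, 1.5))
            motion = generate_motion_trace(spec.n_volumes, target_fd, seeds[2 * idx + 1])
            participants.append(
                Participant(
                    id=f"sub-{group}-{k:03d}",
                    group=group,
                    connectome=conn,
                    age=age,
                    sex=sex,
                    study=study,
                    motion=motion,
                    mean_fd=framewise_displacement(motion).mean_fd,
                    partition=partition,
                )
            )
            idx += 1
    return SyntheticCohort(participants=participants, embedding=embedding, spec=spec)


def write_cohort(cohort: SyntheticCohort, outdir, delimiter: str = ",") -> None:
    """Persist a cohort as the plain-text layout the pipeline consumes.

    Writes one headerless square matrix file per participant
    (``matrices/<id>.csv``), one motion-parameter file per participant
    (``motion/<id>.par``, six whitespace-separated columns, rotations first),
    ``participants.csv`` (id, group, age, sex, study, mean_fd), ``nodes.csv``
    (label, x, y, z), the planted-partition truth file and a YAML spec echo.
    """
    out = Path(outdir)
    (out / "matrices").mkdir(parents=True, exist_ok=True)
    (out / "motion").mkdir(parents=True, exist_ok=True)
    for p in cohort.participants:
        np.savetxt(out / "matrices" / f"{p.id}.csv", p.connectome.weights,
                   delimiter=delimiter, fmt="%.10g")
        params = np.hstack([p.motion.rotations, p.motion.translations])
        np.savetxt(out / "motion" / f"{p.id}.par", params, fmt="%.10g")
    cohort.covariate_table().to_csv(out / "participants.csv", index=False, float_format="%.10g")
    coords = cohort.embedding.coordinates
    pd.DataFrame(
        {
            "label": [str(i) for i in range(coords.shape[0])],
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
        }
    ).to_csv(out / "nodes.csv", index=False, float_format="%.10g")
    pd.DataFrame(
        {"node_label": np.arange(cohort.truth_partition.size), "module_id": cohort.truth_partition}
    ).to_csv(out / "truth_partition.csv", index=False)
    spec = cohort.spec
    echo = {
        "n_nodes": spec.n_nodes,
        "n_modules": int(spec.n_modules),
        "group_sizes": dict(spec.group_sizes),
        "within_module_mean": spec.within_module_mean,
        "between_module_mean": spec.between_module_mean,
        "distance_decay_slope": dict(spec.distance_decay_slope),
        "distance_decay_intercept": dict(spec.distance_decay_intercept),
        "partition_jitter": dict(spec.partition_jitter),
        "noise_sd": spec.noise_sd,
        "age_range": {g: list(r) for g, r in spec.age_range.items()},
        "sex_proportion": spec.sex_proportion,
        "study_labels": list(spec.study_labels),
        "motion_level": dict(spec.motion_level),
        "n_volumes": spec.n_volumes,
        "seed": spec.seed,
    }
    with open(out / "spec.yaml", "w") as fh:
        yaml.safe_dump(echo, fh, sort_keys=False)
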