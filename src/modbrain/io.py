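"""Plain-text I/O for connectomes, partitions, networks and motion files."""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .networks import BinaryNetwork, WeightedConnectome

__all__ = [
    "load_connectome",
    "save_connectome",
    "load_motion_params",
    "load_partition",
    "save_partition",
    "save_binary_network",
    "load_binary_network",
    "load_node_metadata",
]

_ASYM_TOL = 1e-6


def _detect_header(path: Path, delimiter: Optional[str]) -> int:
    """Rows to skip: 1 if the first row does not parse as numbers, else 0."""
    with open(path) as fh:
        first = fh.readline()
    tokens = first.strip().split(delimiter) if delimiter else first.split()
    try:
        [float(t) for t in tokens if t != ""]
        return 0
    except ValueError:
        return 1


def load_connectome(
    path,
    delimiter: Optional[str] = None,
    node_labels=None,
    coordinates=None,
) -> WeightedConnectome:
    """Read a square correlation matrix file into a :class:`WeightedConnectome`.

    Applies the pipeline's weight conventions: the absolute value of the
    correlations is taken (connection strength, not direction), the diagonal
    is zeroed, and symmetry is enforced by averaging with the transpose
    (warning if the raw asymmetry exceeds 1e-6).  Headerless delimited text
    is the default dialect; a non-numeric first row is auto-detected and
    skipped.  ``delimiter=None`` splits on any whitespace or comma.
    """
    path = Path(path)
    if delimiter is None:
        with open(path) as fh:
            delimiter = "," if "," in fh.readline() else None
    skip = _detect_header(path, delimiter)
    mat = np.loadtxt(path, delimiter=delimiter, skiprows=skip, ndmin=2)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{path.name}: matrix is {mat.shape[0]}x{mat.shape[1]}, not square")
    asym = np.abs(mat - mat.T).max()
    if asym > _ASYM_TOL:
        warnings.warn(f"{path.name}: asymmetry up to {asym:.3g} symmetrised by averaging")
    mat = np.abs((mat + mat.T) / 2.0)
    np.fill_diagonal(mat, 0.0)
    return WeightedConnectome(mat, node_labels=node_labels, coordinates=coordinates)


def save_connectome(connectome: WeightedConnectome, path, delimiter: str = ",") -> None:
    np.savetxt(path, connectome.weights, delimiter=delimiter, fmt="%.17g")


def load_motion_params(path, ordering: str = "rotations-first"):
    """Read a six-column rigid-body motion parameter file.

    Whitespace- or comma-delimited.  ``ordering`` declares the column
    convention: ``"rotations-first"`` (FSL-FLIRT: 3 rotations in radians then
    3 translations in mm) or ``"translations-first"``.
    """
    from .stats import MotionTrace

    path = Path(path)
    with open(path) as fh:
        delimiter = "," if "," in fh.readline() else None
    params = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    if params.shape[1] != 6:
        raise ValueError(f"{path.name}: expected 6 motion parameter columns, got {params.shape[1]}")
    if ordering == "rotations-first":
        rot, trans = params[:, :3], params[:, 3:]
    elif ordering == "translations-first":
        trans, rot = params[:, :3], params[:, 3:]
    else:
        raise ValueError("ordering must be 'rotations-first' or 'translations-first'")
    return MotionTrace(translations=trans, rotations=rot)


def save_partition(partition, path, node_labels=None) -> None:
    labels = node_labels if node_labels is not None else np.arange(partition.labels.size)
    pd.DataFrame({"node_label": labels, "module_id": partition.labels}).to_csv(path, index=False)


def load_partition(path):
    from .community import Partition

    df = pd.read_csv(path)
    return Partition(df["module_id"].to_numpy(dtype=int))


def save_binary_network(network: BinaryNetwork, path) -> None:
    """Edge list CSV (i, j with i < j, 0-based) plus a JSON sidecar header."""
    path = Path(path)
    i, j = np.nonzero(np.triu(network.adjacency, 1))
    pd.DataFrame({"i": i, "j": j}).to_csv(path, index=False)
    sidecar = {
        "method": network.method,
        "requested_density": network.requested_density,
        "realized_density": network.realized_density,
        "n_nodes": int(network.adjacency.shape[0]),
        "threshold_tau": network.threshold_tau,
        "k_base": network.k_base,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_binary_network(path) -> BinaryNetwork:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    df = pd.read_csv(path)
    n = sidecar["n_nodes"]
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[df["i"], df["j"]] = 1
    adj |= adj.T
    net = BinaryNetwork(adj, sidecar["method"], sidecar["requested_density"])
    net.threshold_tau = sidecar.get("threshold_tau")
    net.k_base = sidecar.get("k_base")
    return net


def load_node_metadata(path) -> pd.DataFrame:
    """Node metadata CSV with columns label, x, y, z."""
    df = pd.read_csv(path)
    missing = {"label", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"node metadata missing columns: {sorted(missing)}")
    return df
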