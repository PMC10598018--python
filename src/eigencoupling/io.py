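"""Plain-text readers and writers for all pipeline artifacts.

Matrices are tab-delimited with a header row of region IDs, coordinates and
labels are small CSV/TSV tables, and ground truth / run manifests are JSON.
Everything round-trips exactly enough for downstream analysis (floats are
written with repr-level precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import FunctionalConnectome, StructuralConnectome
from .synthetic import SyntheticGroundTruth

__all__ = [
    "write_matrix", "read_matrix",
    "write_structural", "read_structural",
    "write_functional", "read_functional",
    "write_coordinates", "read_coordinates",
    "write_labels", "read_labels",
    "write_ground_truth", "read_ground_truth",
    "write_coupling", "read_coupling",
    "write_json", "read_json",
]

_FLOAT_FMT = "%.17g"


def write_matrix(path, matrix: np.ndarray, region_ids) -> None:
    df = pd.DataFrame(np.asarray(matrix, dtype=float), columns=list(region_ids))
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_matrix(path) -> tuple[np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return df.to_numpy(dtype=float), tuple(df.columns)


def write_structural(path, sc: StructuralConnectome) -> None:
    write_matrix(path, sc.adjacency, sc.region_ids)


def read_structural(path, coordinates_path=None, labels_path=None) -> StructuralConnectome:
    A, ids = read_matrix(path)
    coords = None
    labels = None
    if coordinates_path is not None:
        coords, coord_ids = read_coordinates(coordinates_path)
        if coord_ids != ids:
            raise ValueError("coordinate region ids do not match matrix header")
    if labels_path is not None:
        label_map = read_labels(labels_path)
        labels = tuple(label_map[r] for r in ids)
    return StructuralConnectome(adjacency=A, region_ids=ids, coordinates=coords, labels=labels)


def write_functional(path, fc: FunctionalConnectome) -> None:
    write_matrix(path, fc.matrix, fc.region_ids)


def read_functional(path) -> FunctionalConnectome:
    F, ids = read_matrix(path)
    return FunctionalConnectome(matrix=F, region_ids=ids)


def write_coordinates(path, coordinates: np.ndarray, region_ids) -> None:
    df = pd.DataFrame(np.asarray(coordinates, dtype=float), columns=["x", "y", "z"])
    df.insert(0, "region_id", list(region_ids))
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_coordinates(path) -> tuple[np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path, float_precision="round_trip")
    return df[["x", "y", "z"]].to_numpy(dtype=float), tuple(df["region_id"].astype(str))


def write_labels(path, labels, region_ids) -> None:
    df = pd.DataFrame({"region_id": list(region_ids), "network_name": list(labels)})
    df.to_csv(path, index=False)


def read_labels(path) -> dict[str, str]:
    df = pd.read_csv(path)
    return dict(zip(df["region_id"].astype(str), df["network_name"].astype(str)))


def write_ground_truth(path, gt: SyntheticGroundTruth) -> None:
    payload = {
        "band_weights": gt.band_weights.tolist(),
        "planted_gradient": gt.planted_gradient.tolist(),
        "noise_sigma": gt.noise_sigma,
        "seed": gt.seed,
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path) -> SyntheticGroundTruth:
    payload = json.loads(Path(path).read_text())
    return SyntheticGroundTruth(
        band_weights=np.asarray(payload["band_weights"], dtype=float),
        planted_gradient=np.asarray(payload["planted_gradient"], dtype=float),
        noise_sigma=float(payload["noise_sigma"]),
        seed=int(payload["seed"]),
    )


def write_coupling(path, coupling_R: np.ndarray, region_ids) -> None:
    df = pd.DataFrame({"region_id": list(region_ids),
                       "R": np.asarray(coupling_R, dtype=float)})
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_coupling(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
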