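"""File readers/writers and element alignment.

Tabular interfaces are deliberately simple text formats: two-column label
tables (element id, label), dense CSV/TSV embeddings or MatrixMarket
sparse matrices with a row-name sidecar, (id, x, y) coordinate tables and
membership CSVs whose header names the categories.  When several inputs
carry element ids they are joined on id; otherwise file order aligns
them.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .fuzzy import FuzzyPartition
from .partitions import HardPartition

logger = logging.getLogger("clustival")

#: tokens treated as missing labels and excluded pairwise
NA_TOKENS = {"NA", "NaN", "nan", ""}


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def read_labels(path) -> pd.Series:
    """Two-column (element_id, label) table -> Series indexed by id."""
    df = _read_table(path)
    if df.shape[1] < 2:
        raise InputError(f"{path}: expected two columns (element_id, label)")
    s = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)
    if s.index.duplicated().any():
        raise InputError(f"{path}: duplicated element ids")
    return s


def align_labels(truth: pd.Series, pred: pd.Series) -> tuple[HardPartition, HardPartition, list]:
    """Join two label series on element id and drop missing labels.

    Raises on id mismatch; NA-labeled elements are excluded pairwise with
    a logged count.  Returns the two partitions plus the kept ids.
    """
    missing = set(truth.index) ^ set(pred.index)
    if missing:
        raise InputError(f"element ids do not match between truth and prediction: "
                         f"{sorted(missing)[:10]}{'...' if len(missing) > 10 else ''}")
    pred = pred.reindex(truth.index)
    keep = ~(truth.isin(NA_TOKENS) | pred.isin(NA_TOKENS) | truth.isna() | pred.isna())
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("excluded %d element(s) with missing labels", n_dropped)
    ids = list(truth.index[keep])
    return (HardPartition.from_labels(truth[keep].tolist()),
            HardPartition.from_labels(pred[keep].tolist()), ids)


def read_memberships(path) -> FuzzyPartition:
    """Membership CSV (header = category names; optional leading id col)."""
    df = pd.read_csv(path)
    first = df.columns[0].lower()
    if first in ("id", "element_id", "spot_id", "cell_id"):
        df = df.set_index(df.columns[0])
    W = df.to_numpy(dtype=float)
    bad = np.flatnonzero(np.abs(W.sum(axis=1) - 1.0) > 1e-6)
    if len(bad):
        raise InputError(f"{path}: membership row {bad[0]} does not sum to 1")
    return FuzzyPartition(W / W.sum(axis=1, keepdims=True), tuple(df.columns))


def read_embedding(path, rownames=None) -> np.ndarray:
    """Dense CSV/TSV (rows = cells) or MatrixMarket MTX embedding.

    For MTX, `rownames` may point to a one-column text file naming the
    rows (checked for length agreement).
    """
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        from scipy.io import mmread
        X = np.asarray(mmread(path).todense(), dtype=float)
        if rownames is not None:
            names = [ln.strip() for ln in Path(rownames).read_text().splitlines()
                     if ln.strip()]
            if len(names) != X.shape[0]:
                raise InputError(f"{rownames}: {len(names)} row names for "
                                 f"{X.shape[0]} matrix rows")
        return X
    df = _read_table(path)
    if not df.columns[0].replace(".", "", 1).lstrip("-").isdigit():
        first = df.columns[0].lower()
        if first in ("id", "element_id", "spot_id", "cell_id"):
            df = df.set_index(df.columns[0])
    return df.to_numpy(dtype=float)


def read_edge_list(path, n: int | None = None):
    """Whitespace/TSV edge list (i, j[, weight]) -> NeighborGraph.

    Node ids are 0-based integers; n defaults to max id + 1.
    """
    from .graph import NeighborGraph
    edges, weights = [], []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts or parts[0].startswith("#"):
            continue
        if len(parts) < 2:
            raise InputError(f"{path}: malformed edge line {line!r}")
        i, j = int(parts[0]), int(parts[1])
        edges.append((i, j))
        weights.append(float(parts[2]) if len(parts) > 2 else 1.0)
    if n is None:
        n = max(max(i, j) for i, j in edges) + 1 if edges else 0
    return NeighborGraph.from_edges(n, edges, weights)


def read_coords(path) -> tuple[list, np.ndarray]:
    """(spot_id, x, y) table -> (ids, n x 2 array)."""
    df = _read_table(path)
    if df.shape[1] < 3:
        raise InputError(f"{path}: expected columns (spot_id, x, y)")
    ids = df.iloc[:, 0].tolist()
    xy = df.iloc[:, 1:3].to_numpy(dtype=float)
    return ids, xy


def write_report(results: dict, out, *, config: dict | None = None, seed=None) -> dict:
    """Serialize a results dict (with config, version and seed) to JSON."""
    from . import __version__

    def clean(v):
        if isinstance(v, dict):
            return {str(k): clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        if isinstance(v, np.ndarray):
            return [clean(x) for x in v.tolist()]
        if isinstance(v, (np.floating, float)):
            return None if np.isnan(v) else float(v)
        if isinstance(v, (np.integer, int)):
            return int(v)
        return v

    payload = {"package": "clustival", "version": __version__,
               "seed": seed, "config": clean(config or {}), "results": clean(results)}
    validate_report(payload)
    if out is not None:
        Path(out).write_text(json.dumps(payload, indent=2) + "\n")
    return payload


def report_schema() -> dict:
    """The JSON schema every report validates against (shipped with the
    package)."""
    schema_path = Path(__file__).parent / "report_schema.json"
    return json.loads(schema_path.read_text())


def validate_report(payload: dict) -> None:
    """Structural validation of a report against the shipped schema.

    A lightweight hand-rolled check (no external validator dependency):
    required keys, key whitelist, and basic types.
    """
    schema = report_schema()
    for key in schema["required"]:
        if key not in payload:
            raise InputError(f"report missing required key {key!r}")
    allowed = set(schema["properties"])
    extra = set(payload) - allowed
    if extra:
        raise InputError(f"report has unexpected keys: {sorted(extra)}")
    if payload["package"] != "clustival":
        raise InputError("report package field must be 'clustival'")
    if not isinstance(payload["version"], str):
        raise InputError("report version must be a string")
    if not isinstance(payload["config"], dict) or not isinstance(payload["results"], dict):
        raise InputError("report config and results must be objects")
    seed = payload.get("seed")
    if seed is not None and not isinstance(seed, int):
        raise InputError("report seed must be an integer or null")
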