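"""Plain-text file formats: connectome matrices, edge vectors, partitions.

All text I/O is 1-based in node and edge ids (matching common atlas
conventions); internal arrays are 0-based.  Floats are serialized with 17
significant digits so write-then-read round-trips are exact.

Formats
-------
* connectome matrix — whitespace- or comma-delimited ``V x V`` numeric text;
  must be symmetric (diagonal ignored);
* edge vector — two columns (1-based canonical edge index, value), optional
  header line;
* partition — two columns (1-based node id, community label), optional
  header; labels may be strings or integers and are preserved verbatim;
* config — YAML (JSON accepted interchangeably) with a ``schema`` key;
* run manifest — JSON with config echo, seeds, version, timestamps and
  input digests.
"""

from __future__ import annotations

import hashlib
import json
import re
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from .core import (EdgeIndexMap, EdgeVector, FormatError, PairedSample,
                   Partition, build_edge_index, devectorize_upper,
                   vectorize_upper)

__all__ = [
    "read_connectome", "write_connectome", "write_edge_vector",
    "read_partition", "write_partition", "load_config", "make_manifest",
    "write_manifest", "write_population", "read_population",
]

_FLOAT_FMT = "%.17g"


def _parse_numeric_table(path: Path) -> np.ndarray:
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = re.split(r"[,\s]+", line)
        try:
            rows.append([float(x) for x in fields])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric entry ({exc})") from exc
    if not rows:
        raise FormatError(f"{path}: empty file")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(f"{path}: ragged rows (widths {sorted(widths)})")
    return np.array(rows)


def read_connectome(path, fmt: str = "matrix",
                    index: EdgeIndexMap | None = None) -> EdgeVector:
    """Read a connectome as a canonical edge vector.

    ``fmt='matrix'``: square symmetric numeric text file.
    ``fmt='edge_vector'``: two columns (1-based edge index, value); a header
    line is skipped if present; ``index`` may pin the expected edge count.
    """
    path = Path(path)
    if fmt == "matrix":
        mat = _parse_numeric_table(path)
        v = mat.shape[0]
        if mat.shape != (v, v):
            raise FormatError(f"{path}: expected a square matrix, got {mat.shape}")
        idx = index or build_edge_index(v)
        return vectorize_upper(mat, idx)
    if fmt == "edge_vector":
        raw = _read_two_column(path)
        try:
            ids = np.array([int(a) for a, _ in raw])
            vals = np.array([float(b) for _, b in raw])
        except ValueError as exc:
            raise FormatError(f"{path}: bad edge-vector entry ({exc})") from exc
        n_edges = ids.size
        if index is None:
            # E = V(V-1)/2 must invert to an integer node count
            v = (1 + np.sqrt(1 + 8 * n_edges)) / 2
            if abs(v - round(v)) > 1e-9:
                raise FormatError(
                    f"{path}: {n_edges} edges is not V(V-1)/2 for any integer V"
                )
            index = build_edge_index(int(round(v)))
        if n_edges != index.n_edges:
            raise FormatError(
                f"{path}: {n_edges} edges, expected {index.n_edges}"
            )
        if sorted(ids.tolist()) != list(range(1, n_edges + 1)):
            raise FormatError(f"{path}: edge ids must be exactly 1..{n_edges}")
        out = np.empty(n_edges)
        out[ids - 1] = vals
        return EdgeVector(out, index)
    raise FormatError(f"unknown connectome format {fmt!r}")


def write_connectome(path, edges: EdgeVector, fmt: str = "matrix") -> None:
    path = Path(path)
    if fmt == "matrix":
        np.savetxt(path, devectorize_upper(edges), fmt=_FLOAT_FMT, delimiter=",")
    elif fmt == "edge_vector":
        write_edge_vector(path, edges.values)
    else:
        raise FormatError(f"unknown connectome format {fmt!r}")


def write_edge_vector(path, values: np.ndarray, header: str = "edge_id,value") -> None:
    values = np.asarray(values)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for e, val in enumerate(values, start=1):
            fh.write(f"{e},{_FLOAT_FMT % val}\n")


def _read_two_column(path: Path) -> list[tuple[str, str]]:
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = re.split(r"[,\s]+", line)
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected two columns, got {len(fields)}")
        out.append((fields[0], fields[1]))
    if not out:
        raise FormatError(f"{path}: empty file")
    # tolerate a single header line
    try:
        int(out[0][0])
    except ValueError:
        out = out[1:]
        if not out:
            raise FormatError(f"{path}: no data rows")
    return out


def read_partition(path) -> Partition:
    """Read a two-column (1-based node id, community label) partition file."""
    raw = _read_two_column(Path(path))
    nodes: dict[int, str] = {}
    for a, b in raw:
        try:
            nid = int(a)
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer node id {a!r}") from exc
        if nid in nodes:
            raise FormatError(f"{path}: duplicate node id {nid}")
        nodes[nid] = b
    v = max(nodes)
    missing = set(range(1, v + 1)) - set(nodes)
    if missing:
        raise FormatError(f"{path}: missing node id(s) {sorted(missing)[:5]}")
    return Partition.from_labels([nodes[i] for i in range(1, v + 1)])


def write_partition(path, partition: Partition) -> None:
    with open(path, "w") as fh:
        fh.write("node_id,community\n")
        for i, code in enumerate(partition.node_community, start=1):
            fh.write(f"{i},{partition.labels[code]}\n")


def load_config(path) -> dict:
    """Load a YAML (or JSON) configuration file."""
    text = Path(path).read_text()
    try:
        cfg = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise FormatError(f"{path}: cannot parse config ({exc})") from exc
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_manifest(config: dict, seeds: dict | None = None,
                  inputs: list | None = None) -> dict:
    from . import __version__

    return {
        "schema": "connbench-manifest-1",
        "software_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": config,
        "seeds": seeds or {},
        "input_digests": {str(p): _digest(Path(p)) for p in (inputs or [])},
    }


def write_manifest(path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def write_population(outdir, population: PairedSample) -> None:
    """Write per-subject edge-vector files (task, rest1, rest2) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    conditions = {"task": population.condition_a, "rest1": population.condition_b}
    if population.has_null_runs:
        conditions["rest2"] = population.null_run_b
    for name, arr in conditions.items():
        for s in range(population.n_subjects):
            write_edge_vector(outdir / f"sub-{s + 1:04d}_{name}.csv", arr[s])


def read_population(indir, index: EdgeIndexMap | None = None) -> PairedSample:
    """Read a population directory written by :func:`write_population`."""
    indir = Path(indir)
    task_files = sorted(indir.glob("sub-*_task.csv"))
    if not task_files:
        raise FormatError(f"{indir}: no sub-*_task.csv files found")

    def _stack(name: str) -> np.ndarray | None:
        files = sorted(indir.glob(f"sub-*_{name}.csv"))
        if not files:
            return None
        vecs = [read_connectome(f, "edge_vector", index) for f in files]
        return np.stack([v.values for v in vecs])

    task = _stack("task")
    rest1 = _stack("rest1")
    if rest1 is None or len(rest1) != len(task):
        raise FormatError(f"{indir}: task and rest1 files do not pair up")
    rest2 = _stack("rest2")
    idx = index or read_connectome(task_files[0], "edge_vector").index
    return PairedSample(task, rest1, idx, null_run_b=rest2)
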