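"""Portable matrix artifacts: TSV body with a JSON metadata header line.

Every persisted matrix (node embeddings, encodings) starts with a single
``#`` comment line carrying a JSON object (node order hash, config, input
hashes) followed by one tab-separated row per node. Artifacts are
self-describing and loadable without the objects that produced them.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np


def content_hash(path) -> str:
    """sha256 of a file's bytes."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(obj) -> str:
    """sha256 of a canonical-JSON rendering of a config mapping."""
    blob = json.dumps(obj, sort_keys=True, separators=(",", ":")).encode()
    return hashlib.sha256(blob).hexdigest()


def save_matrix(path, matrix: np.ndarray, meta: dict) -> None:
    path = Path(path)
    meta = dict(meta)
    meta["shape"] = list(matrix.shape)
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta, sort_keys=True) + "\n")
        np.savetxt(fh, matrix, fmt="%.12g", delimiter="\t")


def load_matrix(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# "):
            raise ValueError(f"{path}: missing metadata header line")
        meta = json.loads(header[2:])
        matrix = np.loadtxt(fh, delimiter="\t", ndmin=2)
    expect = tuple(meta.get("shape", matrix.shape))
    if tuple(matrix.shape) != expect:
        raise ValueError(f"{path}: shape {matrix.shape} != header {expect}")
    return matrix, meta
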