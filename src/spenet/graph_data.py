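"""Interactome, disease-subgraph and disease-pair containers with TSV I/O.

The protein-interaction network is an undirected, unweighted graph whose
nodes are gene identifiers. Diseases are node subsets (possibly
overlapping). Disease pairs carry a clinical relative-risk (RR) score that
is binarised under one of two conventions:

* ``RR0`` — a pair is comorbid (label 1) iff RR > 0;
* ``RR1`` — a pair is comorbid (label 1) iff RR >= 1.

All matrices produced downstream share one node index space: the sorted
order of the gene-ID strings, fixed at load time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

LABEL_MODES = ("RR0", "RR1")


@dataclass(frozen=True)
class Interactome:
    """Undirected graph over gene IDs with a fixed, sorted node index space.

    Attributes
    ----------
    node_ids : tuple of str
        Gene identifiers, sorted; position defines the node index used by
        every matrix in the package.
    edges : frozenset of (int, int)
        Unordered node-index pairs ``(i, j)`` stored with ``i < j``;
        no self-loops, no duplicates.
    """

    node_ids: tuple[str, ...]
    edges: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("node_ids must be unique")
        n = len(self.node_ids)
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop on node index {i}")
            if not (0 <= i < j < n):
                raise ValueError(f"edge ({i}, {j}) outside index space [0, {n})")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index_of(self, gene: str) -> int:
        # node_ids is sorted, so bisection would work; dict is simpler and cached
        return self._index()[gene]

    def _index(self) -> dict[str, int]:
        idx = getattr(self, "_idx_cache", None)
        if idx is None:
            idx = {g: i for i, g in enumerate(self.node_ids)}
            object.__setattr__(self, "_idx_cache", idx)
        return idx

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def neighbors(self) -> list[np.ndarray]:
        """Adjacency lists as sorted index arrays, aligned to the node order."""
        nbr: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, j in self.edges:
            nbr[i].append(j)
            nbr[j].append(i)
        return [np.array(sorted(ns), dtype=np.int64) for ns in nbr]


@dataclass(frozen=True)
class DiseaseMap:
    """Disease ID -> set of node indices on a fixed Interactome index space."""

    diseases: tuple[str, ...]
    members: tuple[frozenset[int], ...]

    def __post_init__(self) -> None:
        if len(self.diseases) != len(self.members):
            raise ValueError("diseases and members length mismatch")
        if len(self.diseases) < 2:
            raise ValueError("need at least two diseases")
        for d, m in zip(self.diseases, self.members):
            if not m:
                raise ValueError(f"disease {d!r} has no member nodes")

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)

    def sizes(self) -> np.ndarray:
        return np.array([len(m) for m in self.members], dtype=np.int64)

    def member_arrays(self) -> list[np.ndarray]:
        return [np.array(sorted(m), dtype=np.int64) for m in self.members]


@dataclass(frozen=True)
class RawPair:
    """An unordered disease pair with its relative-risk score."""

    disease_a: int
    disease_b: int
    rr: float

    def __post_init__(self) -> None:
        if self.disease_a == self.disease_b:
            raise ValueError("pair must join two distinct diseases")


@dataclass(frozen=True)
class PairDataset:
    """Binary-labeled disease pairs under an RR-threshold mode."""

    pairs: tuple[tuple[int, int, int], ...]  # (disease_a, disease_b, label)
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in LABEL_MODES:
            raise ValueError(f"mode must be one of {LABEL_MODES}, got {self.mode!r}")

    @property
    def labels(self) -> np.ndarray:
        return np.array([p[2] for p in self.pairs], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def build_interactome(node_ids: Iterable[str], edge_ids: Iterable[tuple[str, str]]) -> Interactome:
    """Build an Interactome from gene-ID edges; nodes are sorted, edges canonicalised."""
    ids = tuple(sorted(set(node_ids)))
    index = {g: i for i, g in enumerate(ids)}
    edges = set()
    dropped_loops = 0
    for a, b in edge_ids:
        if a == b:
            dropped_loops += 1
            continue
        i, j = index[a], index[b]
        edges.add((min(i, j), max(i, j)))
    if dropped_loops:
        logger.info("dropped %d self-loop(s)", dropped_loops)
    return Interactome(node_ids=ids, edges=frozenset(edges))


def _read_tsv_rows(path, n_fields: int) -> list[tuple[str, ...]]:
    rows: list[tuple[str, ...]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != n_fields:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected {n_fields}"
                )
            rows.append(tuple(fields))
    return rows


def load_edge_list(path) -> Interactome:
    """Read a two-column (whitespace/TSV) edge list of gene IDs.

    ``#`` lines are comments. Duplicate and reversed edges collapse to one;
    self-loops are dropped (logged). Raises on an empty file or a malformed
    line.
    """
    rows = _read_tsv_rows(path, 2)
    if not rows:
        raise ValueError(f"{path}: empty edge list")
    nodes = [g for row in rows for g in row]
    return build_interactome(nodes, rows)  # type: ignore[arg-type]


def write_edge_list(g: Interactome, path) -> None:
    with open(path, "w") as fh:
        fh.write("# gene_a\tgene_b\n")
        for i, j in sorted(g.edges):
            fh.write(f"{g.node_ids[i]}\t{g.node_ids[j]}\n")


def build_disease_map(
    assoc: Iterable[tuple[str, str]], g: Interactome
) -> DiseaseMap:
    """Map (disease ID, gene ID) associations onto the interactome index space.

    Genes absent from the interactome are dropped (logged); diseases left
    empty are removed with a warning. Raises if no disease survives.
    """
    index = g._index()
    by_disease: dict[str, set[int]] = {}
    dropped = 0
    for dis, gene in assoc:
        node = index.get(gene)
        if node is None:
            dropped += 1
            continue
        by_disease.setdefault(dis, set()).add(node)
    if dropped:
        logger.info("dropped %d association(s) to genes outside the interactome", dropped)
    empty = [d for d, m in by_disease.items() if not m]
    for d in empty:
        logger.warning("disease %s has no mapped genes; removed", d)
        del by_disease[d]
    if not by_disease:
        raise ValueError("no disease retains at least one interactome gene")
    names = tuple(sorted(by_disease))
    members = tuple(frozenset(by_disease[d]) for d in names)
    if len(names) == 1:
        # DiseaseMap requires K >= 2; surface a clear error instead
        raise ValueError("fewer than two diseases with mapped genes")
    return DiseaseMap(diseases=names, members=members)


def load_disease_associations(path, g: Interactome) -> DiseaseMap:
    """Read a two-column TSV of (disease ID, gene ID) rows."""
    rows = _read_tsv_rows(path, 2)
    if not rows:
        raise ValueError(f"{path}: empty association table")
    return build_disease_map(rows, g)  # type: ignore[arg-type]


def write_disease_associations(dm: DiseaseMap, g: Interactome, path) -> None:
    with open(path, "w") as fh:
        fh.write("# disease\tgene\n")
        for d, members in zip(dm.diseases, dm.member_arrays()):
            for node in members:
                fh.write(f"{d}\t{g.node_ids[node]}\n")


def load_pair_table(path, dm: DiseaseMap) -> list[RawPair]:
    """Read a three-column TSV (disease A, disease B, RR score).

    Pairs are canonicalised to (min disease index, max); duplicate unordered
    pairs raise. Pairs naming a disease absent from the map are dropped
    (logged).
    """
    rows = _read_tsv_rows(path, 3)
    index = {d: i for i, d in enumerate(dm.diseases)}
    pairs: list[RawPair] = []
    seen: set[tuple[int, int]] = set()
    dropped = 0
    for da, db, rr in rows:
        ia, ib = index.get(da), index.get(db)
        if ia is None or ib is None:
            dropped += 1
            continue
        if ia == ib:
            raise ValueError(f"{path}: pair joins disease {da} with itself")
        key = (min(ia, ib), max(ia, ib))
        if key in seen:
            raise ValueError(f"{path}: duplicate unordered pair {da}/{db}")
        seen.add(key)
        pairs.append(RawPair(disease_a=key[0], disease_b=key[1], rr=float(rr)))
    if dropped:
        logger.info("dropped %d pair(s) naming unknown diseases", dropped)
    return pairs


def write_pair_table(pairs: Sequence[RawPair], dm: DiseaseMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("# disease_a\tdisease_b\trr\n")
        for p in pairs:
            fh.write(f"{dm.diseases[p.disease_a]}\t{dm.diseases[p.disease_b]}\t{p.rr:.10g}\n")


def label_pairs(pairs: Sequence[RawPair], mode: str) -> PairDataset:
    """Binarise RR scores: RR0 (positive iff rr > 0) or RR1 (positive iff rr >= 1)."""
    if mode not in LABEL_MODES:
        raise ValueError(f"mode must be one of {LABEL_MODES}, got {mode!r}")
    labeled = []
    for p in pairs:
        if np.isnan(p.rr):
            raise ValueError(f"NaN RR score for pair ({p.disease_a}, {p.disease_b})")
        if mode == "RR0":
            lab = 1 if p.rr > 0 else 0
        else:
            lab = 1 if p.rr >= 1 else 0
        a, b = sorted((p.disease_a, p.disease_b))
        labeled.append((a, b, lab))
    return PairDataset(pairs=tuple(labeled), mode=mode)


def adjacency_matrix(g: Interactome, sparse: bool = False):
    """Binary symmetric adjacency matrix with zero diagonal (dense by default)."""
    n = g.n_nodes
    if sparse:
        import scipy.sparse as sp

        if not g.edges:
            return sp.csr_matrix((n, n))
        ij = np.array(sorted(g.edges), dtype=np.int64)
        rows = np.concatenate([ij[:, 0], ij[:, 1]])
        cols = np.concatenate([ij[:, 1], ij[:, 0]])
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    A = np.zeros((n, n))
    for i, j in g.edges:
        A[i, j] = 1.0
        A[j, i] = 1.0
    return A
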