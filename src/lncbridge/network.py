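"""Bridge heterogeneous information network (BHnet) construction and queries.

The network integrates five molecule types (lncRNA, miRNA, protein, drug,
disease) through eight bridge association types.  Known lncRNA-disease
associations (LDAs) are deliberately *excluded* from the network: they are the
labels being predicted, and every lncRNA-disease connection must therefore run
through bridge molecules.  :func:`build_network` enforces this as a hard
leakage guard.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: The five node types of the heterogeneous network.
NODE_TYPES = ("lncRNA", "miRNA", "protein", "drug", "disease")

#: Endpoint type signature of each of the eight bridge relations.
RELATION_SIGNATURES: dict[str, tuple[str, str]] = {
    "miRNA-lncRNA": ("miRNA", "lncRNA"),
    "miRNA-disease": ("miRNA", "disease"),
    "lncRNA-protein": ("lncRNA", "protein"),
    "protein-disease": ("protein", "disease"),
    "drug-disease": ("drug", "disease"),
    "miRNA-protein": ("miRNA", "protein"),
    "drug-protein": ("drug", "protein"),
    "protein-protein": ("protein", "protein"),
}

#: The held-out label relation.  Loadable for the pair dataset, never for the
#: network itself.
LDA_RELATION = "lncRNA-disease"
LDA_SIGNATURE = ("lncRNA", "disease")

BRIDGE_TYPES = ("miRNA", "protein", "drug")

_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Trim, case-fold and collapse internal whitespace of an identifier."""
    return _WS.sub(" ", str(name).strip()).casefold()


@dataclass(frozen=True, order=True)
class EntityId:
    """A typed, normalized node identifier, unique within one network."""

    node_type: str
    name: str

    def __post_init__(self) -> None:
        if self.node_type not in NODE_TYPES:
            raise ValueError(f"unknown node type: {self.node_type!r}")
        if not self.name:
            raise ValueError("empty entity name after normalization")

    @classmethod
    def make(cls, node_type: str, raw_name: str) -> "EntityId":
        return cls(node_type, normalize_name(raw_name))


@dataclass
class AssociationTable:
    """De-duplicated, typed edge records for one relation."""

    relation_type: str
    records: list[tuple[EntityId, EntityId]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.relation_type not in RELATION_SIGNATURES and self.relation_type != LDA_RELATION:
            raise ValueError(f"unknown relation type: {self.relation_type!r}")

    @property
    def signature(self) -> tuple[str, str]:
        if self.relation_type == LDA_RELATION:
            return LDA_SIGNATURE
        return RELATION_SIGNATURES[self.relation_type]


def _dedup_unordered(records: list[tuple[EntityId, EntityId]]) -> list[tuple[EntityId, EntityId]]:
    seen: set[frozenset] = set()
    out = []
    for a, b in records:
        key = frozenset((a, b))
        if key in seen:
            continue
        seen.add(key)
        out.append((a, b))
    return out


def load_association_table(
    path: str | Path,
    relation_type: str,
    *,
    synonyms: dict[str, str] | None = None,
    strict: bool = False,
) -> AssociationTable:
    """Read a two-column TSV of associations into a normalized table.

    Rows are normalized (trim / case-fold / whitespace collapse), optionally
    mapped through a synonym table, typed according to ``relation_type``'s
    endpoint signature, and de-duplicated as unordered pairs.  Malformed rows
    (fewer than two fields, empty identifiers, self-loops) are dropped with a
    log message, or raise when ``strict`` is set.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = AssociationTable(relation_type)
    src_t, dst_t = table.signature
    syn = {normalize_name(k): normalize_name(v) for k, v in (synonyms or {}).items()}

    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        logger.info("%s: empty file, 0 records", path)
        return table

    n_bad = 0
    records: list[tuple[EntityId, EntityId]] = []
    for row in df.itertuples(index=False):
        fields = [x for x in row if isinstance(x, str)]
        if len(fields) < 2:
            n_bad += 1
            if strict:
                raise ValueError(f"{path}: malformed row {tuple(row)!r}")
            continue
        a, b = normalize_name(fields[0]), normalize_name(fields[1])
        a, b = syn.get(a, a), syn.get(b, b)
        if not a or not b:
            n_bad += 1
            if strict:
                raise ValueError(f"{path}: empty identifier in row {tuple(row)!r}")
            continue
        src, dst = EntityId(src_t, a), EntityId(dst_t, b)
        if src == dst:
            n_bad += 1
            if strict:
                raise ValueError(f"{path}: self-loop {a!r}")
            continue
        records.append((src, dst))

    table.records = _dedup_unordered(records)
    n_dup = len(records) - len(table.records)
    if n_dup or n_bad:
        logger.info("%s [%s]: dropped %d duplicate and %d malformed rows",
                    path, relation_type, n_dup, n_bad)
    logger.info("%s [%s]: %d records", path, relation_type, len(table.records))
    return table


@dataclass
class BHNet:
    """The bridge heterogeneous network: frozen node index + sparse adjacency.

    ``adjacency`` is a binary, symmetric, zero-diagonal CSR matrix whose row
    order follows ``nodes`` (sorted by (node_type, name) for reproducibility).
    """

    nodes: list[EntityId]
    adjacency: sp.csr_matrix

    def __post_init__(self) -> None:
        self.node_index: dict[EntityId, int] = {e: i for i, e in enumerate(self.nodes)}
        self.type_of: list[str] = [e.node_type for e in self.nodes]

    @property
    def n(self) -> int:
        return len(self.nodes)

    def indices_of_type(self, node_type: str) -> np.ndarray:
        return np.array([i for i, t in enumerate(self.type_of) if t == node_type], dtype=int)

    def dense(self) -> np.ndarray:
        return np.asarray(self.adjacency.todense(), dtype=float)

    # --- on-disk round trip (plain TSV, deterministic order) ---

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "nodes.tsv", "w") as fh:
            for i, e in enumerate(self.nodes):
                fh.write(f"{i}\t{e.node_type}\t{e.name}\n")
        coo = sp.triu(self.adjacency, k=1).tocoo()
        order = np.lexsort((coo.col, coo.row))
        with open(outdir / "edges.tsv", "w") as fh:
            for i, j in zip(coo.row[order], coo.col[order]):
                fh.write(f"{i}\t{j}\n")

    @classmethod
    def load(cls, indir: str | Path) -> "BHNet":
        indir = Path(indir)
        nodes: list[EntityId] = []
        with open(indir / "nodes.tsv") as fh:
            for line in fh:
                _, t, name = line.rstrip("\n").split("\t")
                nodes.append(EntityId(t, name))
        rows, cols = [], []
        with open(indir / "edges.tsv") as fh:
            for line in fh:
                i, j = map(int, line.split())
                rows += [i, j]
                cols += [j, i]
        n = len(nodes)
        adj = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        adj.data[:] = 1.0
        return cls(nodes, adj)


def build_network(tables: list[AssociationTable]) -> BHNet:
    """Assemble the BHnet from bridge association tables.

    Raises if any table carries the lncRNA-disease relation: label edges must
    never enter the network used for embedding.  Parallel edges from different
    relation types collapse to a single binary edge.
    """
    if not tables:
        raise ValueError("no association tables given")
    for t in tables:
        if t.relation_type == LDA_RELATION:
            raise ValueError(
                "lncRNA-disease associations are prediction labels and are "
                "excluded from the bridge network"
            )
    edges: set[tuple[EntityId, EntityId]] = set()
    entities: set[EntityId] = set()
    for t in tables:
        for a, b in t.records:
            entities.update((a, b))
            edges.add((a, b) if a <= b else (b, a))
    if not edges:
        raise ValueError("association tables contain no edges")

    nodes = sorted(entities)  # (node_type, name) lexicographic: deterministic
    index = {e: i for i, e in enumerate(nodes)}
    rows, cols = [], []
    for a, b in edges:
        i, j = index[a], index[b]
        rows += [i, j]
        cols += [j, i]
    n = len(nodes)
    adj = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    adj.data[:] = 1.0
    net = BHNet(nodes, adj)
    _validate(net)
    logger.info("BHnet: %d nodes, %d undirected edges", n, len(edges))
    return net


def _validate(net: BHNet) -> None:
    a = net.adjacency
    if (a != a.T).nnz:
        raise AssertionError("adjacency not symmetric")
    if a.diagonal().any():
        raise AssertionError("adjacency has self-loops")
    coo = sp.triu(a, k=1).tocoo()
    for i, j in zip(coo.row, coo.col):
        ti, tj = net.type_of[i], net.type_of[j]
        if {ti, tj} == {"lncRNA", "disease"}:
            raise AssertionError("direct lncRNA-disease edge found in BHnet")


@dataclass
class PathStats:
    """Counts of bridge paths matching one typed template.

    ``role_node_counts[r]`` is the number of distinct nodes that occupy
    position ``r`` of the template in at least one complete path (all edges of
    the path present simultaneously, all nodes pairwise distinct).
    """

    template: list[str]
    path_count: int
    role_node_counts: list[int]

    def to_json(self) -> str:
        return json.dumps(
            {"template": self.template, "path_count": self.path_count,
             "role_node_counts": self.role_node_counts}, indent=2)


#: Short letter codes used by the CLI for path templates.
TYPE_CODES = {"L": "lncRNA", "M": "miRNA", "P": "protein", "Dr": "drug", "D": "disease"}


def parse_template(spec: str) -> list[str]:
    """Parse a template such as ``"L,M,D"`` or ``"L-P-Dr-D"`` into node types."""
    parts = re.split(r"[,\-]", spec)
    try:
        return [TYPE_CODES[p.strip()] for p in parts]
    except KeyError as e:
        raise ValueError(f"unknown node-type code {e.args[0]!r} in template {spec!r}") from None


def count_bridge_paths(net: BHNet, template: list[str]) -> PathStats:
    """Enumerate simple typed paths from lncRNA to disease along a template.

    A path matches when consecutive nodes are adjacent, node types follow the
    template, and all nodes on the path are pairwise distinct.
    """
    if len(template) < 3 or len(template) > 5:
        raise ValueError("template length must be 3-5")
    if template[0] != "lncRNA" or template[-1] != "disease":
        raise ValueError("template must start at lncRNA and end at disease")
    for t in template[1:-1]:
        if t not in BRIDGE_TYPES:
            raise ValueError(f"interior template type {t!r} is not a bridge type")

    indptr, indices = net.adjacency.indptr, net.adjacency.indices
    type_of = net.type_of
    roles: list[set[int]] = [set() for _ in template]
    count = 0

    def extend(node: int, depth: int, path: list[int]) -> int:
        if depth == len(template) - 1:
            for r, v in enumerate(path):
                roles[r].add(v)
            return 1
        want = template[depth + 1]
        c = 0
        for nb in indices[indptr[node]:indptr[node + 1]]:
            if type_of[nb] == want and nb not in path:
                path.append(nb)
                c += extend(nb, depth + 1, path)
                path.pop()
        return c

    for start in net.indices_of_type("lncRNA"):
        count += extend(int(start), 0, [int(start)])
    return PathStats(list(template), count, [len(r) for r in roles])
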