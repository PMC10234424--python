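"""Intrinsic 64-dimensional node attributes for every molecule type.

Each node type gets a 64-vector from its own data modality:

* ncRNA (lncRNA, miRNA): normalized 3-mer frequencies over {A,C,G,U}
  (4^3 = 64 bins).
* protein: residues are first collapsed into four side-chain polarity classes,
  then 3-mer frequencies over the reduced alphabet give the same 64 bins.
* disease: pairwise semantic similarity from MeSH ancestor DAGs
  (0.5-per-generation contribution decay), embedded into 64 dimensions by
  truncated eigendecomposition of the similarity matrix.
* drug: radius-2 Morgan circular fingerprints folded to 64 bits.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

from .network import BHNet

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

ATTR_DIM = 64
KMER_K = 3

RNA_ALPHABET = "ACGU"
#: 3-mers in lexicographic order over (A, C, G, U); bin layout of ncRNA rows.
RNA_KMERS = ["".join(p) for p in itertools.product(RNA_ALPHABET, repeat=KMER_K)]
_RNA_KMER_INDEX = {k: i for i, k in enumerate(RNA_KMERS)}

#: Side-chain polarity partition of the 20 standard amino acids:
#: 0 nonpolar, 1 polar uncharged, 2 positively charged, 3 negatively charged.
PROTEIN_CLASSES: dict[str, str] = {
    **{aa: "0" for aa in "GAVLIPFMW"},
    **{aa: "1" for aa in "STCYNQ"},
    **{aa: "2" for aa in "KRH"},
    **{aa: "3" for aa in "DE"},
}
REDUCED_ALPHABET = "0123"
_REDUCED_KMER_INDEX = {
    "".join(p): i for i, p in enumerate(itertools.product(REDUCED_ALPHABET, repeat=KMER_K))
}


def _kmer_vector(seq: str, index: dict[str, int], k: int = KMER_K) -> np.ndarray:
    """Sliding-window k-mer frequency vector; windows containing symbols
    outside the alphabet are skipped so valid counts still normalize to 1."""
    v = np.zeros(len(index))
    total = 0
    for i in range(len(seq) - k + 1):
        j = index.get(seq[i:i + k])
        if j is not None:
            v[j] += 1
            total += 1
    if total == 0:
        return v
    return v / total


def rna_kmer_vector(sequence: str, k: int = KMER_K) -> np.ndarray:
    """Normalized 3-mer frequencies of an RNA/DNA sequence (T read as U).

    Returns the all-zero vector (with a warning) when no valid k-mer exists,
    e.g. for sequences shorter than ``k``.
    """
    seq = sequence.strip().upper().replace("T", "U")
    v = _kmer_vector(seq, _RNA_KMER_INDEX, k)
    if v.sum() == 0:
        logger.warning("sequence of length %d yields no valid %d-mer", len(seq), k)
    return v


def reduce_protein_alphabet(sequence: str) -> str:
    """Map a protein sequence onto the 4-letter polarity alphabet {0,1,2,3}.

    Ambiguous / nonstandard residues (B, J, X, Z, U, O) are dropped.
    """
    seq = sequence.strip().upper()
    out = []
    dropped = 0
    for aa in seq:
        c = PROTEIN_CLASSES.get(aa)
        if c is None:
            dropped += 1
        else:
            out.append(c)
    if dropped:
        logger.warning("dropped %d nonstandard residues from protein sequence", dropped)
    return "".join(out)


def protein_kmer_vector(sequence: str, k: int = KMER_K) -> np.ndarray:
    """Normalized 3-mer frequencies over the reduced 4-class protein alphabet."""
    reduced = reduce_protein_alphabet(sequence)
    v = _kmer_vector(reduced, _REDUCED_KMER_INDEX, k)
    if v.sum() == 0:
        logger.warning("protein sequence of reduced length %d yields no valid %d-mer",
                       len(reduced), k)
    return v


# ---------------------------------------------------------------------------
# Disease semantics from MeSH ancestor DAGs
# ---------------------------------------------------------------------------

@dataclass
class MeshDag:
    """The ancestor DAG of one disease term.

    ``nodes`` holds the disease's own term plus all its MeSH ancestors;
    ``child_edges[t]`` are the children of term ``t`` *within this DAG*.
    Every ancestor reaches the disease term along child edges.
    """

    disease_term: str
    nodes: set[str]
    child_edges: dict[str, set[str]] = field(default_factory=dict)

    def children(self, term: str) -> set[str]:
        return self.child_edges.get(term, set())

    def validate(self) -> None:
        if self.disease_term not in self.nodes:
            raise ValueError("disease term missing from its own DAG")
        for t, cs in self.child_edges.items():
            if t not in self.nodes or not cs <= self.nodes:
                raise ValueError("child edge endpoint outside DAG node set")


def mesh_contribution(dag: MeshDag) -> dict[str, float]:
    """Semantic contribution of each DAG term to the disease.

    The disease's own term contributes 1; every ancestor contributes half the
    maximum contribution among its children in the DAG, i.e. 0.5^(shortest
    child-path distance to the disease term).  Computed by reverse-topological
    relaxation; a cycle raises.
    """
    dag.validate()
    contrib: dict[str, float] = {dag.disease_term: 1.0}
    # Kahn traversal from the disease term upward along parent links.
    parents: dict[str, set[str]] = {t: set() for t in dag.nodes}
    for t, cs in dag.child_edges.items():
        for c in cs:
            parents[c].add(t)
    pending = {t: len(dag.children(t)) for t in dag.nodes}
    stack = [t for t, k in pending.items() if k == 0]
    seen = 0
    while stack:
        term = stack.pop()
        seen += 1
        if term != dag.disease_term:
            best = max((contrib[c] for c in dag.children(term) if c in contrib), default=None)
            if best is not None:
                contrib[term] = 0.5 * best
        for p in parents[term]:
            pending[p] -= 1
            if pending[p] == 0:
                stack.append(p)
    if seen != len(dag.nodes):
        raise ValueError("cycle detected in MeSH DAG")
    return contrib


def semantic_similarity(dag_i: MeshDag, dag_j: MeshDag) -> float:
    """Semantic similarity of two diseases from their shared ancestor terms.

    S(i,j) = sum over shared terms of (D_i(t) + D_j(t)) divided by the total
    semantic value of both diseases.  Symmetric, in [0, 1]; identical DAGs
    score exactly 1, disjoint term sets score 0.
    """
    ci, cj = mesh_contribution(dag_i), mesh_contribution(dag_j)
    shared = set(ci) & set(cj)
    denom = sum(ci.values()) + sum(cj.values())
    if denom == 0:
        return 0.0
    return sum(ci[t] + cj[t] for t in shared) / denom


def semantic_similarity_matrix(dags: list[MeshDag]) -> np.ndarray:
    m = len(dags)
    contribs = [mesh_contribution(d) for d in dags]
    totals = [sum(c.values()) for c in contribs]
    sims = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            shared = set(contribs[i]) & set(contribs[j])
            denom = totals[i] + totals[j]
            s = sum(contribs[i][t] + contribs[j][t] for t in shared) / denom if denom else 0.0
            sims[i, j] = sims[j, i] = s
    return sims


def disease_attribute_matrix(sims: np.ndarray, dim: int = ATTR_DIM) -> np.ndarray:
    """Embed an m x m disease similarity matrix into ``dim`` coordinates.

    Rows are U * sqrt(S) from the top-``dim`` components of the symmetric
    eigendecomposition (zero-padded when m < dim), so row dot products
    reproduce the similarity matrix whenever its rank fits.  The sign of each
    component vector is fixed by making its largest-magnitude entry positive,
    which keeps the output deterministic.
    """
    m = sims.shape[0]
    if m == 0:
        return np.zeros((0, dim))
    if sims.shape != (m, m) or not np.allclose(sims, sims.T, atol=1e-8):
        raise ValueError("similarity matrix must be square and symmetric")
    w, u = np.linalg.eigh(sims)
    order = np.argsort(w)[::-1][: min(dim, m)]
    w, u = w[order], u[:, order]
    w = np.clip(w, 0.0, None)
    for c in range(u.shape[1]):
        k = np.argmax(np.abs(u[:, c]))
        if u[k, c] < 0:
            u[:, c] = -u[:, c]
    out = np.zeros((m, dim))
    out[:, : u.shape[1]] = u * np.sqrt(w)
    return out


# ---------------------------------------------------------------------------
# Drug fingerprints
# ---------------------------------------------------------------------------

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=ATTR_DIM)


def drug_fingerprint(smiles: str, *, strict: bool = False) -> np.ndarray:
    """Radius-2 Morgan fingerprint folded to 64 bits, as a 0/1 vector.

    Canonicalization inside RDKit makes equivalent SMILES spellings of the
    same molecule map to identical fingerprints.  Unparseable SMILES yield the
    all-zero vector with a warning (or raise under ``strict``).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        if strict:
            raise ValueError(f"unparseable SMILES: {smiles!r}")
        logger.warning("unparseable SMILES %r: zero fingerprint", smiles)
        return np.zeros(ATTR_DIM)
    fp = _MORGAN.GetFingerprint(mol)
    return np.array(fp, dtype=float)


# ---------------------------------------------------------------------------
# Assembly over a network
# ---------------------------------------------------------------------------

def assemble_attributes(
    net: BHNet,
    sequences: dict[str, str] | None = None,
    smiles: dict[str, str] | None = None,
    dags: dict[str, MeshDag] | None = None,
) -> np.ndarray:
    """Build the n x 64 attribute matrix aligned with the network node index.

    Rows are dispatched on node type; nodes whose source data is missing get
    all-zero rows, and the per-type coverage is logged.  Disease rows come
    from a joint eigendecomposition of the pairwise similarity matrix over
    the diseases that have a DAG.
    """
    sequences = {(k.casefold() if isinstance(k, str) else k): v
                 for k, v in (sequences or {}).items()}
    smiles = {k.casefold(): v for k, v in (smiles or {}).items()}
    dags = {k.casefold(): v for k, v in (dags or {}).items()}

    attrs = np.zeros((net.n, ATTR_DIM))
    missing: dict[str, int] = {t: 0 for t in ("lncRNA", "miRNA", "protein", "drug", "disease")}
    totals: dict[str, int] = {t: 0 for t in missing}

    disease_rows = [i for i, t in enumerate(net.type_of) if t == "disease"]
    covered = [i for i in disease_rows if net.nodes[i].name in dags]
    if covered:
        sims = semantic_similarity_matrix([dags[net.nodes[i].name] for i in covered])
        dis_attr = disease_attribute_matrix(sims)
        for r, i in enumerate(covered):
            attrs[i] = dis_attr[r]

    for i, ent in enumerate(net.nodes):
        t = ent.node_type
        totals[t] += 1
        if t in ("lncRNA", "miRNA"):
            seq = sequences.get(ent.name)
            if seq is None:
                missing[t] += 1
            else:
                attrs[i] = rna_kmer_vector(seq)
        elif t == "protein":
            seq = sequences.get(ent.name)
            if seq is None:
                missing[t] += 1
            else:
                attrs[i] = protein_kmer_vector(seq)
        elif t == "drug":
            s = smiles.get(ent.name)
            if s is None:
                missing[t] += 1
            else:
                attrs[i] = drug_fingerprint(s)
        elif t == "disease":
            if ent.name not in dags:
                missing[t] += 1

    for t in totals:
        if totals[t]:
            logger.info("attribute coverage %s: %d/%d", t, totals[t] - missing[t], totals[t])
    total_missing = sum(missing.values())
    if total_missing:
        logger.warning("%d/%d nodes have no attribute data (zero rows)", total_missing, net.n)
    return attrs
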