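"""Self-contained synthetic inputs for the whole pipeline.

The generator emulates the shape of the real data sources without any
download: a cross-type stochastic block model plants community structure into
all eight bridge relations, and the held-out "true" lncRNA-disease pairs are
drawn by the same block law, hence preferentially within communities.  The
association signal is therefore carried
exclusively by bridge molecules — the premise the predictor is built on —
and is recoverable from the network even though no lncRNA-disease edge
exists in it.  Sequences, MeSH-style term hierarchies and drug SMILES are
equally synthetic, generated at the scales typical of each molecule class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .attributes import MeshDag
from .network import RELATION_SIGNATURES, AssociationTable, EntityId

logger = logging.getLogger(__name__)


@dataclass
class SynthConfig:
    """Study conditions of the synthetic benchmark.

    Node counts keep the network desk-scale (~260 nodes); ``p_in``/``p_out``
    set the within/between-community edge probabilities of every bridge
    relation, and ``n_positive_lda`` true pairs are drawn by that same block
    law (weight ``p_in`` within a community, ``p_out`` across), so the
    held-out labels obey the generative rule of the bridge edges without ever
    appearing among them.  The positive density within communities is kept
    high (~940 of the 1500 within-community pairs at the defaults), emulating
    a well-annotated disease module: most unlabeled within-community pairs
    are then exhausted, as in curated association databases where the
    catalogued neighbourhood of a disease is dense.
    """

    n_lncRNA: int = 60
    n_miRNA: int = 40
    n_protein: int = 80
    n_drug: int = 30
    n_disease: int = 50
    n_communities: int = 2
    p_in: float = 0.3
    p_out: float = 0.02
    n_positive_lda: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_out <= self.p_in <= 1):
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        for n in (self.n_lncRNA, self.n_miRNA, self.n_protein, self.n_drug, self.n_disease):
            if n < self.n_communities:
                raise ValueError("every node type needs >= n_communities nodes")


@dataclass
class SynthNetwork:
    tables: list[AssociationTable]
    true_lda: set[tuple[EntityId, EntityId]]
    communities: dict[EntityId, int] = field(default_factory=dict)

    @property
    def lncRNAs(self) -> set[EntityId]:
        return {e for e in self.communities if e.node_type == "lncRNA"}

    @property
    def diseases(self) -> set[EntityId]:
        return {e for e in self.communities if e.node_type == "disease"}


def _make_entities(cfg: SynthConfig) -> dict[str, list[EntityId]]:
    spec = {
        "lncRNA": ("lnc", cfg.n_lncRNA),
        "miRNA": ("mir", cfg.n_miRNA),
        "protein": ("prot", cfg.n_protein),
        "drug": ("drug", cfg.n_drug),
        "disease": ("dis", cfg.n_disease),
    }
    return {
        t: [EntityId(t, f"{prefix}{i:04d}") for i in range(n)]
        for t, (prefix, n) in spec.items()
    }


def generate_network(cfg: SynthConfig) -> SynthNetwork:
    """Sample the eight bridge relations and the held-out true LDA pairs.

    Community labels are assigned round-robin within each node type (balanced
    blocks).  Each relation is an independent cross-type stochastic block
    model: edge probability ``p_in`` for same-community endpoint pairs,
    ``p_out`` otherwise.  Nodes left isolated by sampling are attached to one
    random same-community partner so every generated molecule participates in
    the network.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    ents = _make_entities(cfg)
    comm: dict[EntityId, int] = {}
    for t, es in ents.items():
        for i, e in enumerate(es):
            comm[e] = i % cfg.n_communities

    tables: list[AssociationTable] = []
    degree: dict[EntityId, int] = {e: 0 for es in ents.values() for e in es}

    def sample_relation(rel: str) -> AssociationTable:
        t1, t2 = RELATION_SIGNATURES[rel]
        a_list, b_list = ents[t1], ents[t2]
        records = []
        for ia, a in enumerate(a_list):
            start = ia + 1 if rel == "protein-protein" else 0
            bs = b_list[start:]
            if not bs:
                continue
            probs = np.where(
                np.array([comm[b] == comm[a] for b in bs]), cfg.p_in, cfg.p_out)
            hits = rng.random(len(bs)) < probs
            for b, h in zip(bs, hits):
                if h:
                    records.append((a, b))
        return AssociationTable(rel, records)

    for rel in RELATION_SIGNATURES:
        table = sample_relation(rel)
        if not table.records:
            logger.warning("relation %s empty after sampling; resampling once", rel)
            table = sample_relation(rel)
            if not table.records:
                raise RuntimeError(f"relation {rel} empty after resampling")
        for a, b in table.records:
            degree[a] += 1
            degree[b] += 1
        tables.append(table)

    # attach isolated nodes through one same-community edge of a valid relation
    partner_rel = {
        "lncRNA": ("miRNA-lncRNA", "miRNA", True),
        "miRNA": ("miRNA-disease", "disease", False),
        "protein": ("protein-disease", "disease", False),
        "drug": ("drug-protein", "protein", False),
        "disease": ("miRNA-disease", "miRNA", True),
    }
    by_rel = {t.relation_type: t for t in tables}
    for e, d in degree.items():
        if d:
            continue
        rel, ptype, e_is_target = partner_rel[e.node_type]
        pool = [p for p in ents[ptype] if comm[p] == comm[e]] or ents[ptype]
        p = pool[int(rng.integers(len(pool)))]
        rec = (p, e) if e_is_target else (e, p)
        by_rel[rel].records.append(rec)
        logger.info("attached isolated node %s via %s", e.name, rel)

    # Held-out LDA pairs are governed by the same block law as the bridge
    # edges.  A catalogued association is modelled as needing two independent
    # bridge-chain lines of evidence (curated databases grade associations by
    # evidence count); the dominant lncRNA-bridge-disease chain has affinity
    # p_in*p_in for a same-community pair and p_in*p_out across, so the pair
    # weight is that chain affinity squared.  When p_in == p_out all weights
    # coincide and the labels are exactly uniform over pairs: the null
    # configuration plants no signal of any kind.
    pairs = [(l, d) for l in ents["lncRNA"] for d in ents["disease"]]
    chain = np.array(
        [cfg.p_in * (cfg.p_in if comm[l] == comm[d] else cfg.p_out) for l, d in pairs])
    weights = chain ** 2
    if cfg.n_positive_lda > int(np.count_nonzero(weights)):
        raise ValueError(
            f"n_positive_lda={cfg.n_positive_lda} exceeds the "
            f"{int(np.count_nonzero(weights))} pairs with non-zero weight")
    with np.errstate(divide="ignore"):
        race = np.where(weights > 0, rng.exponential(size=len(pairs)) / weights, np.inf)
    idx = np.argsort(race, kind="stable")[: cfg.n_positive_lda]
    true_lda = {pairs[i] for i in idx}
    logger.info("synthetic network: %d relations, %d true LDA pairs",
                len(tables), len(true_lda))
    return SynthNetwork(tables, true_lda, comm)


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def generate_sequences(
    ids: list[str],
    length_range: tuple[int, int],
    alphabet: str = "ACGU",
    seed: int = 0,
    *,
    communities: dict[str, int] | None = None,
    bias: float = 0.0,
) -> dict[str, str]:
    """I.i.d. random sequences, one per identifier.

    With ``bias`` > 0 and a community map, each community tilts the letter
    distribution toward its own preferred symbol, making sequence attributes
    informative about community membership on demand; at ``bias=0`` letters
    are uniform.
    """
    rng = np.random.default_rng(seed)
    letters = list(alphabet)
    out: dict[str, str] = {}
    for name in ids:
        lo, hi = length_range
        length = int(rng.integers(lo, hi + 1))
        p = np.full(len(letters), 1.0 / len(letters))
        if bias > 0 and communities is not None and name in communities:
            fav = communities[name] % len(letters)
            p = p * (1 - bias)
            p[fav] += bias
        out[name] = "".join(rng.choice(letters, size=length, p=p))
    return out


PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# MeSH-style hierarchy
# ---------------------------------------------------------------------------

@dataclass
class MeshHierarchy:
    """A global synthetic term hierarchy: disease leaf terms plus layered
    ancestor pools, stored as parent -> child edges (as the real MeSH
    parent-child extract would be)."""

    parent_child: set[tuple[str, str]]
    disease_term: dict[str, str]

    def dag_for(self, disease_id: str) -> MeshDag:
        return ancestor_dag(self.parent_child, self.disease_term[disease_id])


def ancestor_dag(parent_child: set[tuple[str, str]], term: str) -> MeshDag:
    """Upward closure of one term in a parent-child edge set."""
    parents: dict[str, set[str]] = {}
    for p, c in parent_child:
        parents.setdefault(c, set()).add(p)
    nodes = {term}
    stack = [term]
    while stack:
        t = stack.pop()
        for p in parents.get(t, ()):
            if p not in nodes:
                nodes.add(p)
                stack.append(p)
    child_edges: dict[str, set[str]] = {}
    for p, c in parent_child:
        if p in nodes and c in nodes:
            child_edges.setdefault(p, set()).add(c)
    return MeshDag(term, nodes, child_edges)


def generate_mesh_hierarchy(
    disease_ids: list[str],
    max_depth: int = 3,
    branching: int = 2,
    pool_size: int = 10,
    seed: int = 0,
    term_prefix: str = "t",
) -> MeshHierarchy:
    """Layered random hierarchy shared across diseases.

    Each depth level holds ``pool_size`` ancestor terms; every disease term
    picks 1..branching parents at depth 1, and every pool term picks
    1..branching parents at the next depth.  Sharing one pool makes pairwise
    semantic similarities vary over (0, 1); acyclicity is guaranteed by the
    level construction.
    """
    rng = np.random.default_rng(seed)
    levels = [[f"{term_prefix}{d}_{i}" for i in range(pool_size)]
              for d in range(1, max_depth + 1)]
    edges: set[tuple[str, str]] = set()
    disease_term = {did: f"{term_prefix}D_{did}" for did in disease_ids}

    def link_up(child: str, parent_pool: list[str]) -> None:
        k = int(rng.integers(1, branching + 1))
        k = min(k, len(parent_pool))
        for j in rng.choice(len(parent_pool), size=k, replace=False):
            edges.add((parent_pool[j], child))

    for did in disease_ids:
        link_up(disease_term[did], levels[0])
    for d in range(len(levels) - 1):
        for t in levels[d]:
            link_up(t, levels[d + 1])
    return MeshHierarchy(edges, disease_term)


def generate_mesh_dags(
    disease_ids: list[str],
    max_depth: int = 3,
    branching: int = 2,
    pool_size: int = 10,
    seed: int = 0,
    term_prefix: str = "t",
) -> dict[str, MeshDag]:
    hier = generate_mesh_hierarchy(
        disease_ids, max_depth, branching, pool_size, seed, term_prefix)
    return {did: hier.dag_for(did) for did in disease_ids}


# ---------------------------------------------------------------------------
# Drug SMILES fixtures
# ---------------------------------------------------------------------------

#: Hand-curated, RDKit-parseable drug-like SMILES (common drugs and simple
#: drug-like scaffolds); synthetic fixture pool, not a database export.
SMILES_POOL: tuple[str, ...] = (
    "CC(=O)OC1=CC=CC=C1C(=O)O",            # aspirin
    "CN1C=NC2=C1C(=O)N(C)C(=O)N2C",        # caffeine
    "CC(C)CC1=CC=C(C=C1)C(C)C(=O)O",       # ibuprofen
    "CC(=O)NC1=CC=C(O)C=C1",               # paracetamol
    "CN(C)CCC=C1C2=CC=CC=C2CCC2=CC=CC=C12",  # amitriptyline
    "NC(=O)C1=CN=CC=C1",                   # nicotinamide
    "OC(=O)C1=CC=CC=C1O",                  # salicylic acid
    "CN1CCC[C@H]1C1=CN=CC=C1",             # nicotine
    "NCC(=O)O",                            # glycine
    "CC(N)C(=O)O",                         # alanine
    "OC1=CC=C(CCN)C=C1",                   # tyramine
    "NCCC1=CNC2=CC=CC=C12",                # tryptamine
    "OCC1=CC=CC=C1",                       # benzyl alcohol
    "CC1=CC=C(C)C=C1",                     # xylene
    "OC1=CC=CC=C1",                        # phenol
    "NC1=CC=CC=C1",                        # aniline
    "OC(=O)CC1=CC=CC=C1",                  # phenylacetic acid
    "CC(=O)C1=CC=CC=C1",                   # acetophenone
    "O=C1CCCCC1",                          # cyclohexanone
    "C1CCNCC1",                            # piperidine
    "C1CCOC1",                             # THF
    "C1=CC=C2C=CC=CC2=C1",                 # naphthalene
    "C1=CC=C2NC=CC2=C1",                   # indole
    "C1=CC=C2OC=CC2=C1",                   # benzofuran
    "C1=CC=C2SC=CC2=C1",                   # benzothiophene
    "C1=CN=CC=C1",                         # pyridine
    "C1=CN=CN=C1",                         # pyrimidine
    "C1=CNC=N1",                           # imidazole
    "C1=CSC=C1",                           # thiophene
    "C1=COC=C1",                           # furan
    "OCCO",                                # ethylene glycol
    "OCC(O)CO",                            # glycerol
    "CC(=O)O",                             # acetic acid
    "CCO",                                 # ethanol
    "CC(C)O",                              # isopropanol
    "CCN(CC)CC",                           # triethylamine
    "CC(=O)NC1=CC=CC=C1",                  # acetanilide
    "COC1=CC=C(CCN)C=C1",                  # methoxyphenethylamine
    "CN1CCN(C)CC1",                        # dimethylpiperazine
    "O=C(O)C1CCCCC1",                      # cyclohexanecarboxylic acid
    "OC(=O)CCC(=O)O",                      # succinic acid
    "OC(=O)C=CC(=O)O",                     # fumaric acid
    "OC(=O)C(O)C(O)C(=O)O",                # tartaric acid
    "NC(CC(=O)O)C(=O)O",                   # aspartate
    "NC(CCC(=O)O)C(=O)O",                  # glutamate
    "CSCCC(N)C(=O)O",                      # methionine
    "CC(C)CC(N)C(=O)O",                    # leucine
    "NC(CC1=CC=CC=C1)C(=O)O",              # phenylalanine
    "NC(CC1=CC=C(O)C=C1)C(=O)O",           # tyrosine
    "NC(CO)C(=O)O",                        # serine
    "CC(O)C(N)C(=O)O",                     # threonine
    "NC(CS)C(=O)O",                        # cysteine
    "OC(=O)C1=CC=CN=C1",                   # niacin
    "CC1=NC=CN1",                          # methylimidazole
    "COC1=CC=CC=C1OC",                     # veratrole
)


def fixture_smiles(drug_ids: list[str], seed: int = 0) -> dict[str, str]:
    """Assign each drug a SMILES from the fixture pool.

    Samples without replacement while the pool lasts; with replacement (and a
    warning) for larger requests.
    """
    rng = np.random.default_rng(seed)
    n = len(drug_ids)
    if n <= len(SMILES_POOL):
        idx = rng.choice(len(SMILES_POOL), size=n, replace=False)
    else:
        logger.warning("requested %d SMILES from a pool of %d: sampling with "
                       "replacement", n, len(SMILES_POOL))
        idx = rng.choice(len(SMILES_POOL), size=n, replace=True)
    return {did: SMILES_POOL[i] for did, i in zip(drug_ids, idx)}


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------

@dataclass
class SynthBundle:
    """Everything the pipeline consumes, generated from one config + seed."""

    config: SynthConfig
    network: SynthNetwork
    sequences: dict[str, str]
    smiles: dict[str, str]
    hierarchy: MeshHierarchy

    @property
    def dags(self) -> dict[str, MeshDag]:
        return {d: self.hierarchy.dag_for(d) for d in self.hierarchy.disease_term}


def generate_bundle(cfg: SynthConfig | None = None) -> SynthBundle:
    """Generate the network plus all attribute source data with one seed."""
    cfg = cfg or SynthConfig()
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s) for s in ss.generate_state(4)]

    net_cfg = SynthConfig(**{**cfg.__dict__, "seed": seeds[0] % (2**31)})
    network = generate_network(net_cfg)
    ents = _make_entities(cfg)

    sequences: dict[str, str] = {}
    sequences.update(generate_sequences(
        [e.name for e in ents["lncRNA"]], (200, 500), "ACGU", seeds[1] % (2**31)))
    sequences.update(generate_sequences(
        [e.name for e in ents["miRNA"]], (20, 25), "ACGU", (seeds[1] + 1) % (2**31)))
    sequences.update(generate_sequences(
        [e.name for e in ents["protein"]], (150, 350), PROTEIN_ALPHABET,
        (seeds[1] + 2) % (2**31)))

    smiles = fixture_smiles([e.name for e in ents["drug"]], seeds[2] % (2**31))
    hierarchy = generate_mesh_hierarchy(
        [e.name for e in ents["disease"]], seed=seeds[3] % (2**31))
    return SynthBundle(cfg, network, sequences, smiles, hierarchy)
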