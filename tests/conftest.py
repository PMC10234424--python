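"""Shared fixtures: hand-built tiny networks and one full synthetic study.

The expensive end-to-end artifacts (default-condition bundle, trained
embedding, cross-validation results) are session-scoped so the structure
recovery, dimensionality and determinism checks share a single run.
"""

from __future__ import annotations

import numpy as np
import pytest

import lncbridge as lb
from lncbridge.network import AssociationTable, EntityId


def ent(t: str, name: str) -> EntityId:
    return EntityId(t, name)


@pytest.fixture
def tiny_net() -> lb.BHNet:
    """l1-m1-d1 chain plus l2-p1-d2: 7 nodes, two bridge routes."""
    tables = [
        AssociationTable("miRNA-lncRNA", [(ent("miRNA", "m1"), ent("lncRNA", "l1"))]),
        AssociationTable("miRNA-disease", [(ent("miRNA", "m1"), ent("disease", "d1"))]),
        AssociationTable("lncRNA-protein", [(ent("lncRNA", "l2"), ent("protein", "p1"))]),
        AssociationTable("protein-disease", [(ent("protein", "p1"), ent("disease", "d2"))]),
        AssociationTable("drug-protein", [(ent("drug", "x1"), ent("protein", "p1"))]),
    ]
    return lb.build_network(tables)


def random_net(seed: int, n_per_type: int = 6, p: float = 0.35) -> lb.BHNet:
    """Small random heterogeneous network for oracle comparisons."""
    rng = np.random.default_rng(seed)
    ents = {
        t: [ent(t, f"{t[:2]}{i}") for i in range(n_per_type)]
        for t in ("lncRNA", "miRNA", "protein", "drug", "disease")
    }
    tables = []
    from lncbridge.network import RELATION_SIGNATURES

    for rel, (t1, t2) in RELATION_SIGNATURES.items():
        records = []
        for i, a in enumerate(ents[t1]):
            for j, b in enumerate(ents[t2]):
                if rel == "protein-protein" and j <= i:
                    continue
                if rng.random() < p:
                    records.append((a, b))
        tables.append(AssociationTable(rel, records))
    return lb.build_network(tables)


class Study:
    """One complete synthetic experiment under the default conditions."""

    def __init__(self, seed: int = 1, **cfg_overrides):
        self.seed = seed
        self.config = lb.SynthConfig(seed=seed, **cfg_overrides)
        self.bundle = lb.generate_bundle(self.config)
        self.net = lb.build_network(self.bundle.network.tables)
        self.embedding = lb.train(self.net, lb.SdneConfig(seed=seed))
        self.dataset = lb.build_pair_dataset(
            self.bundle.network.true_lda,
            self.bundle.network.lncRNAs,
            self.bundle.network.diseases,
            mode="bridge",
            seed=seed,
        )

    def cv(self, mode: str = "bridge", attrs=None, permute: bool = False) -> lb.CVResult:
        ds = lb.PairDataset(list(self.dataset.pairs), self.dataset.labels.copy(), mode)
        if permute:
            ds.labels = np.random.default_rng(self.seed).permutation(ds.labels)
        return lb.cross_validate(ds, self.net, attrs, self.embedding, "xgboost",
                                 k=5, seed=self.seed)


@pytest.fixture(scope="session")
def study() -> Study:
    return Study(seed=1)


@pytest.fixture(scope="session")
def study_cv(study: Study) -> lb.CVResult:
    return study.cv()
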