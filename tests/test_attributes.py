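"""Attribute featurization: k-mers, polarity reduction, MeSH semantics,
disease similarity embedding and drug fingerprints."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lncbridge as lb
from lncbridge.attributes import (
    RNA_KMERS,
    MeshDag,
    disease_attribute_matrix,
    drug_fingerprint,
    mesh_contribution,
    protein_kmer_vector,
    reduce_protein_alphabet,
    rna_kmer_vector,
    semantic_similarity,
    semantic_similarity_matrix,
)
from lncbridge.synthetic import generate_mesh_dags


def naive_kmer_counts(seq: str, alphabet: str, k: int = 3) -> np.ndarray:
    """Sliding-window counting oracle, independent of the implementation."""
    kmers = ["".join(p) for p in itertools.product(alphabet, repeat=k)]
    counts = np.array([
        sum(seq[i:i + k] == km for i in range(len(seq) - k + 1)) for km in kmers
    ], dtype=float)
    return counts / counts.sum() if counts.sum() else counts


class TestRnaKmers:
    def test_homopolymer(self):
        v = rna_kmer_vector("AAAA")
        assert v[RNA_KMERS.index("AAA")] == 1.0
        assert v.sum() == 1.0

    def test_two_window_sequence(self):
        v = rna_kmer_vector("ACGU")
        assert v[RNA_KMERS.index("ACG")] == 0.5
        assert v[RNA_KMERS.index("CGU")] == 0.5

    def test_t_read_as_u(self):
        assert np.array_equal(rna_kmer_vector("ACGT"), rna_kmer_vector("ACGU"))

    def test_short_sequence_gives_zero_vector(self):
        assert rna_kmer_vector("AC").sum() == 0

    def test_ambiguous_symbols_skipped_but_normalization_exact(self):
        v = rna_kmer_vector("ACGNACG")
        assert abs(v.sum() - 1.0) < 1e-12
        assert v[RNA_KMERS.index("ACG")] == 1.0  # only valid windows

    def test_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGU"), size=500))
        assert np.allclose(rna_kmer_vector(seq), naive_kmer_counts(seq, "ACGU"), atol=1e-12)

    @given(st.permutations(list("ACGU")))
    @settings(deadline=None, max_examples=24, derandomize=True)
    def test_nucleotide_permutation_permutes_bins(self, perm):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGU"), size=300))
        mapping = dict(zip("ACGU", perm))
        permuted_seq = "".join(mapping[c] for c in seq)
        v, vp = rna_kmer_vector(seq), rna_kmer_vector(permuted_seq)
        for idx, km in enumerate(RNA_KMERS):
            km_mapped = "".join(mapping[c] for c in km)
            assert v[idx] == vp[RNA_KMERS.index(km_mapped)]


class TestProteinKmers:
    @pytest.mark.parametrize("seq,expected", [
        ("KRH", "222"), ("DE", "33"), ("GASDKE", "001323"),
    ])
    def test_polarity_reduction(self, seq, expected):
        assert reduce_protein_alphabet(seq) == expected

    def test_nonstandard_residues_dropped(self):
        assert reduce_protein_alphabet("KXR") == "22"
        assert reduce_protein_alphabet("") == ""

    def test_homopolymer_bin(self):
        v = protein_kmer_vector("KKKK")
        kmers = ["".join(p) for p in itertools.product("0123", repeat=3)]
        assert v[kmers.index("222")] == 1.0

    def test_too_short_gives_zero(self):
        assert protein_kmer_vector("KR").sum() == 0

    def test_matches_reduce_then_count_oracle(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=300))
        reduced = reduce_protein_alphabet(seq)
        assert np.allclose(protein_kmer_vector(seq),
                           naive_kmer_counts(reduced, "0123"), atol=1e-12)


def chain_dag(*terms: str) -> MeshDag:
    """terms[0] is the disease; terms[i+1] is the parent of terms[i]."""
    child_edges = {terms[i + 1]: {terms[i]} for i in range(len(terms) - 1)}
    return MeshDag(terms[0], set(terms), child_edges)


def oracle_contribution(dag: MeshDag) -> dict[str, float]:
    """Max over all descending paths of 0.5^length (exhaustive oracle)."""
    out = {}
    for t in dag.nodes:
        best = None
        stack = [(t, 0)]
        while stack:
            node, depth = stack.pop()
            if node == dag.disease_term:
                val = 0.5 ** depth
                best = val if best is None else max(best, val)
                continue
            for c in dag.children(node):
                stack.append((c, depth + 1))
        if best is not None:
            out[t] = best
    return out


class TestMeshContribution:
    def test_chain_halves_per_generation(self):
        assert mesh_contribution(chain_dag("d", "p", "g")) == {"d": 1.0, "p": 0.5, "g": 0.25}

    def test_single_node(self):
        assert mesh_contribution(MeshDag("d", {"d"})) == {"d": 1.0}

    def test_diamond_takes_shorter_path(self):
        # a reaches d directly (length 1) and via b (length 2): max rule -> 0.5
        dag = MeshDag("d", {"d", "a", "b"},
                      {"a": {"d", "b"}, "b": {"d"}})
        assert mesh_contribution(dag)["a"] == 0.5

    def test_cycle_raises(self):
        dag = MeshDag("d", {"d", "a", "b"}, {"a": {"b"}, "b": {"a", "d"}})
        with pytest.raises(ValueError, match="cycle"):
            mesh_contribution(dag)

    def test_matches_path_enumeration_oracle_on_random_dags(self):
        dags = generate_mesh_dags([f"dis{i}" for i in range(20)],
                                  max_depth=4, branching=3, pool_size=8, seed=2)
        for dag in dags.values():
            got = mesh_contribution(dag)
            assert got == pytest.approx(oracle_contribution(dag))
            for v in got.values():
                k = round(np.log(v) / np.log(0.5))
                assert v == 0.5 ** k  # exactly a power of one half


class TestSemanticSimilarity:
    def test_identical_dags_score_one(self):
        d = chain_dag("d", "p", "g")
        assert semantic_similarity(d, d) == 1.0

    def test_disjoint_dags_score_zero(self):
        assert semantic_similarity(chain_dag("d1", "a1"), chain_dag("d2", "a2")) == 0.0

    def test_hand_computed_shared_ancestor(self):
        d1 = chain_dag("d1", "a")
        d2 = chain_dag("d2", "a")
        assert semantic_similarity(d1, d2) == pytest.approx((0.5 + 0.5) / (1.5 + 1.5))

    def test_matrix_symmetric_unit_diagonal(self):
        dags = list(generate_mesh_dags([f"x{i}" for i in range(12)], seed=4).values())
        sims = semantic_similarity_matrix(dags)
        assert np.allclose(sims, sims.T)
        assert np.allclose(np.diag(sims), 1.0)
        assert (sims >= 0).all() and (sims <= 1 + 1e-12).all()


class TestDiseaseAttributeMatrix:
    def test_identity_similarity_orthogonal_equal_norm_rows(self):
        M = disease_attribute_matrix(np.eye(3))
        G = M @ M.T
        assert np.allclose(G, np.eye(3), atol=1e-9)

    def test_rank_two_reconstruction(self):
        sims = np.array([[1.0, 0.5], [0.5, 1.0]])
        M = disease_attribute_matrix(sims)
        assert np.allclose(M @ M.T, sims, atol=1e-9)

    def test_dot_products_reproduce_similarities(self):
        dags = list(generate_mesh_dags([f"y{i}" for i in range(30)], seed=6).values())
        sims = semantic_similarity_matrix(dags)
        M = disease_attribute_matrix(sims)
        assert M.shape == (30, 64)
        assert np.allclose(M @ M.T, sims, atol=1e-6)

    def test_empty(self):
        assert disease_attribute_matrix(np.zeros((0, 0))).shape == (0, 64)


class TestDrugFingerprint:
    def test_deterministic_and_nonempty(self):
        v1, v2 = drug_fingerprint("C"), drug_fingerprint("C")
        assert v1.sum() >= 1
        assert np.array_equal(v1, v2)
        assert set(np.unique(v1)) <= {0.0, 1.0}

    def test_smiles_spellings_canonicalize(self):
        assert np.array_equal(drug_fingerprint("CCO"), drug_fingerprint("OCC"))

    def test_unparseable_zero_or_strict_raise(self):
        assert drug_fingerprint("not_smiles").sum() == 0
        with pytest.raises(ValueError):
            drug_fingerprint("not_smiles", strict=True)


class TestAssemble:
    def test_dispatch_and_coverage(self, tiny_net):
        sequences = {"l1": "ACGUACGUACGU", "m1": "ACGUACG", "p1": "KKRRKKRR"}
        dags = {"d1": chain_dag("td1", "a"), "d2": chain_dag("td2", "a")}
        smiles = {"x1": "CCO"}
        attrs = lb.assemble_attributes(tiny_net, sequences, smiles, dags)
        assert attrs.shape == (tiny_net.n, 64)
        for i, e in enumerate(tiny_net.nodes):
            if e.name in ("l1", "m1", "p1"):
                assert attrs[i].sum() == pytest.approx(1.0)
            elif e.name == "l2":  # no sequence supplied -> zero row
                assert attrs[i].sum() == 0
            elif e.node_type == "drug":
                assert set(np.unique(attrs[i])) <= {0.0, 1.0}

    def test_sequence_and_drug_rows_bounded(self, tiny_net):
        attrs = lb.assemble_attributes(
            tiny_net, {"l1": "ACGU" * 30}, {"x1": "CCO"}, {})
        assert attrs.min() >= 0 and attrs.max() <= 1
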