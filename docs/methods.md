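# Methods

## The prediction problem

A lncRNA–disease association (LDA) catalogue is a sparse bipartite label
set. `lncbridge` treats LDA prediction as supervised link scoring in which
the *representation* of lncRNAs and diseases is learned from a network that
deliberately contains no LDA edge. The premise: if a lncRNA and a disease
are biologically associated, the molecules each of them interacts with —
miRNAs that bind the lncRNA and are dysregulated in the disease, proteins
the lncRNA scaffolds that are disease targets, drugs hitting those targets —
already tie them together through *bridge paths* (e.g. lncRNA–miRNA–disease,
lncRNA–protein–protein–disease). Holding the labels out of the graph makes
the evaluation honest (no edge leakage between CV folds is possible, so the
embedding is computed once) and forces the model to exploit exactly this
bridge structure.

## Network model

Eight bridge relations over five node types are merged into one undirected,
unweighted graph with binary symmetric adjacency `S`, zero diagonal, and a
node index sorted by (type, name) so rebuilding from the same inputs is
byte-deterministic. Identifiers are normalized (trim, case-fold, collapse
internal whitespace) and may be passed through a user-supplied synonym
table; duplicate records are removed as unordered pairs; multi-source edges
between the same node pair collapse to a single binary edge. Any table
typed lncRNA–disease is rejected at construction — the leakage guard is
structural, not procedural.

Bridge-path counting enumerates simple typed paths (length 3–5, lncRNA →
bridge types → disease) with all nodes pairwise distinct; requiring
distinctness avoids degenerate protein–protein paths reusing one protein.
Per-role node counts only consider nodes on *complete* paths, i.e. paths
whose every edge is present simultaneously.

## Structural embedding

The embedder is a deep sigmoid autoencoder over adjacency rows with the
joint objective

  L = ‖(X̂−X)⊙B‖²_F + α·Σ_ij s_ij‖y_i−y_j‖² + ν·½Σ_k(‖W⁽ᵏ⁾‖²+‖Ŵ⁽ᵏ⁾‖²)

- second-order term: reconstruction of each node's neighborhood, with
  observed entries reweighted by β > 1 (`b_ij = β` where `s_ij ≠ 0`) so the
  overwhelming zeros of a sparse graph do not dominate;
- first-order term: Laplacian smoothness (equal to 2·tr(YᵀLY)) pulling
  adjacent nodes' codes together;
- L2 weight decay on encoder and decoder weights, biases excluded.

Gradients are derived by hand (plain backpropagation plus the 4αLY code-layer
term) and checked against central differences; optimization is full-batch
Adam, which keeps training deterministic given the seed. Mini-batching is
deliberately not implemented: at the intended scale (hundreds to a few
thousand nodes) full batch fits easily and removes an ordering
nondeterminism.

Defaults, chosen within the operating ranges customary for deep
network-embedding autoencoders and exposed in `SdneConfig`: layers
[256, 128] (128-dim codes), β = 5, α = 0.05, ν = 1e-4, learning rate 1e-3,
200 epochs, Glorot-uniform initialization. The sigmoid output layer suits
the binary adjacency targets.

## Node attributes

All four modalities land in a common 64-dim space so the attribute block of
every node type has one shape:

- **ncRNA**: normalized 3-mer frequencies, bins in lexicographic A/C/G/U
  order (k = 3 is the only k with 4^k = 64); T is read as U; windows
  containing ambiguous symbols are skipped so the valid windows still sum
  to one.
- **protein**: residues first collapse to four side-chain polarity classes
  (nonpolar G A V L I P F M W → 0; polar uncharged S T C Y N Q → 1;
  positive K R H → 2; negative D E → 3), then 3-mer frequencies over the
  reduced alphabet (4³ = 64). The partition is configurable; nonstandard
  residues are dropped.
- **disease**: MeSH-style ancestor DAGs give each term a contribution to
  the disease — 1 for the disease's own term, halving per generation with
  the max taken over children (so a term's value is 0.5^(shortest
  child-path distance)). Pairwise similarity is the shared-term
  contribution mass over the total mass of both diseases. The m×m
  similarity matrix is embedded by top-64 symmetric eigendecomposition,
  rows U·√Σ with a largest-entry-positive sign convention: deterministic,
  and row dot products reproduce the similarity matrix whenever its rank
  fits (disease rows therefore live in [−1, 1], unlike the non-negative
  sequence/fingerprint rows).
- **drug**: RDKit Morgan fingerprints, radius 2, folded to 64 bits. RDKit's
  canonicalization makes equivalent SMILES spellings identical.

Nodes with missing source data get zero rows and are counted in a logged
coverage report rather than failing the assembly.

## Pair features, classification, evaluation

A pair vector is the lncRNA block followed by the disease block; per node
the block is the 64-dim attributes, the 128-dim embedding, or their 192-dim
concatenation (attribute first), giving 128/256/384-dim pair vectors.
Negatives are sampled uniformly without replacement from unlabeled pairs at
a 1:1 ratio (balanced test folds make accuracy/sensitivity/specificity
comparable). Classifiers run at library defaults with only the seed (and
single-threading) pinned. Stratified 5-fold CV reports per-fold and
unweighted-mean accuracy, sensitivity, specificity (TN/(TN+FP)), precision,
F1, MCC, ROC-AUC (Mann–Whitney normalization, ties ½) and PR-AUC (monotone
step sum); metrics with zero denominators are reported as NaN with a
warning, never silently as 0. Because per-fold-averaged and pooled ROC
areas can differ, both are returned. Candidate ranking trains on all
labeled pairs, scores every unlabeled lncRNA for the query disease, and
breaks score ties by name for determinism.

## Synthetic study design

The generator plants one ground truth — a community partition — into every
relation: each of the eight bridge relations is an independent cross-type
stochastic block model (edge probability `p_in` within a community, `p_out`
across; defaults 0.3 / 0.02, two balanced communities, 60/40/80/30/50
nodes per type). Nodes left isolated by sampling are attached to one
same-community partner so every molecule participates. Held-out true LDA
pairs obey the *same* block law: a catalogued association is modelled as
requiring two independent bridge-chain lines of evidence (mirroring the
evidence-count grading of curated databases), so a pair's sampling weight
is the squared affinity of its dominant lncRNA–bridge–disease chain —
(p_in·p_in)² within a community versus (p_in·p_out)² across. Two
properties follow by construction: the association signal is recoverable
through bridge molecules only (the labels concentrate within the same
communities the graph expresses), and when `p_in = p_out` all pair weights
coincide, so the labels are exactly uniform and the null configuration
plants no signal whatsoever — neither in the graph nor in the label
co-occurrence pattern. 1000 positives are drawn at the defaults (dense
annotation of the planted modules, leaving 2000 unlabeled pairs for
negative sampling).

Sequences are i.i.d. uniform over their alphabets (lncRNA 200–500 nt,
miRNA 20–25 nt, protein 150–350 aa) with an optional community-specific
compositional bias for experiments that need informative attributes; MeSH
hierarchies are layered random DAGs over a shared ancestor pool (acyclic by
levels, overlap drives similarity); drugs draw from a hand-curated pool of
55 parseable drug-like SMILES. All artifacts round-trip losslessly through
the plain-text writers/readers (TSV, FASTA, JSON manifest).

What the synthetic benchmark does *not* emulate: realistic degree
distributions (real interactomes are heavy-tailed, the SBM is not),
compositional structure of real sequences, real MeSH topology, and any
correlation between attributes and associations — attributes are
uninformative about the planted labels by default. Passing tests therefore
demonstrate that the pipeline recovers relational structure routed through
bridge nodes, not that it attains any particular accuracy on real
databases. One subtlety worth knowing: even "uninformative" attributes give
above-chance CV scores on the planted benchmark, because distinct per-node
vectors act as node identifiers through which a flexible classifier can
generalize label co-occurrence (a collaborative-filtering effect present in
any entity-feature link-prediction CV); the bridge embedding still
dominates it.

## Numerical choices and degenerate inputs

- Sigmoid computed in the numerically stable two-branch form; training
  aborts with a diagnostic on non-finite loss.
- Similarity eigendecomposition clips tiny negative eigenvalues to zero.
- Sequences shorter than k (or with no valid window) yield zero vectors
  plus a warning; unparseable SMILES yield zero fingerprints (strict mode
  raises).
- Score exactly at the 0.5 decision threshold predicts positive.
- Weighted sampling of true pairs uses the exponential-race construction,
  deterministic given the seed; all derived seeds stay below 2³¹.
- Contribution computation is Kahn-style reverse-topological and raises on
  cycles rather than looping.

## Known limitations

- Full-batch training materializes the dense n×n adjacency: fine to a few
  thousand nodes, not for genome-scale networks.
- Negative "unlabeled" pairs may contain true but uncatalogued
  associations; with a 1:1 ratio the induced label noise is modest but
  real.
- The embedding is transductive — adding a node requires retraining.
- Disease attributes depend on MeSH coverage; diseases without a DAG get
  zero attribute rows.
- Exhaustive path enumeration is exponential in template length and is
  intended for census-style reporting on moderate networks, not for
  million-edge graphs.
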