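"""Plain-text readers and writers for every input the pipeline consumes.

Formats:

* association tables — TSV ``source_id<TAB>target_id``, one file per
  relation, tied together by a JSON manifest mapping relation name to path;
* sequences — FASTA, first header token is the entity name;
* drug structures — TSV ``drug_id<TAB>smiles``;
* disease semantics — TSV ``parent_term<TAB>child_term`` (the MeSH-style
  hierarchy) plus TSV ``disease_id<TAB>mesh_term``;
* labels — TSV ``lncRNA_id<TAB>disease_id`` of positive pairs.
"""

from __future__ import annotations

import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .attributes import MeshDag
from .network import (
    LDA_RELATION,
    AssociationTable,
    EntityId,
    load_association_table,
    normalize_name,
)
from .synthetic import MeshHierarchy, SynthBundle, ancestor_dag

MANIFEST_NAME = "manifest.json"


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sorted(sequences.items())]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {normalize_name(rec.id): str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_smiles_table(smiles: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for did, smi in sorted(smiles.items()):
            fh.write(f"{did}\t{smi}\n")


def read_smiles_table(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            did, smi = line.split("\t")[:2]
            out[normalize_name(did)] = smi.strip()
    return out


def write_mesh(hier: MeshHierarchy, edges_path: str | Path, mapping_path: str | Path) -> None:
    with open(edges_path, "w") as fh:
        for p, c in sorted(hier.parent_child):
            fh.write(f"{p}\t{c}\n")
    with open(mapping_path, "w") as fh:
        for did, term in sorted(hier.disease_term.items()):
            fh.write(f"{did}\t{term}\n")


def read_mesh(edges_path: str | Path, mapping_path: str | Path) -> dict[str, MeshDag]:
    """Per-disease ancestor DAGs from the global hierarchy extract."""
    edges: set[tuple[str, str]] = set()
    with open(edges_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            p, c = line.split("\t")[:2]
            edges.add((p.strip(), c.strip()))
    out: dict[str, MeshDag] = {}
    with open(mapping_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            did, term = line.split("\t")[:2]
            out[normalize_name(did)] = ancestor_dag(edges, term.strip())
    return out


def write_pairs(pairs, path: str | Path) -> None:
    with open(path, "w") as fh:
        for l, d in sorted(pairs):
            fh.write(f"{l.name}\t{d.name}\n")


def read_pairs(path: str | Path) -> set[tuple[EntityId, EntityId]]:
    table = load_association_table(path, LDA_RELATION)
    return set(table.records)


def write_association_table(table: AssociationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in table.records:
            fh.write(f"{a.name}\t{b.name}\n")


def write_bundle(bundle: SynthBundle, outdir: str | Path) -> Path:
    """Write a synthetic bundle as the exact file set the real-data path
    consumes; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for table in bundle.network.tables:
        fname = f"{table.relation_type}.tsv"
        write_association_table(table, outdir / fname)
        manifest[table.relation_type] = fname
    write_pairs(bundle.network.true_lda, outdir / "lda.tsv")

    by_type: dict[str, dict[str, str]] = {"lncRNA": {}, "miRNA": {}, "protein": {}}
    prefixes = {"lnc": "lncRNA", "mir": "miRNA", "prot": "protein"}
    for name, seq in bundle.sequences.items():
        for prefix, t in prefixes.items():
            if name.startswith(prefix):
                by_type[t][name] = seq
                break
    write_fasta(by_type["lncRNA"], outdir / "lncRNA.fa")
    write_fasta(by_type["miRNA"], outdir / "miRNA.fa")
    write_fasta(by_type["protein"], outdir / "protein.fa")
    write_smiles_table(bundle.smiles, outdir / "drugs.tsv")
    write_mesh(bundle.hierarchy, outdir / "mesh_edges.tsv", outdir / "mesh_mapping.tsv")

    manifest_path = outdir / MANIFEST_NAME
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest_path


def read_manifest(manifest_path: str | Path) -> list[AssociationTable]:
    """Load every association table named by a manifest (paths relative to
    the manifest's directory)."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest: dict[str, str] = json.load(fh)
    base = manifest_path.parent
    return [load_association_table(base / fname, rel)
            for rel, fname in sorted(manifest.items())]
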