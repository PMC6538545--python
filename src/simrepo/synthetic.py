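"""Synthetic cluster-structured drug/disease data for end-to-end testing.

The generative model encodes the method's core premise — similar drugs treat
similar diseases — as explicit cluster structure.  Each cluster owns a
prototype for every property (fingerprint, side-effect set, target protein,
gene set, GO subtree, HPO subtree); cluster members are copies of the
prototype with independent per-element corruption at a configurable noise
rate.  Drug-disease associations connect drugs and diseases of the same
cluster; 20% of the within-cluster pairs are withheld from the gold standard
as a natural external-validation / recovery set.  The phenotype matrix is
block-structured (within-cluster base 0.9, between 0.1) with symmetric
jitter.

Every output can be written in the standard tabular/FASTA/OBO formats of
:mod:`simrepo.entities` and :mod:`simrepo.ontology`, byte-identically for a
fixed seed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np

from .entities import (
    AssociationSet,
    DiseaseRecord,
    DrugRecord,
    write_annotation_table,
    write_association_table,
    write_disease_collection,
    write_drug_collection,
)
from .ontology import OntologyDAG, write_obo
from .similarity import SimilarityMatrix

AA_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

CORRUPTIBLE_FIELDS = ("fingerprint", "side_effects", "targets", "genes", "hpo_terms")


@dataclass
class SyntheticConfig:
    """Shape, size and noise of one synthetic study."""

    n_clusters: int = 4
    drugs_per_cluster: int = 5
    diseases_per_cluster: int = 5
    fingerprint_length: int = 1021
    n_side_effect_terms: int = 80
    side_effects_per_drug: int = 10
    target_length: int = 60
    genes_per_cluster: int = 6
    genes_per_entity: int = 4
    ontology_depth: int = 3
    ontology_branching: int = 2
    terms_per_gene: int = 2
    hpo_terms_per_disease: int = 3
    noise: float = 0.05
    holdout_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError("noise must lie in [0, 1]")
        for name in (
            "n_clusters", "drugs_per_cluster", "diseases_per_cluster",
            "fingerprint_length", "n_side_effect_terms", "target_length",
            "genes_per_cluster", "ontology_depth", "ontology_branching",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class SyntheticDataset:
    """All inputs one pipeline run needs, in memory."""

    config: SyntheticConfig
    drugs: dict[str, DrugRecord]
    diseases: dict[str, DiseaseRecord]
    gold: AssociationSet
    held_out: AssociationSet
    go_dag: OntologyDAG
    go_annotations: dict[str, set[str]]
    hpo_dag: OntologyDAG
    phenotype: SimilarityMatrix

    @property
    def hpo_leaves(self) -> list[str]:
        g = self.hpo_dag.graph
        return sorted(t for t in g.nodes if g.in_degree(t) == 0)


def _build_cluster_ontology(prefix: str, n_clusters: int, depth: int, branching: int):
    """One subtree per cluster under a shared root; returns (dag, leaves per cluster)."""
    root = f"{prefix}:ROOT"
    edges = []
    terms = [root]
    leaves: list[list[str]] = []
    for c in range(n_clusters):
        level = [f"{prefix}:C{c:02d}"]
        terms += level
        edges += [(level[0], root)]
        for d in range(1, depth + 1):
            nxt = []
            for parent in level:
                for b in range(branching):
                    child = f"{parent}.{d}{string.ascii_lowercase[b]}"
                    nxt.append(child)
                    edges.append((child, parent))
            terms += nxt
            level = nxt
        leaves.append(level)
    return OntologyDAG(edges=edges, terms=terms), leaves


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one complete synthetic dataset from the cluster-prototype model."""
    rng = np.random.default_rng(config.seed)
    c = config
    noise = c.noise

    go_dag, go_leaves = _build_cluster_ontology(
        "GO", c.n_clusters, c.ontology_depth, c.ontology_branching
    )
    hpo_dag, hpo_leaves = _build_cluster_ontology(
        "HP", c.n_clusters, c.ontology_depth, c.ontology_branching
    )
    all_hpo_leaves = [t for lv in hpo_leaves for t in lv]

    se_vocab = [f"SE{i:04d}" for i in range(c.n_side_effect_terms)]
    gene_pool = [
        f"G{cl:02d}_{g:02d}" for cl in range(c.n_clusters) for g in range(c.genes_per_cluster)
    ]

    # gene -> GO annotation corpus: each cluster gene annotated to leaves of
    # its own cluster subtree
    go_annotations: dict[str, set[str]] = {}
    for cl in range(c.n_clusters):
        for g in range(c.genes_per_cluster):
            gene = f"G{cl:02d}_{g:02d}"
            k = min(c.terms_per_gene, len(go_leaves[cl]))
            picks = rng.choice(len(go_leaves[cl]), size=k, replace=False)
            go_annotations[gene] = {go_leaves[cl][i] for i in picks}

    def corrupt_fingerprint(fp: np.ndarray) -> np.ndarray:
        flip = rng.random(fp.size) < noise
        return np.where(flip, 1 - fp, fp).astype(np.uint8)

    def corrupt_set(items: set[str], pool: list[str]) -> set[str]:
        out = set()
        for it in sorted(items):
            if rng.random() < noise:
                out.add(pool[rng.integers(len(pool))])
            else:
                out.add(it)
        return out

    def corrupt_seq(seq: str) -> str:
        chars = np.array(list(seq))
        hit = rng.random(chars.size) < noise
        repl = AA_ALPHABET[rng.integers(0, len(AA_ALPHABET), size=chars.size)]
        return "".join(np.where(hit, repl, chars))

    drugs: dict[str, DrugRecord] = {}
    diseases: dict[str, DiseaseRecord] = {}
    for cl in range(c.n_clusters):
        proto_fp = rng.integers(0, 2, size=c.fingerprint_length, dtype=np.uint8)
        se_idx = rng.choice(c.n_side_effect_terms, size=min(c.side_effects_per_drug, c.n_side_effect_terms), replace=False)
        proto_se = {se_vocab[i] for i in se_idx}
        proto_target = "".join(AA_ALPHABET[rng.integers(0, len(AA_ALPHABET), size=c.target_length)])
        cluster_genes = [f"G{cl:02d}_{g:02d}" for g in range(c.genes_per_cluster)]
        gene_idx = rng.choice(c.genes_per_cluster, size=min(c.genes_per_entity, c.genes_per_cluster), replace=False)
        proto_genes = {cluster_genes[i] for i in gene_idx}
        hpo_k = min(c.hpo_terms_per_disease, len(hpo_leaves[cl]))
        hpo_idx = rng.choice(len(hpo_leaves[cl]), size=hpo_k, replace=False)
        proto_hpo = {hpo_leaves[cl][i] for i in hpo_idx}

        for k in range(c.drugs_per_cluster):
            drug_id = f"DR{cl:02d}_{k:02d}"
            drugs[drug_id] = DrugRecord(
                drug_id=drug_id,
                fingerprint=corrupt_fingerprint(proto_fp),
                side_effects=corrupt_set(proto_se, se_vocab),
                targets=[corrupt_seq(proto_target)],
                genes=corrupt_set(proto_genes, gene_pool),
            )
        for k in range(c.diseases_per_cluster):
            disease_id = f"DI{cl:02d}_{k:02d}"
            diseases[disease_id] = DiseaseRecord(
                disease_id=disease_id,
                hpo_terms=corrupt_set(proto_hpo, all_hpo_leaves),
                genes=corrupt_set(proto_genes, gene_pool),
            )

    # within-cluster associations; a fixed fraction withheld as held_out
    within = [
        (f"DR{cl:02d}_{i:02d}", f"DI{cl:02d}_{j:02d}")
        for cl in range(c.n_clusters)
        for i in range(c.drugs_per_cluster)
        for j in range(c.diseases_per_cluster)
    ]
    n_held = round(c.holdout_fraction * len(within))
    order = rng.permutation(len(within))
    held = {within[i] for i in order[:n_held]}
    gold = {within[i] for i in order[n_held:]}

    # block phenotype matrix with symmetric jitter
    disease_ids = sorted(diseases)
    n = len(disease_ids)
    cluster_of = np.array([int(d[2:4]) for d in disease_ids])
    base = np.where(cluster_of[:, None] == cluster_of[None, :], 0.9, 0.1).astype(float)
    jitter = rng.uniform(-noise / 2.0, noise / 2.0, size=(n, n))
    jitter = (jitter + jitter.T) / 2.0
    values = np.clip(base + jitter, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    phenotype = SimilarityMatrix(kind="diPhe", ids=disease_ids, values=values)

    return SyntheticDataset(
        config=c,
        drugs=drugs,
        diseases=diseases,
        gold=AssociationSet(gold, "positive"),
        held_out=AssociationSet(held, "positive"),
        go_dag=go_dag,
        go_annotations=go_annotations,
        hpo_dag=hpo_dag,
        phenotype=phenotype,
    )


def corrupt(
    dataset: SyntheticDataset, fieldname: str, rate: float, seed: int
) -> SyntheticDataset:
    """Re-corrupt one property field of an existing dataset (for ablations).

    Every other field is returned bit-identical; only the named field is
    independently perturbed at ``rate`` using the same per-element scheme as
    the generator.
    """
    if fieldname not in CORRUPTIBLE_FIELDS:
        raise ValueError(f"unknown field {fieldname!r}; choose from {CORRUPTIBLE_FIELDS}")
    rng = np.random.default_rng(seed)
    c = dataset.config
    se_vocab = [f"SE{i:04d}" for i in range(c.n_side_effect_terms)]
    gene_pool = sorted(
        {g for d in dataset.drugs.values() for g in d.genes}
        | {g for d in dataset.diseases.values() for g in d.genes}
        | set(dataset.go_annotations)
    )
    hpo_leaves = dataset.hpo_leaves

    def corrupt_set(items: set[str], pool: list[str]) -> set[str]:
        out = set()
        for it in sorted(items):
            out.add(pool[rng.integers(len(pool))] if rng.random() < rate else it)
        return out

    drugs = {}
    for drug_id, d in dataset.drugs.items():
        fp, se, tg, gn = d.fingerprint, set(d.side_effects), list(d.targets), set(d.genes)
        if fieldname == "fingerprint" and fp is not None:
            flip = rng.random(fp.size) < rate
            fp = np.where(flip, 1 - fp, fp).astype(np.uint8)
        elif fieldname == "side_effects":
            se = corrupt_set(se, se_vocab)
        elif fieldname == "targets":
            new = []
            for seq in tg:
                chars = np.array(list(seq))
                hit = rng.random(chars.size) < rate
                repl = AA_ALPHABET[rng.integers(0, len(AA_ALPHABET), size=chars.size)]
                new.append("".join(np.where(hit, repl, chars)))
            tg = new
        elif fieldname == "genes":
            gn = corrupt_set(gn, gene_pool)
        drugs[drug_id] = DrugRecord(drug_id, fp, se, tg, gn)

    diseases = {}
    for disease_id, d in dataset.diseases.items():
        hp, gn = set(d.hpo_terms), set(d.genes)
        if fieldname == "hpo_terms":
            hp = corrupt_set(hp, hpo_leaves)
        elif fieldname == "genes":
            gn = corrupt_set(gn, gene_pool)
        diseases[disease_id] = DiseaseRecord(disease_id, hp, gn)

    return replace(dataset, drugs=drugs, diseases=diseases)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the complete file set in the standard input formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fingerprints": out / "fingerprints.tsv",
        "side_effects": out / "side_effects.tsv",
        "targets": out / "targets.fasta",
        "drug_genes": out / "drug_genes.tsv",
        "hpo_terms": out / "hpo_terms.tsv",
        "disease_genes": out / "disease_genes.tsv",
        "gold": out / "gold_associations.tsv",
        "held_out": out / "held_out_associations.tsv",
        "go_obo": out / "go.obo",
        "hpo_obo": out / "hpo.obo",
        "go_annotations": out / "go_annotations.tsv",
        "phenotype": out / "phenotype_similarity.tsv",
    }
    write_drug_collection(
        dataset.drugs,
        paths["fingerprints"], paths["side_effects"], paths["targets"], paths["drug_genes"],
    )
    write_disease_collection(dataset.diseases, paths["hpo_terms"], paths["disease_genes"])
    write_association_table(dataset.gold, paths["gold"])
    write_association_table(dataset.held_out, paths["held_out"])
    write_obo(dataset.go_dag, paths["go_obo"], "go-synthetic")
    write_obo(dataset.hpo_dag, paths["hpo_obo"], "hpo-synthetic")
    write_annotation_table(dataset.go_annotations, paths["go_annotations"])
    dataset.phenotype.to_tsv(paths["phenotype"])
    return paths


def load_dataset(data_dir: str | Path) -> SyntheticDataset:
    """Read a written dataset back through the standard readers."""
    from .entities import (
        read_annotation_table,
        read_association_table,
        read_disease_collection,
        read_drug_collection,
        read_phenotype_matrix,
    )
    from .ontology import load_obo

    d = Path(data_dir)
    drugs = read_drug_collection(
        d / "fingerprints.tsv", d / "side_effects.tsv", d / "targets.fasta", d / "drug_genes.tsv"
    )
    diseases = read_disease_collection(d / "hpo_terms.tsv", d / "disease_genes.tsv")
    gold = read_association_table(d / "gold_associations.tsv")
    held_path = d / "held_out_associations.tsv"
    held = read_association_table(held_path) if held_path.exists() else AssociationSet(set())
    return SyntheticDataset(
        config=SyntheticConfig(),
        drugs=drugs,
        diseases=diseases,
        gold=gold,
        held_out=held,
        go_dag=load_obo(d / "go.obo"),
        go_annotations=read_annotation_table(d / "go_annotations.tsv"),
        hpo_dag=load_obo(d / "hpo.obo"),
        phenotype=read_phenotype_matrix(d / "phenotype_similarity.tsv"),
    )
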