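"""Wiring of the full workflow: kernels -> features -> models -> predictions."""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass
from pathlib import Path

from .learn import (
    TrialConfig,
    cross_validate,
    external_validate,
    predict_novel,
    predictions_to_frame,
)
from .ontology import build_semantic_matrix, compute_ic, pool_gene_terms
from .similarity import AlignmentScoring, SimilarityMatrix, build_matrix
from .synthetic import SyntheticDataset


def compute_kernels(
    dataset: SyntheticDataset, scoring: AlignmentScoring | None = None
) -> dict[str, SimilarityMatrix]:
    """All seven similarity matrices for one dataset.

    Drug kernels: Tanimoto fingerprints, Jaccard side effects, normalized
    Smith-Waterman targets, and GO similarity of the drug's genes (pooled
    terms, Resnik + BMA).  Disease kernels: GO similarity of disease genes
    (same IC corpus as the drug side), HPO similarity of the disease's direct
    terms (IC corpus = the disease->HPO table itself), and the precomputed
    phenotype matrix.
    """
    scoring = scoring or AlignmentScoring()
    go_ic = compute_ic(dataset.go_dag, dataset.go_annotations)
    drug_terms = {
        d: pool_gene_terms(rec.genes, dataset.go_annotations)
        for d, rec in dataset.drugs.items()
    }
    disease_terms = {
        d: pool_gene_terms(rec.genes, dataset.go_annotations)
        for d, rec in dataset.diseases.items()
    }
    hpo_sets = {d: set(rec.hpo_terms) for d, rec in dataset.diseases.items()}
    hpo_ic = compute_ic(dataset.hpo_dag, hpo_sets)
    return {
        "drChe": build_matrix(dataset.drugs, "drChe"),
        "drSE": build_matrix(dataset.drugs, "drSE"),
        "drTar": build_matrix(dataset.drugs, "drTar", scoring),
        "drGO": build_semantic_matrix(drug_terms, dataset.go_dag, go_ic, "drGO"),
        "diGO": build_semantic_matrix(disease_terms, dataset.go_dag, go_ic, "diGO"),
        "diHPO": build_semantic_matrix(hpo_sets, dataset.hpo_dag, hpo_ic, "diHPO"),
        "diPhe": dataset.phenotype,
    }


@dataclass
class RunConfig:
    """One reproducible pipeline run (simulate -> kernels -> cv -> validate -> predict)."""

    out_dir: str
    seed: int = 0
    n_clusters: int = 4
    drugs_per_cluster: int = 5
    diseases_per_cluster: int = 5
    noise: float = 0.05
    algorithm: str = "random-forest"
    n_trials: int = 5
    n_folds: int = 10
    negative_ratio: float = 2.0
    aggregator: str = "max"
    decision_threshold: float = 0.5


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic study and write every artifact plus a manifest.

    Returns the manifest dict.  Any stage error propagates with the stage
    named in the exception message.
    """
    from .synthetic import SyntheticConfig, generate, write_dataset

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "python": platform.python_version(),
        "stages": {},
        "outputs": [],
    }

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = info

    syn = SyntheticConfig(
        n_clusters=config.n_clusters,
        drugs_per_cluster=config.drugs_per_cluster,
        diseases_per_cluster=config.diseases_per_cluster,
        noise=config.noise,
        seed=config.seed,
    )
    dataset = generate(syn)
    paths = write_dataset(dataset, out / "data")
    manifest["outputs"] += [str(p.relative_to(out)) for p in paths.values()]
    record(
        "simulate",
        n_drugs=len(dataset.drugs),
        n_diseases=len(dataset.diseases),
        n_gold=len(dataset.gold),
        n_held_out=len(dataset.held_out),
    )

    matrices = compute_kernels(dataset)
    for kind, m in matrices.items():
        p = out / f"similarity_{kind}.tsv"
        m.to_tsv(p)
        manifest["outputs"].append(p.name)
    record("similarity", kernels=sorted(matrices))

    tc = TrialConfig(
        algorithm=config.algorithm,
        negative_ratio=config.negative_ratio,
        n_trials=config.n_trials,
        n_folds=config.n_folds,
        seed=config.seed,
        decision_threshold=config.decision_threshold,
        aggregator=config.aggregator,
    )
    cv_report = cross_validate(dataset.gold, matrices, tc)
    cv_path = out / "cv_report.tsv"
    cv_report.to_tsv(cv_path)
    manifest["outputs"].append(cv_path.name)
    record("cv", n_records=len(cv_report.records), mean_auc=round(cv_report.mean("auc"), 6))

    if dataset.held_out.pairs:
        ev_report = external_validate(dataset.held_out, dataset.gold, matrices, tc)
        ev_path = out / "external_report.tsv"
        ev_report.to_tsv(ev_path)
        manifest["outputs"].append(ev_path.name)
        record("validate", n_records=len(ev_report.records), mean_auc=round(ev_report.mean("auc"), 6))

    drug_ids = sorted(dataset.drugs)
    disease_ids = sorted(dataset.diseases)
    queries = [
        (d, s) for d in drug_ids for s in disease_ids if (d, s) not in dataset.gold
    ]
    records = predict_novel(dataset.gold, queries, matrices, tc)
    pred_path = out / "predictions.tsv"
    predictions_to_frame(records).to_csv(pred_path, sep="\t", index=False, float_format="%.6f")
    manifest["outputs"].append(pred_path.name)
    record(
        "predict",
        n_queries=len(records),
        n_novel=sum(r.is_novel for r in records),
    )

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
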