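"""Entity records, tabular/FASTA input-output, and completeness filtering.

All tabular files are tab-separated UTF-8 with a header row; lines starting
with ``#`` are comments.  Multi-target FASTA headers follow the
``drug_id|target_index`` convention so that one standard FASTA file can group
several target protein sequences per drug.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: the 20 standard amino acids, uppercase one-letter codes
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


class EntityIOError(ValueError):
    """Raised for malformed entity input files."""


@dataclass
class DrugRecord:
    """One drug with every property the drug-drug kernels consume.

    Absent properties are represented as ``None`` (fingerprint) or empty
    containers; completeness rules are enforced separately by
    :func:`filter_complete`, not at construction.
    """

    drug_id: str
    fingerprint: np.ndarray | None = None  # uint8 0/1 vector
    side_effects: set[str] = field(default_factory=set)
    targets: list[str] = field(default_factory=list)
    genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.drug_id:
            raise EntityIOError("drug_id must be non-empty")
        for seq in self.targets:
            bad = set(seq) - AMINO_ACIDS
            if bad:
                raise EntityIOError(
                    f"drug {self.drug_id}: invalid amino-acid letters {sorted(bad)} "
                    f"in target sequence"
                )


@dataclass
class DiseaseRecord:
    """One disease with its HPO annotation and associated-gene set."""

    disease_id: str
    hpo_terms: set[str] = field(default_factory=set)
    genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.disease_id:
            raise EntityIOError("disease_id must be non-empty")


@dataclass
class AssociationSet:
    """A labelled set of (drug_id, disease_id) pairs.

    ``M`` and ``N`` are the numbers of distinct drugs and diseases appearing
    in the pairs; they are derived, never stored independently.
    """

    pairs: set[tuple[str, str]] = field(default_factory=set)
    label: str = "positive"

    @property
    def M(self) -> int:
        return len({d for d, _ in self.pairs})

    @property
    def N(self) -> int:
        return len({s for _, s in self.pairs})

    @property
    def drug_ids(self) -> set[str]:
        return {d for d, _ in self.pairs}

    @property
    def disease_ids(self) -> set[str]:
        return {s for _, s in self.pairs}

    def sorted_pairs(self) -> list[tuple[str, str]]:
        return sorted(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs


@dataclass
class FilterReport:
    """Counts of entities removed per completeness rule."""

    drugs_missing_fingerprint: int = 0
    drugs_missing_side_effects: int = 0
    diseases_missing_genes: int = 0
    diseases_without_association: int = 0
    associations_dropped: int = 0


# ---------------------------------------------------------------------------
# readers


def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=required)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise EntityIOError(f"{path}: missing required column(s) {missing}")
    return df


def _parse_fingerprint(drug_id: str, text: str, lineno: int) -> np.ndarray:
    # accepted: compact "0101..." or comma-separated bit list "0,1,0,1"
    bits = text.split(",") if "," in text else list(text)
    if not all(b in ("0", "1") for b in bits):
        raise EntityIOError(
            f"fingerprint table line {lineno} (drug {drug_id}): "
            f"malformed bit string {text!r}"
        )
    return np.array([int(b) for b in bits], dtype=np.uint8)


def read_drug_collection(
    fingerprint_table: str | Path | None = None,
    side_effect_table: str | Path | None = None,
    target_fasta: str | Path | None = None,
    gene_table: str | Path | None = None,
) -> dict[str, DrugRecord]:
    """Assemble drug records from up to four property files.

    A record is created for every drug_id present in *any* input; properties
    absent for a drug are left empty.  Fingerprint lengths must be uniform
    across the collection.
    """
    drugs: dict[str, DrugRecord] = {}

    def rec(drug_id: str) -> DrugRecord:
        return drugs.setdefault(drug_id, DrugRecord(drug_id=drug_id))

    if fingerprint_table is not None:
        df = _read_table(fingerprint_table, ["drug_id", "fingerprint"])
        if df["drug_id"].duplicated().any():
            dup = sorted(df.loc[df["drug_id"].duplicated(), "drug_id"].unique())
            raise EntityIOError(f"{fingerprint_table}: duplicate drug_id {dup}")
        length: int | None = None
        for lineno, row in enumerate(df.itertuples(index=False), start=2):
            fp = _parse_fingerprint(row.drug_id, row.fingerprint, lineno)
            if length is None:
                length = fp.size
            elif fp.size != length:
                raise EntityIOError(
                    f"{fingerprint_table}: inconsistent fingerprint length for "
                    f"{row.drug_id} ({fp.size} != {length})"
                )
            rec(row.drug_id).fingerprint = fp

    if side_effect_table is not None:
        df = _read_table(side_effect_table, ["drug_id", "side_effect_id"])
        for row in df.itertuples(index=False):
            rec(row.drug_id).side_effects.add(row.side_effect_id)

    if target_fasta is not None:
        for entry in SeqIO.parse(str(target_fasta), "fasta"):
            drug_id = entry.id.split("|", 1)[0]
            seq = str(entry.seq).upper()
            bad = set(seq) - AMINO_ACIDS
            if bad:
                raise EntityIOError(
                    f"{target_fasta}: record {entry.id}: invalid residue(s) {sorted(bad)}"
                )
            rec(drug_id).targets.append(seq)

    if gene_table is not None:
        df = _read_table(gene_table, ["drug_id", "gene_id"])
        for row in df.itertuples(index=False):
            rec(row.drug_id).genes.add(row.gene_id)

    return drugs


def read_disease_collection(
    hpo_table: str | Path | None = None,
    gene_table: str | Path | None = None,
) -> dict[str, DiseaseRecord]:
    """Assemble disease records from HPO-term and gene tables."""
    diseases: dict[str, DiseaseRecord] = {}

    def rec(disease_id: str) -> DiseaseRecord:
        return diseases.setdefault(disease_id, DiseaseRecord(disease_id=disease_id))

    if hpo_table is not None:
        df = _read_table(hpo_table, ["disease_id", "hpo_id"])
        for row in df.itertuples(index=False):
            rec(row.disease_id).hpo_terms.add(row.hpo_id)
    if gene_table is not None:
        df = _read_table(gene_table, ["disease_id", "gene_id"])
        for row in df.itertuples(index=False):
            rec(row.disease_id).genes.add(row.gene_id)
    return diseases


def read_association_table(path: str | Path, label: str = "positive") -> AssociationSet:
    """Read a drug-disease association TSV (columns drug_id, disease_id)."""
    df = _read_table(path, ["drug_id", "disease_id"])
    pairs = {(r.drug_id, r.disease_id) for r in df.itertuples(index=False)}
    if not pairs:
        warnings.warn(f"{path}: no associations found", stacklevel=2)
    return AssociationSet(pairs=pairs, label=label)


def read_annotation_table(path: str | Path) -> dict[str, set[str]]:
    """Read gene -> ontology-term annotations (columns gene_id, term_id)."""
    df = _read_table(path, ["gene_id", "term_id"])
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.gene_id, set()).add(row.term_id)
    return out


def read_phenotype_matrix(path: str | Path):
    """Read a precomputed square disease-disease phenotypic similarity TSV.

    The matrix (e.g. text-mining derived phenotype similarity) must be
    symmetric within 1e-6 and lie in [0, 1] up to the same tolerance; values
    are clamped to [0, 1] and the diagonal is forced to exactly 1.
    """
    from .similarity import SimilarityMatrix  # local import to avoid cycle

    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    ids = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != ids:
        raise EntityIOError(f"{path}: row and column disease IDs differ")
    values = df.to_numpy(dtype=float)
    if np.nanmax(np.abs(values - values.T)) > 1e-6:
        raise EntityIOError(f"{path}: matrix asymmetric beyond tolerance 1e-6")
    if np.nanmin(values) < -1e-6 or np.nanmax(values) > 1 + 1e-6:
        raise EntityIOError(f"{path}: values outside [0, 1] beyond tolerance 1e-6")
    values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(kind="diPhe", ids=ids, values=values)


# ---------------------------------------------------------------------------
# completeness filtering


def filter_complete(
    drugs: Mapping[str, DrugRecord],
    diseases: Mapping[str, DiseaseRecord],
    associations: AssociationSet,
    require_disease_association: bool = True,
) -> tuple[dict[str, DrugRecord], dict[str, DiseaseRecord], AssociationSet, FilterReport]:
    """Apply the gold-standard completeness rules.

    Drops drugs missing a fingerprint or with an empty side-effect set, then
    diseases with an empty gene set or (when ``require_disease_association``)
    no surviving association, then every association touching a dropped
    entity.  Idempotent.  For an independent test set pass
    ``require_disease_association=False``: its diseases need only the
    property data the kernels consume.
    """
    report = FilterReport()
    kept_drugs: dict[str, DrugRecord] = {}
    for drug_id, drug in drugs.items():
        if drug.fingerprint is None or drug.fingerprint.size == 0:
            report.drugs_missing_fingerprint += 1
        elif not drug.side_effects:
            report.drugs_missing_side_effects += 1
        else:
            kept_drugs[drug_id] = drug

    surviving = {
        (d, s) for d, s in associations.pairs if d in kept_drugs and s in diseases
    }
    kept_diseases: dict[str, DiseaseRecord] = {}
    associated = {s for _, s in surviving}
    for disease_id, disease in diseases.items():
        if not disease.genes:
            report.diseases_missing_genes += 1
        elif require_disease_association and disease_id not in associated:
            report.diseases_without_association += 1
        else:
            kept_diseases[disease_id] = disease

    kept_pairs = {(d, s) for d, s in surviving if s in kept_diseases}
    report.associations_dropped = len(associations.pairs) - len(kept_pairs)
    if report.associations_dropped:
        logger.info(
            "filter_complete: dropped %d drugs (fingerprint), %d drugs (side effects), "
            "%d diseases (genes), %d diseases (no association), %d associations",
            report.drugs_missing_fingerprint,
            report.drugs_missing_side_effects,
            report.diseases_missing_genes,
            report.diseases_without_association,
            report.associations_dropped,
        )
    return kept_drugs, kept_diseases, AssociationSet(kept_pairs, associations.label), report


# ---------------------------------------------------------------------------
# writers (round-trip counterparts of the readers)


def write_drug_collection(
    drugs: Mapping[str, DrugRecord],
    fingerprint_table: str | Path,
    side_effect_table: str | Path,
    target_fasta: str | Path,
    gene_table: str | Path,
) -> None:
    ordered = [drugs[k] for k in sorted(drugs)]
    with open(fingerprint_table, "w") as fh:
        fh.write("drug_id\tfingerprint\n")
        for d in ordered:
            if d.fingerprint is not None:
                fh.write(f"{d.drug_id}\t{''.join(map(str, d.fingerprint))}\n")
    with open(side_effect_table, "w") as fh:
        fh.write("drug_id\tside_effect_id\n")
        for d in ordered:
            for se in sorted(d.side_effects):
                fh.write(f"{d.drug_id}\t{se}\n")
    records = [
        SeqRecord(Seq(seq), id=f"{d.drug_id}|{i}", description="")
        for d in ordered
        for i, seq in enumerate(d.targets)
    ]
    SeqIO.write(records, str(target_fasta), "fasta")
    with open(gene_table, "w") as fh:
        fh.write("drug_id\tgene_id\n")
        for d in ordered:
            for g in sorted(d.genes):
                fh.write(f"{d.drug_id}\t{g}\n")


def write_disease_collection(
    diseases: Mapping[str, DiseaseRecord],
    hpo_table: str | Path,
    gene_table: str | Path,
) -> None:
    ordered = [diseases[k] for k in sorted(diseases)]
    with open(hpo_table, "w") as fh:
        fh.write("disease_id\thpo_id\n")
        for d in ordered:
            for t in sorted(d.hpo_terms):
                fh.write(f"{d.disease_id}\t{t}\n")
    with open(gene_table, "w") as fh:
        fh.write("disease_id\tgene_id\n")
        for d in ordered:
            for g in sorted(d.genes):
                fh.write(f"{d.disease_id}\t{g}\n")


def write_association_table(associations: AssociationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("drug_id\tdisease_id\n")
        for d, s in associations.sorted_pairs():
            fh.write(f"{d}\t{s}\n")


def write_annotation_table(annotations: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tterm_id\n")
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                fh.write(f"{gene}\t{term}\n")
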