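"""Drug-drug similarity kernels and symmetric similarity matrices.

Three pairwise kernels live here: Tanimoto on molecular fingerprints
(``drChe``), Jaccard on side-effect term sets (``drSE``), and normalized
Smith-Waterman local alignment over target proteins (``drTar``).  The two
ontology-backed kernels (GO, HPO) are assembled in :mod:`simrepo.ontology`
and the phenotype kernel is ingested by
:func:`simrepo.entities.read_phenotype_matrix`; all seven share the
:class:`SimilarityMatrix` container.

Undefined pairwise values (e.g. a drug without annotated targets) are stored
as NaN and handled downstream by the feature builder.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .entities import AMINO_ACIDS, DrugRecord

KERNEL_KINDS = ("drChe", "drSE", "drTar", "drGO", "diPhe", "diHPO", "diGO")


@dataclass
class AlignmentScoring:
    """Affine-gap local-alignment parameters.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend`` (the first
    gapped position pays the open penalty).  Defaults are the conventional
    protein local-alignment setting: BLOSUM62, open -10, extend -1.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")

    def __hash__(self) -> int:
        return hash((self.matrix_name, self.gap_open, self.gap_extend))


@lru_cache(maxsize=8)
def _aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(
        mode="local",
        substitution_matrix=substitution_matrices.load(scoring.matrix_name),
        open_gap_score=scoring.gap_open,
        extend_gap_score=scoring.gap_extend,
    )
    return aligner


class SimilarityMatrix:
    """Symmetric entity-by-entity similarity matrix with values in [0, 1].

    NaN entries mark pairs for which the kernel is undefined.  The diagonal
    is 1 wherever self-similarity is defined.
    """

    def __init__(self, kind: str, ids: Sequence[str], values: np.ndarray):
        if kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {kind!r}")
        values = np.asarray(values, dtype=float)
        if values.shape != (len(ids), len(ids)):
            raise ValueError("matrix shape does not match id list")
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(values - values.T), initial=0.0) > 1e-9:
                raise ValueError("matrix not symmetric within 1e-9")
            finite = values[np.isfinite(values)]
            if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
                raise ValueError("similarity values outside [0, 1]")
        self.kind = kind
        self.ids = list(ids)
        self.values = values
        self._index = {e: i for i, e in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise ValueError("duplicate entity ids")

    def get(self, id_a: str, id_b: str) -> float:
        return float(self.values[self._index[id_a], self._index[id_b]])

    def rows(self, query_id: str, other_ids: Sequence[str]) -> np.ndarray:
        """Similarities of ``query_id`` against an ordered list of ids."""
        i = self._index[query_id]
        cols = [self._index[o] for o in other_ids]
        return self.values[i, cols]

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self._index

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.ids, columns=self.ids)
        df.to_csv(path, sep="\t", float_format="%.6f", index_label="id")

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        return cls(kind=kind, ids=[str(c) for c in df.columns], values=df.to_numpy(float))


# ---------------------------------------------------------------------------
# pairwise kernels


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| of two binary vectors.

    Two all-zero fingerprints yield 0 by convention (no shared substructure
    is no evidence of similarity).
    """
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.size} != {b.size}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return np.count_nonzero(a & b) / union


def jaccard(set_a: set, set_b: set) -> float:
    """Jaccard index |A∩B| / |A∪B|; 0 when both sets are empty."""
    if not set_a and not set_b:
        return 0.0
    return len(set_a & set_b) / len(set_a | set_b)


def smith_waterman(seq_a: str, seq_b: str, scoring: AlignmentScoring | None = None) -> float:
    """Optimal local alignment score under affine gap penalties (>= 0)."""
    scoring = scoring or AlignmentScoring()
    for seq in (seq_a, seq_b):
        if not seq:
            raise ValueError("empty sequence")
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise ValueError(f"invalid residue(s) {sorted(bad)}")
    return float(_aligner(scoring).score(seq_a, seq_b))


def target_similarity(
    drug_a: DrugRecord, drug_b: DrugRecord, scoring: AlignmentScoring | None = None
) -> float | None:
    """Maximum self-score-normalized alignment over all target pairs.

    Each target pair (p, q) scores SW(p,q) / sqrt(SW(p,p) * SW(q,q)), which
    is 1 for identical sequences and bounded by [0, 1]; the drug-level value
    is the maximum over the Cartesian product of the two target lists.
    Returns None (undefined) when either drug has no targets.
    """
    scoring = scoring or AlignmentScoring()
    if not drug_a.targets or not drug_b.targets:
        return None
    self_a = [smith_waterman(p, p, scoring) for p in drug_a.targets]
    self_b = [smith_waterman(q, q, scoring) for q in drug_b.targets]
    best = 0.0
    for p, sp in zip(drug_a.targets, self_a):
        for q, sq in zip(drug_b.targets, self_b):
            denom = np.sqrt(sp * sq)
            if denom <= 0:
                continue
            best = max(best, smith_waterman(p, q, scoring) / denom)
    return min(best, 1.0)


# ---------------------------------------------------------------------------
# matrix assembly


def build_matrix(
    drugs: Mapping[str, DrugRecord],
    kind: str,
    scoring: AlignmentScoring | None = None,
) -> SimilarityMatrix:
    """Assemble one drug-drug similarity matrix.

    Only the upper triangle is computed and mirrored.  ``kind`` selects the
    kernel: ``drChe`` (fingerprints), ``drSE`` (side effects) or ``drTar``
    (targets).  Pairs for which the kernel is undefined (missing fingerprint
    or no targets) are NaN, including the diagonal.
    """
    ids = sorted(drugs)
    n = len(ids)
    values = np.full((n, n), np.nan)
    if kind == "drChe":
        def pair(a: DrugRecord, b: DrugRecord) -> float | None:
            if a.fingerprint is None or b.fingerprint is None:
                return None
            return tanimoto(a.fingerprint, b.fingerprint)
    elif kind == "drSE":
        def pair(a: DrugRecord, b: DrugRecord) -> float | None:
            return jaccard(a.side_effects, b.side_effects)
    elif kind == "drTar":
        scoring = scoring or AlignmentScoring()

        def pair(a: DrugRecord, b: DrugRecord) -> float | None:
            return target_similarity(a, b, scoring)
    else:
        raise ValueError(f"build_matrix handles drChe/drSE/drTar, not {kind!r}")

    for i, id_a in enumerate(ids):
        a = drugs[id_a]
        defined_self = (
            (kind == "drChe" and a.fingerprint is not None)
            or (kind == "drSE")
            or (kind == "drTar" and bool(a.targets))
        )
        if defined_self:
            values[i, i] = 1.0
        for j in range(i + 1, n):
            v = pair(a, drugs[ids[j]])
            if v is not None:
                values[i, j] = values[j, i] = v
    return SimilarityMatrix(kind=kind, ids=ids, values=values)
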