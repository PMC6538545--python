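"""Combined drug-disease similarity features.

A query pair (drug i, disease i') is represented by comparing it with every
known association (drug j, disease j'): each of the four drug kernels is
combined with each of the three disease kernels by the geometric mean
sqrt(S_dr(i,j) * S_di(i',j')), giving 12 values per known association, and
each of the 12 indices is aggregated across the known associations by max
(default; "how close is the query to its nearest known association") or mean.

Feature order is drug-kernel-major over the Cartesian product
(drChe, drSE, drGO, drTar) x (diGO, diHPO, diPhe).
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .entities import AssociationSet
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

DRUG_KERNELS = ("drChe", "drSE", "drGO", "drTar")
DISEASE_KERNELS = ("diGO", "diHPO", "diPhe")
FEATURE_NAMES = tuple(f"{dk}_{sk}" for dk in DRUG_KERNELS for sk in DISEASE_KERNELS)
N_FEATURES = len(FEATURE_NAMES)  # 12


class FeatureUndefinedError(ValueError):
    """No known association yields a defined value for some feature index."""


def combine_single(drug_sim: float, disease_sim: float) -> float:
    """Geometric mean sqrt(drug_sim * disease_sim) of one kernel combination."""
    if drug_sim < 0 or disease_sim < 0:
        raise ValueError("similarities must be non-negative")
    return math.sqrt(drug_sim * disease_sim)


def feature_vector(
    query: tuple[str, str],
    known: AssociationSet,
    matrices: Mapping[str, SimilarityMatrix],
    aggregator: str = "max",
    exclude_self: bool = False,
) -> np.ndarray:
    """The 12-dimensional combined similarity vector for one query pair.

    With ``exclude_self`` the query's own entry, if present in ``known``, is
    removed before aggregation — required during training so a labelled
    positive is not compared against itself (every feature would trivially
    saturate at 1).  Known associations with an undefined kernel value are
    skipped for the affected index only; an index left with no defined value
    raises :class:`FeatureUndefinedError`.
    """
    if aggregator not in ("max", "mean"):
        raise ValueError(f"aggregator must be 'max' or 'mean', not {aggregator!r}")
    drug_id, disease_id = query
    assoc = known.sorted_pairs()
    if exclude_self:
        assoc = [p for p in assoc if p != query]
    if not assoc:
        raise FeatureUndefinedError(f"no known associations to compare {query} against")

    known_drugs = [d for d, _ in assoc]
    known_diseases = [s for _, s in assoc]
    # (4, K) drug similarities to the known drugs; (3, K) disease similarities
    dr = np.stack([matrices[k].rows(drug_id, known_drugs) for k in DRUG_KERNELS])
    di = np.stack([matrices[k].rows(disease_id, known_diseases) for k in DISEASE_KERNELS])
    # (4, 3, K) geometric means; NaN propagates from undefined kernel values
    combined = np.sqrt(dr[:, None, :] * di[None, :, :])

    with np.errstate(invalid="ignore"):
        if aggregator == "max":
            agg = np.nanmax(combined, axis=2)
        else:
            agg = np.nanmean(combined, axis=2)
    flat = agg.reshape(N_FEATURES)
    if np.isnan(flat).any():
        missing = [FEATURE_NAMES[i] for i in np.flatnonzero(np.isnan(flat))]
        raise FeatureUndefinedError(
            f"pair {query}: no defined value for feature(s) {missing}"
        )
    return flat


def build_feature_matrix(
    pairs: Iterable[tuple[str, str]],
    known: AssociationSet,
    matrices: Mapping[str, SimilarityMatrix],
    aggregator: str = "max",
    leakage_mode: str = "predict",
) -> pd.DataFrame:
    """Feature rows for a list of query pairs.

    ``leakage_mode='train'`` excludes each pair's own entry from the known
    set (only pairs actually present in ``known`` are affected);
    ``'predict'`` never excludes.  Pairs with an undefined feature are
    dropped with a logged reason; the returned frame carries columns
    ``drug_id``, ``disease_id`` and the 12 named features, in input order.
    """
    if leakage_mode not in ("train", "predict"):
        raise ValueError(f"leakage_mode must be 'train' or 'predict', not {leakage_mode!r}")
    rows = []
    index = []
    for pair in pairs:
        exclude = leakage_mode == "train" and pair in known
        try:
            vec = feature_vector(pair, known, matrices, aggregator, exclude_self=exclude)
        except FeatureUndefinedError as exc:
            logger.warning("dropping pair %s: %s", pair, exc)
            continue
        index.append(pair)
        rows.append(vec)
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    df.insert(0, "drug_id", [d for d, _ in index])
    df.insert(1, "disease_id", [s for _, s in index])
    return df


def feature_array(df: pd.DataFrame) -> np.ndarray:
    """The bare (n, 12) feature block of a feature frame."""
    return df[list(FEATURE_NAMES)].to_numpy(float)
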