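"""Ontology-backed semantic similarity: information content, Resnik, BMA.

An :class:`OntologyDAG` holds the is_a hierarchy of GO or HPO terms (child ->
parent edges; other relation types are ignored and obsolete terms dropped).
Information content is the corpus-frequency form IC(t) = -ln p(t), with
annotation counts propagated through the ancestor closure: each annotated
entity counts once per term in the closure of its annotation set, so p(root)
is always 1 and IC(root) = 0.

Term-level similarity is Resnik's most-informative-common-ancestor IC,
normalized by the corpus maximum IC so values lie in [0, 1] on the common
scale the geometric-mean feature combination requires.  Entity-level
similarity pools an entity's term set (a drug's or disease's genes' GO
annotations, or a disease's direct HPO terms) and applies the best-match
average over pairwise Resnik values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet

from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)


class OntologyDAG:
    """Acyclic is_a hierarchy; edges run child -> parent."""

    def __init__(self, edges: Iterable[tuple[str, str]], terms: Iterable[str] = ()):
        g = nx.DiGraph()
        g.add_nodes_from(terms)
        g.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology contains an is_a cycle")
        self.graph = g
        self._ancestors: dict[str, frozenset[str]] = {}

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def roots(self) -> set[str]:
        return {t for t in self.graph.nodes if self.graph.out_degree(t) == 0}

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def ancestors(self, term: str) -> frozenset[str]:
        """All strict ancestors of ``term`` (transitive is_a closure)."""
        cached = self._ancestors.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self.graph, term))
            self._ancestors[term] = cached
        return cached

    def closure(self, terms: Iterable[str]) -> set[str]:
        """Terms plus all their ancestors."""
        out: set[str] = set()
        for t in terms:
            out.add(t)
            out |= self.ancestors(t)
        return out

    def __contains__(self, term: str) -> bool:
        return term in self.graph


def load_obo(path: str | Path) -> OntologyDAG:
    """Parse an OBO 1.2/1.4 flat file, keeping is_a edges of non-obsolete terms."""
    g = obonet.read_obo(str(path))
    edges = []
    terms = []
    for node, data in g.nodes(data=True):
        if data.get("is_obsolete") in ("true", True):
            continue
        terms.append(node)
    keep = set(terms)
    for child, parent, key in g.edges(keys=True):
        if key == "is_a" and child in keep and parent in keep:
            edges.append((child, parent))
    return OntologyDAG(edges=edges, terms=terms)


def write_obo(dag: OntologyDAG, path: str | Path, ontology_name: str = "synthetic") -> None:
    """Write a minimal OBO 1.2 file (id/name/is_a stanzas)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        fh.write(f"ontology: {ontology_name}\n")
        for term in sorted(dag.terms):
            fh.write(f"\n[Term]\nid: {term}\nname: {term}\n")
            for parent in sorted(dag.parents(term)):
                fh.write(f"is_a: {parent}\n")


@dataclass
class InformationContentTable:
    """Term -> IC map plus the corpus maximum used for normalization."""

    ic: dict[str, float]
    max_ic: float

    def __contains__(self, term: str) -> bool:
        return term in self.ic


def compute_ic(
    dag: OntologyDAG, annotations: Mapping[str, Iterable[str]]
) -> InformationContentTable:
    """Corpus information content from entity -> term annotations.

    Counts use the annotated-entity closure: an entity contributes once to
    every term in the ancestor closure of its annotation set.  Annotations to
    unknown terms are skipped with a warning.  Terms never reached by any
    annotation get no IC (undefined).
    """
    counts: dict[str, int] = {}
    n_annotated = 0
    for entity, terms in annotations.items():
        known = [t for t in terms if t in dag]
        unknown = set(terms) - set(known)
        if unknown:
            logger.warning("entity %s: skipping unknown term(s) %s", entity, sorted(unknown))
        if not known:
            continue
        n_annotated += 1
        for t in dag.closure(known):
            counts[t] = counts.get(t, 0) + 1
    if n_annotated == 0:
        raise ValueError("no usable annotations")
    ic = {t: -math.log(c / n_annotated) for t, c in counts.items()}
    return InformationContentTable(ic=ic, max_ic=max(ic.values()))


def resnik(
    term_a: str, term_b: str, dag: OntologyDAG, ic: InformationContentTable
) -> float | None:
    """Normalized Resnik similarity: IC of the MICA divided by the corpus max IC.

    Returns None when the two terms share no common ancestor with defined IC
    (e.g. disjoint sub-ontologies).  A corpus whose terms all have IC 0
    (degenerate single-path annotations) yields 0 everywhere.
    """
    if term_a not in dag or term_b not in dag:
        raise KeyError(f"term not in ontology: {term_a if term_a not in dag else term_b}")
    common = (dag.ancestors(term_a) | {term_a}) & (dag.ancestors(term_b) | {term_b})
    ics = [ic.ic[t] for t in common if t in ic.ic]
    if not ics:
        return None
    if ic.max_ic <= 0:
        return 0.0
    return max(ics) / ic.max_ic


def bma(
    terms_a: Sequence[str],
    terms_b: Sequence[str],
    pairwise: Callable[[str, str], float | None],
) -> float | None:
    """Best-match average of a pairwise term similarity.

    Averages the row maxima (best match in B for each a) and the column
    maxima (best match in A for each b), then averages the two means.  Pairs
    with undefined similarity are skipped; a term with no defined partner is
    dropped from its mean.  Returns None when nothing is defined.
    """
    ta, tb = list(terms_a), list(terms_b)
    if not ta or not tb:
        return None
    sim = np.full((len(ta), len(tb)), np.nan)
    for i, a in enumerate(ta):
        for j, b in enumerate(tb):
            v = pairwise(a, b)
            if v is not None:
                sim[i, j] = v
    if np.all(np.isnan(sim)):
        return None
    with np.errstate(invalid="ignore"):
        row_max = np.nanmax(sim, axis=1)
        col_max = np.nanmax(sim, axis=0)
    row_mean = float(np.nanmean(row_max))
    col_mean = float(np.nanmean(col_max))
    return (row_mean + col_mean) / 2.0


def entity_semantic_similarity(
    terms_a: Iterable[str],
    terms_b: Iterable[str],
    dag: OntologyDAG,
    ic: InformationContentTable,
) -> float | None:
    """BMA over pairwise normalized Resnik values of two pooled term sets."""
    ta = sorted(set(terms_a) & dag.terms)
    tb = sorted(set(terms_b) & dag.terms)
    if not ta or not tb:
        return None
    cache: dict[tuple[str, str], float | None] = {}

    def pw(a: str, b: str) -> float | None:
        key = (a, b) if a <= b else (b, a)
        if key not in cache:
            cache[key] = resnik(key[0], key[1], dag, ic)
        return cache[key]

    return bma(ta, tb, pw)


def pool_gene_terms(
    genes: Iterable[str], annotations: Mapping[str, Iterable[str]]
) -> set[str]:
    """Union of the annotation term sets of an entity's genes."""
    pooled: set[str] = set()
    for g in genes:
        pooled |= set(annotations.get(g, ()))
    return pooled


def build_semantic_matrix(
    term_sets: Mapping[str, Iterable[str]],
    dag: OntologyDAG,
    ic: InformationContentTable,
    kind: str,
) -> SimilarityMatrix:
    """Entity-by-entity semantic similarity matrix (kinds drGO, diGO, diHPO).

    The diagonal of an entity with a non-empty in-ontology term set is forced
    to exactly 1 (BMA of a set with itself is its max-normalized
    self-similarity; the unit diagonal keeps all kernels on the convention
    that an entity is maximally similar to itself).  Entities with empty or
    fully out-of-ontology term sets get NaN rows.
    """
    ids = sorted(term_sets)
    pooled = {e: sorted(set(term_sets[e]) & dag.terms) for e in ids}
    n = len(ids)
    values = np.full((n, n), np.nan)
    # shared pairwise-term cache across all entity pairs
    cache: dict[tuple[str, str], float | None] = {}

    def pw(a: str, b: str) -> float | None:
        key = (a, b) if a <= b else (b, a)
        if key not in cache:
            cache[key] = resnik(key[0], key[1], dag, ic)
        return cache[key]

    for i, id_a in enumerate(ids):
        if pooled[id_a]:
            values[i, i] = 1.0
        for j in range(i + 1, n):
            id_b = ids[j]
            if not pooled[id_a] or not pooled[id_b]:
                continue
            v = bma(pooled[id_a], pooled[id_b], pw)
            if v is not None:
                values[i, j] = values[j, i] = min(v, 1.0)
    return SimilarityMatrix(kind=kind, ids=ids, values=values)
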