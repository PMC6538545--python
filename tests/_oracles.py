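"""Independent brute-force oracles used to verify the implementation.

Everything here is deliberately naive and self-contained: full-table dynamic
programming, exhaustive enumeration, direct set counting.  Nothing imports
from simrepo except static scoring data (the substitution matrix values).
"""

from __future__ import annotations

import math

import numpy as np
from Bio.Align import substitution_matrices

NEG_INF = float("-inf")


def sw_affine_score(seq_a: str, seq_b: str, matrix_name: str = "BLOSUM62",
                    gap_open: float = -10.0, gap_extend: float = -1.0) -> float:
    """Full-table Gotoh local alignment (gap of length L costs open + (L-1)*extend)."""
    sub = substitution_matrices.load(matrix_name)
    n, m = len(seq_a), len(seq_b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG_INF)  # gap in seq_a (consume seq_b)
    F = np.full((n + 1, m + 1), NEG_INF)  # gap in seq_b (consume seq_a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = sub[seq_a[i - 1], seq_b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def auc_pairwise(scores, labels) -> float:
    """AUC as the fraction of concordant positive-negative pairs, ties 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


# --- ontology -------------------------------------------------------------


def ancestors_brute(parents: dict[str, set[str]], term: str) -> set[str]:
    """Strict ancestors by recursive parent traversal."""
    out: set[str] = set()
    stack = list(parents.get(term, ()))
    while stack:
        t = stack.pop()
        if t not in out:
            out.add(t)
            stack.extend(parents.get(t, ()))
    return out


def ic_brute(parents: dict[str, set[str]], annotations: dict[str, set[str]]) -> dict[str, float]:
    """IC by direct set counting over per-entity annotation closures."""
    counts: dict[str, int] = {}
    entities = [e for e, ts in annotations.items() if ts]
    for _, terms in ((e, annotations[e]) for e in entities):
        closure: set[str] = set()
        for t in terms:
            closure.add(t)
            closure |= ancestors_brute(parents, t)
        for t in closure:
            counts[t] = counts.get(t, 0) + 1
    return {t: -math.log(c / len(entities)) for t, c in counts.items()}


def resnik_brute(parents: dict[str, set[str]], ic: dict[str, float],
                 a: str, b: str) -> float | None:
    """Normalized MICA IC by exhaustive common-ancestor enumeration."""
    ca = (ancestors_brute(parents, a) | {a}) & (ancestors_brute(parents, b) | {b})
    vals = [ic[t] for t in ca if t in ic]
    if not vals:
        return None
    max_ic = max(ic.values())
    return max(vals) / max_ic if max_ic > 0 else 0.0


def bma_brute(sim: np.ndarray) -> float:
    """Best-match average of a fully defined pairwise similarity matrix."""
    row = np.mean([max(r) for r in sim])
    col = np.mean([max(c) for c in sim.T])
    return (row + col) / 2.0


# --- features -------------------------------------------------------------


def feature_vector_brute(query, known_pairs, matrices, aggregator="max",
                         exclude_self=False) -> list[float]:
    """Triple-loop enumeration over (association x drug kernel x disease kernel)."""
    drug_kernels = ("drChe", "drSE", "drGO", "drTar")
    disease_kernels = ("diGO", "diHPO", "diPhe")
    i, ip = query
    assoc = sorted(p for p in known_pairs if not (exclude_self and p == query))
    out = []
    for dk in drug_kernels:
        for sk in disease_kernels:
            vals = []
            for (j, jp) in assoc:
                a = matrices[dk].get(i, j)
                b = matrices[sk].get(ip, jp)
                if math.isnan(a) or math.isnan(b):
                    continue
                vals.append(math.sqrt(a * b))
            if not vals:
                out.append(float("nan"))
            elif aggregator == "max":
                out.append(max(vals))
            else:
                out.append(sum(vals) / len(vals))
    return out


def random_dag(rng: np.random.Generator, n_terms: int, max_parents: int = 2):
    """Random rooted DAG as a child->parents map; term 'T0' is the root."""
    names = [f"T{i}" for i in range(n_terms)]
    parents: dict[str, set[str]] = {names[0]: set()}
    for i in range(1, n_terms):
        k = int(rng.integers(1, max_parents + 1))
        choices = rng.choice(i, size=min(k, i), replace=False)
        parents[names[i]] = {names[int(c)] for c in choices}
    return parents
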