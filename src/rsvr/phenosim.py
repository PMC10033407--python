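"""Ontology-based family phenotype similarity and enrichment.

Families are annotated with terms from a single-rooted is-a ontology
(HPO-like, parsed from OBO).  Term information content (IC) is the
negative log of the fraction of families whose ancestor-closed term set
contains the term; Resnik similarity of two terms is the maximum IC over
their common ancestors, and family-level similarity is the symmetric
best-match average over assigned terms.

Two permutation procedures are provided:

* :func:`family_cluster_test` -- is a designated set of families more
  phenotypically similar to each other than random subsets of the cohort?
* :func:`term_enrichment` -- which terms shared by most of the target
  families are enriched relative to the rest of the cohort?  Candidate
  terms (present in at least ``min_support`` targets, redundant ancestors
  removed) are ordered by two-sided Fisher exact p-values and compared,
  rank by rank, with the fifth percentile of permuted label orderings,
  declaring significance top-down while every better-ranked term is also
  significant.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from math import comb, inf, log
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.stats import fisher_exact

__all__ = [
    "OntologyDag",
    "FamilyPhenotype",
    "EnrichmentResult",
    "parse_obo",
    "information_content",
    "build_ic_map",
    "resnik_similarity",
    "family_cluster_test",
    "term_enrichment",
]

logger = logging.getLogger(__name__)


class OntologyDag:
    """Directed acyclic is-a graph with a single root; edges child->parent."""

    def __init__(self, edges: Iterable[tuple[str, str]], terms: Iterable[str] = ()):
        g = nx.DiGraph()
        g.add_nodes_from(terms)
        g.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology contains an is-a cycle")
        roots = [n for n in g.nodes if g.out_degree(n) == 0]
        if len(roots) != 1:
            raise ValueError(f"ontology must have exactly one root, found {roots}")
        self.graph = g
        self.root = roots[0]
        self._ancestors: dict[str, frozenset[str]] = {}

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of a term, including the term itself."""
        cached = self._ancestors.get(term)
        if cached is None:
            if term not in self.graph:
                raise KeyError(f"unknown term {term!r}")
            cached = frozenset(nx.descendants(self.graph, term)) | {term}
            self._ancestors[term] = cached
        return cached

    def descendants(self, term: str) -> frozenset[str]:
        return frozenset(nx.ancestors(self.graph, term))

    def closure(self, terms: Iterable[str]) -> frozenset[str]:
        out: set[str] = set()
        for t in terms:
            out |= self.ancestors(t)
        return frozenset(out)


def parse_obo(source: str) -> OntologyDag:
    """Parse a minimal OBO document (id / is_a / is_obsolete) into a DAG."""
    text = source
    if "\n" not in source and source.endswith(".obo"):
        with open(source) as fh:
            text = fh.read()
    terms: list[str] = []
    edges: list[tuple[str, str]] = []
    current: str | None = None
    obsolete = False
    in_term = False
    for raw in text.splitlines():
        line = raw.strip()
        if line == "[Term]":
            in_term, current, obsolete = True, None, False
        elif line.startswith("[") and line.endswith("]"):
            in_term = False
        elif in_term and line.startswith("id:"):
            current = line[3:].strip()
        elif in_term and line.startswith("is_obsolete:") and "true" in line:
            obsolete = True
            if current in terms:
                terms.remove(current)
        elif in_term and line.startswith("is_a:") and current and not obsolete:
            parent = line[5:].split("!")[0].strip()
            edges.append((current, parent))
        elif in_term and not line and current and not obsolete:
            terms.append(current)
            current = None
    if current and not obsolete:
        terms.append(current)
    return OntologyDag(edges, terms)


@dataclass(frozen=True)
class FamilyPhenotype:
    family_id: str
    terms: frozenset[str]

    def closed(self, dag: OntologyDag) -> frozenset[str]:
        return dag.closure(self.terms)


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    p_value: float
    rank: int
    null_bound: float
    significant: bool


def build_ic_map(
    families: Sequence[FamilyPhenotype], dag: OntologyDag
) -> dict[str, float]:
    """IC for every ontology term from family closed-set frequencies.

    Terms annotated to no family get a pseudo-frequency of 1 / (2 N).
    """
    if not families:
        raise ValueError("need at least one family")
    n = len(families)
    counts: dict[str, int] = {}
    for fam in families:
        for t in fam.closed(dag):
            counts[t] = counts.get(t, 0) + 1
    pseudo = 1.0 / (2 * n)
    out = {}
    for term in dag.terms:
        freq = counts.get(term, 0) / n
        out[term] = -log(freq) if freq > 0 else -log(pseudo)
    return out


def information_content(
    term: str, families: Sequence[FamilyPhenotype], dag: OntologyDag
) -> float:
    return build_ic_map(families, dag)[term]


def _term_sim(t1: str, t2: str, dag: OntologyDag, ic: Mapping[str, float]) -> float:
    common = dag.ancestors(t1) & dag.ancestors(t2)
    return max(ic[a] for a in common) if common else 0.0


def resnik_similarity(
    f1: FamilyPhenotype,
    f2: FamilyPhenotype,
    dag: OntologyDag,
    ic: Mapping[str, float],
    aggregate: str = "best_match_average",
) -> float:
    """Family-level Resnik similarity (symmetric)."""
    if not f1.terms or not f2.terms:
        logger.warning(
            "empty term set for family %s or %s: similarity 0",
            f1.family_id,
            f2.family_id,
        )
        return 0.0
    sims = {
        (a, b): _term_sim(a, b, dag, ic) for a in f1.terms for b in f2.terms
    }
    if aggregate == "max_pairwise":
        return max(sims.values())
    if aggregate != "best_match_average":
        raise ValueError(f"unknown aggregate {aggregate!r}")
    fwd = np.mean([max(sims[a, b] for b in f2.terms) for a in f1.terms])
    rev = np.mean([max(sims[a, b] for a in f1.terms) for b in f2.terms])
    return float((fwd + rev) / 2)


def _pairwise_matrix(
    families: Sequence[FamilyPhenotype], dag: OntologyDag, ic: Mapping[str, float]
) -> np.ndarray:
    n = len(families)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = resnik_similarity(families[i], families[j], dag, ic)
    return m


def _mean_pairwise(matrix: np.ndarray, idx: np.ndarray) -> float:
    sub = matrix[np.ix_(idx, idx)]
    k = len(idx)
    return float(sub.sum() / (k * (k - 1))) if k > 1 else 0.0


def family_cluster_test(
    target_ids: Sequence[str],
    families: Sequence[FamilyPhenotype],
    dag: OntologyDag,
    n_perm: int = 10_000,
    seed: int = 0,
    ic: Mapping[str, float] | None = None,
) -> float:
    """Permutation p-value for phenotypic clustering of target families.

    Statistic: mean pairwise similarity among the ``k`` targets.  Null:
    the same statistic over random k-subsets of the cohort.  The p-value
    uses the add-one correction (1 + #{null >= observed}) / (1 + n_perm);
    when the number of distinct k-subsets is small, all subsets are
    enumerated instead and the p-value is exact.
    """
    ids = [f.family_id for f in families]
    if len(set(target_ids)) < 2:
        raise ValueError("need at least two target families")
    missing = set(target_ids) - set(ids)
    if missing:
        raise ValueError(f"unknown target families: {sorted(missing)}")
    k, n = len(target_ids), len(families)
    if k > n:
        raise ValueError("more targets than families")
    ic = ic if ic is not None else build_ic_map(families, dag)
    matrix = _pairwise_matrix(families, dag, ic)
    pos = {fid: i for i, fid in enumerate(ids)}
    observed = _mean_pairwise(matrix, np.array([pos[t] for t in target_ids]))
    if comb(n, k) <= n_perm:
        stats = [
            _mean_pairwise(matrix, np.array(sub))
            for sub in itertools.combinations(range(n), k)
        ]
        return sum(s >= observed for s in stats) / len(stats)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        idx = rng.choice(n, size=k, replace=False)
        if _mean_pairwise(matrix, idx) >= observed:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def _fisher_cache_factory():
    cache: dict[tuple[int, int, int, int], float] = {}

    def p(a: int, k: int, b: int, m: int) -> float:
        key = (a, k, b, m)
        if key not in cache:
            cache[key] = float(
                fisher_exact([[a, k - a], [b, m - b]], alternative="two-sided")[1]
            )
        return cache[key]

    return p


def _candidate_pvals(
    target_idx: set[int],
    closures: Sequence[frozenset[str]],
    dag: OntologyDag,
    min_support: int,
    fisher_p,
    term_totals: Mapping[str, int],
) -> list[tuple[float, str]]:
    """Ranked (p, term) list for one assignment of target labels."""
    k = len(target_idx)
    m = len(closures) - k
    support: dict[str, int] = {}
    for i in target_idx:
        for t in closures[i]:
            support[t] = support.get(t, 0) + 1
    candidates = {t for t, c in support.items() if c >= min_support}
    # redundancy rule: drop a term when a descendant candidate has the same
    # target frequency
    keep = set(candidates)
    for t in candidates:
        for d in dag.descendants(t):
            if d in candidates and support[d] == support[t]:
                keep.discard(t)
                break
    pvals = []
    for t in sorted(keep):
        a = support[t]
        b = term_totals[t] - a
        pvals.append((fisher_p(a, k, b, m), t))
    pvals.sort()
    return pvals


def term_enrichment(
    target_ids: Sequence[str],
    families: Sequence[FamilyPhenotype],
    dag: OntologyDag,
    min_support: int = 3,
    n_perm: int = 10_000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Step-down permutation-calibrated term enrichment; see module docs."""
    ids = [f.family_id for f in families]
    pos = {fid: i for i, fid in enumerate(ids)}
    target_idx = {pos[t] for t in target_ids}
    k = len(target_idx)
    annotated = sum(1 for i in target_idx if families[i].terms)
    if annotated < min_support:
        return []
    closures = [f.closed(dag) - {dag.root} for f in families]
    term_totals: dict[str, int] = {}
    for c in closures:
        for t in c:
            term_totals[t] = term_totals.get(t, 0) + 1
    fisher_p = _fisher_cache_factory()
    observed = _candidate_pvals(
        target_idx, closures, dag, min_support, fisher_p, term_totals
    )
    if not observed:
        return []

    rng = np.random.default_rng(seed)
    n = len(families)
    depth = len(observed)
    null = np.full((n_perm, depth), 1.0)
    for r in range(n_perm):
        perm_idx = set(rng.choice(n, size=k, replace=False).tolist())
        perm_pvals = _candidate_pvals(
            perm_idx, closures, dag, min_support, fisher_p, term_totals
        )
        for j, (p, _) in enumerate(perm_pvals[:depth]):
            null[r, j] = p
    bounds = np.percentile(null, 5, axis=0)

    results = []
    still_significant = True
    for rank, (p, term) in enumerate(observed, start=1):
        bound = float(bounds[rank - 1])
        sig = still_significant and p <= bound
        results.append(
            EnrichmentResult(
                term=term, p_value=p, rank=rank, null_bound=bound, significant=sig
            )
        )
        still_significant = sig
    return results
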