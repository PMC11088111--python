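"""Hierarchy-aware GO term overrepresentation.

The DAG is read from OBO 1.2; ``is_a`` edges are always followed and
``part_of`` optionally.  Annotation counts are ancestor-propagated.  Two
test algorithms are provided:

``classic``
    Independent one-sided Fisher (hypergeometric upper tail) per term.
``elim``
    Terms are visited from the most specific depth upward; when a term's
    raw p-value passes ``elim_cutoff`` its annotated genes are removed from
    all ancestors before those are tested, decorrelating nested terms.

Multiple testing is a Bonferroni factor equal to the number of tested
terms (after the minimum-annotation filter), capped at 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

__all__ = [
    "GoDag",
    "Gene2Go",
    "EnrichmentResult",
    "parse_obo",
    "read_gene2go_tsv",
    "build_gene2go",
    "fisher_overrep",
    "run_enrichment",
    "results_to_dataframe",
]

NAMESPACE_ALIASES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
    "BP": "BP",
    "MF": "MF",
    "CC": "CC",
}


@dataclass(slots=True)
class GoDag:
    """GO term hierarchy: names, namespaces and parent edges."""

    names: dict[str, str] = field(default_factory=dict)
    namespaces: dict[str, str] = field(default_factory=dict)
    parents: dict[str, set[str]] = field(default_factory=dict)
    alt_ids: dict[str, str] = field(default_factory=dict)
    _ancestors: dict[str, frozenset[str]] = field(default_factory=dict)
    _depths: dict[str, int] = field(default_factory=dict)

    def resolve(self, term: str) -> str | None:
        """Primary id for ``term`` (follows alt_id), or None if unknown."""
        if term in self.names:
            return term
        return self.alt_ids.get(term)

    def __contains__(self, term: str) -> bool:
        return self.resolve(term) is not None

    def ancestors(self, term: str) -> frozenset[str]:
        """All strict ancestors of ``term``."""
        term = self.resolve(term) or term
        cached = self._ancestors.get(term)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents.get(t, ()))
        result = frozenset(out)
        self._ancestors[term] = result
        return result

    def depth(self, term: str) -> int:
        """Longest path from a root (term with no parents) to ``term``."""
        term = self.resolve(term) or term
        cached = self._depths.get(term)
        if cached is not None:
            return cached
        parents = self.parents.get(term, set())
        d = 0 if not parents else 1 + max(self.depth(p) for p in parents)
        self._depths[term] = d
        return d

    def terms_in_namespace(self, namespace: str) -> set[str]:
        ns = NAMESPACE_ALIASES.get(namespace, namespace)
        return {t for t, v in self.namespaces.items() if v == ns}

    def validate_acyclic(self) -> None:
        """Raise on cycles or dangling parent references."""
        WHITE, GREY, BLACK = 0, 1, 2
        color = dict.fromkeys(self.names, WHITE)
        for root in self.names:
            if color[root] != WHITE:
                continue
            stack: list[tuple[str, Iterable[str]]] = [(root, iter(self.parents.get(root, ())))]
            color[root] = GREY
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if p not in self.names:
                        raise ValueError(f"dangling parent {p!r} of {node!r}")
                    if color[p] == GREY:
                        raise ValueError(f"cycle through {p!r}")
                    if color[p] == WHITE:
                        color[p] = GREY
                        stack.append((p, iter(self.parents.get(p, ()))))
                        advanced = True
                        break
                if not advanced:
                    color[node] = BLACK
                    stack.pop()


def parse_obo(path, include_part_of: bool = False) -> GoDag:
    """Parse an OBO 1.2 file into a :class:`GoDag`.

    Obsolete terms are skipped; ``alt_id`` entries resolve to their primary
    term.  The resulting graph is checked for cycles and dangling parents.
    """
    dag = GoDag()
    term: dict[str, object] | None = None

    def commit() -> None:
        if term is None or term.get("obsolete"):
            return
        tid = term.get("id")
        if not tid:
            return
        dag.names[tid] = str(term.get("name", tid))
        ns = NAMESPACE_ALIASES.get(str(term.get("namespace", "")), str(term.get("namespace", "")))
        dag.namespaces[tid] = ns
        dag.parents[tid] = set(term.get("parents", set()))
        for alt in term.get("alt_ids", ()):
            dag.alt_ids[alt] = tid

    with open(path) as fh:
        in_term = False
        for raw in fh:
            line = raw.strip()
            if line.startswith("["):
                commit()
                term = {"parents": set(), "alt_ids": []} if line == "[Term]" else None
                in_term = line == "[Term]"
                continue
            if not in_term or term is None or not line or ":" not in line:
                continue
            key, value = line.split(":", 1)
            value = value.strip()
            if key == "id":
                term["id"] = value
            elif key == "name":
                term["name"] = value
            elif key == "namespace":
                term["namespace"] = value
            elif key == "alt_id":
                term["alt_ids"].append(value)  # type: ignore[union-attr]
            elif key == "is_obsolete" and value.startswith("true"):
                term["obsolete"] = True
            elif key == "is_a":
                term["parents"].add(value.split("!")[0].strip())  # type: ignore[union-attr]
            elif key == "relationship" and include_part_of:
                parts = value.split()
                if len(parts) >= 2 and parts[0] == "part_of":
                    term["parents"].add(parts[1])  # type: ignore[union-attr]
    commit()
    dag.validate_acyclic()
    return dag


class Gene2Go:
    """Gene → direct GO terms, with ancestor propagation on demand."""

    def __init__(self, direct: Mapping[str, set[str]], dag: GoDag):
        self.direct = {g: set(t) for g, t in direct.items()}
        self.dag = dag

    def propagated(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for gene, terms in self.direct.items():
            full = set(terms)
            for t in terms:
                full |= self.dag.ancestors(t)
            out[gene] = full
        return out

    def genes(self) -> set[str]:
        return set(self.direct)


def read_gene2go_tsv(path) -> dict[str, set[str]]:
    """Read a gene→term TSV (columns: gene, term[, source]); no header."""
    table: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"bad gene2go row: {line!r}")
            table.setdefault(parts[0], set()).add(parts[1])
    return table


def build_gene2go(
    sources: Sequence[Mapping[str, set[str]]], dag: GoDag
) -> Gene2Go:
    """Union gene→term tables from several sources, resolving alt_ids.

    Terms that cannot be resolved in the DAG are dropped (count logged).
    """
    merged: dict[str, set[str]] = {}
    dropped = 0
    for source in sources:
        for gene, terms in source.items():
            bucket = merged.setdefault(gene, set())
            for t in terms:
                primary = dag.resolve(t)
                if primary is None:
                    dropped += 1
                else:
                    bucket.add(primary)
    if dropped:
        logger.warning("dropped %d annotations with unknown terms", dropped)
    merged = {g: t for g, t in merged.items() if t}
    g2g = Gene2Go(merged, dag)
    g2g.n_dropped = dropped  # type: ignore[attr-defined]
    return g2g


def fisher_overrep(study_count: int, study_size: int, term_count: int, universe_size: int) -> float:
    """One-sided hypergeometric upper tail P[X >= study_count]."""
    if not (
        0 <= study_count <= min(study_size, term_count)
        and term_count <= universe_size
        and study_size <= universe_size
    ):
        raise ValueError(
            f"inconsistent counts k={study_count} n={study_size} "
            f"K={term_count} N={universe_size}"
        )
    return float(hypergeom.sf(study_count - 1, universe_size, term_count, study_size))


@dataclass(slots=True)
class EnrichmentResult:
    term: str
    name: str
    annotated: int
    significant: int
    expected: float
    p_raw: float
    p_bonferroni: float
    algorithm: str


def run_enrichment(
    study: set[str],
    universe: set[str],
    g2g: Gene2Go,
    dag: GoDag,
    namespace: str = "BP",
    algorithm: str = "classic",
    min_genes: int = 10,
    elim_cutoff: float = 0.01,
) -> list[EnrichmentResult]:
    """Test GO-term overrepresentation of ``study`` against ``universe``.

    The universe should be the annotated gene background for the tested
    namespace; genes without a term in that namespace are ignored.  Terms
    annotated to fewer than ``min_genes`` universe genes are excluded
    before testing, and the Bonferroni factor equals the number of terms
    actually tested.  Results are sorted by raw p.
    """
    if not study or not universe:
        raise ValueError("empty study or universe")
    if not study <= universe:
        raise ValueError("study set must be a subset of the universe")
    if algorithm not in ("classic", "elim"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    ns = NAMESPACE_ALIASES.get(namespace, namespace)

    propagated = g2g.propagated()
    term_genes: dict[str, set[str]] = {}
    for gene in universe:
        for t in propagated.get(gene, ()):
            if dag.namespaces.get(t) == ns:
                term_genes.setdefault(t, set()).add(gene)

    annotated_universe = {g for genes in term_genes.values() for g in genes}
    study_ns = study & annotated_universe
    if not study_ns:
        raise ValueError("no study gene has an annotation in this namespace")
    n = len(study_ns)
    N = len(annotated_universe)

    tested = {t: g for t, g in term_genes.items() if len(g) >= min_genes}
    n_tested = len(tested)
    if n_tested == 0:
        return []

    results: list[EnrichmentResult] = []

    if algorithm == "classic":
        for t, genes in tested.items():
            K = len(genes)
            k = len(genes & study_ns)
            p = fisher_overrep(k, n, K, N)
            results.append(_mk_result(dag, t, K, k, n, N, p, n_tested, "classic"))
    else:
        removed: dict[str, set[str]] = {t: set() for t in tested}
        order = sorted(tested, key=lambda t: (-dag.depth(t), t))
        for t in order:
            genes = tested[t] - removed[t]
            K = len(genes)
            k = len(genes & study_ns)
            p = fisher_overrep(k, n, K, N) if K > 0 else 1.0
            results.append(_mk_result(dag, t, K, k, n, N, p, n_tested, "elim"))
            if p <= elim_cutoff:
                doomed = tested[t]
                for anc in dag.ancestors(t):
                    if anc in removed:
                        removed[anc] |= doomed

    results.sort(key=lambda r: (r.p_raw, r.term))
    return results


def _mk_result(dag, term, K, k, n, N, p, n_tested, algorithm) -> EnrichmentResult:
    return EnrichmentResult(
        term=term,
        name=dag.names.get(term, term),
        annotated=K,
        significant=k,
        expected=n * K / N,
        p_raw=p,
        p_bonferroni=min(1.0, p * n_tested),
        algorithm=algorithm,
    )


def results_to_dataframe(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "name": r.name,
                "annotated": r.annotated,
                "significant": r.significant,
                "expected": r.expected,
                "p_raw": r.p_raw,
                "p_bonferroni": r.p_bonferroni,
                "algorithm": r.algorithm,
            }
            for r in results
        ]
    )
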